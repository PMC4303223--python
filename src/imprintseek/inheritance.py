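"""Inheritance-mode searches over trio genotypes, including the
imprinted-gene parent-of-origin mode.

The trio classifiers are pure predicates on (child, mother, father)
zygosities. The imprinted-gene mode encodes the parent-of-origin logic:
for a maternally expressed gene, a causative variant manifests only when
on the maternal allele, so the affected child is het or hom-alt, the
unaffected carrier mother is het (she carries it silently on *her*
paternal allele), and the unaffected father is hom-ref — or het, if he
inherited it from his own father. The paternal search mirrors this.

An extended-pedigree checker (`pedigree_origin_consistency`) then asks
whether *any* assignment of parental origins to the carriers' mutant
alleles explains every family member's affected status under full
penetrance — the confirmation step once genotypes beyond the trio are
available.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Set

from .core import (
    CandidateSet,
    ExpressedParent,
    ImprintedRegion,
    InheritanceMode,
    Pedigree,
    VariantRecord,
    Zygosity,
    is_fully_called,
)
from .filters import (
    CohortPattern,
    FilterThresholds,
    excluded_by_cohort,
    genotype_configuration_label,
    is_candidate_deleterious,
    passes_frequency,
    passes_trio_quality,
)


@dataclass(frozen=True)
class TrioGenotypes:
    """Child/mother/father zygosities at one biallelic site."""

    child: Zygosity
    mother: Zygosity
    father: Zygosity

    @classmethod
    def from_variant(
        cls, variant: VariantRecord, child: str, mother: str, father: str
    ) -> "TrioGenotypes":
        return cls(
            child=variant.genotype(child).zygosity,
            mother=variant.genotype(mother).zygosity,
            father=variant.genotype(father).zygosity,
        )


def classify_de_novo(trio: TrioGenotypes, allow_hom_alt: bool = False) -> bool:
    """Child carries a mutation absent from both parents.

    Canonical pattern: child het, both parents hom-ref. ``allow_hom_alt``
    additionally admits a hom-alt child (two independent mutations — or
    more plausibly a genotyping artifact — hence off by default).
    """
    if trio.mother is not Zygosity.HOM_REF or trio.father is not Zygosity.HOM_REF:
        return False
    if trio.child is Zygosity.HET:
        return True
    return allow_hom_alt and trio.child is Zygosity.HOM_ALT


def classify_recessive(
    trio: TrioGenotypes, allow_hom_alt_parent: bool = False
) -> bool:
    """Autosomal recessive: hom-alt child of two het carrier parents.

    The default requires both parents het, matching families with
    unaffected parents; ``allow_hom_alt_parent`` relaxes each parent to
    carrier-or-hom-alt.
    """
    if trio.child is not Zygosity.HOM_ALT:
        return False
    parental_ok = (Zygosity.HET, Zygosity.HOM_ALT) if allow_hom_alt_parent else (Zygosity.HET,)
    return trio.mother in parental_ok and trio.father in parental_ok


def classify_imprinted(trio: TrioGenotypes, expressed_parent: ExpressedParent) -> bool:
    """Parent-of-origin pattern for a variant in an imprinted gene.

    MATERNAL (maternally expressed gene): child het or hom-alt, mother het
    (unaffected carrier), father hom-ref or het. PATERNAL mirrors with the
    parents' roles swapped. Operates on genotypes only; affected status is
    the province of :func:`pedigree_origin_consistency`.
    """
    if expressed_parent is ExpressedParent.MATERNAL:
        carrier, other = trio.mother, trio.father
    elif expressed_parent is ExpressedParent.PATERNAL:
        carrier, other = trio.father, trio.mother
    else:
        raise ValueError("expressed_parent must be MATERNAL or PATERNAL")
    return (
        trio.child in (Zygosity.HET, Zygosity.HOM_ALT)
        and carrier is Zygosity.HET
        and other in (Zygosity.HOM_REF, Zygosity.HET)
    )


def _parent_carrier_state(
    variant: VariantRecord, mother: str, father: str
) -> tuple[bool, bool]:
    return (
        variant.genotype(mother).carries_alt,
        variant.genotype(father).carries_alt,
    )


def unambiguous_parent(
    variant: VariantRecord, mother: str, father: str
) -> Optional[str]:
    """Transmission-based phasing of a child-het variant.

    A variant is unambiguously maternal iff the mother carries it and the
    father does not (and vice versa); carried by both or neither →
    ambiguous (None).
    """
    mo, fa = _parent_carrier_state(variant, mother, father)
    if mo and not fa:
        return "maternal"
    if fa and not mo:
        return "paternal"
    return None


def find_compound_het_pairs(
    gene_variants: Sequence[VariantRecord],
    child: str,
    mother: str,
    father: str,
) -> list[tuple[VariantRecord, VariantRecord]]:
    """Candidate compound-het pairs among one gene's child-het variants.

    Since not every variant can be phased, only pairs *clearly
    incompatible* with trans inheritance are excluded:

    (a) both variants unambiguously inherited from the same parent (cis);
    (b) either variant homozygous-alt in a parent.

    Unphasable pairs are retained. Requires the child het in every input
    variant.
    """
    for v in gene_variants:
        if v.genotype(child).zygosity is not Zygosity.HET:
            raise ValueError(
                f"child {child!r} not heterozygous at {v.chrom}:{v.pos}"
            )
    pairs = []
    for v1, v2 in itertools.combinations(gene_variants, 2):
        if any(
            v.genotype(p).zygosity is Zygosity.HOM_ALT
            for v in (v1, v2)
            for p in (mother, father)
        ):
            continue
        p1 = unambiguous_parent(v1, mother, father)
        p2 = unambiguous_parent(v2, mother, father)
        if p1 is not None and p1 == p2:
            continue
        pairs.append((v1, v2))
    return pairs


# ---------------------------------------------------------------------------
# search drivers


def _mode_label(mode: InheritanceMode) -> str:
    return mode.value


def _apply_variant_gates(
    cand: CandidateSet,
    variants: list[VariantRecord],
    mode: InheritanceMode,
    trio_ids: tuple[str, str, str],
    thresholds: FilterThresholds,
    cohort: Optional[Set[CohortPattern]],
) -> list[VariantRecord]:
    """Quality → deleteriousness → frequency → cohort, with attrition."""
    child, mother, father = trio_ids
    stages = [
        ("trio-quality", lambda v: passes_trio_quality(v, list(trio_ids), thresholds)),
        ("deleterious", is_candidate_deleterious),
        ("frequency", lambda v: passes_frequency(v, mode, thresholds)),
    ]
    if cohort is not None:
        stages.append(
            (
                "cohort-exclusion",
                lambda v: not excluded_by_cohort(
                    v, genotype_configuration_label(v, child, mother, father), cohort
                ),
            )
        )
    surviving = variants
    for name, keep in stages:
        before = len(surviving)
        surviving = [v for v in surviving if keep(v)]
        cand.log_stage(name, before, len(surviving))
    return surviving


def search_de_novo(
    variants: Iterable[VariantRecord],
    pedigree: Pedigree,
    thresholds: Optional[FilterThresholds] = None,
    cohort: Optional[Set[CohortPattern]] = None,
    allow_hom_alt: bool = False,
) -> CandidateSet:
    """De novo search: quality/deleteriousness/rarity gates, then the
    de novo genotype pattern."""
    thresholds = thresholds or FilterThresholds()
    trio_ids = pedigree.trio()
    cand = CandidateSet(mode=InheritanceMode.DE_NOVO)
    pool = _apply_variant_gates(cand, list(variants), cand.mode, trio_ids, thresholds, cohort)
    before = len(pool)
    cand.items = [
        v
        for v in pool
        if classify_de_novo(TrioGenotypes.from_variant(v, *trio_ids), allow_hom_alt)
    ]
    cand.log_stage("genotype-pattern", before, len(cand.items))
    cand.validate()
    return cand


def search_recessive(
    variants: Iterable[VariantRecord],
    pedigree: Pedigree,
    thresholds: Optional[FilterThresholds] = None,
    cohort: Optional[Set[CohortPattern]] = None,
    allow_hom_alt_parent: bool = False,
) -> CandidateSet:
    thresholds = thresholds or FilterThresholds()
    trio_ids = pedigree.trio()
    cand = CandidateSet(mode=InheritanceMode.AUTOSOMAL_RECESSIVE)
    pool = _apply_variant_gates(cand, list(variants), cand.mode, trio_ids, thresholds, cohort)
    before = len(pool)
    cand.items = [
        v
        for v in pool
        if classify_recessive(TrioGenotypes.from_variant(v, *trio_ids), allow_hom_alt_parent)
    ]
    cand.log_stage("genotype-pattern", before, len(cand.items))
    cand.validate()
    return cand


def search_compound_het(
    variants: Iterable[VariantRecord],
    pedigree: Pedigree,
    thresholds: Optional[FilterThresholds] = None,
    cohort: Optional[Set[CohortPattern]] = None,
) -> CandidateSet:
    """Compound-het search: gated child-het variants grouped by gene symbol,
    then paired with the cis / parent-homozygous exclusions.

    Variants lacking a gene symbol cannot be grouped and are skipped.
    """
    thresholds = thresholds or FilterThresholds()
    trio_ids = pedigree.trio()
    child, _, _ = trio_ids
    cand = CandidateSet(mode=InheritanceMode.COMPOUND_HET)
    pool = _apply_variant_gates(cand, list(variants), cand.mode, trio_ids, thresholds, cohort)
    before = len(pool)
    pool = [
        v
        for v in pool
        if v.annotations.gene is not None
        and v.genotype(child).zygosity is Zygosity.HET
    ]
    cand.log_stage("child-het-in-gene", before, len(pool))
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in pool:
        by_gene.setdefault(v.annotations.gene, []).append(v)
    pairs = []
    for gene in sorted(by_gene):
        pairs.extend(find_compound_het_pairs(by_gene[gene], *trio_ids))
    # pairing changes the counting unit from variants to pairs; the
    # attrition chain restarts on pairs
    cand.attrition.append(("candidate-pairs", len(pairs), len(pairs)))
    cand.items = list(pairs)
    cand.validate()
    return cand


def search_imprinted(
    variants: Iterable[VariantRecord],
    regions: Sequence[ImprintedRegion],
    pedigree: Pedigree,
    thresholds: Optional[FilterThresholds] = None,
    expressed_parent: ExpressedParent = ExpressedParent.MATERNAL,
    cohort: Optional[Set[CohortPattern]] = None,
) -> CandidateSet:
    """Imprinted-gene search for one parent-of-origin expression class.

    After the shared gates, a candidate must overlap at least one imprinted
    region on the requested list (regions of ambiguous/unknown expression
    are on both lists) and show the matching parent-of-origin genotype
    pattern in the trio.
    """
    if expressed_parent is ExpressedParent.BOTH:
        raise ValueError("search one expression class at a time")
    thresholds = thresholds or FilterThresholds()
    trio_ids = pedigree.trio()
    mode = (
        InheritanceMode.IMPRINTED_MATERNAL
        if expressed_parent is ExpressedParent.MATERNAL
        else InheritanceMode.IMPRINTED_PATERNAL
    )
    cand = CandidateSet(mode=mode)
    pool = _apply_variant_gates(cand, list(variants), mode, trio_ids, thresholds, cohort)
    search_regions = [r for r in regions if r.matches_search(expressed_parent)]
    before = len(pool)
    pool = [
        v for v in pool if any(r.contains(v.chrom, v.pos) for r in search_regions)
    ]
    cand.log_stage("imprinted-region", before, len(pool))
    before = len(pool)
    cand.items = [
        v
        for v in pool
        if classify_imprinted(TrioGenotypes.from_variant(v, *trio_ids), expressed_parent)
    ]
    cand.log_stage("genotype-pattern", before, len(cand.items))
    cand.validate()
    return cand


def search_all_modes(
    variants: Sequence[VariantRecord],
    regions: Sequence[ImprintedRegion],
    pedigree: Pedigree,
    thresholds: Optional[FilterThresholds] = None,
    cohort: Optional[Set[CohortPattern]] = None,
    modes: Optional[Sequence[InheritanceMode]] = None,
) -> dict[InheritanceMode, CandidateSet]:
    """Run every requested search; a variant satisfying several modes is
    reported under each (recessive and imprinted patterns overlap by
    construction — hom-alt child of two hets — and must not be
    deduplicated)."""
    modes = list(modes) if modes is not None else list(InheritanceMode)
    out: dict[InheritanceMode, CandidateSet] = {}
    for mode in modes:
        if mode is InheritanceMode.DE_NOVO:
            out[mode] = search_de_novo(variants, pedigree, thresholds, cohort)
        elif mode is InheritanceMode.AUTOSOMAL_RECESSIVE:
            out[mode] = search_recessive(variants, pedigree, thresholds, cohort)
        elif mode is InheritanceMode.COMPOUND_HET:
            out[mode] = search_compound_het(variants, pedigree, thresholds, cohort)
        elif mode is InheritanceMode.IMPRINTED_MATERNAL:
            out[mode] = search_imprinted(
                variants, regions, pedigree, thresholds, ExpressedParent.MATERNAL, cohort
            )
        elif mode is InheritanceMode.IMPRINTED_PATERNAL:
            out[mode] = search_imprinted(
                variants, regions, pedigree, thresholds, ExpressedParent.PATERNAL, cohort
            )
    return out


# ---------------------------------------------------------------------------
# extended-pedigree parent-of-origin consistency

MATERNAL_ALLELE = "maternal-allele"
PATERNAL_ALLELE = "paternal-allele"
BOTH_ALLELES = "both-alleles"


@dataclass(frozen=True)
class ConsistencyResult:
    """Verdict of the origin-assignment search, with a witness when found."""

    consistent: bool
    assignment: Optional[dict[str, str]]
    diagnostic: str

    def __bool__(self) -> bool:
        return self.consistent


def pedigree_origin_consistency(
    pedigree: Pedigree,
    genotypes: Mapping[str, Zygosity],
    expressed_parent: ExpressedParent,
) -> ConsistencyResult:
    """Is any parental-origin assignment consistent with the family?

    Searches exhaustively over assignments of the carriers' mutant alleles
    to parental origins (het carriers: maternal or paternal; hom-alt:
    both). An assignment is accepted iff

    * transmission-consistent: an allele assigned maternal origin requires
      the member's mother, when genotyped, to carry the variant (paternal
      analogously); an ungenotyped or absent parent permits either origin;
      a hom-alt member requires both genotyped parents to carry;
    * phenotype-consistent, under full penetrance: a genotyped member is
      affected iff the allele of the expressed parent carries the mutation.

    A family with no carriers is trivially consistent (provided no carrier
    is affected). Contradictory genotypes (e.g. a hom-alt child of two
    genotyped hom-ref parents) admit no assignment and yield False with a
    diagnostic.
    """
    if expressed_parent is ExpressedParent.BOTH:
        raise ValueError("expressed_parent must be MATERNAL or PATERNAL")
    members = {m.sample_id: m for m in pedigree.members}
    unknown = sorted(set(genotypes) - set(members))
    if unknown:
        raise ValueError(f"genotyped samples not in pedigree: {unknown}")

    het_carriers = sorted(s for s, z in genotypes.items() if z is Zygosity.HET)
    hom_carriers = sorted(s for s, z in genotypes.items() if z is Zygosity.HOM_ALT)

    def parent_carries(parent_id: Optional[str]) -> Optional[bool]:
        """True/False if the parent is genotyped, None if unconstrained."""
        if parent_id is None or parent_id not in genotypes:
            return None
        return genotypes[parent_id] in (Zygosity.HET, Zygosity.HOM_ALT)

    # fixed constraints for hom-alt members
    for s in hom_carriers:
        m = members[s]
        for pid, side in ((m.mother_id, "mother"), (m.father_id, "father")):
            if parent_carries(pid) is False:
                return ConsistencyResult(
                    False,
                    None,
                    f"{s} is homozygous for the variant but genotyped "
                    f"{side} {pid} is homozygous reference",
                )

    def origin_ok(sample: str, origin: str) -> bool:
        m = members[sample]
        if origin in (MATERNAL_ALLELE, BOTH_ALLELES):
            if parent_carries(m.mother_id) is False:
                return False
        if origin in (PATERNAL_ALLELE, BOTH_ALLELES):
            if parent_carries(m.father_id) is False:
                return False
        return True

    def phenotype_ok(assignment: Mapping[str, str]) -> bool:
        expressed_origin = (
            MATERNAL_ALLELE
            if expressed_parent is ExpressedParent.MATERNAL
            else PATERNAL_ALLELE
        )
        for s, z in genotypes.items():
            origin = assignment.get(s)
            expressed_allele_mutant = origin in (expressed_origin, BOTH_ALLELES)
            if members[s].affected != expressed_allele_mutant:
                return False
        return True

    base = {s: BOTH_ALLELES for s in hom_carriers}
    if not all(origin_ok(s, BOTH_ALLELES) for s in hom_carriers):
        # unreachable: checked above with diagnostics; kept as a guard
        return ConsistencyResult(False, None, "transmission contradiction")

    for choices in itertools.product(
        (MATERNAL_ALLELE, PATERNAL_ALLELE), repeat=len(het_carriers)
    ):
        assignment = dict(base)
        assignment.update(dict(zip(het_carriers, choices)))
        if all(origin_ok(s, o) for s, o in assignment.items()) and phenotype_ok(
            assignment
        ):
            return ConsistencyResult(True, assignment, "consistent")
    return ConsistencyResult(
        False,
        None,
        f"no parental-origin assignment reconciles the genotypes with "
        f"{expressed_parent.value} expression under full penetrance",
    )
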