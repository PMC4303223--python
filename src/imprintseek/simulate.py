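"""Synthetic family cohort generator for end-to-end pipeline testing.

Produces a multi-sample VCF, PED file, imprinted-region table, background
cohort pattern file, and a truth table, with variants planted for every
inheritance class. Background variants are generated founder-first —
founder genotypes are Hardy–Weinberg draws at a site frequency sampled
from a rare-skewed Beta spectrum — and then dropped through the pedigree,
so every child allele is present in a parent and the only Mendelian
violations are the deliberately planted de novo events. Planted variants
bypass transmission sampling and receive annotations that guarantee
passage of the quality and deleteriousness gates, so each one's recovery
depends only on the genotype logic under test.

All randomness flows from ``SimulationConfig.seed``; a repeated seed
yields byte-identical output files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .core import (
    AnnotationBundle,
    ClinvarClass,
    ExpressedParent,
    GenotypeCall,
    HgmdClass,
    Impact,
    ImprintedRegion,
    InheritanceMode,
    Pedigree,
    PedigreeMember,
    Sex,
    VariantRecord,
    Zygosity,
)
from .filters import CohortPattern, genotype_configuration_label, write_cohort_patterns
from .inheritance import TrioGenotypes, classify_de_novo, classify_imprinted, classify_recessive
from .vcf_io import AnnotationConfig, write_vcf

_BASES = "ACGT"

# default imprinted-region table used by generated fixtures: a maternally
# expressed CDKN1C-like region, two paternally expressed regions, a second
# maternal region, and one gene of ambiguous expression (on both lists)
DEFAULT_REGIONS = (
    ImprintedRegion("CDKN1C", "chr11", 2883213, 2887392, ExpressedParent.MATERNAL),
    ImprintedRegion("H19", "chr11", 2016406, 2022700, ExpressedParent.PATERNAL),
    ImprintedRegion("MEG3", "chr14", 101245747, 101327368, ExpressedParent.MATERNAL),
    ImprintedRegion("SNRPN", "chr15", 25068794, 25223870, ExpressedParent.PATERNAL),
    ImprintedRegion("AMBIG1", "chr20", 5000000, 5010000, ExpressedParent.BOTH),
)

_CHROM_SIZES = {
    "chr2": 240_000_000,
    "chr3": 200_000_000,
    "chr4": 190_000_000,
    "chr11": 135_000_000,
    "chr14": 107_000_000,
    "chr15": 102_000_000,
    "chr20": 63_000_000,
    "chr22": 51_000_000,
}

_Z_ALLELES = {
    Zygosity.HOM_REF: (0, 0),
    Zygosity.HET: (0, 1),
    Zygosity.HOM_ALT: (1, 1),
}


class SimulationConfigError(ValueError):
    """Planted pattern or template inconsistent with the pedigree."""


@dataclass(frozen=True)
class PlantedVariant:
    """One variant injected with an exact genotype pattern.

    ``genotypes`` maps sample id → zygosity for every pedigree member.
    ``pair_id`` groups the two members of a compound-het (or decoy) pair.
    ``expected_modes`` is normally derived from the pattern; pass an empty
    tuple explicitly for decoys that must NOT be reported.
    """

    name: str
    genotypes: Mapping[str, Zygosity]
    gene: Optional[str] = None
    chrom: str = "chr2"
    pos: Optional[int] = None
    frequency: float = 0.0001
    impact: Impact = Impact.HIGH
    pair_id: Optional[str] = None
    expected_modes: Optional[tuple[InheritanceMode, ...]] = None


def trio_pattern(child: Zygosity, mother: Zygosity, father: Zygosity) -> dict[str, Zygosity]:
    return {"proband": child, "mother": mother, "father": father}


def default_planted() -> tuple[PlantedVariant, ...]:
    """One planted variant (or pair) per inheritance class, plus decoys.

    The compound-het decoys exercise the exclusion rules: a cis pair (both
    variants unambiguously maternal) and a pair with a homozygous parent.
    """
    Z = Zygosity
    return (
        PlantedVariant("planted_de_novo", trio_pattern(Z.HET, Z.HOM_REF, Z.HOM_REF),
                       gene="GENEDN", chrom="chr22", pos=21570310),
        PlantedVariant("planted_recessive", trio_pattern(Z.HOM_ALT, Z.HET, Z.HET),
                       gene="GENEAR", chrom="chr3", pos=12_000_000),
        PlantedVariant("planted_cmphet_mat", trio_pattern(Z.HET, Z.HET, Z.HOM_REF),
                       gene="GENECH", chrom="chr4", pos=30_000_000, pair_id="pairA"),
        PlantedVariant("planted_cmphet_pat", trio_pattern(Z.HET, Z.HOM_REF, Z.HET),
                       gene="GENECH", chrom="chr4", pos=30_000_400, pair_id="pairA"),
        PlantedVariant("planted_imprinted_maternal", trio_pattern(Z.HET, Z.HET, Z.HOM_REF),
                       gene="CDKN1C", chrom="chr11", pos=2_884_100),
        PlantedVariant("planted_imprinted_paternal", trio_pattern(Z.HET, Z.HOM_REF, Z.HET),
                       gene="SNRPN", chrom="chr15", pos=25_100_000),
        # decoys: must never be reported by any search
        PlantedVariant("decoy_cis_1", trio_pattern(Z.HET, Z.HET, Z.HOM_REF),
                       gene="GENECIS", chrom="chr4", pos=50_000_000, pair_id="pairCis",
                       expected_modes=()),
        PlantedVariant("decoy_cis_2", trio_pattern(Z.HET, Z.HET, Z.HOM_REF),
                       gene="GENECIS", chrom="chr4", pos=50_000_300, pair_id="pairCis",
                       expected_modes=()),
        PlantedVariant("decoy_parent_hom_1", trio_pattern(Z.HET, Z.HOM_ALT, Z.HOM_REF),
                       gene="GENEPH", chrom="chr4", pos=60_000_000, pair_id="pairHom",
                       expected_modes=()),
        PlantedVariant("decoy_parent_hom_2", trio_pattern(Z.HET, Z.HOM_REF, Z.HET),
                       gene="GENEPH", chrom="chr4", pos=60_000_500, pair_id="pairHom",
                       expected_modes=()),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for one simulated family dataset.

    Defaults emulate a deeply sequenced trio: ~40x mean depth with a small
    fraction of shallow sites, site qualities spread across the pass/fail
    boundary, a rare-skewed Beta(0.3, 3) site-frequency spectrum annotated
    into both population-frequency sources, and mostly benign impact
    classes (MODIFIER 0.55 / LOW 0.30 / MEDIUM 0.10 / HIGH 0.05).
    """

    seed: int = 0
    n_background_variants: int = 1000
    pedigree_template: str = "trio"  # "trio" or "extended"
    freq_beta: tuple[float, float] = (0.3, 3.0)
    depth_mean: float = 40.0
    low_depth_fraction: float = 0.05
    low_depth_mean: float = 6.0
    lowqual_fraction: float = 0.05
    qual_range: tuple[float, float] = (20.0, 90.0)
    impact_probs: tuple[tuple[Impact, float], ...] = (
        (Impact.MODIFIER, 0.55),
        (Impact.LOW, 0.30),
        (Impact.MEDIUM, 0.10),
        (Impact.HIGH, 0.05),
    )
    n_cohort_families: int = 659
    cohort_hit_fraction: float = 0.10
    planted: tuple[PlantedVariant, ...] = field(default_factory=default_planted)
    regions: tuple[ImprintedRegion, ...] = DEFAULT_REGIONS


@dataclass
class SimulatedFamily:
    """In-memory result of one simulation, plus file paths when written."""

    pedigree: Pedigree
    records: list[VariantRecord]
    regions: list[ImprintedRegion]
    cohort: set[CohortPattern]
    truth: "list[TruthEntry]"
    paths: dict[str, Path] = field(default_factory=dict)


@dataclass(frozen=True)
class TruthEntry:
    name: str
    chrom: str
    pos: int
    ref: str
    alt: str
    expected_modes: tuple[InheritanceMode, ...]
    pair_id: Optional[str] = None


def trio_pedigree() -> Pedigree:
    return Pedigree(
        members=(
            PedigreeMember("proband", Sex.MALE, mother_id="mother", father_id="father", affected=True),
            PedigreeMember("mother", Sex.FEMALE),
            PedigreeMember("father", Sex.MALE),
        ),
        proband_id="proband",
    )


def extended_pedigree() -> Pedigree:
    """Six-member family: trio plus maternal grandparents and a maternal aunt."""
    return Pedigree(
        members=(
            PedigreeMember("proband", Sex.MALE, mother_id="mother", father_id="father", affected=True),
            PedigreeMember("mother", Sex.FEMALE, mother_id="grandmother", father_id="grandfather"),
            PedigreeMember("father", Sex.MALE),
            PedigreeMember("grandfather", Sex.MALE),
            PedigreeMember("grandmother", Sex.FEMALE),
            PedigreeMember("aunt", Sex.FEMALE, mother_id="grandmother", father_id="grandfather"),
        ),
        proband_id="proband",
    )


def fig1_family_fixture() -> tuple[Pedigree, dict[str, Zygosity]]:
    """The extended family with the genotype configuration of a maternally
    silenced carrier lineage: proband het (affected); mother, maternal
    grandfather, and maternal aunt het (unaffected, carrying on their
    paternally derived allele); father and maternal grandmother hom-ref.
    """
    Z = Zygosity
    genotypes = {
        "proband": Z.HET,
        "mother": Z.HET,
        "father": Z.HOM_REF,
        "grandfather": Z.HET,
        "grandmother": Z.HOM_REF,
        "aunt": Z.HET,
    }
    return extended_pedigree(), genotypes


def expected_modes_for(
    planted: PlantedVariant,
    regions: Sequence[ImprintedRegion],
    pedigree: Pedigree,
) -> tuple[InheritanceMode, ...]:
    """Modes whose genotype (and region) criteria the planted pattern meets.

    Frequency and quality gates are guaranteed by construction, so the
    expectation reduces to the pattern logic. Compound-het expectation is
    marked on both members of a pair whose variants are not excluded by
    the cis / homozygous-parent rules (evaluated at pair level by the
    caller, since it needs the partner variant).
    """
    if planted.expected_modes is not None:
        return planted.expected_modes
    child, mother, father = pedigree.trio()
    trio = TrioGenotypes(
        child=planted.genotypes[child],
        mother=planted.genotypes[mother],
        father=planted.genotypes[father],
    )
    modes = []
    if classify_de_novo(trio):
        modes.append(InheritanceMode.DE_NOVO)
    if classify_recessive(trio):
        modes.append(InheritanceMode.AUTOSOMAL_RECESSIVE)
    if planted.pair_id is not None and trio.child is Zygosity.HET:
        modes.append(InheritanceMode.COMPOUND_HET)
    pos = planted.pos or 0
    for parent, mode in (
        (ExpressedParent.MATERNAL, InheritanceMode.IMPRINTED_MATERNAL),
        (ExpressedParent.PATERNAL, InheritanceMode.IMPRINTED_PATERNAL),
    ):
        if classify_imprinted(trio, parent) and any(
            r.matches_search(parent) and r.contains(planted.chrom, pos)
            for r in regions
        ):
            modes.append(mode)
    return tuple(modes)


def _chrom_sort_key(chrom: str) -> tuple:
    m = re.match(r"chr(\d+)$", chrom)
    return (0, int(m.group(1))) if m else (1, chrom)


def _validate_planted(p: PlantedVariant, pedigree: Pedigree) -> None:
    ids = set(pedigree.sample_ids)
    extra = set(p.genotypes) - ids
    if extra:
        raise SimulationConfigError(
            f"{p.name}: genotype pattern samples {sorted(extra)} not in "
            f"pedigree samples {sorted(ids)}"
        )
    trio_ids = pedigree.trio()
    missing_trio = [s for s in trio_ids if s not in p.genotypes]
    if missing_trio:
        raise SimulationConfigError(
            f"{p.name}: pattern must cover the trio; missing {missing_trio}"
        )
    # a hom-alt member with a genotyped hom-ref parent is impossible without
    # two independent mutations; reject it outright
    for m in pedigree.members:
        if p.genotypes.get(m.sample_id) is not Zygosity.HOM_ALT:
            continue
        for pid in (m.mother_id, m.father_id):
            if p.genotypes.get(pid) is Zygosity.HOM_REF:
                raise SimulationConfigError(
                    f"{p.name}: {m.sample_id} hom-alt but parent {pid} hom-ref"
                )
    if p.chrom not in _CHROM_SIZES:
        raise SimulationConfigError(f"{p.name}: unknown chromosome {p.chrom}")


def _founder_order(pedigree: Pedigree) -> tuple[list[str], list[str]]:
    """(founders, non-founders in parents-before-children order)."""
    ids = set(pedigree.sample_ids)
    founders, children = [], []
    for m in pedigree.members:
        if m.mother_id in ids or m.father_id in ids:
            children.append(m.sample_id)
        else:
            founders.append(m.sample_id)
    # members() order already lists parents before children in the built-in
    # templates; verify rather than assume for custom pedigrees
    placed = set(founders)
    ordered: list[str] = []
    pending = children[:]
    while pending:
        progressed = False
        for sid in list(pending):
            m = pedigree.member(sid)
            deps = [p for p in (m.mother_id, m.father_id) if p in ids]
            if all(d in placed for d in deps):
                ordered.append(sid)
                placed.add(sid)
                pending.remove(sid)
                progressed = True
        if not progressed:  # cycle guard; Pedigree already rejects cycles
            raise SimulationConfigError("unorderable pedigree")
    return founders, ordered


def simulate_family(
    config: SimulationConfig,
    out_dir: Optional[Union[str, Path]] = None,
    annotation_config: Optional[AnnotationConfig] = None,
) -> SimulatedFamily:
    """Generate the full fixture set for one family.

    Returns the in-memory records/pedigree/regions/cohort/truth table and,
    when ``out_dir`` is given, writes family.vcf, family.ped, regions.tsv,
    cohort.tsv, and truth.tsv there.
    """
    rng = np.random.default_rng(config.seed)
    cfg_ann = annotation_config or AnnotationConfig()
    pedigree = (
        trio_pedigree() if config.pedigree_template == "trio" else extended_pedigree()
    )
    for p in config.planted:
        _validate_planted(p, pedigree)

    founders, ordered_children = _founder_order(pedigree)
    sample_ids = list(pedigree.sample_ids)
    regions = list(config.regions)

    records: list[VariantRecord] = []
    taken_positions = {(p.chrom, p.pos) for p in config.planted if p.pos is not None}

    # --- background variants -------------------------------------------------
    chroms = list(_CHROM_SIZES)
    impacts, impact_p = zip(*config.impact_probs)
    impact_p = np.array(impact_p) / np.sum(impact_p)
    n = config.n_background_variants
    chrom_idx = rng.integers(0, len(chroms), size=n)
    for i in range(n):
        chrom = chroms[chrom_idx[i]]
        while True:
            pos = int(rng.integers(10_000, _CHROM_SIZES[chrom]))
            if (chrom, pos) not in taken_positions:
                taken_positions.add((chrom, pos))
                break
        ref = _BASES[rng.integers(0, 4)]
        alt = _BASES[rng.integers(0, 4)]
        while alt == ref:
            alt = _BASES[rng.integers(0, 4)]
        if rng.random() < 0.1:  # small anchored indel
            ins = "".join(_BASES[j] for j in rng.integers(0, 4, size=int(rng.integers(1, 4))))
            alt = ref + ins

        freq = float(rng.beta(*config.freq_beta))
        alleles: dict[str, tuple[int, int]] = {}
        for s in founders:
            alleles[s] = (int(rng.random() < freq), int(rng.random() < freq))
        for s in ordered_children:
            m = pedigree.member(s)
            ma = alleles[m.mother_id][int(rng.integers(0, 2))] if m.mother_id in alleles else int(rng.random() < freq)
            fa = alleles[m.father_id][int(rng.integers(0, 2))] if m.father_id in alleles else int(rng.random() < freq)
            alleles[s] = (ma, fa)

        genotypes = {}
        shallow = rng.random() < config.low_depth_fraction
        for s in sample_ids:
            mean = config.low_depth_mean if shallow else config.depth_mean
            genotypes[s] = GenotypeCall(
                sample_id=s,
                allele_a=alleles[s][0],
                allele_b=alleles[s][1],
                depth=int(rng.poisson(mean)),
            )
        jitter = rng.normal(1.0, 0.1, size=2)
        freqs = {
            "ESP6500": float(np.clip(freq * jitter[0], 0.0, 1.0)),
            "1KG": float(np.clip(freq * jitter[1], 0.0, 1.0)),
        }
        gene = None
        for r in regions:
            if r.contains(chrom, pos):
                gene = r.gene
        if gene is None:
            gene = f"GENE{chrom[3:]}_{pos // 1_000_000}"
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                site_filter="LowQual" if rng.random() < config.lowqual_fraction else "PASS",
                site_quality=float(rng.uniform(*config.qual_range)),
                genotypes=genotypes,
                annotations=AnnotationBundle(
                    impact_severity=impacts[int(rng.choice(len(impacts), p=impact_p))],
                    frequencies=freqs,
                    gene=gene,
                ),
            )
        )

    # --- planted variants ----------------------------------------------------
    truth: list[TruthEntry] = []
    for p in config.planted:
        pos = p.pos
        if pos is None:
            while True:
                pos = int(rng.integers(10_000, _CHROM_SIZES[p.chrom]))
                if (p.chrom, pos) not in taken_positions:
                    taken_positions.add((p.chrom, pos))
                    break
        ref = _BASES[rng.integers(0, 4)]
        alt = _BASES[rng.integers(0, 4)]
        while alt == ref:
            alt = _BASES[rng.integers(0, 4)]
        genotypes = {
            s: GenotypeCall(
                sample_id=s,
                allele_a=_Z_ALLELES[p.genotypes.get(s, Zygosity.HOM_REF)][0],
                allele_b=_Z_ALLELES[p.genotypes.get(s, Zygosity.HOM_REF)][1],
                depth=int(rng.poisson(config.depth_mean)) + 10,  # clear the depth gate
            )
            for s in sample_ids
        }
        gene = p.gene
        for r in regions:
            if r.contains(p.chrom, pos):
                gene = r.gene
        rec = VariantRecord(
            chrom=p.chrom,
            pos=pos,
            ref=ref,
            alt=alt,
            site_filter="PASS",
            site_quality=float(rng.uniform(60.0, 90.0)),
            genotypes=genotypes,
            annotations=AnnotationBundle(
                impact_severity=p.impact,
                frequencies={"ESP6500": p.frequency, "1KG": p.frequency},
                gene=gene,
            ),
        )
        records.append(rec)
        truth.append(
            TruthEntry(
                name=p.name,
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=rec.alt,
                expected_modes=expected_modes_for(
                    replace(p, pos=rec.pos), regions, pedigree
                ),
                pair_id=p.pair_id,
            )
        )

    records.sort(key=lambda r: (_chrom_sort_key(r.chrom), r.pos, r.ref, r.alt))

    # --- background cohort patterns ------------------------------------------
    child, mother, father = pedigree.trio()
    cohort: set[CohortPattern] = set()
    planted_keys = {(t.chrom, t.pos, t.ref, t.alt) for t in truth}
    fam_counter = 0
    for r in records:
        if r.key in planted_keys or rng.random() >= config.cohort_hit_fraction:
            continue
        label = genotype_configuration_label(r, child, mother, father)
        if label is None:
            continue
        fam_counter += 1
        fam = f"BG{fam_counter % max(config.n_cohort_families, 1):04d}"
        cohort.add(
            CohortPattern(
                chrom=r.chrom, pos=r.pos, ref=r.ref, alt=r.alt,
                family=fam, label=label,
            )
        )

    sim = SimulatedFamily(
        pedigree=pedigree,
        records=records,
        regions=regions,
        cohort=cohort,
        truth=truth,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        sim.paths = {
            "vcf": out / "family.vcf",
            "ped": out / "family.ped",
            "regions": out / "regions.tsv",
            "cohort": out / "cohort.tsv",
            "truth": out / "truth.tsv",
        }
        write_vcf(records, sim.paths["vcf"], sample_ids, cfg_ann)
        write_ped(pedigree, sim.paths["ped"])
        write_regions(regions, sim.paths["regions"])
        write_cohort_patterns(sorted(cohort, key=lambda c: (c.chrom, c.pos, c.family)), sim.paths["cohort"])
        write_truth(truth, sim.paths["truth"])
    return sim


def write_ped(pedigree: Pedigree, path: Union[str, Path], family_id: str = "FAM1") -> None:
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    lines = []
    for m in pedigree.members:
        lines.append(
            "\t".join(
                [
                    family_id,
                    m.sample_id,
                    m.father_id or "0",
                    m.mother_id or "0",
                    sex_code[m.sex],
                    "2" if m.affected else "1",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_regions(regions: Sequence[ImprintedRegion], path: Union[str, Path]) -> None:
    lines = ["#gene\tchrom\tstart\tend\texpressed_parent"]
    for r in regions:
        lines.append(f"{r.gene}\t{r.chrom}\t{r.start}\t{r.end}\t{r.expressed_parent.value}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth(truth: Sequence[TruthEntry], path: Union[str, Path]) -> None:
    lines = ["#name\tchrom\tpos\tref\talt\texpected_modes\tpair_id"]
    for t in truth:
        modes = ",".join(m.value for m in t.expected_modes)
        lines.append(
            f"{t.name}\t{t.chrom}\t{t.pos}\t{t.ref}\t{t.alt}\t{modes}\t{t.pair_id or '.'}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
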