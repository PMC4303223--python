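"""Core domain types for family-based variant prioritization.

Everything downstream — quality gates, inheritance-mode classifiers, the
imprinted-gene search — operates on the small vocabulary defined here:
biallelic variant records with per-sample diploid genotype calls, a pedigree
with affected status, imprinted-region intervals tagged with their
parent-of-origin expression class, and the enumeration of search modes.

Genotypes are always diploid; hemizygous sex-chromosome calls are not
modeled (the searches implemented here are autosomal).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union


class Impact(enum.Enum):
    """Predicted functional impact severity (snpEff-style)."""

    HIGH = "HIGH"
    MEDIUM = "MEDIUM"
    LOW = "LOW"
    MODIFIER = "MODIFIER"
    UNKNOWN = "UNKNOWN"


class ClinvarClass(enum.Enum):
    PATHOGENIC = "PATHOGENIC"
    PROBABLY_PATHOGENIC = "PROBABLY_PATHOGENIC"
    OTHER = "OTHER"
    ABSENT = "ABSENT"


class HgmdClass(enum.Enum):
    DISEASE_CAUSING = "DISEASE_CAUSING"
    OTHER = "OTHER"
    ABSENT = "ABSENT"


class Zygosity(enum.Enum):
    HOM_REF = "hom-ref"
    HET = "het"
    HOM_ALT = "hom-alt"


class ExpressedParent(enum.Enum):
    """Which parental allele of an imprinted gene is transcribed.

    BOTH encodes ambiguous/unknown parent-of-origin expression: such genes
    are effectively on both the maternal and the paternal search lists.
    """

    MATERNAL = "maternal"
    PATERNAL = "paternal"
    BOTH = "both"


class InheritanceMode(enum.Enum):
    DE_NOVO = "de_novo"
    AUTOSOMAL_RECESSIVE = "autosomal_recessive"
    COMPOUND_HET = "compound_het"
    IMPRINTED_MATERNAL = "imprinted_maternal"
    IMPRINTED_PATERNAL = "imprinted_paternal"


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class PedigreeError(ValueError):
    """Raised on structurally invalid pedigrees (cycles, duplicates...)."""


class UnknownSampleError(KeyError):
    """Raised when an operation references a sample absent from a record."""


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's diploid genotype at one biallelic site.

    Allele indices are 0 (reference) or 1 (the record's single alt);
    ``None`` marks a missing allele. A call is *fully called* iff neither
    allele is missing.
    """

    sample_id: str
    allele_a: Optional[int]
    allele_b: Optional[int]
    depth: int = 0
    phased: bool = False

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"negative depth for sample {self.sample_id!r}")
        for a in (self.allele_a, self.allele_b):
            if a is not None and a < 0:
                raise ValueError(f"negative allele index for {self.sample_id!r}")

    @property
    def fully_called(self) -> bool:
        return self.allele_a is not None and self.allele_b is not None

    @property
    def zygosity(self) -> Zygosity:
        """Zygosity of a fully-called biallelic genotype.

        Total over fully-called calls: every (a, b) with a, b in {0, 1}
        maps to exactly one of hom-ref / het / hom-alt.
        """
        if not self.fully_called:
            raise ValueError(
                f"zygosity undefined for partially called genotype of "
                f"{self.sample_id!r}"
            )
        n_alt = (self.allele_a != 0) + (self.allele_b != 0)
        return (Zygosity.HOM_REF, Zygosity.HET, Zygosity.HOM_ALT)[n_alt]

    @property
    def carries_alt(self) -> bool:
        return self.fully_called and self.zygosity is not Zygosity.HOM_REF


@dataclass(frozen=True)
class AnnotationBundle:
    """Per-variant annotations the deleteriousness and frequency gates use.

    Absent annotations default to UNKNOWN/ABSENT so that filters compose on
    sparsely annotated input; an absent frequency source means the variant
    was not observed there.
    """

    impact_severity: Impact = Impact.UNKNOWN
    clinvar_class: ClinvarClass = ClinvarClass.ABSENT
    hgmd_class: HgmdClass = HgmdClass.ABSENT
    frequencies: Mapping[str, float] = field(default_factory=dict)
    gene: Optional[str] = None

    def __post_init__(self) -> None:
        for src, f in self.frequencies.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f!r} from {src!r} outside [0, 1]")

    def max_frequency(self) -> float:
        """Maximum allele frequency across sources; 0 when unobserved."""
        return max(self.frequencies.values(), default=0.0)


@dataclass(frozen=True)
class VariantRecord:
    """A normalized biallelic variant site with per-sample genotypes."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    site_filter: str = "PASS"
    site_quality: float = 0.0
    genotypes: Mapping[str, GenotypeCall] = field(default_factory=dict)
    annotations: AnnotationBundle = field(default_factory=AnnotationBundle)

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.site_quality < 0:
            raise ValueError("site quality must be non-negative")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def genotype(self, sample_id: str) -> GenotypeCall:
        try:
            return self.genotypes[sample_id]
        except KeyError:
            raise UnknownSampleError(
                f"sample {sample_id!r} not present at {self.chrom}:{self.pos}"
            ) from None


def is_fully_called(variant: VariantRecord, sample_ids: Sequence[str]) -> bool:
    """True iff every listed sample has both alleles determined."""
    return all(variant.genotype(s).fully_called for s in sample_ids)


@dataclass(frozen=True)
class PedigreeMember:
    sample_id: str
    sex: Sex = Sex.UNKNOWN
    mother_id: Optional[str] = None
    father_id: Optional[str] = None
    affected: bool = False


@dataclass(frozen=True)
class Pedigree:
    """Family members with parental links and affected status.

    Validation rejects duplicate ids, members listed among their own
    ancestors, and parents of the wrong recorded sex. Parents need not be
    members themselves (founder parents outside the genotyped family are
    simply absent links).
    """

    members: tuple[PedigreeMember, ...]
    proband_id: str

    def __post_init__(self) -> None:
        ids = [m.sample_id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise PedigreeError(f"duplicate sample ids: {dupes}")
        if self.proband_id not in set(ids):
            raise PedigreeError(f"proband {self.proband_id!r} not in pedigree")
        by_id = {m.sample_id: m for m in self.members}
        for m in self.members:
            mo = by_id.get(m.mother_id) if m.mother_id else None
            fa = by_id.get(m.father_id) if m.father_id else None
            if mo is not None and mo.sex is Sex.MALE:
                raise PedigreeError(f"mother {mo.sample_id!r} recorded as male")
            if fa is not None and fa.sex is Sex.FEMALE:
                raise PedigreeError(f"father {fa.sample_id!r} recorded as female")
        # cycle check: walk every ancestor chain
        for m in self.members:
            seen = {m.sample_id}
            frontier = [p for p in (m.mother_id, m.father_id) if p]
            while frontier:
                pid = frontier.pop()
                if pid in seen:
                    raise PedigreeError(
                        f"{pid!r} appears among its own ancestors (cycle)"
                    )
                seen.add(pid)
                parent = by_id.get(pid)
                if parent is not None:
                    frontier.extend(
                        p for p in (parent.mother_id, parent.father_id) if p
                    )

    def member(self, sample_id: str) -> PedigreeMember:
        for m in self.members:
            if m.sample_id == sample_id:
                return m
        raise UnknownSampleError(f"no pedigree member {sample_id!r}")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(m.sample_id for m in self.members)

    def trio(self) -> tuple[str, str, str]:
        """(child, mother, father) ids for the proband's trio.

        Raises PedigreeError if the proband lacks a genotyped parent.
        """
        proband = self.member(self.proband_id)
        ids = set(self.sample_ids)
        if proband.mother_id not in ids or proband.father_id not in ids:
            raise PedigreeError(
                f"proband {self.proband_id!r} must have both parents in the "
                f"pedigree for trio analysis"
            )
        return (proband.sample_id, proband.mother_id, proband.father_id)


@dataclass(frozen=True)
class ImprintedRegion:
    """Genomic interval of an imprinted gene (1-based, inclusive ends)."""

    gene: str
    chrom: str
    start: int
    end: int
    expressed_parent: ExpressedParent

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"degenerate interval for {self.gene}: {self.start}-{self.end}"
            )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def matches_search(self, search_parent: ExpressedParent) -> bool:
        """Whether this region belongs on the given search list.

        Regions with BOTH (ambiguous/unknown) expression match either list.
        """
        return (
            self.expressed_parent is search_parent
            or self.expressed_parent is ExpressedParent.BOTH
        )


VariantItem = Union[VariantRecord, tuple[VariantRecord, VariantRecord]]


@dataclass
class CandidateSet:
    """Variants (or pairs) surviving one inheritance-mode search.

    ``attrition`` records (filter_name, count_before, count_after) for each
    gate in application order; counts are non-increasing.
    """

    mode: InheritanceMode
    items: list[VariantItem] = field(default_factory=list)
    attrition: list[tuple[str, int, int]] = field(default_factory=list)

    def log_stage(self, name: str, before: int, after: int) -> None:
        if after > before:
            raise ValueError(f"attrition stage {name!r} increased the count")
        if self.attrition and self.attrition[-1][2] != before:
            raise ValueError(
                f"attrition stage {name!r} count_before={before} does not "
                f"chain from previous count_after={self.attrition[-1][2]}"
            )
        self.attrition.append((name, before, after))

    def validate(self) -> None:
        if self.attrition and len(self.items) != self.attrition[-1][2]:
            raise ValueError("final attrition count != number of items")


def zygosities(
    variant: VariantRecord, sample_ids: Iterable[str]
) -> tuple[Zygosity, ...]:
    """Zygosity per sample, in the given order; requires fully-called."""
    return tuple(variant.genotype(s).zygosity for s in sample_ids)
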