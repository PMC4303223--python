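"""Per-variant gating criteria used by every inheritance-mode search.

Four independent predicates: trio call quality, candidate deleteriousness,
mode-specific population-frequency rarity, and background-cohort exclusion.
Each is a pure function of one variant, so they compose in any order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Set, Union

from .core import (
    ClinvarClass,
    GenotypeCall,
    HgmdClass,
    Impact,
    InheritanceMode,
    VariantRecord,
    Zygosity,
    is_fully_called,
)


@dataclass(frozen=True)
class FilterThresholds:
    """Gating thresholds; defaults follow common trio-pipeline practice.

    Frequency bounds are strict upper bounds per mode: candidates must be
    rarer than 0.5% for de novo and 1% for recessive / compound-het
    searches. The imprinted-mode bound defaults to the recessive one but is
    its own knob.
    """

    min_site_quality: float = 30.0
    min_depth: int = 10
    freq_max_de_novo: float = 0.005
    freq_max_recessive: float = 0.01
    freq_max_imprinted: float = 0.01

    def __post_init__(self) -> None:
        if self.min_site_quality < 0 or self.min_depth < 0:
            raise ValueError("quality/depth thresholds must be non-negative")
        for f in (self.freq_max_de_novo, self.freq_max_recessive, self.freq_max_imprinted):
            if not 0.0 <= f <= 1.0:
                raise ValueError("frequency thresholds must lie in [0, 1]")

    def freq_bound(self, mode: InheritanceMode) -> float:
        if mode is InheritanceMode.DE_NOVO:
            return self.freq_max_de_novo
        if mode in (InheritanceMode.AUTOSOMAL_RECESSIVE, InheritanceMode.COMPOUND_HET):
            return self.freq_max_recessive
        return self.freq_max_imprinted


@dataclass(frozen=True)
class CohortPattern:
    """One background family's genotype configuration at one variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    family: str
    label: str

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def passes_trio_quality(
    variant: VariantRecord,
    sample_ids: Sequence[str],
    thresholds: FilterThresholds,
) -> bool:
    """Site PASS, QUAL at the bound, and every sample fully called at depth.

    All four conditions: FILTER == PASS, site quality >= min_site_quality,
    each listed sample fully called, each listed sample depth >= min_depth.
    """
    if not sample_ids:
        raise ValueError("sample_ids must be nonempty")
    if variant.site_filter != "PASS":
        return False
    if variant.site_quality < thresholds.min_site_quality:
        return False
    for s in sample_ids:
        g = variant.genotype(s)
        if not g.fully_called or g.depth < thresholds.min_depth:
            return False
    return True


def is_candidate_deleterious(variant: VariantRecord) -> bool:
    """Possibly deleterious: high/medium impact, or a pathogenic database hit.

    True iff impact severity is HIGH or MEDIUM, or the ClinVar class is
    pathogenic / probably pathogenic, or HGMD calls it disease-causing.
    """
    ann = variant.annotations
    return (
        ann.impact_severity in (Impact.HIGH, Impact.MEDIUM)
        or ann.clinvar_class in (ClinvarClass.PATHOGENIC, ClinvarClass.PROBABLY_PATHOGENIC)
        or ann.hgmd_class is HgmdClass.DISEASE_CAUSING
    )


def passes_frequency(
    variant: VariantRecord,
    mode: InheritanceMode,
    thresholds: FilterThresholds,
) -> bool:
    """Rarity gate: the max frequency across sources is strictly below the
    mode's bound. A variant absent from every source counts as frequency 0
    (unobserved, hence compatible with a very rare causative allele)."""
    return variant.annotations.max_frequency() < thresholds.freq_bound(mode)


def genotype_configuration_label(
    variant: VariantRecord, child: str, mother: str, father: str
) -> Optional[str]:
    """Canonical child/mother/father genotype-configuration label.

    e.g. ``child-het/mother-het/father-ref``; None if any member is not
    fully called (no configuration to compare).
    """
    if not is_fully_called(variant, [child, mother, father]):
        return None
    short = {Zygosity.HOM_REF: "ref", Zygosity.HET: "het", Zygosity.HOM_ALT: "hom"}

    def z(s: str) -> str:
        return short[variant.genotype(s).zygosity]

    return f"child-{z(child)}/mother-{z(mother)}/father-{z(father)}"


def excluded_by_cohort(
    variant: VariantRecord,
    observed_pattern_label: Optional[str],
    cohort: Set[CohortPattern],
) -> bool:
    """Background-cohort exclusion.

    True iff some cohort family carries the same variant with the same
    genotype-configuration label as the study family — i.e. the variant
    segregates with inheritance consistent with the proband's family in an
    unrelated (presumably unaffected) family, so it is unlikely causative.
    """
    if observed_pattern_label is None:
        return False
    return any(
        p.variant_key == variant.key and p.label == observed_pattern_label
        for p in cohort
    )


def read_cohort_patterns(path: Union[str, Path]) -> set[CohortPattern]:
    """Read cohort patterns from TSV: chrom, pos, ref, alt, family, label."""
    patterns = set()
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 6:
            raise ValueError(f"{path}:{line_no}: expected 6 columns")
        chrom, pos, ref, alt, family, label = cols[:6]
        patterns.add(
            CohortPattern(
                chrom=chrom, pos=int(pos), ref=ref, alt=alt,
                family=family, label=label,
            )
        )
    return patterns


def write_cohort_patterns(
    patterns: Sequence[CohortPattern], path: Union[str, Path]
) -> None:
    lines = ["#chrom\tpos\tref\talt\tfamily\tlabel"]
    for p in sorted(patterns, key=lambda p: (p.chrom, p.pos, p.ref, p.alt, p.family)):
        lines.append(f"{p.chrom}\t{p.pos}\t{p.ref}\t{p.alt}\t{p.family}\t{p.label}")
    Path(path).write_text("\n".join(lines) + "\n")
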