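"""Allele-biased expression arithmetic from RNA-Seq allele counts.

For a heterozygous site in an imprinted gene, the fraction of RNA-Seq
reads supporting the variant allele measures which parental copy is being
transcribed. Counts are inputs here (read-level processing is upstream);
this module computes the percent-variant statistic, an exact binomial test
against balanced (50/50) expression, and a per-family report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd
from scipy import stats

from .core import Zygosity


@dataclass(frozen=True)
class AlleleCounts:
    """Reference/variant read counts for one sample at one site.

    ``total_reads`` may exceed ref + variant (reads carrying other alleles
    or filtered base calls); the bias statistics use ref + variant as the
    informative denominator.
    """

    sample_id: str
    total_reads: int
    ref_count: int
    variant_count: int

    def __post_init__(self) -> None:
        if min(self.total_reads, self.ref_count, self.variant_count) < 0:
            raise ValueError(f"negative read count for {self.sample_id!r}")
        if self.ref_count + self.variant_count > self.total_reads:
            raise ValueError(
                f"{self.sample_id!r}: ref + variant reads exceed total"
            )

    @property
    def informative(self) -> int:
        return self.ref_count + self.variant_count


def percent_variant(counts: AlleleCounts) -> float:
    """Percent of informative reads carrying the variant allele.

    100 * variant / (ref + variant), rounded half-up to one decimal. The
    denominator is the informative read count, not ``total_reads``: extra
    reads carrying neither allele are uninformative about allelic balance.
    """
    n = counts.informative
    if n == 0:
        raise ValueError(
            f"{counts.sample_id!r}: no informative reads; percent undefined"
        )
    raw = Decimal(100) * Decimal(counts.variant_count) / Decimal(n)
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def allele_bias_test(counts: AlleleCounts, null_fraction: float = 0.5) -> float:
    """Exact two-sided binomial p-value for allelic imbalance.

    Tests variant_count successes out of ref + variant informative reads
    against the null variant fraction (0.5 = balanced biallelic
    expression).
    """
    if not 0.0 < null_fraction < 1.0:
        raise ValueError("null_fraction must lie strictly within (0, 1)")
    n = counts.informative
    if n == 0:
        raise ValueError(f"{counts.sample_id!r}: no informative reads")
    return float(
        stats.binomtest(counts.variant_count, n, null_fraction).pvalue
    )


def family_ase_report(
    counts: Sequence[AlleleCounts],
    genotypes: Optional[Mapping[str, Zygosity]] = None,
    null_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-member allele-bias table with genotype sanity flags.

    Columns: sample, total, ref, variant, informative, percent_variant,
    p_value, genotype, anomaly. A hom-ref member with any variant reads is
    flagged as an anomaly (reads contradict the genotype); members whose
    total exceeds ref + variant raise a warning (uninformative extra
    reads). No significance verdict is attached — at the depths typical of
    a single heterozygous site the test is underpowered, and the report is
    meant for ordering, not inference.
    """
    genotypes = genotypes or {}
    rows = []
    for c in counts:
        if c.total_reads > c.informative:
            warnings.warn(
                f"{c.sample_id}: total reads ({c.total_reads}) exceed "
                f"ref+variant ({c.informative}); percent uses ref+variant",
                stacklevel=2,
            )
        z = genotypes.get(c.sample_id)
        anomaly = z is Zygosity.HOM_REF and c.variant_count > 0
        rows.append(
            {
                "sample": c.sample_id,
                "total": c.total_reads,
                "ref": c.ref_count,
                "variant": c.variant_count,
                "informative": c.informative,
                "percent_variant": percent_variant(c) if c.informative else float("nan"),
                "p_value": allele_bias_test(c, null_fraction) if c.informative else float("nan"),
                "genotype": z.value if z is not None else "unknown",
                "anomaly": bool(anomaly),
            }
        )
    return pd.DataFrame(rows)


def read_allele_counts(path: Union[str, Path]) -> list[AlleleCounts]:
    """Read a counts TSV: sample_id, total, ref_count, variant_count."""
    out = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("sample"):
            continue
        cols = line.split("\t")
        if len(cols) < 4:
            raise ValueError(f"{path}:{line_no}: expected 4 columns")
        out.append(
            AlleleCounts(
                sample_id=cols[0],
                total_reads=int(cols[1]),
                ref_count=int(cols[2]),
                variant_count=int(cols[3]),
            )
        )
    return out
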