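from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from imprintseek.core import (
    AnnotationBundle,
    GenotypeCall,
    Impact,
    VariantRecord,
    Zygosity,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

Z_ALLELES = {
    Zygosity.HOM_REF: (0, 0),
    Zygosity.HET: (0, 1),
    Zygosity.HOM_ALT: (1, 1),
}


def make_variant(
    zygosities: dict[str, Zygosity],
    chrom: str = "chr1",
    pos: int = 1000,
    ref: str = "A",
    alt: str = "G",
    site_filter: str = "PASS",
    site_quality: float = 60.0,
    depth: int = 30,
    impact: Impact = Impact.HIGH,
    frequencies: dict | None = None,
    gene: str | None = "GENE1",
) -> VariantRecord:
    """Variant with the given per-sample zygosities and passing defaults."""
    genotypes = {
        s: GenotypeCall(s, *Z_ALLELES[z], depth=depth) for s, z in zygosities.items()
    }
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        site_filter=site_filter,
        site_quality=site_quality,
        genotypes=genotypes,
        annotations=AnnotationBundle(
            impact_severity=impact,
            frequencies=frequencies or {},
            gene=gene,
        ),
    )


@pytest.fixture
def trio_ids() -> tuple[str, str, str]:
    return ("proband", "mother", "father")


def trio_variant(child: Zygosity, mother: Zygosity, father: Zygosity, **kw) -> VariantRecord:
    return make_variant(
        {"proband": child, "mother": mother, "father": father}, **kw
    )
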