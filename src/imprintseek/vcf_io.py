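"""Readers and writers for the formats the pipeline touches.

VCF ingestion is built on :mod:`cyvcf2`. Multiallelic rows are split into
one biallelic record per alternate allele, and each split record is
prefix/suffix trimmed (``normalize_variant``). True left-alignment against
a reference genome is deliberately not performed — inputs are assumed
reference-consistent — so only the parsimony trimming step is applied.

Coordinate conventions: VCF positions and imprinted-region intervals are
1-based with inclusive ends throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

from cyvcf2 import VCF

from .core import (
    AnnotationBundle,
    ClinvarClass,
    ExpressedParent,
    GenotypeCall,
    HgmdClass,
    Impact,
    ImprintedRegion,
    Pedigree,
    PedigreeMember,
    Sex,
    VariantRecord,
)


class VcfFormatError(ValueError):
    """Malformed or unusable VCF input."""


class SampleMismatchError(ValueError):
    """VCF samples do not cover the pedigree samples."""


class InvalidVariantError(ValueError):
    """Allele pair that cannot represent a variant (e.g. ref == alt)."""


class RegionTableError(ValueError):
    """Unparseable imprinted-region table."""


def normalize_variant(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared flanking bases from an allele pair (vt-style parsimony).

    Shared trailing bases are removed first, then shared leading bases,
    each only while both alleles retain at least one base; the position
    advances by the number of leading bases removed. Idempotent.
    """
    if not ref or not alt:
        raise InvalidVariantError("ref and alt must be non-empty")
    if ref == alt:
        raise InvalidVariantError(f"ref == alt ({ref!r}) is not a variant")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


# value vocabularies are matched case-insensitively after stripping
_IMPACT_ALIASES = {
    "HIGH": Impact.HIGH,
    "MEDIUM": Impact.MEDIUM,
    "MODERATE": Impact.MEDIUM,  # snpEff prints MODERATE for this tier
    "LOW": Impact.LOW,
    "MODIFIER": Impact.MODIFIER,
}

_DEFAULT_CLINVAR_VOCAB = {
    "pathogenic": ClinvarClass.PATHOGENIC,
    "probably_pathogenic": ClinvarClass.PROBABLY_PATHOGENIC,
    "likely_pathogenic": ClinvarClass.PROBABLY_PATHOGENIC,
}

_DEFAULT_HGMD_VOCAB = {
    "dm": HgmdClass.DISEASE_CAUSING,
    "disease_causing": HgmdClass.DISEASE_CAUSING,
}


@dataclass(frozen=True)
class AnnotationConfig:
    """Maps INFO keys (and value vocabularies) onto the annotation bundle.

    ``frequency_keys`` lists (source-name, INFO key) pairs; source names
    must be unique. Unrecognized vocabulary values fall back to
    OTHER; absent keys fall back to UNKNOWN/ABSENT.
    """

    impact_key: str = "IMPACT"
    clinvar_key: str = "CLNSIG"
    clinvar_vocab: dict = field(default_factory=lambda: dict(_DEFAULT_CLINVAR_VOCAB))
    hgmd_key: str = "HGMD"
    hgmd_vocab: dict = field(default_factory=lambda: dict(_DEFAULT_HGMD_VOCAB))
    frequency_keys: tuple[tuple[str, str], ...] = (
        ("ESP6500", "AF_ESP"),
        ("1KG", "AF_1KG"),
    )
    gene_key: str = "GENE"

    def __post_init__(self) -> None:
        sources = [s for s, _ in self.frequency_keys]
        if len(set(sources)) != len(sources):
            raise ValueError("frequency source names must be unique")

    def parse_impact(self, raw: Optional[str]) -> Impact:
        if raw is None:
            return Impact.UNKNOWN
        return _IMPACT_ALIASES.get(str(raw).strip().upper(), Impact.UNKNOWN)

    def parse_clinvar(self, raw: Optional[str]) -> ClinvarClass:
        if raw is None:
            return ClinvarClass.ABSENT
        return self.clinvar_vocab.get(str(raw).strip().lower(), ClinvarClass.OTHER)

    def parse_hgmd(self, raw: Optional[str]) -> HgmdClass:
        if raw is None:
            return HgmdClass.ABSENT
        return self.hgmd_vocab.get(str(raw).strip().lower(), HgmdClass.OTHER)


def _scalar_for_alt(value, alt_index: int):
    """Pick the per-alt element from a possibly Number,A-typed INFO value."""
    if isinstance(value, (tuple, list)):
        if alt_index < len(value):
            return value[alt_index]
        return None
    return value


def read_variants(
    vcf_path: Union[str, Path],
    annotation_config: Optional[AnnotationConfig] = None,
    required_samples: Optional[Sequence[str]] = None,
) -> Iterator[VariantRecord]:
    """Stream biallelic, trimmed VariantRecords from a VCF.

    Multiallelic rows yield one record per alternate allele; per-sample
    allele indices are remapped so that the record's alt is index 1, and a
    sample carrying a *different* alternate allele at the site gets a
    missing allele (it is not a carrier of this alt, and downstream
    fully-called gates will drop it). A missing DP is treated as depth 0.
    """
    cfg = annotation_config or AnnotationConfig()
    vcf = VCF(str(vcf_path))
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise VcfFormatError(f"{vcf_path}: no GT FORMAT field declared")
    if required_samples is not None:
        missing = sorted(set(required_samples) - set(vcf.samples))
        if missing:
            raise SampleMismatchError(
                f"{vcf_path}: pedigree samples absent from VCF: {missing}"
            )
    samples = list(vcf.samples)
    for v in vcf:
        depths = v.format("DP")
        site_filter = v.FILTER if v.FILTER is not None else "PASS"
        qual = float(v.QUAL) if v.QUAL is not None else 0.0
        for k, alt in enumerate(v.ALT, start=1):
            if alt in (".", "*", None) or not alt:
                continue
            genotypes = {}
            for i, sample in enumerate(samples):
                raw = v.genotypes[i]
                a, b, phased = raw[0], raw[1], bool(raw[-1])
                depth = 0
                if depths is not None:
                    d = int(depths[i][0]) if depths.ndim > 1 else int(depths[i])
                    if d >= 0:
                        depth = d
                genotypes[sample] = GenotypeCall(
                    sample_id=sample,
                    allele_a=_remap_allele(a, k),
                    allele_b=_remap_allele(b, k),
                    depth=depth,
                    phased=phased,
                )
            pos, ref, nalt = normalize_variant(v.POS, v.REF, alt)
            freqs = {}
            for source, key in cfg.frequency_keys:
                val = _scalar_for_alt(v.INFO.get(key), k - 1)
                if val is not None:
                    freqs[source] = float(val)
            gene = v.INFO.get(cfg.gene_key)
            ann = AnnotationBundle(
                impact_severity=cfg.parse_impact(v.INFO.get(cfg.impact_key)),
                clinvar_class=cfg.parse_clinvar(v.INFO.get(cfg.clinvar_key)),
                hgmd_class=cfg.parse_hgmd(v.INFO.get(cfg.hgmd_key)),
                frequencies=freqs,
                gene=str(gene) if gene is not None else None,
            )
            yield VariantRecord(
                chrom=v.CHROM,
                pos=pos,
                ref=ref,
                alt=nalt,
                site_filter=site_filter,
                site_quality=qual,
                genotypes=genotypes,
                annotations=ann,
            )


def _remap_allele(allele: int, alt_index: int) -> Optional[int]:
    """Remap a site-level allele index to the split biallelic record.

    0 stays reference, the chosen alt becomes 1; a missing allele (-1) and
    any *other* alternate allele both become missing — the sample is not a
    carrier of this alt, and conservatively not treated as reference either.
    """
    if allele == 0:
        return 0
    if allele == alt_index:
        return 1
    return None


def read_pedigree(
    ped_path: Union[str, Path], proband_id: Optional[str] = None
) -> Pedigree:
    """Parse a 6-column PED file (family, id, father, mother, sex, phenotype).

    Phenotype 2 marks affected; parent id "0" marks an absent link. The
    proband defaults to the first affected member, else the first member
    with both parents in the file.
    """
    members = []
    for line_no, line in enumerate(Path(ped_path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise ValueError(f"{ped_path}:{line_no}: expected 6 columns, got {len(cols)}")
        _fam, sid, father, mother, sex, phenotype = cols[:6]
        members.append(
            PedigreeMember(
                sample_id=sid,
                sex={"1": Sex.MALE, "2": Sex.FEMALE}.get(sex, Sex.UNKNOWN),
                mother_id=None if mother == "0" else mother,
                father_id=None if father == "0" else father,
                affected=(phenotype == "2"),
            )
        )
    if not members:
        raise ValueError(f"{ped_path}: empty pedigree file")
    if proband_id is None:
        ids = {m.sample_id for m in members}
        affected = [m for m in members if m.affected]
        if affected:
            proband_id = affected[0].sample_id
        else:
            with_parents = [
                m for m in members if m.mother_id in ids and m.father_id in ids
            ]
            proband_id = (with_parents or members)[0].sample_id
    return Pedigree(members=tuple(members), proband_id=proband_id)


_PARENT_TOKENS = {
    "maternal": ExpressedParent.MATERNAL,
    "paternal": ExpressedParent.PATERNAL,
    "both": ExpressedParent.BOTH,
}


def read_imprinted_regions(table_path: Union[str, Path]) -> list[ImprintedRegion]:
    """Parse the imprinted-gene table: gene, chrom, start, end, parent.

    Tab- or whitespace-delimited; ``expressed_parent`` must be one of
    maternal / paternal / both (genes with ambiguous or unknown expression
    are encoded as ``both`` and match either search list). Intervals are
    1-based inclusive. Returned sorted by (chrom, start).
    """
    regions = []
    for line_no, line in enumerate(Path(table_path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("gene\t"):
            continue
        cols = line.split()
        if len(cols) < 5:
            raise RegionTableError(
                f"{table_path}:{line_no}: expected 5 columns, got {len(cols)}"
            )
        gene, chrom, start, end, parent = cols[:5]
        token = parent.strip().lower()
        if token not in _PARENT_TOKENS:
            raise RegionTableError(
                f"{table_path}:{line_no}: unknown expressed_parent {parent!r} "
                f"(expected maternal/paternal/both)"
            )
        regions.append(
            ImprintedRegion(
                gene=gene,
                chrom=chrom,
                start=int(start),
                end=int(end),
                expressed_parent=_PARENT_TOKENS[token],
            )
        )
    return sorted(regions, key=lambda r: (r.chrom, r.start))


def bed_to_region_interval(start0: int, end0: int) -> tuple[int, int]:
    """Convert a BED 0-based half-open interval to 1-based inclusive."""
    return start0 + 1, end0


def write_vcf(
    records: Sequence[VariantRecord],
    path: Union[str, Path],
    sample_ids: Sequence[str],
    annotation_config: Optional[AnnotationConfig] = None,
    mode_tags: Optional[dict[tuple, str]] = None,
    extra_header_lines: Sequence[str] = (),
) -> None:
    """Write biallelic records to a VCF 4.2 text file, deterministically.

    The writer emits exactly the INFO keys named by the annotation config
    (plus an optional MODE tag keyed by variant), so records written here
    round-trip through :func:`read_variants` field-by-field.
    """
    cfg = annotation_config or AnnotationConfig()
    out = io.StringIO()
    out.write("##fileformat=VCFv4.2\n")
    for line in extra_header_lines:
        out.write(line.rstrip("\n") + "\n")
    contigs = sorted({r.chrom for r in records})
    for c in contigs:
        out.write(f"##contig=<ID={c}>\n")
    for f in sorted({r.site_filter for r in records} - {"PASS", "."}):
        out.write(f'##FILTER=<ID={f},Description="{f}">\n')
    out.write(f'##INFO=<ID={cfg.impact_key},Number=1,Type=String,Description="Predicted impact severity">\n')
    out.write(f'##INFO=<ID={cfg.clinvar_key},Number=1,Type=String,Description="ClinVar classification">\n')
    out.write(f'##INFO=<ID={cfg.hgmd_key},Number=1,Type=String,Description="HGMD classification">\n')
    for source, key in cfg.frequency_keys:
        out.write(f'##INFO=<ID={key},Number=A,Type=Float,Description="Allele frequency ({source})">\n')
    out.write(f'##INFO=<ID={cfg.gene_key},Number=1,Type=String,Description="Gene symbol">\n')
    if mode_tags:
        out.write('##INFO=<ID=MODE,Number=.,Type=String,Description="Matching inheritance mode(s)">\n')
    out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    out.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
    out.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sample_ids)
        + "\n"
    )
    rev_clinvar = _first_token_by_class(cfg.clinvar_vocab)
    rev_hgmd = _first_token_by_class(cfg.hgmd_vocab)
    for r in records:
        info = []
        ann = r.annotations
        if ann.impact_severity is not Impact.UNKNOWN:
            info.append(f"{cfg.impact_key}={ann.impact_severity.value}")
        if ann.clinvar_class is not ClinvarClass.ABSENT:
            token = rev_clinvar.get(ann.clinvar_class, ann.clinvar_class.value.lower())
            info.append(f"{cfg.clinvar_key}={token}")
        if ann.hgmd_class is not HgmdClass.ABSENT:
            token = rev_hgmd.get(ann.hgmd_class, ann.hgmd_class.value.lower())
            info.append(f"{cfg.hgmd_key}={token}")
        for source, key in cfg.frequency_keys:
            if source in ann.frequencies:
                info.append(f"{key}={ann.frequencies[source]:.10g}")
        if ann.gene is not None:
            info.append(f"{cfg.gene_key}={ann.gene}")
        if mode_tags and r.key in mode_tags:
            info.append(f"MODE={mode_tags[r.key]}")
        fmt_cells = []
        for s in sample_ids:
            g = r.genotypes.get(s)
            if g is None:
                fmt_cells.append("./.:0")
                continue
            sep = "|" if g.phased else "/"
            a = "." if g.allele_a is None else str(g.allele_a)
            b = "." if g.allele_b is None else str(g.allele_b)
            fmt_cells.append(f"{a}{sep}{b}:{g.depth}")
        out.write(
            "\t".join(
                [
                    r.chrom,
                    str(r.pos),
                    ".",
                    r.ref,
                    r.alt,
                    f"{r.site_quality:.10g}",
                    r.site_filter,
                    ";".join(info) if info else ".",
                    "GT:DP",
                ]
                + fmt_cells
            )
            + "\n"
        )
    Path(path).write_text(out.getvalue())


def _first_token_by_class(vocab: dict) -> dict:
    rev: dict = {}
    for token, cls in vocab.items():
        rev.setdefault(cls, token)
    return rev
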