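# Methods

## Variant model and normalization

All searches operate on biallelic records. Multiallelic VCF rows are split
at ingestion into one record per alternate allele; per-sample allele
indices are remapped so the record's alt is index 1. A sample carrying a
*different* alternate allele at the site is given a missing allele on that
record: it is not a carrier of this alt, and treating it as reference
would fabricate a genotype. Such samples fail the fully-called requirement
and the record is dropped for that trio by the quality gate — the
conservative choice for a diagnostic filter.

Split records are parsimony-trimmed (shared trailing bases removed, then
shared leading bases, each while both alleles keep ≥ 1 base, advancing the
position with each leading base). True left-alignment against a reference
genome is **not** performed; inputs are assumed reference-consistent. This
keeps the package free of genome downloads and is the documented
limitation of the normalizer: an un-left-aligned indel in a repeat tract
may fail to match a cohort or frequency record for the same event.

Coordinates are 1-based with inclusive interval ends everywhere (VCF
convention); BED-style inputs must be converted at the boundary (a helper
is provided).

## Filter gates

Four independent per-variant predicates, composable in any order:

* **Trio quality** — FILTER == `PASS`, site QUAL ≥ `min_site_quality`
  (default 30), and every trio member fully called with DP ≥ `min_depth`
  (default 10). The quality threshold is read as *site* quality; the
  wording "quality ≥ 30 in mother, father and child" could also be read as
  per-sample genotype quality, and the site-level reading is the simpler
  default (a per-sample GQ interpretation can be wired through the
  annotation configuration if an input provides GQ).
* **Deleteriousness** — impact ∈ {HIGH, MEDIUM} (snpEff's `MODERATE` is
  accepted as MEDIUM), or ClinVar pathogenic / probably pathogenic
  (likely-pathogenic accepted as the modern synonym), or HGMD
  disease-causing. Absent annotations default to UNKNOWN/ABSENT rather
  than erroring, so the gate composes on sparsely annotated input.
* **Frequency** — strict maximum across all configured population sources
  must be < 0.005 (de novo) or < 0.01 (recessive / compound-het); the
  imprinted bound is its own knob, defaulting to 0.01. An unobserved
  variant counts as frequency 0: taking the maximum is conservative
  against common variants while never penalizing novel ones. Bounds are
  strict (`<`), and thresholds are exposed rather than hard-coded.
* **Cohort exclusion** — a variant is excluded iff some background family
  carries the identical (chrom, pos, ref, alt) with the identical
  child/mother/father genotype-configuration label. "Inheritance
  consistent with the study family" is operationalized as exact
  configuration match — the most testable reading; mere presence in the
  cohort, or same-mode classification, are plausible alternatives and
  would exclude strictly more.

## Inheritance-mode classifiers

Pure predicates on (child, mother, father) zygosities; affected status
deliberately does not enter the trio classifiers (it is handled by the
pedigree consistency check, separating the genome-wide search from the
family-level confirmation):

| mode | accepting patterns (of 27) |
|---|---|
| de novo | child het, both parents hom-ref (1) |
| autosomal recessive | child hom-alt, both parents het (1) |
| imprinted maternal | child het/hom-alt × mother het × father hom-ref/het (4) |
| imprinted paternal | mirror of maternal (4) |

The de novo search can optionally admit a hom-alt child (two independent
hits — almost always an artifact, so off by default). The recessive search
requires both parents het; a flag relaxes to carrier-or-hom-alt for
families with an affected parent. De novo and imprinted accepting sets are
provably disjoint (de novo needs the carrier parent hom-ref); the
recessive pattern (hom-alt, het, het) is *also* an imprinted-maternal and
imprinted-paternal pattern, and such variants are reported under every
matching mode with a cross-reference column rather than deduplicated — the
overlap is biologically real.

**Compound heterozygotes.** All unordered pairs of child-het variants
sharing a gene symbol, excluding only pairs *clearly incompatible* with
trans inheritance: (a) both variants unambiguously inherited from the same
parent — unambiguous meaning one parent carries the variant and the other
does not — or (b) either variant homozygous-alt in a parent. Unphasable
pairs (a variant carried by both parents or by neither) are retained, since
read-backed phasing is unavailable. Variants without a gene symbol cannot
be grouped and are skipped by this search only.

**Imprinted region gate.** Candidates must overlap ≥ 1 interval in the
imprinted-gene table whose expression class matches the search; genes with
ambiguous or unknown parent-of-origin expression are encoded as `both` and
belong to both search lists. The gate is purely coordinate-based, so the
table is extensible to non-coding and regulatory regions.

## Extended-pedigree parent-of-origin consistency

Given zygosities for any subset of family members, the checker decides
whether some assignment of each carrier's mutant allele to a parental
origin (het → maternal or paternal; hom-alt → both) satisfies:

1. *transmission*: an allele of maternal origin requires the member's
   mother, when genotyped, to carry the variant (paternal analogously);
   an ungenotyped or absent parent constrains nothing;
2. *phenotype under full penetrance*: a genotyped member is affected iff
   the allele of the expressing parent is mutant.

The search is exhaustive over the 2^(#het carriers) assignments — trivially
cheap for family-scale pedigrees (≤ 20 carriers) and exact, so no heuristic
is needed. Assumptions: full penetrance, no second de novo hits, no
uniparental disomy, no methylation mosaicism. These match the confirmation
role the check plays; it is not a general linkage tool. For the six-member
configuration shipped as a fixture (affected proband het; mother, maternal
grandfather, and maternal aunt het, unaffected; father and maternal
grandmother hom-ref), the checker returns consistent under maternal
expression — with the witness assignment putting the proband's mutant
allele on his maternal allele and every unaffected carrier's on their
paternal allele — and inconsistent under paternal expression, since the
hom-ref father forces the proband's mutant allele to be maternal, which
paternal-only expression would silence.

## Allele-biased expression

`percent_variant` = 100 × variant / (ref + variant), rounded half-up to one
decimal. The denominator is the *informative* read count, not the total:
reads carrying neither allele (sequencing error, other alleles) say nothing
about allelic balance. When a sample's total exceeds ref + variant the
report warns and shows both numbers. The optional exact two-sided binomial
test (`scipy.stats.binomtest`) quantifies imbalance against a null variant
fraction of 0.5; at the read depths typical of a single heterozygous site
(< 40×) it is underpowered, so the family report attaches no significance
verdict and is meant for ordering carriers, not hypothesis testing. A
hom-ref control member with any variant reads is flagged as an anomaly.

## Amplicon bookkeeping

Primer footprints are 1-based inclusive genomic intervals, orientation-free
(coordinates may be written in either order; reverse primers naturally
descend). Amplicon length = outer-edge span (max − min + 1) plus both
non-genomic 5' tail lengths; the shipped M13 tail constants are 18 bases
each. Overlapping footprints are a design error. The target-flanked check
requires the position strictly between the inner footprint boundaries — a
target under a primer would be dictated by the primer sequence.

## Synthetic family generator

The generator emulates the filtering context of a deeply sequenced family:

* **Pedigrees** — a trio, or a six-member extended family (trio plus
  maternal grandparents and a maternal aunt).
* **Background variants** (default 1,000) — site frequency drawn from
  Beta(0.3, 3) (rare-skewed spectrum, mean ≈ 9 %); founder genotypes are
  Hardy–Weinberg draws at that frequency; children receive one uniformly
  chosen allele from each parent, so transmission is valid by construction
  and the only Mendelian violations are planted de novo events. Depth is
  Poisson with mean 40 (matching > 40× genomes), with 5 % of sites drawn
  shallow (mean 6) to exercise the depth gate; site QUAL is uniform on
  [20, 90] and 5 % of sites carry a non-PASS filter. Impact classes are
  MODIFIER 0.55 / LOW 0.30 / MEDIUM 0.10 / HIGH 0.05; the drawn frequency
  is annotated into both population sources with ±10 % multiplicative
  noise.
* **Planted variants** — exact genotype patterns injected with PASS
  status, high QUAL, depth ≥ 10, HIGH impact, and frequency 10⁻⁴, so
  recovery depends only on the inheritance logic. The default plant list
  covers every mode plus two compound-het decoy pairs (a cis pair and a
  homozygous-parent pair) that must never be reported. A truth table
  records each planted variant's expected mode(s).
* **Cohort file** — ~10 % of background variants are echoed into a
  background-cohort file with the study trio's own configuration label,
  exercising the exclusion gate.
* Identical seeds produce byte-identical output files.

What the generator does *not* emulate: linkage disequilibrium, sequencing
error in genotypes, population structure, reference bias, structural
variants. Passing the planted-recovery suite therefore demonstrates the
correctness of the filtering and inheritance logic, not robustness to
real-world calling noise.

## Problem sizes and numerical choices

The shipped test suite and the acceptance script use 120–2,000 background
variants per simulated family — ample to populate every filter stage while
keeping a full run in seconds. Classifier checks are exhaustive (27 trio
combinations; all origin assignments for ≤ 6-member families), not
sampled. Rounding of reported percentages is decimal half-up to match how
such tables are conventionally printed; all internal arithmetic is exact
(integer or `Decimal`) until presentation.

## Known limitations

* No X-linked or mitochondrial modes, no uniparental disomy detection, no
  methylation analysis; sex chromosomes are treated as diploid.
* No reference-genome left-alignment (above).
* Frequency sources are taken from INFO annotations as given; no liftover
  or assembly checking is attempted — coordinates are opaque keys.
* The cohort exclusion assumes the cohort file and study VCF share the
  same normalization convention.
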