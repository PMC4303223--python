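# imprintseek

Family-trio variant prioritization with an **imprinted-gene inheritance
search mode**, plus the supporting pieces a diagnostic analysis needs: an
extended-pedigree parent-of-origin consistency check, allele-biased
expression arithmetic for RNA-Seq confirmation, Sanger amplicon
bookkeeping, and a synthetic family simulator for testing.

## The problem

Trio-based pipelines prioritize candidate disease variants by Mendelian
inheritance: de novo, autosomal recessive, compound heterozygous. Imprinted
genes break these filters. An imprinted gene is expressed from only one
parental allele, so a pathogenic variant manifests only when inherited from
the expressing parent — an affected child and an unaffected carrier parent
can share the same heterozygous genotype, and every Mendelian filter
discards exactly that configuration. Disorders such as IMAGe syndrome
(gain-of-function variants in the maternally expressed gene *CDKN1C*),
Angelman syndrome, and Beckwith–Wiedemann syndrome live in this blind spot.

`imprintseek` adds the missing search. For a maternally expressed gene, a
candidate variant must show: child het or hom-alt, mother het (the
unaffected carrier, silenced because she inherited it from *her* father),
father hom-ref or het. The paternal search mirrors this. Candidates must
also lie inside a known imprinted-gene region whose parent-of-origin
expression class matches the satisfied pattern (regions of ambiguous or
unknown expression are searched under both classes), and pass the same
quality, deleteriousness, and population-rarity gates as the Mendelian
modes:

* site FILTER `PASS`, site quality ≥ 30, every trio member fully called
  with read depth ≥ 10;
* snpEff-style impact HIGH/MEDIUM, or pathogenic / probably pathogenic in
  ClinVar, or disease-causing in HGMD;
* maximum population allele frequency across sources < 0.5 % (de novo) or
  < 1 % (recessive, compound-het, and by default imprinted searches);
* optional exclusion of variants seen with the same trio genotype
  configuration in a background cohort of unrelated families.

Once genotypes beyond the trio are available, the consistency checker asks
whether *any* assignment of the carriers' mutant alleles to parental
origins explains every member's affected status under full penetrance —
the formal version of "the unaffected mother must carry it on her paternal
allele".

## Worked example

Generate a synthetic trio (1,000 background variants plus one planted
variant per inheritance class, including an imprinted-maternal variant
inside the *CDKN1C* region), then run every search:

```
$ imprintseek simulate --seed 7 --n-background 1000 --out-dir demo
$ imprintseek search --vcf demo/family.vcf --ped demo/family.ped \
      --regions demo/regions.tsv --cohort demo/cohort.tsv \
      --modes all --out-prefix demo/out
...
INFO [imprinted_maternal] trio-quality         1010 ->    787
INFO [imprinted_maternal] deleterious           787 ->    126
INFO [imprinted_maternal] frequency             126 ->     61
INFO [imprinted_maternal] cohort-exclusion       61 ->     51
INFO [imprinted_maternal] imprinted-region       51 ->      1
INFO [imprinted_maternal] genotype-pattern        1 ->      1
imprinted_maternal: 1 candidate(s)
```

The attrition log shows each gate's survivor count; the single surviving
imprinted-maternal candidate is the planted one:

```
$ grep chr11 demo/out.imprinted_maternal.tsv
chr11  2884100  C  T  CDKN1C  imprinted_maternal  .  het  het  hom-ref  0.0001  HIGH  ABSENT  ABSENT  .
```

— child het, mother het, father hom-ref: invisible to the de novo search
(the mother carries it) yet fully consistent with a maternally expressed
gene.

Allele-biased expression from RNA-Seq read counts at the candidate site
(`percent_variant` = 100 × variant / (ref + variant); the p-value is an
exact two-sided binomial test against balanced expression):

```
$ imprintseek ase --counts counts.tsv --genotypes gt.tsv
sample   total  ref  variant  informative  percent_variant  p_value    genotype  anomaly
proband  8      3    4        7            57.1             1          het       False
mother   20     16   4        20           20               0.01182    het       False
father   29     29   0        29           0                3.725e-09  hom-ref   False
```

The affected proband expresses the variant allele at ~57 % while the
unaffected carrier mother shows ~20 % — the ordering expected if the
variant is expressed from the maternal allele and the carriers' paternal
copies are silenced.

Sanger confirmation geometry for the primer pair flanking the site (two
18-base M13 tails included):

```
$ imprintseek amplicon --forward 2884287,2884268 --reverse 2884008,2883988 \
      --forward-tail 18 --reverse-tail 18 --target 2884135
amplicon length: 336 bp
target 2884135: flanked
```

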