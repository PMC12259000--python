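# Methods

## Scope and model

The package treats an IRD gene atlas as the composition of five deterministic
classifiers over structured inputs:

1. a **curation rule engine** over expert evidence records;
2. a **bulk retina-prevalence classifier** over a genes × tissue-samples nTPM
   matrix;
3. a **single-cell specificity classifier** over a genes × 53 cell-subtype
   matrix of transcripts per 10,000;
4. a **variant-spectrum classifier** over per-gene ClinVar-style PLP variant
   counts;
5. a **functional-category assigner** over per-gene GO term sets.

plus the aggregate statistics computed over the curated gene table. All five
classifiers produce exhaustive, mutually exclusive partitions; the test suite
asserts this as a property, not per-example.

## Tissue grouping and the bulk rule

The bulk scheme ships 53 tissue sample names organized into 13 groups
(23 brain regions, 3 glands, 6 digestive tissues, 12 "diversive" tissues,
single-sample groups for heart, liver, lung, pancreas, skeletal muscle, lymph
node, testis, kidney, and retina). Aggregation is the arithmetic **mean** of
member samples; the `_max` suffixes in some group names are kept as naming
convention only. Because this mean-vs-max reading is a genuine ambiguity, the
aggregation function is configurable (`agg="mean"|"max"`); the default is
mean, which matches the prose definition of the grouping step.

z uses the mean and **sample** standard deviation (n−1) of the 12 non-retina
groups; a population-sd option (`ddof=0`) exists because the original choice
is not documented. Degenerate cases are closed deterministically:

- sd(others) = 0 → z is ±inf by direction (0 when equal), so the `z > 3`
  test reduces to `v_retina > mean(others)`;
- max(others) = 0 → ratio is +inf when v_retina > 0, and 1 for 0/0
  (a flat all-zero profile is maximally non-specific, not prevalent);
- the four bulk categories partition all genes: the published definition of
  "not retina-prevalent" (both z ≤ 3 and ratio ≤ 3) leaves the two mixed
  cases undefined, and we close that gap by assigning any expressed gene
  that fails the full prevalent conjunction to "not retina-prevalent".

Thresholds (z > 3, ratio > 3, expression floor 1 nTPM, all strict except the
floor which is inclusive: v ≤ 1 is low expression) are a single
`SpecificityThresholds` object, overridable everywhere; relaxing any of them
can only grow the prevalent set (tested as a monotonicity property).

## Single-cell scheme and rule

The 53 subtype names and their per-major-group multiplicities shipped in
`retina_cell_types.yaml` are a **synthetic reconstruction** (the upstream
per-cell-type table is not bundled); counts follow adult human peripheral
retina conventions (e.g. 12 bipolar types, 11 amacrine types, L/M + S cones).
The scheme is plain YAML and is expected to be replaced to match a real
table's column names; all code paths take it as a parameter.

Scoring differs from the bulk rule in two deliberate ways: the background of
a candidate category excludes **all major groups the candidate covers** (so a
cone gene's own signal cannot contaminate the Rods+Cones background), and the
ratio denominator is the background **mean**, not its max. The group-specific
threshold keeps the same z > 3 AND ratio > 3 form; the expression term of the
published rule is truncated in the source text, and we complete it as
value > 1, mirroring the bulk floor (configurable).

"Low expression" for a single-cell profile is operationalized as max over
the 19 major-group values ≤ 1, since no single whole-retina value exists in
this table. When a gene is specific both to a photoreceptor/RPE candidate and
to another cell type, the overarching label is Rods/Cones/RPE — photoreceptor
expression is treated as the biologically primary label for IRD genes.

## Variant spectrum

Fractions are computed over LoF + missense only; other PLP consequences
(in-frame indels, UTR, synonymous, …) count toward the rare threshold
(< 5 PLP) but not the fraction. The "mostly" bins are strict (> 0.75) and the
mixed band inclusive [0.25, 0.75], so the three fraction bins partition
[0, 1]; rare takes precedence over all fraction bins. A gene with ≥ 5 PLP
variants but zero LoF + missense has an undefined fraction and is categorized
mixed with a warning. Counting is per ALT allele. The ClinVar combined
assertion "Pathogenic/Likely_pathogenic" is included by default and
conflicting-interpretation records are excluded by default; both are flags.

## Curation engine

Consistency ("phenotype and inheritance consistent") and relatedness are
boolean expert judgments carried on the evidence records — they are inputs,
not computations. Criterion (i) requires at least one pair of records with
distinct variants, distinct family ids, both marked unrelated and both
consistent. Criterion (ii) requires a variant shared by such a pair with
strong functional evidence attached to that variant; the criterion does not
additionally require phenotype consistency. Exclusion flags (conflicting
evidence, proven non-association, locus without causative variant) are
definitive and take precedence over both criteria. What counts as "strong"
functional evidence is deferred to the user via the enumerated field.

## Functional annotation

GO matching is exact-term (no ontology ancestor propagation — noted as a
possible extension); the union of mapped categories over a gene's terms is
its category set, an empty union falls back to "Others", and per-gene manual
overrides (with free-text provenance) take precedence, modelling curator
reclassification of genes annotated only under generic terms. "Others"
counts as a category in the single/multiple membership split. The four
mapped loci carry no GO terms and are skipped by annotation.

## Synthetic data: what it emulates and what it does not

Expression noise is multiplicative log-normal with unit mean,
parameterized by its coefficient of variation (σ² = ln(1 + CV²)): expression
data are non-negative and heteroscedastic, so additive Gaussian noise would
misrepresent them. Planted prevalent/specific genes sit at
baseline × fold-change in their target columns; low-expression genes are
drawn uniformly in (0, 1] so the floor rule fires deterministically at zero
noise. Study conditions used throughout the tests and the acceptance script:
baseline 5, fold-change 10, CV 0.1, 50 planted of 1,000 genes, 10% low
expression, seeds 1–5.

The generator does **not** model single-cell count sparsity or transcript
dropout, library-size variation, batch effects, or correlated co-expression.
Passing recovery tests therefore demonstrates correctness of the scoring
arithmetic and decision rules under the stated noise model, not robustness
to real scRNA-seq artifacts.

The published-design gene table (`simulate.published_atlas`) plants the
atlas's printed marginal structure — 468/196/16 statuses, the 202/322/56
Venn partition, the 323/70/36/22/17 inheritance split, per-subset counts
(RP = 103, …), 52 multi-phenotype non-syndromic genes, the 299/165
single/multi functional split with Cilium = 83 and a Cilium×Cytoskeleton
overlap of 20, and discovery rates of 11/year before 2010 and 8/year from
2018 (6 genes in the final year). Subset-to-gene assignment uses a
deterministic greedy deal (most-abundant-subset-first), and everything not
pinned by a marginal (gene symbols, which gene gets which year, pairings of
inheritance and phenotype) is synthetic and seed-shuffled. One marginal
cannot be honored simultaneously with the others: per-period rates of
11, 26 and 8 genes/year over 1988–2009, 2010–2017 and 2018–2024 would sum to
more genes than the atlas contains, so the design keeps the first and last
rates exact and lets the middle period absorb the remainder (21.25/year);
the overall mean, 468/37 ≈ 12.7/year, is preserved.

Expression-specificity and variant-spectrum *percentages* of a real atlas
depend on versioned external datasets (expression compendia, a ClinVar
snapshot) and are not reproducible from code alone; for those stages the
package substitutes oracle-equivalence checks (brute-force arithmetic on
random genes; exhaustive enumeration of PLP compositions to total 20) and
planted-truth recovery, which the acceptance script reports.

## Numerical and reporting conventions

- Sample sd (ddof=1) everywhere by default.
- Percentages are printed to one decimal, round half up.
- Period rates use half-open year intervals [start, end); both the mean of
  annual counts and the OLS slope of the cumulative curve are reported, since
  "average discoveries per year" can mean either.
- Multi-membership counting in all co-occurrence matrices: a gene with two
  labels on an axis increments both rows. Row sums therefore exceed gene
  totals in the presence of multi-label genes — deliberate, and asserted in
  tests.
- TSV/VCF float round-tripping uses pandas' `float_precision="round_trip"`
  so write-then-read is bit-exact.
- Problem sizes in the tests (matrices of 150–1,000 genes, 1–5 seeds,
  enumeration to 3 evidence records and 20 PLP variants) were chosen as the
  smallest designs that exercise every rule branch and give stable recovery
  statistics.

## Known limitations

- The shipped cell-type scheme is a reconstruction; results on real
  single-cell tables require the matching scheme file.
- No ClinVar review-status (star) filtering; all assertions weigh equally.
- Exact-term GO matching can under-annotate genes whose relevant terms are
  descendants of the mapped ids.
- The curation engine evaluates records as given; it cannot detect
  inconsistencies between records (e.g. contradictory relatedness claims).
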