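# Methods

This note documents the statistical procedures implemented in `mdrpipe`,
the conventions chosen where the analysis recipe is genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## Data model

Genotypes are unordered biallelic calls. Internally each call is the
count (0/1/2) of the lexicographically later allele, with −1 for
missing; the canonical serialized form orders alleles lexicographically
("GA" and "AG" are the same genotype and both serialize as "AG").
Phenotypes carry a binary case/control status, an optional binary
sub-phenotype defined only within cases (e.g. coronary-lesion formation
among patients), and non-negative continuous biomarker concentrations in
pg/ml. The TSV genotype dialect stores SNP metadata (gene symbol, allele
pair, panel category) in the header cells so a write/read cycle is the
identity; the PLINK-style text ped/map dialect, which cannot carry that
metadata, uses a small `.snpinfo.tsv` sidecar for the same reason.

## SNP quality control

A SNP is excluded when its call rate is strictly below 0.90 or its
Hardy-Weinberg p-value is at or below 0.001. HWE is tested with the
exact conditional test: given the observed allele counts, the
probability of each attainable heterozygote count follows

P(n_AB | n, n_rare) ∝ n! · 2^{n_AB} / (n_AA! · n_AB! · n_BB!),

and the two-sided p is the sum over configurations no more probable than
the observed one, computed with the standard mid-outward recurrence. The
exact test is preferred over the chi-square (available as an option)
because its behaviour at low MAF matters at cohort sizes of a few
hundred; the test suite verifies it against full enumeration with exact
integer arithmetic to 1e-12. When phenotypes are available HWE is
evaluated in controls only — the standard convention, since deviation in
cases can be genuine signal. MAF is computed from non-missing calls. A
MAF < 5% pre-filter is provided for emulating assay design but is not
part of cohort QC.

Boundary conventions: call rate exactly 0.90 is retained; HWE p exactly
0.001 is excluded.

## Single-locus association

**Univariate screen.** Each SNP is tested with a Pearson chi-square on
the 2×3 outcome-by-genotype table (df = 2, no continuity correction;
empty genotype columns dropped; an allelic 2×2 variant is available).
Results with p < 0.10 are flagged; all results are retained. A SNP with
a single observed genotype class is reported as degenerate with p = 1.

**Best genetic model.** For each SNP, the outcome is regressed
logistically on each of four encodings of the reference allele R
(default: the minor allele): dominant (≥1 copy of R), co-dominant
(heterozygote vs. pooled homozygotes), recessive (homozygous R), and
additive (copy count, giving a per-allele OR — which is why additive ORs
sit close to 1). The encoding with the smallest Wald p is reported as
the best-fitting model with OR = exp(β) and Wald 95% CI; p ≤ 0.05 is
flagged. Samples missing the genotype are dropped for that SNP; constant
encodings are skipped; on (quasi-)separation, binary encodings fall back
to the Haldane-corrected 2×2 collapse (add 0.5 to every cell iff any
cell is zero) with a Wald p from the corrected table, and the result is
annotated.

Because the best-of-four minimum p is taken without correction, the MVA
stage is anti-conservative relative to its nominal 0.05 level; this is
deliberate (the downstream permutation machinery owns error control) and
is asserted empirically in the test suite. No covariate adjustment is
applied by default.

## Multifactor dimensionality reduction

For a set of k loci (k ≤ 3), the 3^k genotype cells are labelled
high-risk when the cell's training case:control ratio is ≥ T, with
T = (training cases)/(training controls) — the standard threshold for
unbalanced designs, which together with balanced-accuracy scoring keeps
a 226:575 design from degenerating into majority prediction. A sample is
"predicted case" iff its cell is high-risk; model quality is balanced
accuracy (sens + spec)/2.

Conventions where the procedure is underdetermined:

* cells empty in training are low-risk, and a test sample falling in an
  unlabelled cell is predicted low-risk (deterministic, conservative);
* a cell with training controls = 0 and cases > 0 is high-risk;
* the ratio boundary is inclusive (ratio = T ⇒ high-risk);
* samples missing a genotype at any model locus are excluded from that
  locus set's fit (complete-case per set);
* the stratified fold partition is drawn once per run from the seed and
  reused across all locus sets and all permutations (permutations
  shuffle outcome labels only), which removes fold-resampling noise from
  the permutation comparison;
* fold winners maximize training balanced accuracy with ties broken
  lexicographically; the best fit per k maximizes CVC, then mean testing
  balanced accuracy, then lexicographic order, giving a total order;
* a fold whose training or testing split lacks a class (possible only in
  tiny fixtures) contributes NaN and is dropped from that set's mean.

The search is exhaustive over all C(m, k) locus sets, vectorized as two
weighted bincounts per set per evaluation so that label permutations are
cheap. The permutation p for the best model's mean testing balanced
accuracy is add-one: p = (1 + #{permuted ≥ observed})/(B + 1), which is
never zero and is super-uniform under the null. Testing balanced
accuracy below 0.5 is attainable (overfit models generalizing worse than
chance) and is reported as computed.

Defaults mirror the emulated analysis: 20 folds, 10,000 permutations,
significance at permutation p ≤ 0.05; both are configurable because
desk-scale work uses 99–1,000 permutations.

## Risk profiling and biomarkers

The final reported grid re-derives cell labels on the full dataset with
T = the full-data case:control ratio — this is how a single 3^k grid
with one label per cell exists even though model selection used 20
folds. Every complete-genotype sample is assigned its cell's label;
the high-vs-low effect is quantified by unadjusted logistic regression
(OR, Wald 95% CI and p) plus a Pearson chi-square on the 2×2 table, with
Haldane-corrected OR and Fisher's exact p when a cell is zero. Shares
such as "percentage of cases in high-risk cells" are computed on the
full data. Report percentages are rounded to one decimal, half-up.

Biomarkers are compared between risk groups with a two-sided Welch
t-test on raw levels (the Mann-Whitney U is an option), reporting group
means ± SEM. The per-level odds ratio is a convention: exp(β) from a
logistic regression of group membership on the standardized
log-transformed level, i.e. the odds multiplier per 1 SD of log
concentration — a continuous-exposure OR is dimensionless only once a
unit convention is fixed, and this one is stated explicitly wherever it
is reported. No multiplicity correction is applied across the panel
(matching the emulated analysis); a Bonferroni column is emitted for
transparency.

## Synthetic data

The generator draws genotypes per SNP under Hardy-Weinberg proportions
at a MAF sampled uniformly from [0.05, 0.5] (overridable per SNP), and
accrues cases and controls retrospectively: population candidates are
drawn, their case probability evaluated, and sampling continues until
the requested margins are hit exactly — matching a fixed-margin
case-control design. Case probability combines, on the logit scale, a
baseline (or a planted k-locus penetrance table) with any single-locus
marginal effects (log-OR per encoding unit).

The bundled study-scale configuration uses a rare-disease baseline
(0.5%), so controls approximate the source population and causal loci
remain in HWE among controls; with a common-disease baseline,
conditioning controls on non-case status induces a real heterozygote
deficit at strong causal loci, which is a property of case-control
sampling, not of the genotyping.

Planted structure:

* *QC failures*: designated SNPs with elevated missingness (default 20%,
  guaranteeing call rate < 90% at n ≈ 800) and HWE violators drawn with
  an inbreeding-style heterozygote deficit F (default 0.8, which the
  exact test rejects at 0.001 with near certainty at these sample
  sizes). Missingness elsewhere is MCAR at 2%.
* *Epistasis*: the two-locus pattern elevates penetrance on cells where
  exactly one locus is heterozygous (heterozygosity-XOR). At MAFs
  0.3/0.4 the heterozygote probabilities are ≈ 0.42/0.48, so the
  single-locus marginals are near null while the joint effect is strong
  — the regime in which interaction-aware search outperforms per-SNP
  tests. A carrier-status XOR was rejected because carrier probabilities
  (0.51/0.64) leave a marginal OR ≈ 0.75 that a univariate screen
  detects too often.
* *Biomarkers*: lognormal concentrations assayed in cases only (as in
  the emulated study), with a configurable log-mean shift for samples in
  true high-risk cells.

A truth record lists every planted effect for recovery scoring. The
generator does **not** emulate linkage disequilibrium between SNPs,
population stratification, informative missingness, or assay noise;
passing recovery tests therefore demonstrate correctness of the
machinery under the stated generative model, not robustness to those
real-data phenomena.

## Problem sizes and runtime choices

Exhaustive three-locus search over a 345-SNP panel is C(345,3) ≈ 6.8M
locus sets per evaluation; with permutation testing this is not a
desk-scale computation. The packaged experiments therefore use panels of
6–20 SNPs for MDR (where exhaustive search plus hundreds of permutations
takes seconds to minutes) while QC and the single-locus stages run at the
full 384-SNP scale; the pipeline also accepts an optional cap that
restricts the MDR pool to the top-m univariate SNPs for larger panels.
Null-calibration experiments use 99–500 permutations with the add-one
estimator; recovery experiments use 100–200 replicates. Within one run
everything derives from a single integer seed, and report files contain
no timestamps, so identical (inputs, config, seed) produce byte-identical
artifacts.

## Known limitations

* The MVA "multivariate" stage is unadjusted single-SNP modelling under
  four encodings, not a joint multi-SNP model.
* Covariate-adjusted and model-based MDR variants are out of scope.
* The permutation engine is single-process; 10,000 permutations over a
  large panel is a batch job, not an interactive one.
* The biomarker per-level OR depends on the stated 1-SD-of-log
  convention; values computed under other unit conventions are not
  comparable.
* Haplotypes, imputation, sex chromosomes, multiallelic sites and phased
  genotypes are unsupported by design.
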