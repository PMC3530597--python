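# Methods

This note documents the models and procedures implemented in `cnvburden`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that matter for
reproducing results.

## Coordinates and data model

All genomic coordinates are 1-based inclusive internally, the convention
of PennCNV-style call files; BED gene annotations are converted on read
(start + 1). A CNV is a segment with copy number ≠ 2; copy number < 2 is a
deletion, > 2 a duplication (the *dosage class*). Marker maps give each
SNP or CNV probe a fixed position; CNV calls are marker-delimited, so
marker counts within a segment are well defined and are always recomputed
from the map rather than trusted from caller output.

## Consensus harmonization

Two callers observe the same samples. Only variants called by both are
analysed. A match requires the same sample, chromosome and dosage class
plus positive coordinate overlap; the consensus boundaries are the
intersection `[max(starts), min(ends)]`. Matching is at dosage-class
level, not exact copy number — requiring CN=0 to match CN=1 would
discard real deletions over a disagreement callers are known to have —
and both callers' copy numbers are retained as provenance. One-to-many
overlaps are resolved greedily by largest overlap, ties by leftmost
start: deterministic and order-independent after sorting.

**Split-segment merging.** Callers sometimes emit one variant as two
adjacent fragments. Two adjacent segments of the same sample, chromosome
and dosage class are merged when each member is strictly longer than
200 kb and the gap (next start − current end − 1) is strictly less than
half the merged span. The 200 kb condition is applied to *each* member —
the stricter of the two possible readings; both thresholds are
configurable (`--min-merge-length`, `--max-gap-fraction`). The rule is
applied left-to-right and iterated to a fixpoint. Because merging only
enlarges segments and both conditions are monotone in segment length,
the fixpoint is unique regardless of merge order (verified in the test
suite by exhaustive enumeration of merge orders on random chains).
Visual inspection of merge candidates is replaced by unconditional
application of the rule, for reproducibility.

## Quality control

Sample level (all thresholds configurable, defaults in parentheses):
exclude samples with LRR SD strictly above 0.3; with 30 or more CNV calls
longer than 100 kb; and the lower-SNP-call-rate member of each
duplicate-genotyped pair (ties broken by sample id). Every exclusion is
logged with its reason. A duplicate-pair concordance diagnostic (fraction
of one member's CNVs overlapped by a same-class CNV in the other) is
provided as a report, not a filter.

CNV level: keep consensus segments spanning ≥ 15 markers *and* ≥ 500 kb.
Rarity: for every marker and cohort, the carrier frequency is the number
of distinct cohort samples with a CNV covering that marker divided by the
cohort size; a CNV is discarded when any marker along its length exceeds
1% in the carrier's cohort. Frequencies are computed once, on the
post-basic-QC consensus set, and applied in a single pass — the removal
step is not iterated, so the filter is idempotent given a fixed frequency
table. A `whole_sample` scope (one pooled frequency column) is available
as a sensitivity option. Basic CNV QC precedes the rarity filter, so
frequency estimation sees only well-supported segments; the pipeline
logs record counts surviving every stage.

Note a practical constraint that the demo configuration respects: with a
1% threshold, a cohort must exceed 100 samples for even a single carrier
to count as rare; tiny cohorts make the rarity filter degenerate.

## Burden metrics

Per individual and per dosage class (all / deletions / duplications):
CNV count, total consensus length in bp (the intersection segment is the
analysis unit, not either caller's original span), and genes disrupted —
the number of *distinct* genes whose coordinates padded by ± 20 kb
(clamped at position 1) overlap any of the individual's CNVs. A gene hit
by two CNVs of one person counts once for that person, but contributes to
every carrier's record. Non-carriers get explicit zero records. Cohort
summaries report load (sum of counts), rate (load / cohort N, rounded to
3 decimals in reports, full precision retained), the carrier histogram
(0/1/2/3+), and gene load/rate, each split by class. Gene-overlap queries
use interval trees (`intervaltree`).

## Cognitive phenotypes

*g*<sub>f</sub> is the first unrotated principal component of the
fluid-type subtest battery, extracted per cohort from the correlation
matrix of complete cases (rows missing any subtest are dropped within the
battery). Eigen-decomposition is by `numpy.linalg.eigh`; the component
sign is fixed so the majority of loadings are positive; the report states
eigenvalues, loadings, variance explained, and whether only the first
eigenvalue exceeds 1. *g*<sub>c</sub> is a single vocabulary-type score,
no PCA. Both are residualized by OLS on age, plus a sex indicator except
in cohorts whose phenotypes are derived separately by sex (there the
model is fitted and residuals standardized within sex, then
concatenated). Standardized residuals (mean 0, SD 1 within the derivation
group, population SD) are the analysis phenotypes; because derivation and
standardization are per cohort, cohort mean differences are removed by
construction and the cohort covariate in the regressions is a guard, not
a load-bearing correction.

One cohort family in the target study derived fluid scores from a
maximum-likelihood random-effects model over alternating test batteries.
That model's battery structure is not specified anywhere usable, so this
package applies the same PCA path to those cohorts, with sex-stratified
residualization preserved.

## Association

**Burden regressions.** OLS of the residualized phenotype on one burden
variable plus cohort indicator covariates (statsmodels). Both outcome and
predictor are scaled to unit sample SD, so the reported coefficient is a
standardized β; the analytic p is the coefficient's two-sided t-test. A
zero-variance burden variable (no carriers) yields a flagged, undefined
result rather than an exception.

**Permutation empirical p.** The phenotype vector is permuted uniformly
across individuals; burden and covariates stay put. By
Frisch–Waugh–Lovell the refit per permutation reduces to a dot product
with the cohort-residualized predictor, making 100,000 refits cheap. The
empirical p is the proportion of permutations with |β| ≥ |β observed|
(it can therefore be exactly 0; an add-one smoothing option exists,
default off). Permutations are unrestricted across the whole sample; a
within-cohort option is provided. Permutation streams are chunked with a
fixed chunk size (512) so a given seed always yields the same stream,
and every model in the regression grid draws an independent substream of
the base seed, so each result is reproducible component-wise.

**Candidate-region carrier tests.** A sample is a carrier of a region if
any of its rare CNVs overlaps it (any positive overlap, either dosage
class). A region is testable only when more than two individuals carry a
variant. Carriers vs non-carriers are compared by a two-sample two-sided
t-test. The default *pools* variances. This is a deliberate choice: with
carrier groups of 3–5, the Welch statistic has roughly k − 1 ≈ 2
effective degrees of freedom and a permutation null with extremely heavy
tails, which makes the corrected test essentially powerless at any
realistic effect size; the pooled statistic borrows the large non-carrier
group's variance and behaves like a z-statistic. The Welch variant
remains available (`equal_var=False`). Degenerate inputs (all phenotype
values equal) yield NaN statistics flagged not-computable.

**Max-T correction.** Carrier sets — hence testability — are fixed once
from observed data. Each permutation shuffles the phenotype vector,
recomputes every testable region's statistic (complement moments are
recovered from the permutation-invariant totals, so cost scales with
carriers, not n), and retains the maximum; by default statistics enter as
absolute values (a signed option exists). A region's corrected empirical
p is the proportion of permutations whose maximum *strictly* exceeds its
observed statistic. Untestable regions are excluded from the maximum at
every permutation. The permutation stream depends only on (seed, n,
chunking), not on the panel, so enlarging the panel under the same seed
never decreases an existing region's corrected p.

## The synthetic generator

Everything is a pure function of (config, seed); each stage — sample
attributes, CNV placement, QC metrics, phenotypes, each caller — draws
from an independent, deterministically derived substream.

Defaults describe the study conditions the pipeline targets: five cohorts
of community-dwelling older adults (sizes 346 / 482 / 877 / 730 / 698,
N = 3,133; birth cohorts with age SD under a year, volunteer cohorts
wider), rare CNVs arriving per sample as Poisson with mean 0.053, of
which 24.6% are deletions, lengths log-uniform on 500 kb – 3 Mb, placed
uniformly on a 22-chromosome marker map (2,000 markers per 50 Mb
chromosome by default, ~25 kb spacing, so a 500 kb CNV spans ~20
markers and the 15-marker rule binds realistically). Callers observe the
truth with boundary jitter (± 10 kb, snapped to the first/last marker
inside the jittered span), a 5% per-caller miss rate, and a 5% chance of
emitting a call as two fragments separated by a one-marker gap — the
artefact the merge rule repairs. QC metrics plant a configurable 2% of
samples above the LRR SD threshold, 1% with excess long calls, and 10
duplicate pairs. Optional common CNV loci (> 1% carriers) exercise the
rarity filter.

Phenotypes: each sample gets `n_subtests` (default 4) fluid subtest
scores and one vocabulary score. Subtests load 0.7 on a shared latent
factor (one factor per battery — the simplest structure under which
first-PC extraction is the right thing to do), giving PC1 about half the
battery variance; plus an age slope (−0.03 SD/yr for fluid, −0.01 for
vocabulary), a small sex offset, a cohort offset, and unit-variance
noise. Configured standardized burden effects (β for count, length,
genes) enter the latent factors directly, with the latent residual
variance shrunk so each latent keeps unit variance. Consequently a
planted β is recoverable as a standardized regression coefficient of ≈ β
on the single-score (vocabulary) phenotype, while the PCA-derived fluid
phenotype recovers it attenuated by the PC1–latent correlation — in
closed form √(kλ²/(kλ² + 1 − λ²)) ≈ 0.89 at k = 4, λ = 0.7. Parameter-
recovery checks therefore target the vocabulary path; the attenuation on
the PCA path is itself asserted against the closed form.

What the generator does **not** emulate: LRR/BAF intensity signals or HMM
calling (callers are modelled directly as noisy interval observers),
linkage structure between markers, non-uniform CNV hotspots, genuinely
recurrent region-specific variants, per-cohort battery differences, or
missing phenotype data. Passing tests therefore demonstrate the
correctness and calibration of the pipeline's logic under a clean
generative model, not robustness to real-array artefacts.

## Numerical conventions and edge cases

- Threshold directions follow the stated rules exactly: LRR SD strictly
  > 0.3 excludes; ≥ 30 long calls excludes; ≥ 15 markers and ≥ 500 kb
  keep; frequency strictly > 1% discards; merge members strictly
  > 200 kb.
- Standardization uses population SD (ddof 0) for residuals, sample SD
  (ddof 1) for regression scaling; both choices cancel where ratios are
  taken and are asserted in tests where they do not.
- Covariates that numerically explain all phenotype variance raise an
  error rather than standardizing noise.
- Empirical p-values are proportions over exactly B permutations;
  determinism under a seed is bit-for-bit, including across chunking.
- Reports round rates to 3 decimals; all internal computation is full
  precision.

## Problem sizes used in the checks

Calibration and recovery suites run at reduced but honest scale:
permutation uniformity and family-wise error with n = 3,000, B = 1,000
over 500 replicates each; effect recovery (β = −0.5) over 100 replicates
at n = 3,000; the 3-carrier region analogue over 15 replicates. Oracle
equivalence suites use ≥ 1,000 random small instances per primitive
against brute-force enumeration.

## Known limitations

- The consensus model handles exactly two callers; multi-caller consensus
  and reciprocal-overlap matching are out of scope.
- The rarity filter assumes cohorts large enough that 1/N < 1%; it is
  degenerate for cohorts of ≤ 100 samples.
- Carrier tests with very few carriers are sensitive to the
  pooled-variance assumption; the Welch option is provided but is
  low-powered by construction at these group sizes.
- The random-effects fluid-score model of one cohort family is
  approximated by the common PCA path (see above).
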