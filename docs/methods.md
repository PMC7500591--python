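# Methods

`phyllodiff` implements a differential functional-annotation analysis for
leaf-surface (phyllosphere) metagenomes sampled under contrasting water
treatments. The unit of analysis is an annotation-by-sample count table
(UniProt gene-family counts on a counts-per-megabase scale, as produced by
HUMAnN2-style profilers), with a handful of samples per field site: two to
three replicates per treatment group, plus mock and soil control samples
collected with the same protocol.

## Data cleaning

**Contaminant filtering.** Any annotation with a nonzero count in any mock
or soil control sample is treated as a contaminant — sampling-equipment or
soil carryover — and removed from every sample before testing; the control
columns are then dropped. The presence threshold is configurable (default
0, i.e. any presence) and the removed IDs are reported for audit.

**Depth classes.** Samples are classed by total reads as small (< 233k),
moderate (233–500k), large (500k–1.7m) or deep (> 1.7m). The published
class definitions leave the range 1.6–1.7m unassigned; we assign it to
"large" since "deep" is defined as strictly above 1.7m. Intervals are
half-open on the right.

**Imputation.** The second-stage model needs three replicates per group.
A group observed with exactly two samples receives one pseudo-replicate,
drawn per annotation from a negative binomial whose mean and dispersion
come from the two observed values (dispersion floored at 0.01), at a
sequencing depth equal to the geometric mean of the two observed column
totals. The imputed column is flagged `imputed=True`, never overwrites
observed data, and is excluded from any trait-style summary. The exact
imputation algorithm used by the original two-stage software is not
published; drawing from the fitted count model is our choice because it
matches the downstream NB model and is auditable.

## Two-stage differential testing

**Normalization.** Method 1 is TMM (trimmed mean of M-values): per sample
against the highest-depth reference column, genes positive in both are
trimmed 30% from each tail of the log-ratio distribution and 5% from each
tail of the average-abundance distribution, and the factor is the
precision-weighted mean of surviving log ratios; factors are rescaled to
geometric mean one and multiply the library size to give an effective
depth. Method 2 is the DESeq-type median-of-ratios size factor: the
per-sample median of gene-wise ratios to the geometric-mean
pseudo-reference, computed over genes positive in every sample (with a
positive-entries fallback when no such gene exists). Both implementations
were verified to eight decimals against the R reference implementations on
toy tables; the tests carry independent brute-force oracles.

**Stage 1 — elastic-net screen.** A penalized binomial regression of
treatment on per-annotation abundances, transformed as
`log(count / relative depth + 1)` and standardized. The mixing parameter
defaults to 0.5 (equal L1/L2). The penalty is chosen by cross-validated
deviance over a 16-point grid — leave-one-out for designs of up to 8
samples (this pipeline's regime), 5-fold otherwise. With six samples the
deviance minimum is extremely shallow and routinely admits ~95% of all
annotations, which would make the screen vacuous; the default is therefore
the one-standard-error rule (the strongest penalty within one SE of the
minimum, the glmnet convention), which keeps the screened set at roughly a
fifth of the table while retaining about 70% of annotations with a
four-fold planted change. `cv_rule="min"` restores the plain minimizer.
Annotations constant across samples are dropped from the screen with a log
line. Whether the screen regresses treatment on annotations or vice versa
is not documented for the original software; we regress treatment on
annotation predictors, the standard orientation for elastic-net screening.

**Stage 2 — negative-binomial test.** For each screened annotation, a NB
GLM with log link, treatment as the sole factor (the two-stage method
cannot fit factorials), an offset of log effective depth, and variance
mu + phi·mu². The treatment coefficient is tested with a Wald statistic.

Dispersion estimation is the critical numerical choice at three samples
per group:

- The default, `dispersion_mode="common"`, estimates a single dispersion
  shared across annotations by maximizing a Cox–Reid-adjusted profile
  likelihood summed over all annotations that pass the prevalence filter
  (the adjustment `0.5·log det(X'WX)` corrects the bias from estimating
  two group means per annotation from six observations; without it the
  shared dispersion is underestimated by roughly 40% and the test is
  anticonservative). With thousands of annotations the shared estimate is
  precise, so the Wald statistic is referred to the normal distribution.
  Null simulations at the reference conditions (phi = 0.2, n = 3 vs 3)
  give empirical type-I error within the binomial 99% band of the nominal
  0.05 and near-nominal tail behavior at 0.001.
- `dispersion_mode="moments"` uses a per-annotation leverage-corrected
  method-of-moments estimate (floor 1e-8) and refers the statistic to
  Student t with n − 2 degrees of freedom, acknowledging the four degrees
  of freedom behind the estimate. This mode is robust to
  annotation-specific dispersion but pays a large power cost at small n.

A fit that does not converge, or an annotation with an all-zero treatment
group, yields a flagged result with p = 1 rather than an exception.

**Prevalence filter.** Before stage 2, annotations are required to be
nonzero in every experimental sample (configurable via `min_nonzero`;
zero-total rows are always dropped). Zero-inflated tables otherwise
produce null annotations whose structural zeros happen to concentrate in
one group, mimicking large fold changes that the NB model cannot absorb;
with three replicates per group such annotations cannot support NB
inference at all. This is the analogue of the expression filtering rule
that count-based differential-expression packages apply routinely.

**Thresholding.** No multiple-testing correction is applied within a run;
the operating alpha is calibrated by simulation (below), mirroring the
original analysis. Benjamini–Hochberg adjustment is available as an
option. Post-selection inference is documented, not corrected: p-values of
screened annotations are not uniform under the null, which is exactly why
the realized FDR is measured by simulation rather than read off alpha.

## Synthetic data

The generator simulates at the count-table level — the pipeline's entry
point — rather than at the sequence level; simulated reads in the original
study existed only to be turned into counts, and an alignment stage would
add nothing testable here. One simulated experiment is a per-site
two-group design with:

- lognormal baseline abundances (meanlog 3.0, sdlog 1.5), giving the
  heavy-tailed rank-abundance structure of real annotation tables;
- zero-inflated NB counts, mean = baseline · library size · 2^(lfc·treat),
  dispersion phi = 0.2, structural zeros as an independent Bernoulli(0.1)
  mask per entry;
- library sizes spanning the observed sequencing-depth classes: one
  sample per class at representative depths 0.15 / 0.35 / 1.0 / 2.0
  million reads, so normalization is exercised across the full observed
  depth spread (controls sit at 0.15, matching the observed "small"
  controls);
- 5% truly differential annotations at |log2 fold change| = 2 with random
  sign, 50 contaminant annotations present in both the experimental
  columns (where they behave like nulls) and the mock/soil columns (so
  the filter has real work to do), and the remainder null;
- 3 replicates per treatment group, seeded and byte-reproducible.

What the generator does not emulate: phylogenetic or pathway correlation
between annotations (rows are independent given their baselines),
compositional coupling, depth-dependent annotation bias, and
between-replicate overdispersion beyond the NB. Passing tests therefore
demonstrate correctness of the machinery and calibration under the stated
generative family, not performance guarantees on field data.

The trait generator produces two-group (optionally plot-blocked) normal
trait tables with a known watered-minus-drought difference, used for
parameter-recovery tests at the effect magnitudes reported for the field
trials.

## FDR calibration

`run_grid` sweeps alpha ∈ {0.05, 0.01, 0.001} × normalization method
∈ {TMM, DESeq-type} over 25 seeded replicates of the generator at the
reference conditions, runs the full filter + two-stage pipeline on each,
and tabulates TP/FP/TN/FN against the planted truth (contaminants are
excluded from the universe once filtered; FDR = FP/(FP+TP) and power =
TP/(TP+FN), both 0/0 ↦ 0). Since neither the screen nor the dispersion
estimate depends on alpha, each (seed, method) pipeline is run once and
re-thresholded per alpha — equivalent to a full re-run per grid point.
The operating point is the FDR argmin subject to a configurable power
floor, ties broken toward smaller alpha and then method 1. The original
grid varied sequence-similarity cutoffs; a count-level simulation has no
alignment step, so the analogous axes here are effect size, signal
fraction, dispersion and alpha. 25 seeds keeps the sweep under ~4 minutes
on one CPU while bounding the Monte-Carlo error of mean FDR at roughly
0.01.

## Cross-site comparison

Significant UniProt IDs are mapped to GO terms through a local
many-to-many TSV (an offline join; the interactive conversion service the
original analysis used would break reproducible testing), with unmapped
IDs reported rather than dropped. Per-site term sets are decomposed into
exact Venn regions (every region computed from exact membership, so
inclusion–exclusion holds by construction), and term networks are
exported to GraphML or TSV with node sizes taken from supplied term
frequencies. Semantic clustering (SimRel-style) and layout are out of
scope; edges are accepted as input.

## Plant traits

Treatment effects on height, seed weight and cob diameter are estimated by
OLS with water treatment as a nominal factor and optional plot-ID fixed
effects (no treatment × plot interaction, consistent with the reported
absence of one; whether the original block term was fixed or random is not
published — fixed is assumed). Effects are reported as reduction under
drought (positive = smaller under drought) together with SE, p-value,
group means/sizes and percent reduction relative to the watered mean.
Declarative exclusion rules (zero-valued rows, whole plots, arbitrary
predicates) are applied with an audit trail, and removing an entire
treatment level is an error.

## Numerical choices and degenerate inputs

- Dispersion bounds for the profile search: [1e-4, 10] on phi, optimized
  on the log scale by bounded scalar minimization.
- Moment dispersion floor 1e-8; imputation dispersion floor 0.01.
- TMM trim proportions 0.3 (log-ratio) and 0.05 (abundance), each per
  tail; reference = highest-depth sample.
- Elastic-net C grid: 16 points log-spaced in [1e-3, 1e2]; saga solver,
  seeded; duplicated predictors enter or leave together for mixing < 1.
- Ties at identical mean FDR resolve toward smaller alpha, then method 1.
- FDR and power use the 0/0 ↦ 0 convention.
- Child seeds for replicate sweeps derive from a seed sequence over
  (base seed, replicate index) and stay below 2^31.

## Known limitations

- The common-dispersion default assumes dispersion is exchangeable across
  annotations; strongly annotation-specific dispersion would call for the
  moments mode or an empirical-Bayes trend, which is not implemented.
- Post-selection p-values are not corrected; realized error is controlled
  only through the simulation-calibrated alpha.
- The screen's recall (~0.7 at four-fold changes, 3 vs 3) bounds overall
  power; the pipeline is designed to be conservative at the operating
  alpha, not powerful.
- Imputation treats the two observed replicates as exchangeable and
  cannot manufacture real degrees of freedom; it exists to satisfy the
  three-sample requirement of the second stage.
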