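# Methods

## The model

Methylation beta-values `β ∈ (0,1)` are mapped to M-values
`M = log2(β/(1−β))` (clipped at `ε = 1e−6` so rounded 0/1 betas stay
finite), residualized on sample covariates by ordinary least squares
(intercept always included; categorical covariates treatment-coded), and
rank inverse normal transformed (RINT) per CpG with the Blom offset 3/8:
the value with average rank `r` among `n` maps to
`Φ⁻¹((r − 3/8)/(n + 1/4))`.  Ties receive average ranks, deterministically.
The fixed order — M-transform, residualize, RINT — means the mixed model
always sees approximately Gaussian, covariate-free outcomes.

Per CpG, slide susceptibility is quantified by the one-way random-effects
model

    y_is = μ + b_s + e_is ,   b_s ~ N(0, σ²_b),  e_is ~ N(0, σ²_e),

with slide `s` as the grouping factor.  Estimation is by REML (unbiased
for variance components and the default of standard mixed-model software)
via a one-dimensional profile of the restricted likelihood over
`λ = σ²_b/σ²_e`: with per-slide sizes `n_s`, slide means `ȳ_s`, and the
pooled within-slide sum of squares `W`, the profiled criterion

    f(λ) = (N−1)·log Q(λ) + Σ_s log(1+λ n_s) + log Σ_s n_s/(1+λ n_s),
    Q(λ) = W + Σ_s n_s (ȳ_s − μ̂(λ))² / (1+λ n_s),

is minimized over `log λ ∈ [−18, 18]` (bounded scalar minimization,
`xatol = 1e−10`; a golden-section sweep over all CpGs at once in
`decompose_all`, which matches the scalar path to optimizer tolerance) and
compared against the boundary `λ = 0`, so negative variance solutions
truncate to fraction 0.  This supports unbalanced slides, including
single-sample slides.  The explained fraction is `λ/(1+λ)`; fitted
per-slide effects are the shrunken deviations

    b̂_s = σ²_b/(σ²_b + σ²_e/n_s) · (ȳ_s − μ̂),   μ̂ the GLS grand mean,

so `|b̂_s|` never exceeds the raw slide-mean deviation.  Constant rows are
flagged, not fatal, in matrix-level fitting.

## Susceptibility sets

CpGs are binned by the maximum explained fraction across cohorts (only
cohorts with a valid fit count) into S0–20, S20–40, S40–60, S60–80,
S80–100.  Bins are half-open with the lower edge inclusive and the top bin
closed at 1, so a fraction of exactly 0.80 is in S80–100 — the only edge
convention the set definitions pin down, applied uniformly.  *Shigh*
flags CpGs reaching ≥ 60 % in at least 7 of 9 cohorts (both parameters
configurable; with a single cohort the rule degenerates to a plain
threshold).  Median-methylation classes use a 50 % beta cutoff with the
tie assigned to "high" (the low class is *below* 50 %).

PCA of the slide × CpG matrix of fitted effects centres each CpG column
but does not rescale it: the fitted effects already share the RINT-derived
scale, and rescaling would erase exactly the effect-magnitude differences
of interest.  Component signs are fixed by requiring a non-negative
loading sum, making serialized output deterministic.  The
neighbour-enrichment test compares max fractions of non-*Shigh* CpGs
within ±100 bp (endpoints inclusive) of a *Shigh* CpG against all
remaining non-*Shigh* CpGs with a two-sided Wilcoxon rank-sum test — a
rank test avoids distributional assumptions on fractions.  Count
comparisons use Pearson chi-squared without continuity correction;
quantitative comparisons use one-way ANOVA.

## Adjustment methods

*ComBat.*  Parametric empirical-Bayes location/scale correction: per-CpG
standardization by the batch-mean fit and pooled variance (denominator
N), normal/inverse-gamma priors for the standardized per-batch means and
variances with moment-matched hyperparameters, iterative conditional
posterior solution to relative tolerance 1e−6, then back-transformation.
No covariate design matrix is used — the input is residualized upstream.
The implementation agrees with the Bioconductor reference (`sva::ComBat`)
to ~1e−6 on shared fixtures, and the test suite keeps that cross-check.
With a single batch the input is returned unchanged: there is no batch
contrast to remove, and the EB machinery is undefined there.  Two
behaviours worth knowing: (i) EB shrinkage deliberately leaves a residue
of the realized batch means, so post-correction batch-mean differences
are small but not zero in any single realization (the expected residue
under a 1-unit shift on half the CpGs at n = 200/batch is ≈ 0.04); and
(ii) correction induces a slight negative within-batch correlation, which
can make downstream tests conservative when the phenotype itself carries
batch structure.

*ComBat_high.*  ComBat applied independently to the *Shigh* stratum and
its complement, rows re-merged in input order.  Because susceptible CpGs
have large, mutually aligned batch means, pooling them with the bulk of
unaffected CpGs drags the EB prior toward zero and under-corrects them;
stratifying restores an appropriate prior within the susceptible set.  An
empty stratum falls back to a single run with a warning.

*PC covariates.*  Top-k sample-space principal component scores of the
CpG-centred matrix via SVD (k = 10 for the methylome-wide variant,
computed on the same scale as the downstream regression input).  Scores
have exactly zero mean and are returned in decreasing-variance order with
the loading-sum sign convention.

*PC_high.*  The same computation restricted to the *Shigh* submatrix,
k = 1 by default: under the shared-factor structure this single covariate
tracks the slide factor and transfers across chromosomes.

## The synthetic generator

Generation is on the M-value scale:

    m_ij = baseline_j + covariates + loading_j·u_s(i) + c_j·v_s(i),j
           + Σ_k w_jk·η_ki + e_ij

with `u_s` (shared slide factor), `v_s,j` (CpG-specific slide noise),
`η_ki` (latent sample-level factors) and `e_ij` all standard normal
sources.  Scales are calibrated so the slide share of total variance
equals the per-CpG target fraction exactly; total per-CpG SD defaults to
0.5 on the M scale, a typical blood-array magnitude.  Defaults:

* **bin composition** (0.307, 0.453, 0.197, 0.041, 0.002) — the relative
  set sizes observed on real blood EPIC data; fractions are uniform
  within bins, the top bin capped at 0.97 so residual variance never
  degenerates.  `fixed_fractions` overrides the mix for calibration
  experiments.
* **shared factor** — CpGs with fraction ≥ 0.6 load on the single factor
  `u`, with `shared_factor_share = 0.95` of their slide variance on it;
  this puts the PCA of fitted effects near the top of the 77–92 %
  PC1+PC2 range real cohorts display.  Loading sign is +1 for
  high-methylation CpGs and −1 for low (`high_meth_share = 0.6` of
  susceptible CpGs are high), producing the two-cluster joint pattern.
* **baselines** — a ±2 two-component M-value mixture (|baseline| ≥ 0.8),
  so median-beta classes are non-trivial but deterministic.
* **latent heterogeneity** — 14 sample-level factors carrying 55 % of
  each CpG's non-slide variance.  They emulate unmodelled biology
  (genetic background, residual cell composition): slide-independent, but
  large enough that the top methylome-wide PCs track them rather than
  the slide factor, as in real data — this is what makes the PC_10
  strategy insufficient for strongly susceptible CpGs.
* **layout** — slides of 8 samples (EPIC capacity), 60 slides (~480
  arrays, the scale of a single large cohort), CpGs spread round-robin
  over 22 autosomes at 5 kb spacing.

Cohorts generated from one universe share all CpG-level structure but
draw independent slides, samples and noise, via one seed split into
per-cohort child streams; adding cohorts never perturbs earlier ones.

What the generator does **not** emulate: probe chemistry (type I/II,
colour channels), detection failures, position-within-slide or plate
structure, genomic autocorrelation of baselines, and non-Gaussian
residuals.  Passing tests therefore demonstrate the statistical machinery
under the assumed variance structure, not robustness to those artefacts.

## The simulation study

Autosomal CpGs split by chromosome parity.  Fitted slide effects of
*all* even-chromosome CpGs are reduced to their first principal
component; the per-slide score is rescaled *downward* to unit variance
when it exceeds it (never amplified), and the phenotype is
`y_i = z_i + f_s(i)` with fresh standard-normal `z` per test.  Capping
rather than always standardizing matters in the null case: with slide
effects absent, the true first PC of slide effects is zero, and inflating
an overfit noise PC to unit variance would inject an artificial batch
signal into the phenotype.  For the same reason the null-calibration
experiment supplies the known zero factor directly.  A related caveat
surfaced by the generator's latent factors: when a phenotype factor is
*estimated* from null fitted effects, it picks up slide-averaged latent
biology shared with the test CpGs and miscalibrates every approach — an
honest hazard of building phenotypes from estimated batch effects, which
is why the null experiment defines the factor by ground truth.

Association tests regress the phenotype on the (adjusted) CpG value plus
the approach's covariates — OLS with a two-sided t-test on the CpG
coefficient; the phenotype is the outcome, matching how it is
constructed.  Adjustments are computed once per run from odd-chromosome
data only; ComBat variants correct the M-value matrix and the corrected
values are re-RINTed when the scan scale is RINT (default; `scale="m"`
repeats everything on M-values).  10,000 draws per set is the default
design; the packaged studies use 2,000.  Summaries are the empirical
rejection rate at α = 0.05 with exact binomial intervals, and the genomic
inflation factor λ = median observed χ² / 0.4549.

## Problem sizes and numerical choices

The packaged studies run one cohort of 60 slides × 8 samples with 40,000
CpGs (simulation study) — a desk-scale stand-in preserving the *bin
composition* of an 850k-probe array rather than its size.  Size matters
in one specific way: the accuracy of the PC_high covariate, hence the
residual type-I error of the PC_high approach, improves with the number
of susceptible CpGs (≈ 1,700 at 40k CpGs, ~850 per parity).  At much
smaller sizes the covariate's residual slide component leaves type-I
error a few tenths of a percent above nominal; 40k CpGs brings the study
into the regime where PC_high is calibrated within binomial noise at
2,000 draws.  The REML oracle comparisons use ≤ 10 slides × ≤ 8 samples
where dense-matrix likelihood evaluation is exact and cheap; fraction
recovery uses 500 CpGs per target level.

Degenerate inputs are handled explicitly: constant CpGs are rejected
(RINT, ComBat) or flagged (matrix-level variance fits); all-missing CpGs
drop out of partitions with a warning; rank-deficient covariate designs
raise with the offending column names; `λ` at its search bound still
yields a valid boundary fraction.  All serialized tables are TSV with
17-significant-digit floats (exact float64 round trips) and fixed column
orders; every random quantity flows from a single integer seed.

## Known limitations

* Plate and within-slide position effects are out of scope; slide is the
  only batch level modelled.
* The parametric EB priors are misspecified when batch effects are
  strongly bimodal across CpGs (as in the half-shifted test scenario);
  the resulting shrinkage residue is inherent to the method, not an
  implementation artefact.
* Real-data preprocessing (normalization, QC, cell-type estimation) is
  assumed done upstream; the pipeline starts from a beta matrix.
* The generator's latent factors are Gaussian and slide-independent;
  confounding between biology and slides — common in poorly randomized
  designs — is not simulated.
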