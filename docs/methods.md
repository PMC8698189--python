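# Methods

This note documents the models and procedures implemented in `tmrqc`, the
parameters that matter, the design choices made where the published method
left the design open, and what the synthetic-data generators do and do not
emulate.

## Particle-size model

The five-sieve separator assigns each stratum a geometric midpoint length:
48, 38.04, 17.32, 7.73, 3.69 mm and 0.90 mm for the pan. Raw retained
masses (% w/w of the wet sample) are proportionally rescaled to sum to
100 exactly; duplicate sievings are averaged *before* normalisation. GMPL
is `exp(Σ p_j ln m_j)` with `p_j` the stratum *proportions* (percent / 100):
percent weights would exponentiate a sum near 190 and are physically
meaningless, so the implementation always divides by 100. GMPL is therefore
bounded by the extreme midpoints, 0.90–48 mm, and strictly increases when
mass moves to a coarser stratum.

The physical-effectiveness factor treats the 3.8 mm sieve as the separator's
"4 mm" screen, so `pef = (S1+S2+S3+S4)/100` and `peNDF = aNDF · pef ≤ aNDF`,
with equality only at `pef = 1`.

A note on aggregation: the mean of per-sample GMPLs is not the GMPL of the
mean fractions (Jensen's inequality); on the reference mean fractions the
latter evaluates to ≈ 6.41 mm. Cohort-level GMPL summaries in this package
therefore always average per-sample GMPLs.

## Spectral pretreatment and PLS calibration

Spectra live on a shared, strictly increasing grid within 902–1660 nm.
Pretreatment steps are pure functions and order-sensitive:

* **SNV** centres each spectrum and scales it to unit sample SD (constant
  spectra are rejected as degenerate).
* **Detrend** removes a least-squares polynomial (default degree 2) in the
  wavelength coordinate, computed on an orthonormalised basis for numerical
  stability.
* **Savitzky–Golay** smoothing or first derivative (defaults window 7,
  polynomial 2; the published procedure names no parameters, so these are
  configurable). Edges are handled by refitting the local polynomial on
  truncated windows (`scipy.signal.savgol_filter(mode="interp")`), which
  preserves vector length. Derivatives are per nm.

The sample set is split 55 % calibration / 45 % validation by a seeded
permutation, `|c| = floor(0.55·N + 0.5)` (round half up); each trait may
redraw its own split.

Calibration runs PLS1 (`scale=False`, mean-centring only) with factor counts
1–10 under 10-fold seeded cross-validation, twice:

1. Pass 1 selects the factor count minimising RMSEcv (ties broken toward
   fewer factors at a 1e-6 relative tolerance), fits the full calibration
   set, and flags outliers as the union of
   * score-space Mahalanobis distance `sqrt(D²/k) > 3.0`, where `D` is the
     Mahalanobis distance of a sample's PLS scores to the score centroid and
     `k` the factor count (this per-factor normalisation has expectation ≈ 1
     on clean data, so the 3.0 cut-off flags essentially nothing under the
     null while catching genuine spectral aliens), and
   * Cook's `D = t²·h / ((k+1)(1−h)) > 3`, with `t` the internally
     studentized *cross-validated* residual and `h` the score-space
     leverage.
2. Pass 2 re-runs the cross-validation on the cleaned set, reselects the
   factor count and refits. `Ncal` = input count − outliers removed.

The cross-validation scheme (10-fold, seeded, applied twice around outlier
removal) is this package's concrete reading of a two-step cross-validation
with outlier elimination; the published procedure names no fold structure.

Validation metrics: RMSE and R² in cross-validation and validation; F-value
as the ratio of fitted-value variance to residual variance; skew as the
slope of the least-squares line of *predicted on actual* (ideal 1; reported
as missing when predictions are constant); GH as the mean squared
Mahalanobis distance of validation scores in the calibration score space
divided by the factor count. ISV/IRV-style proprietary indices have no
public formula and are absent by default; `evaluate(extra_metrics=...)` is
the hook for user-supplied implementations.

Replicate-scan error reduction uses the two-sided 95 % Student-t multiplier
with degrees of freedom equal to the number of repeated analyses, the
convention under which a single reading carries a 12.7 × SEM interval and
the 16-point alley protocol 2.12 × SEM.

## Homogeneity and Sorting indexes

No closed form for Hi was ever published, only its properties (range 0–100,
100 at perfect homogeneity, a weighted comparison of CVs against maximal
acceptable ratios). The implemented score, `s = min(1, CV_acc/CV)`, is the
simplest continuous, scale-free form with those properties; it is a
pluggable strategy (`homogeneity_index(score_fn=...)`) so a hard 0/1
compliance rule can be swapped in. Outlier trimming is a *single* pass per
trait: points strictly outside mean ± 2 SD of all 16 are dropped (boundary
points retained), never re-iterated; fewer than 3 survivors is an error.

Si uses a two-sided, equal-variance, two-sample Student t-test per trait
(fresh vs +2 h), each time set trimmed independently. A paired variant
(`paired=True`) exists because the 16 points are positionally matched, and
`trim_later=False` records the ambiguity of whether the +2 h set should be
trimmed at all. p-value bins are left-open/right-closed exactly as printed;
a p of exactly 0.05 scores 0.5. Identical fresh/later sets produce an
undefined t statistic, which is scored 0 (no evidence of sorting) — distinct
from the *not computable* signal raised when the +2 h set is missing
entirely. Classification thresholds are frozen at Hi ≤ 79 % and Si ≤ 0.30
(the published approximate medians) rather than recomputed per dataset; a
recompute option would be a one-liner on the caller's side and is
deliberately not the default, so classes are comparable across cohorts.

## Cohort statistics

Mixer-wagon fullness is `100 · (load weight / specific weight) / declared
volume`: weight (t) over specific weight (t/m³) is the only dimensionally
valid reading of the published product formula, which is available verbatim
behind `literal=True`. Overloads (> 100 %) are accepted as real
observations.

Repeated visits are averaged per farm before any modelling (categorical
fields must agree across visits). Normality screening is Shapiro–Wilk at
α = 0.05, choosing mean ± SD vs median/quartile summaries. Linear models are
OLS with adjusted R² and RSE; logistic models are maximum-likelihood with
odds ratios `exp(β)` and AUC computed by the rank (Mann–Whitney)
construction over fitted probabilities — perfect separation is flagged and
the odds ratios reported as non-estimable. Correlation screening uses
Pearson for quantitative and Spearman for ordinal variables at |r| ≥ 0.6
with a named-exception list. PCA standardises variables to unit variance
first. Stepwise selection prunes predictors to VIF < 10, then runs a
bidirectional AIC search from the intercept-only model. AIC is known to
admit each null predictor with probability ≈ 0.157, so "exact" support
recovery holds only about half the time even at large n; the package
documents rather than fights this property of the criterion. Missing fields
are handled by complete-case analysis per model. The low/high milk-yield
split uses the cohort median, recomputed on the data at hand.

## Synthetic-data generators

One global integer seed drives everything; each generator call derives an
independent stream as `default_rng([seed, stream_id])` (calibration 1, alley
2, cohort 3), so outputs are bit-identical across runs and generators never
share draws.

**Calibration set** (default n = 311). Chemistry (DM 49.2 ± 4.35, CP
15.2 ± 0.62, aNDF 33.1 ± 1.61, starch 26.0 ± 1.18 % — the cohort reference
means; ADF 21.5 ± 1.40, a typical maize-silage TMR value since no reference
mean exists) is multivariate normal with fixed correlations: aNDF–ADF
+0.85, aNDF–starch −0.50, ADF–starch −0.35, all other pairs 0 — unreported
correlations are set to zero without any claim that real data look like
that. Sieve fractions are Dirichlet around the reference mean fractions
(concentration 150, giving within-set stratum SDs of a few percent), tilted
toward coarser strata by a latent correlated at −0.71 with DM so the DM–GMPL
relationship the cohort layer screens for is present. Spectra are sums of
fixed Gaussian absorption bands per constituent (moisture 1450/970 nm, CP
1510, aNDF 1364, ADF 1210, starch 1528 nm — plumbing constants chosen only
to give the pretreatments realistic structure), plus a slowly varying
polynomial baseline scaled by GMPL/6.73 that reproduces the light-scattering
cross-sensitivity which makes particle-size prediction from NIR possible at
all, plus heteroscedastic Gaussian noise (SD 0.002 absorbance units by
default). `scatter_strength`, `spectral_noise_sd` and `sieve_concentration`
exist so degenerate regimes (noise-free, single-constituent) are exactly
realisable.

**Alley batches** (default 16 points). Point values vary around the batch
means with a per-trait CV equal to `heterogeneity` (default 5 %, which
lands mean Hi near the high-70s observed in practice), plus a 1e-9 relative
machine-noise floor. The +2 h refusals shift trait means by
`sorting_effect` × fixed relative shifts (GMPL +25 %, aNDF +8 %, S4 +6 %,
CP −3 %, starch −12 %, S5 −12 %, bottom −18 %): cows select against coarse,
fibrous material and eat the fine, starch-rich fraction first.
`sorting_effect = 0` draws the +2 h points from exactly the fresh
distribution.

**Cohort** (n ≥ 5 farms). Fullness is uniform on [62.2, 131] %; Hi follows
`96.0 − 0.19 · fullness + N(0, 4.33)` clipped to [0, 100]; Si is
N(0.25, 0.13) clipped to [0, 1]; DM, GMPL and total intake share the
correlation block (−0.71, −0.87 and their product); peNDF derives from aNDF
times a GMPL-driven effectiveness factor; the remaining covariates are
independent draws around the cohort reference means with natural-range
clipping. Optional repeated visits jitter farm-level numerics by 2 % CV.

**What the generators do not emulate** — and hence what passing tests do not
show about real data: real NIR spectra (instrument drift, temperature,
moisture-dependent band shifts, non-Gaussian scatter), real feedstuff
composition beyond trait-level statistics, seasonal structure, spatial
autocorrelation along the feeding alley, and any between-trait correlations
the development study did not report. Recovery tests demonstrate that the
estimators are correctly implemented and well-calibrated under the stated
model, not that the published field results would replicate.

## Numerical choices and degenerate inputs

* Fraction normalisation requires a positive sum; all-zero or negative
  fractions are errors. GMPL requires normalised input (sum 100 ± 1e-6).
* Factor-count ties in PLS resolve to the smallest count within 1e-6
  relative RMSE. Singular score covariances raise a diagnostic error with a
  remedy hint instead of producing NaNs.
* Hi trait means must be positive (CV undefined otherwise); a CV of zero
  scores 1. Boundary p-values fall in the lower-significance bin.
* The acceptance script derives every random quantity from its `--seed`
  argument through the generator configs; values on the printed scales
  (Hi in %, Si unitless, GMPL in mm).

## Problem sizes

The test suite uses calibration sets of 40–120 samples and full-size
(n = 311) draws where a reference mean is checked, 100-seed Monte-Carlo
loops for the monotonicity and null-rate properties, and 200 replicates of
200-farm cohorts for slope-recovery coverage; the demo pipeline defaults to
120 calibration samples and 19 farms. These sizes make every property
decisive (coverage checks have binomial SEs well inside their margins)
while the whole suite runs in well under a minute.
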