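# Methods

This note records the models, defaults and numerical choices behind
`nmrfp`, and what the synthetic test bed does and does not establish.

## Spectral processing

**Input.** Frequency-domain 1D ¹H-NMR spectra (ppm, intensity pairs).
Phase and baseline correction are assumed done upstream; the package
deliberately starts after Fourier transformation.

**Calibration.** `calibrate_ppm` shifts the ppm axis so the tallest
point within ±0.05 ppm of the anomeric glucose reference (δ 5.24) lands
exactly on it. Intensities are untouched. A flat window raises an
error naming the search window. Shifts below 1 × 10⁻⁹ ppm are treated
as zero so an already-calibrated spectrum is returned bit-identical.

**Binning.** Uniform 0.02 ppm bins over 0.2–10 ppm (490 bins before
exclusion). Each bin receives the trapezoidal integral of the
piecewise-linear spectrum over [edge_k, edge_{k+1}), computed exactly by
interpolating the cumulative integral at the bin edges; this is robust
to unequal ppm grids and invariant to the axis direction. A bin is
dropped iff it overlaps an exclusion interval with positive measure
(touching at an endpoint does not count). With the default water
(4.37–5.13) and ethanol (1.12–1.23, 3.53–3.73) exclusions this retains
**434** bins; published workflows report slightly different counts
(434–439) depending on their edge convention, so the value under this
convention is frozen in a regression test rather than forced. Bins are
labeled by their starting ppm.

**PQN.** The reference is the element-wise median spectrum of the
cohort. A sample's quotient is the median of sample-bin / reference-bin
over bins where the reference is strictly positive; the sample is
divided by its quotient. The reference is stored on the normalized
matrix and reused when renormalizing, which makes PQN exactly
idempotent (quotients of a normalized matrix are all 1 to 1e-10).
Note that PQN identifies the *dominant* multiplicative effect: with
biological between-subject concentration variation present, the
recovered quotient is dilution × a sample-specific concentration
factor. The exact-recovery property (correlation > 0.99 with applied
dilutions) therefore holds when dilution is the only multiplicative
difference between samples, and the tests construct exactly that case.

## PLS-DA ensemble

**Model.** PLS1 by NIPALS with sequential deflation of X and y,
y ∈ {−1 (survivor), +1 (deceased)}, decision threshold 0. X is
mean-centered only — no unit-variance scaling — preserving the natural
intensity weighting of fingerprint bins. 7 components by default.
Weights, loadings and scores match scikit-learn's `PLSRegression`
(scale=False) up to per-component sign.

**Cross-validation.** Leave-one-out: n refits, metrics computed on
held-out predictions only.

**Balanced ensemble.** The cohort is class-unbalanced, so each of 100
iterations draws 25 patients per class without replacement and fits a
PLS-DA model to the balanced subsample. Votes: in-subsample patients
are voted by their LOOCV held-out prediction; out-of-subsample patients
by the fitted model's prediction. Every patient thus accrues exactly
100 votes. (Whether out-of-subsample patients should vote at all is
genuinely open; this resolution is the one that gives every patient a
full vote count, which a majority vote over patients requires.)

**Majority vote and gray zone.** The predicted class is the one with
more votes; the margin is |vote share − 0.5|; a patient is gray-zone
iff margin < 0.10 (strict, computed in integer arithmetic so a 60/100
vote sits exactly on the boundary and is *not* gray). An exact 50/50
tie defaults to the lower-risk survivor class and is always flagged
gray — a conservative, clinically neutral rule.

**Randomness.** Iteration k draws from `default_rng([seed, k])`
(counter-based), so increasing the iteration count never reshuffles
earlier iterations.

**VIP.** VIP_j = √( p · Σ_a SS_a w²_ja / Σ_a SS_a ), SS_a = q_a² t_aᵀt_a.
Since the w_a are unit vectors, Σ_j VIP²_j = p identically — the test
suite asserts mean(VIP²) = 1 on every fitted model. Selection
threshold: VIP > 1.

## Survival analysis

Implemented directly (no survival library at runtime):

- **Kaplan–Meier**: product-limit estimator with at-risk and
  cumulative-event counts exposed for risk-table strips; censored
  subjects leave the risk set after their censoring time.
- **Log-rank**: k-sample observed-minus-expected statistic with the
  multivariate hypergeometric variance, df = k − 1. On tie-free data
  the two-group statistic equals the score test of the univariate Cox
  model at β = 0 (verified to 1e-8).
- **Cox PH**: Newton–Raphson maximization of the partial likelihood,
  Breslow ties by default (Efron available). Stopping rule: relative
  log-likelihood change < 1e-9 or 50 iterations, followed by one full
  polishing Newton step, which leaves the gradient at ~1e-13 —
  tighter than typical library defaults, so oracle comparisons are
  bounded by the oracle's own tolerance (~1e-5). Step-halving keeps
  the likelihood ascending. 95% CIs are Wald intervals on the
  log-hazard scale from the inverse observed information; model
  significance is a likelihood-ratio chi-square on the coefficient
  count. |β| > 15 flags possible monotone likelihood (separation).
- **Covariate coding** for adjusted models: age > 60 y,
  time-from-diagnosis > 15 y, NT-proBNP > 400 pg/ml, SBP > 130 mmHg,
  EDDi > 30 mm/m², LAVi > 40 ml/m² (all strict ">"), sex male vs
  female, NYHA II and III–IV vs I, LVEF reduced and mid-range vs
  preserved.

## Risk rules

LVEF: HiR < 40 ≤ IR < 50 ≤ LR. NT-proBNP: high iff strictly above
400 pg/ml. Combined metabolomics × LVEF: metabolomics screens first;
LVEF < 35 % overrides a survivor prediction to high risk and LVEF > 50 %
overrides a deceased prediction to low risk (strict inequalities, so on
[35, 50] the rule is the identity on the metabolomic class). The
NT-proBNP combination rule is not uniquely determined by published
descriptions, so it is a named strategy (`either_high` default,
`both_high`, `met_only`).

## Feature statistics

- Wilcoxon rank-sum per feature (exact for tie-free groups of ≤ 10,
  normal approximation with tie correction otherwise), BH step-up FDR
  across all features jointly; constant features get p = 1 with a
  warning.
- Tertile Cox: type-7 quantile cuts at 1/3 and 2/3, ties to the lower
  tertile; indicators for the 2nd and 3rd tertile vs the 1st; a cut
  value spanning more than a third of the samples raises an error
  naming the feature.
- Winsorized correlation: g = ⌊γn⌋ values per tail replaced by the
  nearest retained order statistic (γ = 0.10), Pearson r of the
  winsorized pairs, t = r√(n−2)/√(1−r²) on n − 2g − 2 df; γ = 0 reduces
  exactly to Pearson. BH across the correlation matrix.
- Cohort summaries report median (MAD) and n (%) by outcome group.
  The MAD is scaled by 1.4826 by default (common in clinical reporting;
  a flag restores the raw MAD). Group tests: rank-sum for continuous
  rows; chi-square for categoricals, Fisher exact for 2×2 tables with
  any expected count < 5; BH down the table.

## Synthetic cohort

The generator emulates the study conditions the pipeline targets:

- **Cohort**: 106 patients, 26 deceased-like (24.5 %). Survival times
  are exponential per latent class — baseline 0.04 events/year for
  survivor-like, × 5.71 for deceased-like — with administrative
  censoring at 8 years. Exponential hazards were chosen because they
  make the class hazard ratio exactly the configured constant,
  enabling closed-form parameter-recovery checks.
- **Covariates**: class-conditional normals (log-normal for NT-proBNP)
  centered on published-cohort-style medians with MAD-scale spreads
  (lower LVEF and higher NT-proBNP in the deceased-like class). Sex,
  NYHA class and diuretic use are assigned by within-class quota
  (largest-remainder rounding, shuffled), so cohort-level percentages
  are stable across seeds; continuous covariates use per-patient
  substreams of the master seed so enlarging the cohort never
  reshuffles existing patients.
- **Spectra**: sum of Lorentzian multiplets (FWHM 0.004 ppm) for
  creatine (3.03/3.93, lower in the deceased-like class, effect 0.70),
  creatinine (3.05/4.06, 1.40), trimethylamine-N-oxide (3.27, 1.50),
  lactate (doublet 1.32/1.34 plus 4.10/4.12, 1.30), alanine and
  glucose (neutral), and broad lipoprotein humps (FWHM 0.05 ppm at
  0.85 and 1.25, 1.15); log-normal between-subject concentrations
  (cv 0.15–0.25), a log-normal per-sample dilution factor (cv 0.15)
  and additive Gaussian noise (sd 0.02). The anomeric glucose
  reference is a single line at 5.24 (J fine structure is out of
  scope), so calibration of an already-calibrated spectrum is exact.
- **Feature table**: log-normal concentrations with unit survivor
  median and per-feature deceased/survivor effect ratios, standing in
  for an external quantification platform's output.

**What passing tests show — and don't.** The synthetic spectra lack
peak-position jitter, J-coupling fine structure, baseline drift and
missing data, and their class difference is exactly the configured
concentration ratios. Tests therefore establish correctness of the
algorithms and calibration of the statistics (null behavior, parameter
recovery, oracle equivalence) — not clinical performance on real serum
spectra. The default effect sizes give ensemble accuracy near 0.88 at
n = 106; the power benchmarks use effect ratio 2 ("strong" library),
where accuracy exceeds 0.95.

## Problem sizes used in the test suite

Oracle comparisons run on ≤ 10-sample toys and n ≈ 300 simulations;
hazard-ratio recovery uses 100 cohorts of n = 800 (~30 % censored);
ensemble power and permutation-null checks use the full n = 106 cohort
with 100 ensemble iterations and 20 label permutations; large-sample
consistency checks use a single n = 5000 cohort.

## Known limitations

- No time-varying covariates, stratified Cox, proportionality
  diagnostics or competing risks (transplant is treated as censoring).
- Single-response (two-class) PLS-DA only; no orthogonal PLS, no
  data-driven choice of the component count (fixed at 7).
- No peak alignment or deconvolution; binning assumes calibrated,
  baseline-corrected input.
- The cohort summary's Fisher fallback applies to 2×2 tables only;
  larger sparse tables fall back to chi-square.
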