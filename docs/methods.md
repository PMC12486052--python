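# Methods

`orncausal` estimates, from an observational two-modality head-and-neck
radiotherapy cohort, dose-volume constraints (DVCs) for mandible
osteoradionecrosis (ORN) that carry a causal — not merely correlational —
interpretation, and converts the paired photon/proton constraint curves
into empirical proton RBE values. This note records the model, the
estimators, the numerical choices, and what the synthetic cohort does and
does not demonstrate.

## Estimand and causal structure

Patient-level variables split into three roles: the *treatment* is a
binarized dosimetric factor T = 1[D > v] (D one of V40Gy...V70Gy, Dmax,
Dmean of the mandible; v a candidate threshold); the *outcome* is the
binary ORN indicator Y; the *covariates* X are nine clinical factors (age
continuous; tumor stage, gender, chemotherapy, smoking history, current
smoker, hypertension, diabetes, dental extraction categorical, with an
explicit MISSING level — missingness in such registries is structural, so
it is treated as information, never imputed). The estimand is the average
treatment effect

    ATE(v) = E[Y(T=1) - Y(T=0)],

a risk difference for the normalized binary outcome. Because dose and
outcome share clinical causes (tumor extent drives both dose burden and
ORN risk), the naive difference in means is biased; everything below is
about removing that bias.

## Stage 1 — between-group matching

P(modality = PBSPT | X) is fit by unpenalized maximum-likelihood logistic
regression on the one-hot covariates (drop-first coding to avoid the dummy
trap; a ridge fallback with lambda = 1e-6 handles near-separation, and a
covariate that perfectly predicts modality raises a named error). Photon
patients are matched 1:1 to proton patients by *globally optimal*
assignment minimizing the total |logit propensity| distance — solved as a
rectangular min-cost assignment problem, not greedy nearest-neighbour;
every patient is used at most once and the pair count equals the smaller
group. No caliper is applied by default, so no pairs are discarded.
Balance is reported as chi-square p-values (no continuity correction, so a
table with zero discrepancy reports exactly p = 1) for categorical factors
and a Welch t-test for age, before and after matching.

## Stage 2 — within-group balance (SMD)

Matching balances the two modality groups against each other but says
nothing about confounding *within* a group across dose levels. For each
clinical factor c and dosimetric factor D, patients of one modality are
stratified into quartiles of D (ties assigned to the lower stratum, which
keeps heavily tied factors such as V70Gy deterministic) and the worst-case
standardized mean difference

    SMD_max = max_{i != j} |mu_i - mu_j| / sqrt((s_i^2 + s_j^2) / 2)

is taken over the six stratum pairs, and over per-level indicator means
for categorical factors (the worst case over levels, consistent with the
worst-case philosophy of the diagnostic). Cells are flagged balanced
(< 0.2), moderately biased ([0.2, 0.8)) or highly biased (>= 0.8), with
boundaries closed on the left; a zero-variance pair with unequal means is
flagged degenerate rather than given a number. On confounded synthetic
cohorts this diagnostic stays biased after matching — the observation that
motivates the causal forest.

## Stage 3 — honest causal forest

The forest follows the generalized-random-forest recipe, re-implemented in
simplified but faithful form (numba kernels; flat-array trees):

* **Subsampling.** Each of `n_trees` (default 2000) trees is grown on a
  fraction (default 0.5) of patients drawn *without* replacement.
* **Honesty.** Each subsample is split in half: the structure half chooses
  splits, the estimation half supplies leaf effect estimates. Permuting
  estimation-half outcomes changes leaf values but never tree shape (a
  property test asserts this).
* **Local centering.** Before tree growth, Y and T are replaced by
  residuals against out-of-bag regression-forest estimates of
  m(x) = E[Y|X] and the propensity e(x) = E[T|X] (default 200 trees,
  min leaf 5, mtry = ceil(sqrt(p))). Centering is what lets the splitting
  criterion see effect heterogeneity rather than confounding gradients; a
  `center=False` ablation mode uses raw Y and mean-centred T with literal
  difference-in-means child effects.
* **Split rule.** At each node every cut point of every feature (default
  mtry = all features, matching GRF's effective default at p ~ 20) is
  scored by n_L*tau_L^2 + n_R*tau_R^2, the size-weighted heterogeneity of
  child effects, where tau_child = sum(Yres*Tres)/sum(Tres^2) on the
  structure half — the residual-on-residual slope that reduces to the
  difference in arm means when e(x) is constant. A split is admissible
  only if each child retains >= `min_leaf` (default 5) treated and
  control patients in *both* halves; ties break to the first feature in
  schema order, then the lowest cut. Cut points are midpoints between
  consecutive distinct values, demoted to the lower value if floating-point
  rounding would swallow the gap.
* **OOB CATE.** A patient's CATE averages the leaf values of the trees
  whose subsample excluded that patient (~n_trees/2 trees). A patient in
  every subsample has no OOB vote: the strict accessor raises, while the
  ATE path falls back to the all-trees prediction for that patient (this
  matters only at very small tree counts inside bootstrap loops).
* **ATE.** The default estimator is the doubly robust AIPW mean: with
  tau_i the OOB CATE, e_i the (clipped to [0.01, 0.99]) OOB propensity and
  m_i the OOB outcome regression,

      psi_i = tau_i + (T_i - e_i)/(e_i(1 - e_i)) * (Y_i - m_i - (T_i - e_i) tau_i),
      ATE = mean(psi),  SE = sd(psi)/sqrt(n),

  an influence-function standard error (simpler and simulation-testable,
  in place of the bootstrap-of-little-bags). If more than 5% of propensity
  estimates needed clipping the estimate carries a positivity warning. A
  plain mean-of-OOB-CATE estimator is available for cross-checking.

Verified behaviour (all in the test suite): under randomized treatment the
AIPW ATE agrees with the difference in means within Monte-Carlo error and
recovers a planted tau = 0.25 at n = 4000; under strong covariate
confounding with tau = 0.2 the forest lands closer to the truth than the
naive difference in >= 90/100 replicates; identical seeds reproduce the
ATE to the last bit.

## Stage 4 — DVC scan

"1% increments" of a threshold scan are interpreted as *percentiles of the
factor's empirical distribution* (1st-99th), which guarantees populated
arms even for heavily skewed volumes; a raw-range grid exists as an
option. Each modality cohort is scanned separately with clinical
covariates as forest features. Thresholds leaving an arm under 10 patients
are skipped and logged. The critical constraint is the *most significant*
threshold, argmax of z = ATE/SE (ties to the smallest threshold). The raw
argmax-of-ATE rule is available (`rule="max_ate"`) but is not the default:
near-edge grid points have 3-5x the interior SE, and in step-effect
simulations the raw argmax escapes to such points in a material fraction
of replicates while the z rule recovers the planted threshold reliably.
The outcome-regression m(x) is estimated once per scan (it does not depend
on the threshold); the propensity forest is refit at every grid point.

95% CIs for critical values come from a percentile bootstrap (default
1000 replicates; scaled down in tests) that resamples patients with
replacement *within the modality cohort* and reruns the entire
scan-plus-argmax per replicate, so the interval reflects
threshold-selection variability, not just ATE noise at a fixed threshold.
Replicate seeds derive from the master seed via a counter scheme; more
than 10% failed replicates aborts with a log.

A robustness (null-calibration) check replaces each dosimetric factor in
turn by iid Uniform(0,1) draws, binarizes at the median, refits the forest
and reports the ATE per factor plus the maximum |ATE|: with pure-noise
dosimetry any systematic deviation from zero would expose leakage in the
estimator. At n = 670 and ~3% outcome prevalence the information bound
for a risk difference at e = 0.5 puts the null SE near 0.013, so the
maximum over six factors is expected around 0.02 — single-seed values a
few thousandths above or below that are equally consistent with a
well-calibrated null.

## Stage 5 — tolerance curves and empirical RBE

The critical volumes at dose levels 40/50/60/70 Gy form one
volume-tolerance curve per modality (dose strictly increasing; a
non-monotone volume sequence warns but is not rejected). Proton
prescriptions are in Gy[RBE=1.1], so the proton physical dose is the
nominal dose divided by exactly 1.1; photon doses are physical. The
*equivalent constraint dose* at a proton critical volume V is the
piecewise-linear inverse of the photon curve at V (no smoothing; on a
non-monotone curve the lowest attaining dose is returned with a
multiplicity warning; volumes outside the photon range raise an
extrapolation error — the pipeline records such rows as NaN). Then

    RBE = equivalent photon dose / proton physical dose.

Worked check: equivalent doses 58.58, 59.10, 61.75 Gy at nominal
40, 50, 60 Gy[RBE=1.1] give 1.611, 1.300, 1.132. CIs pair the photon
bootstrap curve replicates with the proton bootstrap volumes replicate by
replicate; replicates hitting extrapolation are dropped and counted, and
a CI with > 20% drops is flagged unreliable. With linear interpolation
between only four knots the equivalent dose is resolution-limited — the
curve can be built from any set of dose levels if finer resolution is
wanted. No RBE is reported at 70 Gy by default (the proton 70 Gy volume
usually falls below the photon curve's last knot).

## Synthetic cohort

The generator replaces the unavailable institutional registry and is the
fixed study condition for every test:

* Covariate marginals follow a typical matched H&N chemoradiotherapy
  cohort (median age 62 (SD 13), 74.2% male, stage IV 52.8%, chemo 58%,
  smoking history 52.1%, current smoker 10.7%, hypertension 50.2%,
  diabetes 14.3%, dental extraction 16.3%), each categorical covariate
  MCAR-missing at 3% into the MISSING level.
* Modality assignment is logistic in the covariates (stage-X positive,
  smoking/hypertension/chemo negative by default), scaled by
  `confounding_strength`; arm quotas (default 335/335, optionally
  931/335 for the pre-matching registry) are filled deterministically
  from seeded batches.
* Dosimetry: a latent per-patient dose burden (standard normal plus a
  covariate shift scaled by `dose_confounding`) loads with correlation
  0.6 on every factor; factor-specific means/SDs differ by modality
  (photon V40...V70 ~ 85/70/50/12 cc, proton ~ 40/32/16/5 cc; Dmax/Dmean
  in cGy), values are clipped at zero, and the four V-columns are sorted
  per patient so V40 >= V50 >= V60 >= V70 holds by construction
  (Dmax >= Dmean likewise).
* Outcome: default logit P(Y=1) = logit(0.0066) + sum beta_c x_c +
  gamma 1[D > v*] with gamma = 1.2 on V50Gy at v* = 50 cc, giving ~3%
  marginal ORN prevalence at 670 patients; a linear-probability variant
  makes the risk difference exact for oracle tests. `ground_truth_ate`
  returns the implied true ATE of any binarization analytically per
  patient (normal tail ratios for the threshold indicator, the
  intervention drawing the factor from its conditional distribution given
  the assigned arm) averaged by Monte Carlo; zero-clipping of volumes is
  ignored there, exact whenever the threshold and v* are positive.

What passing tests on this generator do *not* show: real DVH shapes
(four volumes plus two summary doses stand in for full curves), dose-LET
structure, informative missingness, calendar effects, or inter-factor
causal pathways (a single latent burden drives all factors). Conclusions
about estimator calibration and pipeline correctness transfer; clinical
constants do not.

## Problem sizes and scaling

Production defaults are 2000 trees, 1-percentile grids and 1000 bootstrap
replicates. The test suite demonstrates the same properties at reduced
sizes chosen as the smallest that keep each check statistically
meaningful: ATE recovery at n = 4000 (100 confounded replicates at 50
trees), threshold recovery at n = 2000 (20 replicates, 40 trees,
2-percentile grid), bootstrap coverage at n = 500 (8 replicates of
100-replicate bootstraps, 20 trees, 5-percentile grid), and the
null-calibration bound at the full n = 670 / 2000-tree configuration.
`analysis/04_derive_dvcs.py --full` switches the pipeline to the
production configuration.

## Known limitations

* The AIPW ATE at extreme thresholds (arm fractions beyond roughly
  1:10) inherits rare-arm variance; the percentile grid plus the min-arm
  cutoff and the z-rule mitigate but do not remove this.
* The influence-function SE ignores threshold-selection uncertainty; that
  is exactly what the outer bootstrap is for — use the bootstrap CI, not
  the per-threshold SE, for the critical value.
* SMD on indicator means treats a k-level factor as k separate contrasts;
  a multivariate balance metric is out of scope.
* The forest implements neither gradient-based pseudo-outcome splitting
  nor clustered standard errors; with a single site and moderate p the
  simplified criterion matches GRF behaviour in simulation, but exact
  numerical agreement with GRF is not a goal.
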