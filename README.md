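# orncausal

Causal-machine-learning derivation of mandible dose-volume constraints
(DVCs) and empirical proton RBE for osteoradionecrosis (ORN) after
head-and-neck radiotherapy.

## The problem

ORN of the mandible is one of the most serious late toxicities of
head-and-neck radiotherapy. Retrospective dose-toxicity studies are
usually correlational: patients who receive more mandible dose differ
systematically in tumor stage, smoking, dental history and other clinical
factors that also drive ORN, so a threshold that merely *correlates* with
toxicity may not be the threshold that *causes* it. This package
implements, for photon (VMAT) vs proton (PBSPT) cohorts, an analysis chain
that targets the causal quantity directly:

1. **Propensity matching** — 1:1 globally optimal matching of photon to
   proton patients on the logit propensity score, with before/after
   chi-square / t-test balance tables.
2. **Within-group SMD diagnostics** — worst-case standardized mean
   difference of each clinical factor across dose-quartile strata,
   `SMD_max = max_{i≠j} |μ_i−μ_j| / √((σ_i²+σ_j²)/2)`, flagged at 0.2
   (biased) and 0.8 (highly biased): matching balances *between* groups
   but leaves confounding *within* them.
3. **Honest causal forest** — subsampled honest trees with
   heterogeneity-maximizing splits, local centering of outcome and
   treatment, out-of-bag CATEs, and a doubly robust (AIPW) average
   treatment effect `ATE = E[Y(T=1) − Y(T=0)]` (a risk difference for the
   binary ORN outcome) with influence-function standard errors.
4. **DVC scan** — for each mandible DVH index (V40–V70 Gy in cc, Dmax,
   Dmean in cGy), binarize at every percentile threshold, estimate the
   ATE, and take the most significant threshold as the critical
   constraint; 95% CIs from a patient-resampling bootstrap that reruns
   the whole scan.
5. **Empirical RBE** — the per-modality critical volumes form volume
   tolerance curves; linear interpolation of the photon curve at each
   proton critical volume gives the equivalent constraint dose, and
   `RBE = equivalent photon dose / (nominal proton dose / 1.1)`
   with paired-bootstrap CIs.
6. **Robustness check** — replacing each dosimetric factor with
   Uniform(0,1) noise must drive the estimated ATE to zero.

Because the institutional registry behind such analyses is not public,
the package ships a seeded synthetic cohort generator
(`orncausal.synthetic`) reproducing the relevant structure — confounded
modality assignment, covariate-driven dose burden, monotone VxGy columns,
threshold-driven ORN at ~3% prevalence — with the true causal effect of
any binarization available via `ground_truth_ate`. It is the test bed for
every stage. See `docs/methods.md` for models, estimators and numerical
choices.

## Worked example

The numbered scripts under `analysis/` run the study chain end to end on
the synthetic registry (931 photon / 335 proton patients):

```bash
python analysis/01_simulate_cohort.py   # cohort -> scratch/cohort.csv
python analysis/02_match_and_balance.py # 335:335 matched pairs + balance table
python analysis/03_within_group_smd.py  # SMD matrices per modality
python analysis/04_derive_dvcs.py       # threshold scans + bootstrap CIs
python analysis/05_tolerance_rbe.py     # tolerance curves + RBE table
python analysis/06_robustness.py        # uniform-noise null check
```

Stage 02 prints the balance table; on the default seed the four
pre-matching imbalances (smoking history p < 1e-4, current smoker
p = 0.006, hypertension p = 2e-4, tumor stage p = 0.045) all move above
p = 0.34 after matching, with 0 of 9 covariates remaining significant.
Stage 04 derives the per-modality critical volumes; on the scaled default
configuration (100 trees, 4-percentile grid, 50 bootstrap replicates) it
prints

```
VMAT  V40Gy: critical 83.24 cc (95% CI 61.54-120.02)   PBSPT V40Gy: 21.55 cc (17.85-59.27)
VMAT  V50Gy: critical 38.53 cc (95% CI 32.32-98.39)    PBSPT V50Gy: 15.28 cc (8.82-29.99)
VMAT  V60Gy: critical 32.14 cc (95% CI 15.80-55.64)    PBSPT V60Gy: 10.30 cc (0.03-16.65)
VMAT  V70Gy: critical 19.93 cc (95% CI 0.00-20.57)     PBSPT V70Gy:  8.19 cc (0.00-11.77)
```

— proton critical volumes below photon at every dose level, the
qualitative signature the method is built to expose. Stage 05 then prints

```
 nominal_proton_gy_rbe11  proton_physical_gy  equivalent_photon_gy   rbe  ci_lo  ci_hi
                    40.0              36.364                68.672 1.888  1.209   1.86
                    50.0              45.455                   NaN   NaN    NaN    NaN
                    60.0              54.545                   NaN   NaN    NaN    NaN
```

RBE at 40 Gy[RBE=1.1] lands well above the generic 1.1. The NaN rows are
the honest desk-scale outcome: with only ~20 ORN events in the matched
cohort, the proton 50/60 Gy critical volumes fall below the photon
curve's last knot, so the equivalent dose would require extrapolation and
is refused (flagged, not invented). Exact values shift with the
simulation seed and scan resolution; `--full` sharpens them. Stage 06
reports `max |ATE| = 0.0180` across the six uniform-noise factors at
n = 670 — the forest finds no effect where none exists.

The same chain is available as a library pipeline / CLI:

```bash
orncausal run-all --config analysis/pipeline_demo.yaml --out results/pipeline
```

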