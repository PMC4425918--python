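# Methods

`bnpjm` implements a three-step dynamic-prognosis analysis for severe
aortic stenosis (AS) cohorts in which brain natriuretic peptide (BNP) is
measured repeatedly at clinic visits and two right-censored outcomes —
death and aortic-valve intervention — end follow-up.

## 1. Longitudinal submodel

Log-BNP follows a linear mixed model

    y_i(t) = x_i(t)'β + b_i0 + b_i1 t + ε_it,
    b_i ~ N(0, D),  ε_it ~ N(0, σ²),

with fixed effects for time (years), aortic valve area (AVA, cm²), age
(years), symptoms (0/1), male gender (0/1), and LV ejection fraction and
creatinine each divided by a standard deviation; a random intercept and
slope per subject; unstructured 2×2 D. The natural log is used (standard
for this biomarker and required for the hazard-ratio reading of the
association parameter). Estimation is maximum likelihood (not REML, so the
fit can initialize the ML joint likelihood), delegated to statsmodels
`MixedLM`. Trajectories are deliberately linear: with roughly three
measurements per subject a richer time trend is not identifiable.

Scaling SDs are computed from the analysis cohort with the n−1 denominator
and cached on the cohort and every fit, so a new subject at prediction time
is scaled by the *training* constants.

## 2. Joint model

Each outcome gets its own joint model (the competing-risk structure between
death and intervention is acknowledged but not modelled). The hazard
depends on the current value of the smooth subject-specific trajectory
m_i(t) = x_i(t)'β + b_i0 + b_i1 t:

    h_i(t | b_i) = h0(t) exp(γ'w_i + α m_i(t)),

with w_i the baseline covariates and α the log hazard ratio per unit
current log-BNP. The marginal likelihood integrates b_i out:

    L_i = ∫ p(y_i | b) p(T_i, δ_i | b) N(b; 0, D) db.

Design choices and numerics:

* **Association scale.** α multiplies the modelled (log-pg/ml) trajectory;
  reported hazard ratios are per unit log-BNP.
* **Baseline hazard.** Weibull (PH parameterization) by default; a
  piecewise-constant baseline with knots at event-time quantiles is
  available. The Weibull default keeps a closed form in the severed-link
  α = 0 case, which the tests exploit as an oracle.
* **Cumulative hazard.** Because m_i(t) is linear in t,
  H(T|b) = e^η (k/λ^k) ∫₀ᵀ s^(k−1) e^(cs) ds with c = α(β_time + b_1).
  The integral uses a Gauss–Jacobi rule whose weight function absorbs
  s^(k−1) exactly, so the rule is exact at c = 0 and reaches ~machine
  precision for the smooth exponential factor at 12–20 nodes — and it
  vectorizes over subjects and quadrature points, unlike per-point adaptive
  quadrature. For the piecewise baseline the integral is closed-form.
* **Quadrature over b.** Tensor Gauss–Hermite. Two modes: *standard*
  (grid centered at the prior, 15 nodes/dimension by default) and
  *pseudo-adaptive* (grid re-centered per subject at the Gaussian
  approximation of p(b | y), with explicit importance re-weighting; centers
  fixed at the initializer during optimization). On data like these — the
  random-intercept SD (~0.9) double the residual SD (~0.45) — subject
  posteriors sit far from the prior, and standard GH at 15 nodes still
  carries O(1e−3) relative log-likelihood error, while the pseudo-adaptive
  grid is converged by 7–9 nodes (and exact when α = 0). The pipeline,
  bootstrap and heavy simulations therefore run pseudo-adaptive with
  reduced nodes.
* **Optimization.** Parameters are packed unconstrained (log σ²,
  log-Cholesky of D, log Weibull shape/scale); L-BFGS-B with forward
  finite-difference gradients (fixed 1e−5 step; the likelihood is smooth
  and computed to ~1e−10, giving ~1e−4 gradient accuracy at half the cost
  of central differences). Initialization is two-stage: the mixed model,
  then a parametric PH fit with the BLUP-based current value held fixed.
  Convergence: relative log-likelihood change below 1e−9 and projected
  gradient below 1e−3; the fitted optimum is checked against the
  initializer (monotone improvement).
* **Uncertainty.** vcov = inverse of the central-difference observed
  information on the packed scale (eigenvalue-clipped if numerically
  indefinite); Wald SEs and p-values for β, γ, α follow directly because
  those coordinates are untransformed.

## 3. Dynamic prediction

For a subject event-free at time t with history y (measurements at times
≤ t) the event-free probability at horizon u is

    π(u|t) = E[ S(u|b) / S(t|b) ]  over  p(b | y, T* > t; θ).

Two estimators:

* **Monte Carlo** (default, n_mc = 500): each draw samples θ* from
  N(θ̂, vcov) on the packed scale (so every draw maps to valid parameters),
  then b* from p(b | y, T* > t; θ*) by independence Metropolis–Hastings — a
  multivariate-t (df 4) proposal centered at the empirical-Bayes mode with
  curvature-based scale inflated 1.5×, 10 steps per draw, chain continued
  across θ draws. Point estimate = draw mean; 95% band = 2.5/97.5
  percentiles; per-point MC standard errors are returned. π(t|t) = 1
  exactly, each draw's curve is non-increasing in u, and identical inputs
  plus seed reproduce curves bitwise.
* **First-order** (deterministic): θ fixed at θ̂, adaptive Gauss–Hermite
  over the b posterior (mode + numerical curvature). This is the cheap
  estimator used to score every subject in the ROC analysis, and the
  oracle against which the MC mode is tested.

Updating with a new measurement appends it (chronology enforced), advances
t, and recomputes — the "renewing over time" behavior across visits. Note
an implication of conditioning: for a high-risk subject, surviving to a
later t is itself strong good news, so a later curve may sit *above* an
earlier one on a common horizon even when the new BNP is bad; the clinically
meaningful comparison across visits is the fixed-lookahead probability
π(t+Δ|t), which deteriorates when BNP jumps.

## 4. Discrimination and internal validation

At landmark t (default 1.0 y) with window dt (default 0.5 y — the
approximate visit spacing), subjects at risk at t are scored with
1 − π(t+dt | t) (first-order mode, each using their own history to t).
Cases: observed event in (t, t+dt]; controls: event-free beyond t+dt;
censored within the window: excluded (no inverse-probability weighting —
the simplest defensible estimand, and a known limitation). The ROC is a
threshold sweep (scikit-learn); the trapezoid AUC equals the Mann–Whitney
concordance with ties counted 1/2.

Internal validation resamples whole subjects with replacement (preserving
within-subject correlation), refits the joint model on each resample
(warm-started, reduced quadrature, capped iterations) and records the
resample's apparent AUC; degenerate resamples are skipped, logged and
redrawn with a capped attempt count.

Two cautions established while testing: apparent (resubstitution) AUC
carries substantial optimism when event counts in the window are small
(a pure-noise model can score ~0.7), and with strong baseline covariate
effects a *larger* generating α can lower the full-model AUC because
hazard variation moves onto the noisily-observed random effect. Properties
about the biomarker's discriminative ability are therefore tested with the
covariate channel switched off and with out-of-sample scoring.

## 5. Synthetic cohorts

The generator emulates the cohort the analysis assumes: n = 191 by
default; covariate marginals age ~ N(72.6, 11.4²), male ~ Bern(0.62),
symptoms ~ Bern(0.69), AVA ~ N(0.74, 0.27²) truncated to (0.2, 1.0),
LVEF ~ N(61, 6.7²), creatinine log-normal with moments matched to mean 89 /
SD 125 (a normal would go negative); covariates independent (their joint
correlation structure is unreported). Longitudinal and survival parameters
default to the reported coefficient tables. Values no table pins down were
chosen once as typical for log-biomarker panels and frozen: random-effect
SDs 0.9 (intercept) and 0.25 (slope), correlation 0, residual SD 0.45;
Weibull baseline shapes 1.2 (death — gently rising hazard) and 1.0
(intervention — flat); baseline scales calibrated by
`scripts/calibrate_truth.py` so a 191-subject cohort averages ~15% deaths
and ~48% interventions, then frozen (446.7 and 2.19).

Event times are drawn by inverting the subject's cumulative hazard
(bracketed root finding on H(T|b) = −log U); death and intervention share
the same random effects and trajectory; the first event ends follow-up and
administrative censoring is at 2.5 y. Visits follow the schedule
{0, 0.5, 1, 2} y with N(0, 0.1²) jitter on the non-baseline visits, each
missed with probability 0.15 (yielding ≈3 measurements/subject, matching
the reported assay density); measured BNP is exp(trajectory + residual).
Identical truth, n and seed reproduce the cohort exactly.

What the generator does **not** emulate: covariate correlations,
informative visit timing, assay detection limits, non-linear BNP
trajectories, and any dependence between death and intervention beyond the
shared trajectory. Passing tests therefore demonstrate internal
correctness and frequentist calibration under the assumed model, not
robustness to real-data violations of it.

## Problem sizes in the default test suite

Chosen as the smallest sizes at which the checked properties are
statistically decisive: oracle comparisons on 20 subjects; fitting checks
at n = 150–300; frequentist coverage over 50 replicates of n = 300 with
9-node pseudo-adaptive quadrature; bootstrap suites at B = 50; the
acceptance script runs the full analysis at the study size n = 191 with
B = 30 bootstrap resamples.

## Known limitations

* Separate single-outcome models: probabilities are not cause-specific
  cumulative incidences; with ~48% interventions the death model's
  censoring is informative to an unquantified degree.
* Apparent-AUC bootstrap (no optimism correction), exclusion of
  within-window censorings, and Wald (asymptotic-normal) uncertainty for
  the prediction bands.
* The association enters on log-BNP; published tables label the row in
  pg/ml, so reported HRs per unit are not numerically comparable to a
  raw-scale association.
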