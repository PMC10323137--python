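# Methods

This note records the models implemented in `vancomipd`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
experiments can and cannot say about real patients.

## Disposition models and closed forms

Both disposition models are linear and time-invariant with zero-order
infusion input into the central compartment.

* **One-compartment:** parameters CL (L/h) and V1 (L); elimination rate
  ke = CL/V1.
* **Two-compartment:** CL, V1, intercompartmental clearance Q (L/h) and
  peripheral volume V2 (L). The central unit-bolus response is decomposed
  into macro-constants, `C(t) = (A1·e^{−αt} + A2·e^{−βt})/V1`, with
  α+β = k10+k12+k21 and α·β = k10·k21 (k10 = CL/V1, k12 = Q/V1,
  k21 = Q/V2). Q ≤ 1e−12 L/h degenerates the β mode to zero; the code warns
  and falls back to one-compartment behaviour.

All predictions are sums over exponential "modes" (one mode for the
one-compartment model, two for the two-compartment model), which gives a
single implementation for:

* single-infusion responses (rising branch during the infusion, washout
  after);
* transient prediction over arbitrary dose histories by superposition —
  overlapping infusions simply add;
* steady state under a repeating regimen via per-mode geometric
  accumulation `1/(1 − e^{−λτ})`, including the during-infusion branch of
  the interval (needed for peaks and mid-infusion samples);
* steady-state AUC24 by analytic mode-wise integration of the profile over
  one interval, scaled by 24/τ. This route is algebraically independent of
  the mass-balance shortcut AUC24 = daily dose/CL, which is why the test
  suite can assert their agreement to 1e−9 as a genuine cross-check.

Conventions: hours everywhere, t = 0 at first-dose start, a dose's start
time marks infusion onset, trough ≡ concentration at τ (immediately before
the next dose). Exponent arguments are clamped at −700 to guard underflow on
very long histories. Bolus input, oral absorption and nonlinear elimination
are out of scope.

## Traditional arm

Cockcroft–Gault CrCL = (140 − age)·W/(72·SCr), ×0.85 for females unless the
variant omits it. Hospital practice differs in which W enters, so the weight
handling is an explicit enum: actual, ideal, adjusted (IBW + 0.4·(ABW−IBW)),
and an ideal-weight variant with the female coefficient omitted, which is
the default because it reproduces the hospital workflow of the packaged case
patient. Ideal body weight is Devine (45.5/50 + 2.3 kg per inch over
60 in), rounded to 0.1 kg before entering the CrCL formula — the convention
of common clinical calculators; without that rounding the case patient's
displayed CrCL would read 149 rather than the hospital's 148. Displayed CrCL
is truncated to integer mL/min; full precision is used downstream. The
policy cap (default 120 mL/min) applies to all dose-related calculations.

Population parameters: Vd = 0.65 L/kg·weight, ke = 0.00083·CrCL + 0.0044 h⁻¹
with capped CrCL. The printed coefficient of this linear relation appears in
degraded typesetting in secondary sources ("000083"); 0.00083 is used
because it reproduces ke = 0.104 h⁻¹ at CrCL 120 exactly. Dose inversion
uses linearity: the unique D with C_ss(τ; D) = target is
target/C_ss(τ; D = 1). Rounding is configuration (default nearest 250 mg at
≥ 40 kg, nearest 10 mg below, half away from zero); the default trough
target 17.5 mg/L is the midpoint of the traditional 15–20 mg/L range.

## Population prior and covariate model

A prior holds typical values at reference covariates (70 kg, CrCL
120 mL/min), allometric weight exponents per parameter, a renal exponent on
CL, a log-scale between-subject covariance Ω over a declared subset of
parameters, and a combined residual model σ² = (prop·f)² + add². Individual
parameters are `typical·exp(η)`, so they are strictly positive by
construction and Ω entries read as approximate CVs.

`DEFAULT_PRIOR` is deliberately a package default, not a published model:
two-compartment, CL 4.5 L/h·(wt/70)^0.75·(CrCL/120)^0.8, V1 0.5 L/kg,
Q 2.2 L/h·(wt/70)^0.75, V2 0.45 L/kg, ω(CL) = 0.35, ω(V1) = 0.30
(diagonal), residual 15% proportional + 1.0 mg/L additive. The typical
values are round numbers inside the ranges adult vancomycin studies report;
the framework, not this particular parameter set, is the point. Priors
round-trip losslessly through YAML, and an optional declared covariate
support triggers an extrapolation warning when conditioning outside it.

## MAP estimation and the Laplace approximation

The MAP objective is J(η) = Σⱼ(cⱼ − f(tⱼ; η))²/σⱼ² + ηᵀΩ⁻¹η, i.e. twice
the negative log-posterior kernel under the Gaussian residual and prior.
Consequences adopted deliberately:

* the mode is invariant to the factor of two, so J is minimized as written
  (BFGS from η = 0, gradient tolerance 1e−8, with a derivative-free
  Nelder–Mead polish when near-interpolating fits make BFGS report
  precision loss);
* the Laplace covariance is 2·H⁻¹ with H the central-difference Hessian of
  J at the mode (step 1e−4); a non-PD H gets a documented diagonal jitter;
* σⱼ is evaluated at the model prediction f, and the ½Σlog σⱼ² term of the
  full likelihood is omitted — the standard extended-least-squares
  simplification for MAP point estimation with a fixed residual model.

Zero usable levels return the prior mode with covariance Ω exactly, so
prior-only forecasting and zero-observation recommendation are the same code
path. Directions with ω² ≤ 1e−12 are pinned at η = 0 (no-IIV parameters are
not estimated). Below-quantification levels are excluded with a warning (the
M1 method); levels timed before the first dose are rejected outright.
Estimation places no steady-state requirement on sampling times — a single
level between the first and second doses is a tested, supported case.

Posterior draws are multivariate normal on η (Cholesky, seeded
`numpy.random.default_rng`), mapped through the covariate model. Forecast
intervals are empirical quantiles over draws; they are predictive for the
parameters, not for future measurement noise.

## PTA and recommendation

PTA for a candidate regimen is the fraction of draws whose steady-state
exposure satisfies the target jointly. Two target modes are explicit because
AUC and trough criteria can genuinely conflict: `auc_with_trough_cap`
(default; AUC24 ∈ [400, 600] mg·h/L at MIC 1 μg/mL, trough < 20 mg/L) and
the legacy `trough_range` ([10, 20] mg/L). The grid search reuses one draw
set across candidates (common random numbers), making the recommendation
deterministic given (posterior, grid, seed); default 2000 draws, and the
seed and draw count are recorded in the recommendation object. Ties are
broken by lower total daily dose then longer interval — the
toxicity-conservative order. One known behaviour worth stating: under the
AUC-mode target, AUC24 depends only on daily dose while troughs fall as the
interval lengthens, so the optimizer legitimately prefers longer intervals
when the trough cap is the binding constraint.

## Synthetic cohort and the policy contest

The cohort generator emulates a mixed adult/adolescent TDM population: age
uniform 16–70 y, sexes balanced, heights normal by sex (162/176 ± 7 cm),
weight = BMI·height² with lognormal BMI (median 24, log-sd 0.18) so body
proportions stay realistic, lognormal serum creatinine (median 0.8 mg/dL,
log-sd 0.25). Truth parameters come from the default prior's covariate model
plus η ~ N(0, Ω). Measured levels add 15% proportional + 1.0 mg/L additive
noise, truncated at zero. Defaults: 200 patients, seed 7.

The comparison doses every patient under both policies and judges attainment
of a 10–20 mg/L trough range against the patient's TRUE parameters. The
traditional arm sees covariates only; the Bayesian arm conditions the (here,
correctly specified) prior and may use one early level drawn 2 h after its
own first recommended dose — an opportunistic non-steady-state sample —
before re-recommending. Per-patient seeds are derived from patient identity,
so the experiment is exchangeable under cohort reordering and byte-
reproducible. The Bayesian arm targets the same trough range it is judged
on; the policy objects expose every one of these choices as configuration.

What this does and does not show: the synthetic contest demonstrates the
*direction* of the benefit (model-guided ≥ traditional, with equality-to-1.0
in the perfect-information limit and a tested guard that a grossly
misspecified prior forfeits the edge). It does not estimate real-world
attainment rates — the truth model and the Bayesian prior share a family
here, covariate distributions are stylized, and adherence/assay artifacts
are absent — so the attainment percentages it prints characterize the
simulation, not any hospital.

## Two-proportion statistic

Responder-rate differences are reported in percentage points (display
rounded to one decimal) with 95% intervals by two methods, Newcombe's
Wilson-score hybrid and the Miettinen–Nurminen score interval (both via
statsmodels). Both are always computable; neither is privileged, because
published reports frequently omit which method produced their interval.

## Problem sizes and numerical defaults

Defaults used by the shipped tests and scripts: 100 random oracle cases for
the ODE cross-check (rtol 1e−10), 200 simulated patients × 4 levels for
recovery, 200-patient cohorts for the policy contest, 2000 draws for
clinical-facing PTA and 500 within the cohort loop (attainment there is
judged on true parameters, so draw noise only perturbs the chosen dose by at
most a grid step). These sizes give stable medians and proportions at
interactive runtimes; all of them are arguments, not constants.

## Known limitations

* The Laplace approximation can understate skew in small-information
  posteriors; an MCMC hook is an intended extension point, not present.
* The residual model is homogeneous across times and assays.
* Cockcroft–Gault is the only renal model; pediatric GFR equations
  (Schwartz) and neonatal maturation are out of scope, which is why the
  cohort generator starts at age 16.
* Loading doses, continuous infusions and titration schedules beyond
  re-running the recommendation after each update are not modelled.
* Nephrotoxicity risk and economic outcomes are not modelled.
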