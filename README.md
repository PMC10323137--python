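# vancomipd

Model-informed precision dosing (MIPD) for intermittent intravenous
antimicrobials, built around the vancomycin workflow: a closed-form infusion
pharmacokinetics engine, the traditional trough-targeted dosing arm used by
many hospitals, a MAP-Bayesian engine that updates a population prior with
sparse measured levels, probability-of-target-attainment (PTA) regimen
recommendation, and a virtual-cohort harness for comparing dosing policies
head to head.

It is written for clinical pharmacists, pharmacometricians and
stewardship-minded researchers who want the mechanics of Bayesian
dose individualization — prior → new data → posterior → recommendation —
as an inspectable, scriptable library rather than a black-box platform.

## The models

**Disposition.** Linear one- and two-compartment models with zero-order
infusion input, evaluated in closed form. The steady-state concentration at
time *t* within a dosing interval for the one-compartment model is the
classic intermittent-infusion equation

```
            D   (1 − e^{−ke·T}) · e^{−ke(t−T)}
C_ss(t) = ————— · ——————————————————————————————,    T ≤ t ≤ τ,
          T·Vd·ke        1 − e^{−ke·τ}
```

with dose D, infusion time T, interval τ, volume Vd and elimination rate
ke; the during-infusion branch (0 ≤ t ≤ T) and the two-compartment
biexponential analogue are handled by the same mode-wise machinery.
Arbitrary dose histories are predicted by superposition — no numeric
integration anywhere in the production path.

**Traditional arm.** Cockcroft–Gault creatinine clearance (configurable
weight/sex-coefficient variant, policy cap 120 mL/min), population equations
Vd = 0.65 L/kg and ke = 0.00083·CrCL + 0.0044 h⁻¹, and the initial dose
obtained by inverting C_ss(τ) = target trough (default 17.5 mg/L).

**Bayesian arm.** A population prior (typical values, allometric weight and
renal covariate scaling, log-scale between-subject covariance Ω, combined
residual error) is conditioned on the patient's covariates; the individual
random effects η are estimated by maximizing the posterior,

```
minimize  Σⱼ (cⱼ − f(tⱼ; η))²/σⱼ²  +  ηᵀ Ω⁻¹ η,    σⱼ² = (prop·f)² + add²,
```

from any number of levels at any times — steady state is not required.
Uncertainty comes from the Laplace approximation at the mode; forecasts and
PTA are Monte-Carlo over posterior draws. A regimen grid is scored with
common random numbers and the PTA-maximal candidate is recommended
(ties broken by lower daily dose, then longer interval). The default
exposure target is AUC24 ∈ [400, 600] mg·h/L with trough < 20 mg/L (MIC
1 μg/mL); the legacy 10–20 mg/L trough-range target is one switch away.

The shipped prior (`vancomipd.priors.DEFAULT_PRIOR`) is an explicit,
clearly-labeled package default with round-number typical values in the
adult vancomycin range — not a published institutional model. Replace it via
`load_prior("my_prior.yaml")` for real use.

## Worked example

The packaged case is a 16-year-old female, 170 cm, 86 kg, serum creatinine
0.71 mg/dL, who received 1250 mg over 90 min at t = 0 and t = 6.5 h with a
level of 7.6 mg/L drawn at t = 14.5 h.

```
$ vancomipd casestudy
=== Traditional arm (trough-targeted) ===
CrCL (Cockcroft-Gault, display): 148 mL/min
CrCL capped for dosing:          120 mL/min
ke:                              0.104 1/h
Vd:                              55.9 L
raw dose for 17.5 mg/L trough:  1173 mg
rounded dose:                    1250 mg q8h
```

The traditional workflow lands on exactly the regimen the patient received.
The Bayesian panel then conditions the default prior on her covariates,
updates with the single 7.6 mg/L level and forecasts both regimens
(`examples/02_bayesian_update_forecast.py`):

```
prior typical CL 5.25 L/h -> posterior mode CL 7.36 L/h
forecast Ctr,ss on 1250 mg q8h: 11.2 mg/L (90% interval 7.6-16.3)
forecast AUC24: 509 mg*h/L (90% interval 383-680)
```

The low measured level pulls the clearance estimate up and the forecast
trough down; the command also prints the published platform's outputs for
this patient beside ours for inspection (its proprietary prior is not
reproduced, so the numbers are expected to differ).

The `examples/` directory has one short script per capability: traditional
dosing, Bayesian update + forecast, PTA recommendation, the cohort policy
comparison, and the two-proportion responder statistic. The same
functionality is available from the shell via `vancomipd recommend | update |
simulate | compare | casestudy`.

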