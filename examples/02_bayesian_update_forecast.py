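"""MAP-Bayesian update from a single measured level, then a forecast.

The population prior is conditioned on the patient's covariates, updated
with one level drawn mid-therapy (well before steady state), and used to
forecast the steady-state trough and AUC24 of the current regimen with
uncertainty intervals.
"""

from vancomipd import (
    DEFAULT_PRIOR,
    DoseEvent,
    ObservedLevel,
    PatientRecord,
    RegimenSpec,
    Sex,
    cockcroft_gault,
    condition_prior,
    forecast,
    map_estimate,
)

patient = PatientRecord("adolescent-01", age=16, sex=Sex.female, height=170.0, weight=86.0, serum_creatinine=0.71)
doses = [DoseEvent(0.0, 1250.0, 1.5), DoseEvent(6.5, 1250.0, 1.5)]
level = ObservedLevel(time=14.5, concentration=7.6)  # 8 h after the second dose

iprior = condition_prior(DEFAULT_PRIOR, patient, cockcroft_gault(patient))
posterior = map_estimate(iprior, doses, [level])
fc = forecast(posterior, RegimenSpec(1250.0, 8.0, 1.5), n_samples=2000, seed=0)

print(f"prior typical CL {iprior.typical.CL:.2f} L/h -> posterior mode CL {posterior.mode_params.CL:.2f} L/h")
print(f"posterior eta (log-scale): {posterior.mode_eta.round(3)}")
print(f"forecast Ctr,ss on 1250 mg q8h: {fc.point.trough_ss:.1f} mg/L "
      f"(90% interval {fc.intervals['trough_ss']['q05']:.1f}-{fc.intervals['trough_ss']['q95']:.1f})")
print(f"forecast AUC24: {fc.point.auc24_ss:.0f} mg*h/L "
      f"(90% interval {fc.intervals['auc24_ss']['q05']:.0f}-{fc.intervals['auc24_ss']['q95']:.0f})")
# A measured level below the prior prediction pulls clearance up (positive
# eta on CL), lowering the forecast trough relative to the prior forecast.
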