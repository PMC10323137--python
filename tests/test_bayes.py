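"""Prior conditioning, MAP estimation, sampling and forecasting."""

import numpy as np
import pytest

from vancomipd import (
    DEFAULT_PRIOR,
    DomainError,
    DoseEvent,
    ObservedLevel,
    PatientRecord,
    PKParameters,
    PopulationPrior,
    PosteriorEstimate,
    RegimenSpec,
    Sex,
    auc24_steady_state,
    cockcroft_gault,
    condition_prior,
    forecast,
    map_estimate,
    posterior_sample,
    predict_concentrations,
    steady_state_concentration,
)
from vancomipd.priors import IndividualPrior, load_prior, save_prior


@pytest.fixture
def reference_patient() -> PatientRecord:
    """Covariates exactly at the default prior's reference values."""
    return PatientRecord("ref", age=40, sex=Sex.male, height=178.0, weight=70.0, serum_creatinine=0.75)


@pytest.fixture
def iprior(reference_patient):
    renal = cockcroft_gault(reference_patient)
    assert renal.crcl_capped == 120.0  # reference renal function
    return condition_prior(DEFAULT_PRIOR, reference_patient, renal)


@pytest.fixture
def regimen():
    return RegimenSpec(dose=1000.0, interval=8.0, infusion_duration=1.0)


def _simulate_levels(params, events, times, prior, rng=None, prop=0.0):
    f = predict_concentrations(params, events, times).concentrations
    if rng is not None and prop > 0:
        f = f * (1.0 + prop * rng.standard_normal(f.size))
    return [ObservedLevel(float(t), float(max(c, 0.0))) for t, c in zip(np.sort(times), f)]


class TestConditionPrior:
    def test_identity_at_reference_covariates(self, iprior):
        for name in ("CL", "V1", "Q", "V2"):
            assert getattr(iprior.typical, name) == pytest.approx(DEFAULT_PRIOR.typical_values[name], rel=1e-12)

    def test_allometric_scaling_of_clearance(self, reference_patient):
        heavy = PatientRecord("h", 40, Sex.male, 178.0, 140.0, 0.9)
        r = cockcroft_gault(reference_patient)
        ih = condition_prior(DEFAULT_PRIOR, heavy, r)
        iref = condition_prior(DEFAULT_PRIOR, reference_patient, r)
        assert ih.typical.CL / iref.typical.CL == pytest.approx(2.0**0.75, rel=1e-12)
        assert ih.typical.V1 / iref.typical.V1 == pytest.approx(2.0, rel=1e-12)

    def test_renal_scaling_of_clearance(self, reference_patient):
        renal_lo = cockcroft_gault(
            PatientRecord("lo", 40, Sex.male, 178.0, 70.0, 3.0)
        )
        i_lo = condition_prior(DEFAULT_PRIOR, reference_patient, renal_lo)
        expected = DEFAULT_PRIOR.typical_values["CL"] * (renal_lo.crcl_capped / 120.0) ** 0.8
        assert i_lo.typical.CL == pytest.approx(expected, rel=1e-12)

    def test_case_patient_smoke(self):
        p = PatientRecord("c", 16, Sex.female, 170.0, 86.0, 0.71)
        ip = condition_prior(DEFAULT_PRIOR, p, cockcroft_gault(p))
        assert ip.typical.CL > 0 and ip.typical.V1 > 0 and ip.typical.Q > 0 and ip.typical.V2 > 0

    def test_out_of_support_warns(self, reference_patient):
        import dataclasses

        prior = dataclasses.replace(DEFAULT_PRIOR, covariate_support={"weight": (30.0, 60.0)})
        with pytest.warns(UserWarning, match="outside"):
            condition_prior(prior, reference_patient, cockcroft_gault(reference_patient))


class TestMapEstimate:
    def test_zero_levels_returns_prior_mode(self, iprior, regimen):
        post = map_estimate(iprior, regimen.events(3), [])
        np.testing.assert_array_equal(post.mode_eta, 0.0)
        assert post.mode_params == iprior.typical
        np.testing.assert_allclose(post.covariance_eta, iprior.omega)

    def test_noiseless_rich_sampling_recovers_eta(self, iprior, regimen):
        """12 exact levels with a nearly-vanishing residual model pin η to
        within 1% of the simulation truth."""
        import dataclasses

        sharp = dataclasses.replace(iprior, residual_proportional=1e-4, residual_additive=1e-4)
        eta_true = np.array([0.25, -0.2])
        truth = iprior.params_from_eta(eta_true)
        events = regimen.events(4)
        times = np.array([0.5, 1.5, 2.5, 4.0, 6.0, 7.9, 9.0, 12.0, 15.9, 20.0, 26.0, 31.9])
        post = map_estimate(sharp, events, _simulate_levels(truth, events, times, sharp))
        np.testing.assert_allclose(post.mode_eta, eta_true, atol=0.01 * np.abs(eta_true).max())

    def test_low_level_pulls_clearance_up(self, regimen):
        """IIV on CL only: a level below the prior prediction implies
        faster-than-typical elimination (checked against a 1-D grid scan)."""
        typ = PKParameters(CL=4.5, V1=35.0, Q=2.2, V2=31.5)
        ip = IndividualPrior(
            typical=typ, omega=np.array([[0.35**2]]), omega_params=("CL",),
            residual_proportional=0.15, residual_additive=1.0,
        )
        events = regimen.events(2)
        t_obs = 7.5
        f_typ = predict_concentrations(typ, events, [t_obs]).concentrations[0]
        obs = [ObservedLevel(t_obs, 0.5 * f_typ)]
        post = map_estimate(ip, events, obs)
        assert post.mode_params.CL > typ.CL

        # brute-force scan of the 1-D objective
        grid = np.linspace(-1.5, 1.5, 601)
        omega_inv = 1.0 / 0.35**2

        def obj(e):
            par = ip.params_from_eta(np.array([e]))
            f = predict_concentrations(par, events, [t_obs]).concentrations[0]
            s2 = (0.15 * f) ** 2 + 1.0
            return (obs[0].concentration - f) ** 2 / s2 + e**2 * omega_inv

        best = grid[np.argmin([obj(e) for e in grid])]
        assert post.mode_eta[0] == pytest.approx(best, abs=0.01)

    def test_level_before_first_dose_rejected(self, iprior, regimen):
        with pytest.raises(DomainError):
            map_estimate(iprior, [DoseEvent(2.0, 1000.0, 1.0)], [ObservedLevel(1.0, 5.0)])

    def test_no_dose_events_rejected(self, iprior):
        with pytest.raises(DomainError):
            map_estimate(iprior, [], [ObservedLevel(1.0, 5.0)])

    def test_bql_levels_excluded_with_warning(self, iprior, regimen):
        events = regimen.events(2)
        with pytest.warns(UserWarning, match="quantification"):
            post = map_estimate(iprior, events, [ObservedLevel(2.0, 0.0, below_quantification=True)])
        assert post.n_levels_used == 0

    def test_single_level_between_first_and_second_dose(self, iprior, regimen):
        """Estimation does not require steady state: one mid-interval level
        after the first dose suffices."""
        truth = iprior.params_from_eta(np.array([0.4, 0.1]))
        events = regimen.events(2)
        levels = _simulate_levels(truth, events, np.array([3.0]), iprior)
        post = map_estimate(iprior, events, levels)
        assert post.n_levels_used == 1
        assert np.any(post.mode_eta != 0.0)

    def test_shrinkage_trace_nonincreasing(self, iprior, regimen, rng):
        """Posterior uncertainty (trace of the η covariance) only shrinks as
        levels accrue on a fixed patient."""
        truth = iprior.params_from_eta(np.array([0.2, -0.1]))
        events = regimen.events(5)
        times = np.array([2.0, 7.5, 15.5, 23.5, 31.5])
        levels = _simulate_levels(truth, events, times, iprior, rng=rng, prop=0.15)
        traces = []
        for k in range(len(levels) + 1):
            post = map_estimate(iprior, events, levels[:k])
            traces.append(np.trace(post.covariance_eta))
        assert all(b <= a + 1e-9 for a, b in zip(traces, traces[1:]))


class TestPosteriorSample:
    def test_fixed_seed_reproducible(self, iprior, regimen):
        post = PosteriorEstimate.from_prior(iprior)
        d1 = posterior_sample(post, 100, seed=5)
        d2 = posterior_sample(post, 100, seed=5)
        np.testing.assert_array_equal(d1.CL, d2.CL)
        np.testing.assert_array_equal(d1.V1, d2.V1)

    def test_degenerate_covariance_collapses_to_mode(self, iprior):
        post = PosteriorEstimate(
            mode_eta=np.array([0.1, -0.2]),
            mode_params=iprior.params_from_eta(np.array([0.1, -0.2])),
            covariance_eta=np.zeros((2, 2)),
            n_levels_used=3,
            prior=iprior,
        )
        d = posterior_sample(post, 50, seed=0)
        np.testing.assert_allclose(d.CL, post.mode_params.CL, rtol=1e-12)

    def test_log_mean_converges_at_monte_carlo_rate(self, iprior):
        post = PosteriorEstimate.from_prior(iprior)
        n = 100_000
        d = posterior_sample(post, n, seed=11)
        log_cl = np.log(d.CL) - np.log(iprior.typical.CL)
        se = 0.35 / np.sqrt(n)
        assert abs(log_cl.mean()) < 4 * se

    def test_invalid_n(self, iprior):
        with pytest.raises(DomainError):
            posterior_sample(PosteriorEstimate.from_prior(iprior), 0, seed=0)


class TestForecast:
    def test_degenerate_posterior_equals_closed_forms(self, case_params, case_regimen):
        ip = IndividualPrior(
            typical=case_params, omega=np.zeros((2, 2)), omega_params=("CL", "V1"),
            residual_proportional=0.15, residual_additive=1.0,
        )
        fc = forecast(PosteriorEstimate.from_prior(ip), case_regimen, n_samples=200, seed=0)
        assert fc.point.trough_ss == pytest.approx(
            steady_state_concentration(case_params, case_regimen, 8.0), rel=1e-12
        )
        assert fc.point.auc24_ss == pytest.approx(auc24_steady_state(case_params, case_regimen), rel=1e-12)
        assert fc.point.trough_ss == pytest.approx(18.645, abs=0.01)
        assert fc.point.auc24_ss == pytest.approx(645.0, abs=0.5)

    def test_interval_contains_median_draw(self, iprior, regimen):
        fc = forecast(PosteriorEstimate.from_prior(iprior), regimen, n_samples=1000, seed=3)
        iv = fc.intervals["trough_ss"]
        assert iv["q05"] <= iv["q50"] <= iv["q95"]
        assert iv["q05"] <= fc.point.trough_ss <= iv["q95"]

    def test_wider_omega_widens_predictive_interval(self, reference_patient, regimen):
        renal = cockcroft_gault(reference_patient)
        narrow = condition_prior(DEFAULT_PRIOR, reference_patient, renal)
        wide = condition_prior(DEFAULT_PRIOR.with_omega_scale(4.0), reference_patient, renal)
        fc_n = forecast(PosteriorEstimate.from_prior(narrow), regimen, n_samples=2000, seed=9)
        fc_w = forecast(PosteriorEstimate.from_prior(wide), regimen, n_samples=2000, seed=9)
        width_n = fc_n.intervals["trough_ss"]["q95"] - fc_n.intervals["trough_ss"]["q05"]
        width_w = fc_w.intervals["trough_ss"]["q95"] - fc_w.intervals["trough_ss"]["q05"]
        assert width_w > width_n


class TestPriorSerialization:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "prior.yaml"
        save_prior(DEFAULT_PRIOR, path)
        loaded = load_prior(path)
        assert loaded.typical_values == DEFAULT_PRIOR.typical_values
        assert loaded.omega_params == DEFAULT_PRIOR.omega_params
        np.testing.assert_allclose(loaded.omega, DEFAULT_PRIOR.omega)
        assert loaded.residual_proportional == DEFAULT_PRIOR.residual_proportional
        assert loaded.model_order == DEFAULT_PRIOR.model_order

    def test_invalid_prior_rejected(self):
        with pytest.raises(DomainError):
            PopulationPrior(
                model_order="one_compartment",
                typical_values={"CL": 5.0, "V1": 35.0},
                allometric_exponents={},
                omega=np.array([[0.1, 0.2], [0.3, 0.1]]),  # asymmetric
                omega_params=("CL", "V1"),
            )
        with pytest.raises(DomainError):
            PopulationPrior(
                model_order="one_compartment",
                typical_values={"CL": 5.0, "V1": 35.0},
                allometric_exponents={},
                omega=np.diag([0.1, 0.1]),
                omega_params=("CL", "V1"),
                residual_proportional=0.0,
                residual_additive=0.0,
            )
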