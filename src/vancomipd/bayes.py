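"""MAP-Bayesian estimation and forecasting from sparse drug levels.

The Bayesian arm of model-guided dosing combines three components: the
population prior (historical knowledge, conditioned on the patient's
covariates), the patient's new data (one or more measured levels at
arbitrary times — steady state is NOT required), and the resulting posterior
over the patient's individual parameters.

Individual deviation from the patient-typical parameters is a log-scale
random-effect vector η with prior η ~ N(0, Ω). The maximum a posteriori
(MAP) estimate minimizes

    J(η) = Σⱼ (cⱼ − f(tⱼ; η))² / σⱼ²  +  ηᵀ Ω⁻¹ η,

with combined residual variance σⱼ² = (prop·f)² + add². J is twice the
negative log-posterior kernel, so the Laplace covariance of η is
2·H⁻¹ with H the Hessian of J at the mode. Posterior-predictive quantities
(forecast intervals, probability of target attainment) come from multivariate
normal draws of η mapped through the covariate model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .pk import (
    DomainError,
    DoseEvent,
    ExposureMetrics,
    PKParameters,
    RegimenSpec,
    exposure_metrics,
    predict_concentrations,
    steady_state_metrics_arrays,
)
from .priors import IndividualPrior

__all__ = [
    "ObservedLevel",
    "PosteriorEstimate",
    "ParameterDraws",
    "ForecastResult",
    "EstimationError",
    "map_estimate",
    "posterior_sample",
    "forecast",
]

#: ω² below this is treated as a fixed (no-IIV) direction
_OMEGA_FLOOR = 1e-12


class EstimationError(RuntimeError):
    """MAP optimizer failed to converge; carries the optimizer trace."""

    def __init__(self, message: str, result=None):
        super().__init__(message)
        self.result = result


@dataclass(frozen=True)
class ObservedLevel:
    """One measured drug level: time (h from first dose) and concentration
    (mg/L). ``below_quantification`` flags BQL reports, which are excluded
    from estimation with a warning."""

    time: float
    concentration: float
    below_quantification: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DomainError(f"level time must be non-negative, got {self.time}")
        if self.concentration < 0:
            raise DomainError(f"level concentration must be non-negative, got {self.concentration}")


@dataclass(frozen=True)
class PosteriorEstimate:
    """MAP posterior over the individual random effects.

    mode_eta : log-scale point estimate (zero vector with no levels).
    mode_params : the individual parameters at the mode.
    covariance_eta : Laplace covariance (the prior Ω when no levels are used).
    prior : the individualized prior the estimate was computed under.
    """

    mode_eta: np.ndarray
    mode_params: PKParameters
    covariance_eta: np.ndarray
    n_levels_used: int
    prior: IndividualPrior

    def __post_init__(self) -> None:
        cov = np.atleast_2d(np.asarray(self.covariance_eta, dtype=float))
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise DomainError("posterior covariance must be symmetric")
        object.__setattr__(self, "covariance_eta", cov)
        object.__setattr__(self, "mode_eta", np.asarray(self.mode_eta, dtype=float))

    @classmethod
    def from_prior(cls, prior: IndividualPrior) -> "PosteriorEstimate":
        """The zero-observation posterior: mode at the patient-typical values,
        covariance equal to the prior Ω."""
        k = len(prior.omega_params)
        return cls(
            mode_eta=np.zeros(k),
            mode_params=prior.typical,
            covariance_eta=prior.omega.copy(),
            n_levels_used=0,
            prior=prior,
        )


@dataclass(frozen=True)
class ParameterDraws:
    """Vectorised parameter draws (posterior or prior predictive)."""

    CL: np.ndarray
    V1: np.ndarray
    Q: np.ndarray | None
    V2: np.ndarray | None

    @property
    def n(self) -> int:
        return int(np.asarray(self.CL).shape[0])

    def steady_state_metrics(self, regimen: RegimenSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(trough_ss, peak_ss, auc24_ss) arrays across draws for a regimen."""
        return steady_state_metrics_arrays(self.CL, self.V1, self.Q, self.V2, regimen)


@dataclass(frozen=True)
class ForecastResult:
    """Point exposure metrics at the posterior mode plus empirical predictive
    intervals (quantiles over posterior draws) for each metric."""

    point: ExposureMetrics
    intervals: dict
    n_samples: int
    seed: int


def _objective_factory(prior: IndividualPrior, events, times, conc, omega_inv, free_scale):
    """Build J(η) for the free (non-degenerate) IIV directions.

    ``free_scale`` masks directions whose ω² is at the degeneracy floor;
    those η components are pinned to zero.
    """
    prop = prior.residual_proportional
    add = prior.residual_additive

    def objective(eta_free: np.ndarray) -> float:
        eta = eta_free * free_scale
        params = prior.params_from_eta(eta)
        f = predict_concentrations(params, events, times).concentrations
        sigma2 = (prop * f) ** 2 + add**2
        resid = np.sum((conc - f) ** 2 / sigma2)
        return float(resid + eta @ omega_inv @ eta)

    return objective


def map_estimate(
    prior: IndividualPrior,
    dose_events: list[DoseEvent],
    levels: list[ObservedLevel],
) -> PosteriorEstimate:
    """MAP estimate of the individual random effects from measured levels.

    Levels flagged below quantification are dropped with a warning (the M1
    approach). Levels timed before the first dose are rejected — there is no
    drug on board to inform the fit. With zero usable levels the prior mode
    is returned unchanged. Optimization is quasi-Newton (BFGS) from η = 0;
    the covariance is the Laplace approximation 2·H⁻¹ from a central-difference
    Hessian at the mode, with a diagonal jitter fallback if H is not positive
    definite.
    """
    if not dose_events:
        raise DomainError("at least one dose event is required for estimation")
    events = sorted(dose_events)
    usable = []
    for lv in levels:
        if lv.below_quantification:
            warnings.warn(f"level at t={lv.time} h below quantification: excluded (M1)")
            continue
        usable.append(lv)
    first_dose = events[0].start_time
    early = [lv.time for lv in usable if lv.time < first_dose]
    if early:
        raise DomainError(f"levels before the first dose are not usable: t={early}")
    if not usable:
        return PosteriorEstimate.from_prior(prior)

    k = len(prior.omega_params)
    omega = prior.omega
    diag = np.diag(omega).copy()
    free = diag > _OMEGA_FLOOR
    if not np.any(free):
        # no between-subject variability to estimate: posterior = prior point
        return PosteriorEstimate(
            mode_eta=np.zeros(k),
            mode_params=prior.typical,
            covariance_eta=omega.copy(),
            n_levels_used=len(usable),
            prior=prior,
        )
    # invert Ω on the free block only; pinned directions contribute nothing
    omega_inv = np.zeros((k, k))
    idx = np.ix_(free, free)
    omega_inv[idx] = np.linalg.inv(omega[idx])
    free_scale = free.astype(float)

    times = np.array([lv.time for lv in usable])
    conc = np.array([lv.concentration for lv in usable])
    objective = _objective_factory(prior, events, times, conc, omega_inv, free_scale)

    x0 = np.zeros(k)
    res = optimize.minimize(objective, x0, method="BFGS", options={"gtol": 1e-8, "maxiter": 500})
    grad_ok = np.max(np.abs(res.jac)) < 1e-3 if res.jac is not None else False
    if not res.success and not grad_ok:
        # near-interpolating fits make the quadratic term ill-scaled for BFGS
        # ("precision loss"); a derivative-free polish from its iterate settles it
        polish = optimize.minimize(
            objective, res.x, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if polish.fun <= res.fun:
            res = polish
        if not res.success:
            raise EstimationError(f"MAP optimizer did not converge: {res.message}", result=res)

    eta = res.x * free_scale
    hess = _central_hessian(objective, res.x)
    cov = _laplace_covariance(hess, free, omega)
    return PosteriorEstimate(
        mode_eta=eta,
        mode_params=prior.params_from_eta(eta),
        covariance_eta=cov,
        n_levels_used=len(usable),
        prior=prior,
    )


def _central_hessian(fun, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    k = x.size
    h = np.empty((k, k))
    e = np.eye(k) * step
    f0 = fun(x)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                h[i, i] = (fun(x + e[i]) - 2.0 * f0 + fun(x - e[i])) / step**2
            else:
                fpp = fun(x + e[i] + e[j])
                fpm = fun(x + e[i] - e[j])
                fmp = fun(x - e[i] + e[j])
                fmm = fun(x - e[i] - e[j])
                h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step**2)
    return h


def _laplace_covariance(hess: np.ndarray, free: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """cov = 2·H⁻¹ on the free block (J is twice the negative log posterior);
    pinned directions keep their (degenerate) prior variance."""
    k = free.size
    cov = np.zeros((k, k))
    idx = np.ix_(free, free)
    hf = hess[idx]
    hf = 0.5 * (hf + hf.T)
    try:
        eig = np.linalg.eigvalsh(hf)
        if eig.min() <= 0:
            raise np.linalg.LinAlgError("Hessian not positive definite")
        block = 2.0 * np.linalg.inv(hf)
    except np.linalg.LinAlgError:
        warnings.warn("MAP Hessian not positive definite: applying diagonal jitter")
        jitter = max(1e-8, 1e-6 * float(np.max(np.abs(hf))))
        block = 2.0 * np.linalg.inv(hf + jitter * np.eye(hf.shape[0]))
    cov[idx] = 0.5 * (block + block.T)
    pinned = ~free
    cov[np.ix_(pinned, pinned)] = omega[np.ix_(pinned, pinned)]
    return cov


def posterior_sample(posterior: PosteriorEstimate, n: int, seed: int) -> ParameterDraws:
    """``n`` parameter draws from the Laplace-approximate posterior.

    η is drawn multivariate normal (mode, covariance) and mapped through the
    covariate model; parameters without IIV stay at their typical value.
    Reproducible for a fixed seed. A non-PD covariance triggers the documented
    jitter fallback inside the sampler (Cholesky on cov + εI).
    """
    if n < 1:
        raise DomainError(f"need n >= 1 draws, got {n}")
    rng = np.random.default_rng(seed)
    cov = posterior.covariance_eta
    k = cov.shape[0]
    if np.allclose(cov, 0.0):
        eta = np.tile(posterior.mode_eta, (n, 1))
    else:
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            warnings.warn("posterior covariance not positive definite: jitter fallback")
            chol = np.linalg.cholesky(cov + 1e-10 * np.eye(k))
        eta = posterior.mode_eta + rng.standard_normal((n, k)) @ chol.T
    prior = posterior.prior
    typical = prior.typical
    values = {
        name: np.full(n, getattr(typical, name), dtype=float)
        for name in ("CL", "V1", "Q", "V2")
        if getattr(typical, name) is not None
    }
    for j, name in enumerate(prior.omega_params):
        values[name] = values[name] * np.exp(eta[:, j])
    return ParameterDraws(
        CL=values["CL"], V1=values["V1"], Q=values.get("Q"), V2=values.get("V2")
    )


def forecast(
    posterior: PosteriorEstimate,
    regimen: RegimenSpec,
    n_samples: int = 2000,
    seed: int = 0,
    quantiles: tuple[float, ...] = (0.05, 0.5, 0.95),
) -> ForecastResult:
    """Steady-state exposure forecast: point metrics at the posterior mode plus
    empirical predictive intervals over posterior draws."""
    point = exposure_metrics(posterior.mode_params, regimen)
    draws = posterior_sample(posterior, n_samples, seed)
    trough, peak, auc24 = draws.steady_state_metrics(regimen)
    intervals = {
        name: {f"q{int(q * 100):02d}": float(np.quantile(arr, q)) for q in quantiles}
        for name, arr in (("trough_ss", trough), ("peak_ss", peak), ("auc24_ss", auc24))
    }
    return ForecastResult(point=point, intervals=intervals, n_samples=n_samples, seed=seed)
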