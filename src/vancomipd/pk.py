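"""Closed-form concentration prediction for intermittent intravenous infusions.

Implements the linear one- and two-compartment disposition models used
throughout therapeutic drug monitoring of vancomycin and similar
antimicrobials:

* steady-state concentration at any time within the dosing interval
  (the classic intermittent-infusion equation, with the during-infusion
  branch included so peaks and mid-infusion samples can be evaluated);
* transient prediction over an arbitrary dose history by superposition of
  single-infusion solutions (no numeric integration in the production path);
* steady-state exposure metrics: trough (end of interval), peak (end of
  infusion) and AUC24, the 24-hour area under the curve.

All concentrations are mg/L, amounts mg, times and durations hours, volumes
litres and clearances L/h. Time zero is the start of the first dose; a dose's
``start_time`` marks infusion onset; the trough is the concentration at t = τ,
i.e. immediately before the next scheduled dose.

The two-compartment model is expressed through its macro-constants: the
central-compartment unit-bolus response is ``(A1·e^(−αt) + A2·e^(−βt))/V1``
with α > β > 0 the hybrid rate constants. The one-compartment model is the
single-mode special case (coefficient 1, rate ke = CL/V1), so every routine
below works uniformly on a set of exponential "modes". Parameter inputs may be
numpy arrays (e.g. posterior draws); all routines broadcast over them.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ModelOrder",
    "PKParameters",
    "DoseEvent",
    "RegimenSpec",
    "ConcentrationProfile",
    "ExposureMetrics",
    "steady_state_concentration",
    "predict_concentrations",
    "auc24_steady_state",
    "exposure_metrics",
    "two_compartment_constants",
]

#: exponent clamp guarding against underflow on very long dose histories
_EXP_FLOOR = -700.0

#: below this intercompartmental clearance (L/h) a two-compartment model is
#: treated as one-compartment (the β mode degenerates to 0)
_Q_DEGENERATE = 1e-12


def _exp(x: np.ndarray) -> np.ndarray:
    return np.exp(np.maximum(x, _EXP_FLOOR))


class ModelOrder(str, enum.Enum):
    one_compartment = "one_compartment"
    two_compartment = "two_compartment"


class ParameterError(ValueError):
    """Disposition parameters outside their admissible domain."""


class DomainError(ValueError):
    """Evaluation time or target outside the admissible domain."""


@dataclass(frozen=True)
class PKParameters:
    """Individual disposition parameters.

    CL : clearance, L/h. V1 : central volume, L. Q : intercompartmental
    clearance, L/h, and V2 : peripheral volume, L (two-compartment only).
    ``ke`` is the elimination rate constant CL/V1 (for the one-compartment
    model this is the terminal slope).
    """

    CL: float
    V1: float
    Q: float | None = None
    V2: float | None = None
    model_order: ModelOrder = field(init=False)

    def __post_init__(self) -> None:
        if not (self.CL > 0 and self.V1 > 0):
            raise ParameterError(f"CL and V1 must be positive, got CL={self.CL}, V1={self.V1}")
        if (self.Q is None) != (self.V2 is None):
            raise ParameterError("Q and V2 must be given together")
        if self.Q is not None:
            if self.Q < 0:
                raise ParameterError(f"Q must be non-negative, got {self.Q}")
            if not self.V2 > 0:  # type: ignore[operator]
                raise ParameterError(f"V2 must be positive, got {self.V2}")
            order = ModelOrder.two_compartment
        else:
            order = ModelOrder.one_compartment
        object.__setattr__(self, "model_order", order)

    @classmethod
    def one_compartment_from_ke(cls, ke: float, Vd: float) -> "PKParameters":
        """Build from the (ke, Vd) parameterisation of the simplified equations."""
        if ke <= 0 or Vd <= 0:
            raise ParameterError(f"ke and Vd must be positive, got ke={ke}, Vd={Vd}")
        return cls(CL=ke * Vd, V1=Vd)

    @property
    def ke(self) -> float:
        return self.CL / self.V1


@dataclass(frozen=True, order=True)
class DoseEvent:
    """One realized infusion: start time (h from reference), amount (mg),
    infusion duration (h). Bolus administration (zero duration) is not
    supported."""

    start_time: float
    amount: float
    infusion_duration: float

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise DomainError(f"dose amount must be non-negative, got {self.amount}")
        if not self.infusion_duration > 0:
            raise DomainError(
                f"infusion duration must be positive (bolus unsupported), got {self.infusion_duration}"
            )


@dataclass(frozen=True)
class RegimenSpec:
    """A repeating prescription: dose D (mg) every ``interval`` τ (h), infused
    over ``infusion_duration`` T (h). ``n_doses`` is a count or the string
    ``"steady-state"`` for an indefinitely repeated regimen."""

    dose: float
    interval: float
    infusion_duration: float
    n_doses: int | str = "steady-state"

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise DomainError(f"dose must be non-negative, got {self.dose}")
        if not (self.interval > self.infusion_duration > 0):
            raise DomainError(
                f"need interval > infusion_duration > 0, got τ={self.interval}, T={self.infusion_duration}"
            )
        if isinstance(self.n_doses, str):
            if self.n_doses != "steady-state":
                raise DomainError(f"n_doses must be a count or 'steady-state', got {self.n_doses!r}")
        elif self.n_doses < 1:
            raise DomainError(f"n_doses must be >= 1, got {self.n_doses}")

    @property
    def daily_dose(self) -> float:
        return self.dose * 24.0 / self.interval

    def events(self, n_doses: int | None = None, start: float = 0.0) -> list[DoseEvent]:
        """Expand to realized dose events (``n_doses`` required if the regimen
        is open-ended)."""
        if n_doses is None:
            if isinstance(self.n_doses, str):
                raise DomainError("n_doses required to expand a steady-state regimen")
            n_doses = self.n_doses
        return [
            DoseEvent(start + i * self.interval, self.dose, self.infusion_duration)
            for i in range(n_doses)
        ]


@dataclass(frozen=True)
class ConcentrationProfile:
    """Concentration-time carrier: ascending times (h), concentrations (mg/L)."""

    times: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise DomainError("times and concentrations must be equal-length 1-D arrays")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise DomainError("times must be ascending")
        if np.any(c < -1e-12):
            raise DomainError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", np.maximum(c, 0.0))


@dataclass(frozen=True)
class ExposureMetrics:
    """Steady-state exposure summary: trough (at τ), peak (end of infusion),
    AUC24 (mg·h/L)."""

    trough_ss: float
    peak_ss: float
    auc24_ss: float

    def __post_init__(self) -> None:
        if min(self.trough_ss, self.peak_ss, self.auc24_ss) < 0:
            raise DomainError("exposure metrics must be non-negative")
        if self.peak_ss < self.trough_ss - 1e-9:
            raise DomainError("peak must not be below trough")


# ---------------------------------------------------------------------------
# exponential-mode machinery (arrays broadcast over parameter draws)
# ---------------------------------------------------------------------------


def _modes_arrays(
    CL: np.ndarray, V1: np.ndarray, Q: np.ndarray | None, V2: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-bolus macro-decomposition: coefficients ``A_i`` (summing to 1) and
    rates ``λ_i`` such that C_bolus(t) = Σ A_i e^{−λ_i t} / V1.

    Returns arrays of shape ``broadcast(...) + (m,)`` with m = 1 or 2.
    """
    CL = np.asarray(CL, dtype=float)
    V1 = np.asarray(V1, dtype=float)
    if np.any(CL <= 0) or np.any(V1 <= 0):
        raise ParameterError("CL and V1 must be positive")
    k10 = CL / V1
    if Q is None or V2 is None:
        return np.ones(k10.shape + (1,)), k10[..., None]
    Q = np.asarray(Q, dtype=float)
    V2 = np.asarray(V2, dtype=float)
    if np.any(Q < 0) or np.any(V2 <= 0):
        raise ParameterError("need Q >= 0 and V2 > 0")
    if np.all(Q <= _Q_DEGENERATE):
        warnings.warn("Q ~ 0: two-compartment model degenerates to one-compartment")
        k10b = np.broadcast_to(k10, np.broadcast_shapes(k10.shape, Q.shape)).copy()
        return np.ones(k10b.shape + (1,)), k10b[..., None]
    k12 = Q / V1
    k21 = Q / V2
    s = k10 + k12 + k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
    alpha = 0.5 * (s + disc)
    beta = 0.5 * (s - disc)
    # guard the (measure-zero) repeated-root case
    denom = np.where(alpha - beta == 0.0, np.finfo(float).tiny, alpha - beta)
    A1 = (alpha - k21) / denom
    A2 = (k21 - beta) / denom
    coef = np.stack([A1, A2], axis=-1)
    lam = np.stack([alpha, beta], axis=-1)
    return coef, lam


def _modes(params: PKParameters) -> tuple[np.ndarray, np.ndarray]:
    if params.model_order is ModelOrder.two_compartment and params.Q is not None and params.Q <= _Q_DEGENERATE:
        warnings.warn("Q ~ 0: falling back to one-compartment behaviour")
        return np.ones((1,)), np.array([params.ke])
    q = None if params.Q is None else np.asarray(params.Q)
    v2 = None if params.V2 is None else np.asarray(params.V2)
    coef, lam = _modes_arrays(np.asarray(params.CL), np.asarray(params.V1), q, v2)
    return coef, lam


def two_compartment_constants(params: PKParameters) -> tuple[float, float, float, float]:
    """Macro-constants (α, β, A1, A2) of the two-compartment unit-bolus
    response ``(A1 e^{−αt} + A2 e^{−βt})/V1``, with α > β > 0 and A1 + A2 = 1.

    Satisfies α·β = (CL/V1)·(Q/V2) and α+β = CL/V1 + Q/V1 + Q/V2. For Q ≈ 0
    the model degenerates; a warning is raised and the one-compartment mode
    (ke, coefficient 1) is returned as (ke, ke, 1, 0).
    """
    if params.model_order is not ModelOrder.two_compartment:
        raise ParameterError("two_compartment_constants requires a two-compartment parameter set")
    coef, lam = _modes(params)
    if lam.shape[-1] == 1:  # degenerate fallback (warning already emitted)
        return float(lam[0]), float(lam[0]), 1.0, 0.0
    return float(lam[..., 0]), float(lam[..., 1]), float(coef[..., 0]), float(coef[..., 1])


def _single_infusion_conc(
    coef: np.ndarray,
    lam: np.ndarray,
    V1: np.ndarray,
    dose: float,
    duration: float,
    t: np.ndarray,
) -> np.ndarray:
    """Concentration at times ``t`` (h after infusion start) from one infusion.

    During the infusion (0 ≤ t ≤ T): (D/T)·Σ aᵢ(1 − e^{−λᵢt}); afterwards the
    accrued amount washes out: (D/T)·Σ aᵢ(1 − e^{−λᵢT})e^{−λᵢ(t−T)}, with
    aᵢ = Aᵢ/(V1 λᵢ). Zero before the infusion starts.
    """
    t = np.asarray(t, dtype=float)
    a = coef / (V1[..., None] * lam)
    te = np.clip(t, 0.0, duration)  # time "inside" the infusion
    tail = np.maximum(t - duration, 0.0)
    g = (1.0 - _exp(-lam * te[..., None])) * _exp(-lam * tail[..., None])
    c = (dose / duration) * np.sum(a * g, axis=-1)
    return np.where(t <= 0.0, 0.0, c)


def predict_concentrations(
    params: PKParameters, events: Iterable[DoseEvent], times: Sequence[float]
) -> ConcentrationProfile:
    """Transient concentration over an arbitrary dose history by superposition.

    Exact closed form — the sum over events of the single-infusion solution.
    Overlapping infusions superpose; times before all events yield 0. Query
    times are sorted ascending in the returned profile.
    """
    t = np.sort(np.asarray(list(times), dtype=float))
    coef, lam = _modes(params)
    V1 = np.asarray(params.V1, dtype=float)
    c = np.zeros_like(t)
    for ev in events:
        c = c + _single_infusion_conc(coef, lam, V1, ev.amount, ev.infusion_duration, t - ev.start_time)
    return ConcentrationProfile(times=t, concentrations=c)


def _ss_conc_arrays(
    coef: np.ndarray,
    lam: np.ndarray,
    V1: np.ndarray,
    dose: float,
    tau: float,
    duration: float,
    t: float,
) -> np.ndarray:
    """Steady-state concentration at t ∈ [0, τ] (array-broadcast core).

    Post-infusion (T ≤ t ≤ τ) this is the classic accumulating form
    (D/T)·Σ aᵢ(1−e^{−λᵢT}) e^{−λᵢ(t−T)} / (1−e^{−λᵢτ}); during the infusion
    the current dose's rising branch is added to the washout of all previous
    doses (geometric accumulation per exponential mode).
    """
    a = coef / (V1[..., None] * lam)
    q = _exp(-lam * tau)
    acc = q / (1.0 - q)
    te = min(t, duration)
    tail = t - duration  # may be negative during the infusion
    current = (1.0 - _exp(-lam * te)) * np.where(t >= duration, _exp(-lam * tail), 1.0)
    previous = (1.0 - _exp(-lam * duration)) * _exp(-lam * tail) * acc
    return (dose / duration) * np.sum(a * (current + previous), axis=-1)


def steady_state_concentration(params: PKParameters, regimen: RegimenSpec, t: float) -> float:
    """Steady-state concentration Css,t at time ``t`` within the dosing interval.

    For the one-compartment model and T < t ≤ τ this is the intermittent-
    infusion equation D(1−e^{−keT})e^{−ke(t−T)} / (T·Vd·ke·(1−e^{−keτ}));
    0 ≤ t ≤ T is handled by the during-infusion closed form with the
    accumulation term. Linear in D.
    """
    if not (0.0 <= t <= regimen.interval):
        raise DomainError(f"t={t} outside the dosing interval [0, {regimen.interval}]")
    coef, lam = _modes(params)
    c = _ss_conc_arrays(
        coef, lam, np.asarray(params.V1, float), regimen.dose, regimen.interval, regimen.infusion_duration, t
    )
    return float(c)


def _auc_tau_ss_arrays(
    coef: np.ndarray, lam: np.ndarray, V1: np.ndarray, dose: float, tau: float, duration: float
) -> np.ndarray:
    """Analytic ∫₀^τ Css(t) dt: mode-wise integration of the steady-state
    profile (independent of the dose/CL mass-balance identity)."""
    a = coef / (V1[..., None] * lam)
    eT = _exp(-lam * duration)
    etau = _exp(-lam * tau)
    one_minus_q = 1.0 - etau
    # rising branch of the current dose over [0, T]
    rise = duration - (1.0 - eT) / lam
    # washout of all previous doses over [0, T]: q(e^{λT}−1) = e^{−λ(τ−T)} − e^{−λτ}
    prev = (1.0 - eT) * (_exp(-lam * (tau - duration)) - etau) / (one_minus_q * lam)
    # post-infusion branch over [T, τ]
    post = (1.0 - eT) * (1.0 - _exp(-lam * (tau - duration))) / (one_minus_q * lam)
    return (dose / duration) * np.sum(a * (rise + prev + post), axis=-1)


def auc24_steady_state(params: PKParameters, regimen: RegimenSpec) -> float:
    """Steady-state AUC24 (mg·h/L): (24/τ) × the per-interval area.

    Computed by analytic mode-wise integration of the steady-state profile;
    for linear PK this equals daily dose / CL for both model orders.
    """
    if params.CL <= 0:
        raise ParameterError(f"CL must be positive, got {params.CL}")
    coef, lam = _modes(params)
    auc_tau = _auc_tau_ss_arrays(
        coef, lam, np.asarray(params.V1, float), regimen.dose, regimen.interval, regimen.infusion_duration
    )
    return float(24.0 / regimen.interval * auc_tau)


def exposure_metrics(params: PKParameters, regimen: RegimenSpec) -> ExposureMetrics:
    """Trough (t = τ), peak (t = T) and AUC24 at steady state."""
    return ExposureMetrics(
        trough_ss=steady_state_concentration(params, regimen, regimen.interval),
        peak_ss=steady_state_concentration(params, regimen, regimen.infusion_duration),
        auc24_ss=auc24_steady_state(params, regimen),
    )


def steady_state_metrics_arrays(
    CL: np.ndarray,
    V1: np.ndarray,
    Q: np.ndarray | None,
    V2: np.ndarray | None,
    regimen: RegimenSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (trough_ss, peak_ss, auc24_ss) across parameter arrays.

    The workhorse behind Monte-Carlo target-attainment: one call evaluates a
    whole set of posterior draws against a candidate regimen.
    """
    coef, lam = _modes_arrays(CL, V1, Q, V2)
    V1a = np.asarray(V1, dtype=float)
    trough = _ss_conc_arrays(coef, lam, V1a, regimen.dose, regimen.interval, regimen.infusion_duration, regimen.interval)
    peak = _ss_conc_arrays(coef, lam, V1a, regimen.dose, regimen.interval, regimen.infusion_duration, regimen.infusion_duration)
    auc24 = 24.0 / regimen.interval * _auc_tau_ss_arrays(coef, lam, V1a, regimen.dose, regimen.interval, regimen.infusion_duration)
    return trough, peak, auc24
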