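"""Population priors: typical values, covariate model, variability — and the
package default.

A :class:`PopulationPrior` is the "historical knowledge" half of the Bayesian
workflow: typical disposition parameters at reference covariates, a
declarative covariate model (allometric weight scaling per parameter, renal
scaling of clearance), a between-subject variance–covariance matrix Ω of
log-scale random effects η, and a combined residual-error model
σ² = (prop·f)² + add².

DEFAULT_PRIOR below is this package's own configurable default, NOT a
published vancomycin model: the typical values are round numbers in the range
adult vancomycin literature reports (CL ≈ 4–6 L/h at 70 kg and normal renal
function, central volume ≈ 0.4–0.6 L/kg, a distribution compartment of
similar size), chosen so the framework can be exercised end-to-end. Any
serious deployment replaces it with an institution-validated prior via
``load_prior``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import yaml

from .pk import DomainError, ModelOrder, PKParameters
from .renal import PatientRecord, RenalFunction

__all__ = [
    "PopulationPrior",
    "IndividualPrior",
    "DEFAULT_PRIOR",
    "condition_prior",
    "load_prior",
    "save_prior",
]

_PARAM_ORDER = ("CL", "V1", "Q", "V2")


@dataclass(frozen=True)
class PopulationPrior:
    """Population model: typical values at reference covariates plus
    variability.

    typical_values : parameter -> value at ``reference_weight`` and
        ``reference_crcl`` (L/h for CL and Q, L for V1 and V2).
    allometric_exponents : parameter -> exponent on (weight / reference_weight).
    renal_exponent : exponent on (CrCL_capped / reference_crcl), applied to CL.
    omega : between-subject covariance of log-scale random effects, over
        ``omega_params`` (order matters); symmetric positive semi-definite.
    residual_proportional / residual_additive : combined residual error,
        unitless s.d. and mg/L s.d.; not both zero.
    """

    model_order: ModelOrder
    typical_values: Mapping[str, float]
    allometric_exponents: Mapping[str, float]
    omega: np.ndarray
    omega_params: tuple[str, ...] = ("CL", "V1")
    reference_weight: float = 70.0
    reference_crcl: float = 120.0
    renal_exponent: float = 0.8
    residual_proportional: float = 0.15
    residual_additive: float = 1.0
    #: optional declared covariate support, e.g. {"weight": [30, 200],
    #: "crcl": [10, 200]}; conditioning outside it warns (extrapolation)
    covariate_support: Mapping[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "model_order", ModelOrder(self.model_order))
        object.__setattr__(self, "typical_values", dict(self.typical_values))
        object.__setattr__(self, "allometric_exponents", dict(self.allometric_exponents))
        object.__setattr__(self, "omega_params", tuple(self.omega_params))
        om = np.atleast_2d(np.asarray(self.omega, dtype=float))
        if om.shape[0] != om.shape[1] or om.shape[0] != len(self.omega_params):
            raise DomainError("omega must be square and match omega_params")
        if not np.allclose(om, om.T):
            raise DomainError("omega must be symmetric")
        if np.any(np.linalg.eigvalsh(om) < -1e-10):
            raise DomainError("omega must be positive semi-definite")
        object.__setattr__(self, "omega", om)
        needed = {"CL", "V1"} | ({"Q", "V2"} if self.model_order is ModelOrder.two_compartment else set())
        missing = needed - set(self.typical_values)
        if missing:
            raise DomainError(f"typical_values missing {sorted(missing)}")
        if any(self.typical_values[p] <= 0 for p in needed):
            raise DomainError("typical values must be positive")
        if self.residual_proportional < 0 or self.residual_additive < 0:
            raise DomainError("residual s.d.s must be non-negative")
        if self.residual_proportional == 0 and self.residual_additive == 0:
            raise DomainError("residual s.d.s must not both be zero")
        unknown = set(self.omega_params) - needed
        if unknown:
            raise DomainError(f"omega_params not in the model: {sorted(unknown)}")

    @property
    def param_names(self) -> tuple[str, ...]:
        if self.model_order is ModelOrder.two_compartment:
            return _PARAM_ORDER
        return ("CL", "V1")

    def with_omega_scale(self, factor: float) -> "PopulationPrior":
        """A copy with Ω scaled by ``factor`` (handy for dispersion studies)."""
        return replace(self, omega=self.omega * factor)

    def to_dict(self) -> dict:
        return {
            "model_order": self.model_order.value,
            "typical_values": dict(self.typical_values),
            "allometric_exponents": dict(self.allometric_exponents),
            "omega": [[float(x) for x in row] for row in self.omega],
            "omega_params": list(self.omega_params),
            "reference_weight": self.reference_weight,
            "reference_crcl": self.reference_crcl,
            "renal_exponent": self.renal_exponent,
            "residual_proportional": self.residual_proportional,
            "residual_additive": self.residual_additive,
            "covariate_support": (
                None
                if self.covariate_support is None
                else {k: [float(a), float(b)] for k, (a, b) in self.covariate_support.items()}
            ),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationPrior":
        d = dict(d)
        d["omega"] = np.asarray(d["omega"], dtype=float)
        d["omega_params"] = tuple(d["omega_params"])
        return cls(**d)


@dataclass(frozen=True)
class IndividualPrior:
    """A population prior conditioned on one patient's covariates: the
    patient-typical parameters plus the unchanged variability components."""

    typical: PKParameters
    omega: np.ndarray
    omega_params: tuple[str, ...]
    residual_proportional: float
    residual_additive: float

    def typical_vector(self) -> np.ndarray:
        """Typical values for the parameters carrying IIV, in omega order."""
        return np.array([getattr(self.typical, p) for p in self.omega_params], dtype=float)

    def params_from_eta(self, eta: np.ndarray) -> PKParameters:
        """Map a log-scale random-effect vector to individual parameters:
        pᵢ = typicalᵢ·exp(ηᵢ) for parameters with IIV, typical otherwise."""
        values = {p: getattr(self.typical, p) for p in ("CL", "V1", "Q", "V2") if getattr(self.typical, p) is not None}
        for name, e in zip(self.omega_params, np.asarray(eta, dtype=float)):
            values[name] = values[name] * float(np.exp(e))
        return PKParameters(**values)


#: Package default prior — a configurable stand-in with round-number typical
#: values in the adult vancomycin range; NOT a published model (see module
#: docstring). Two-compartment; allometric weight scaling (0.75 on
#: clearances, 1 on volumes); CL scales with capped CrCL to the 0.8 power.
DEFAULT_PRIOR = PopulationPrior(
    model_order=ModelOrder.two_compartment,
    typical_values={"CL": 4.5, "V1": 35.0, "Q": 2.2, "V2": 31.5},
    allometric_exponents={"CL": 0.75, "V1": 1.0, "Q": 0.75, "V2": 1.0},
    omega=np.diag([0.35**2, 0.30**2]),
    omega_params=("CL", "V1"),
    reference_weight=70.0,
    reference_crcl=120.0,
    renal_exponent=0.8,
    residual_proportional=0.15,
    residual_additive=1.0,
)


def condition_prior(
    prior: PopulationPrior, patient: PatientRecord, renal: RenalFunction
) -> IndividualPrior:
    """Deterministic covariate substitution: typical parameters for this
    patient; the random-effect structure (Ω, residual error) is untouched.

    Each parameter scales allometrically with (weight/ref_weight); clearance
    additionally scales with (CrCL_capped/ref_crcl)^renal_exponent. Covariates
    outside the prior's declared support trigger an extrapolation warning.
    """
    if prior.covariate_support:
        observed = {"weight": patient.weight, "crcl": renal.crcl_capped, "age": patient.age}
        for key, (lo, hi) in prior.covariate_support.items():
            val = observed.get(key)
            if val is not None and not (lo <= val <= hi):
                warnings.warn(
                    f"covariate {key}={val:.3g} outside the prior's declared support [{lo}, {hi}]"
                )
    w_ratio = patient.weight / prior.reference_weight
    values: dict[str, float] = {}
    for name in prior.param_names:
        tv = prior.typical_values[name] * w_ratio ** prior.allometric_exponents.get(name, 0.0)
        if name == "CL":
            tv *= (renal.crcl_capped / prior.reference_crcl) ** prior.renal_exponent
        values[name] = tv
    typical = PKParameters(**values)
    return IndividualPrior(
        typical=typical,
        omega=prior.omega,
        omega_params=prior.omega_params,
        residual_proportional=prior.residual_proportional,
        residual_additive=prior.residual_additive,
    )


def save_prior(prior: PopulationPrior, path) -> None:
    """Serialize a prior to YAML (lossless round trip with :func:`load_prior`)."""
    with open(path, "w") as fh:
        yaml.safe_dump(prior.to_dict(), fh, sort_keys=True)


def load_prior(path) -> PopulationPrior:
    with open(path) as fh:
        return PopulationPrior.from_dict(yaml.safe_load(fh))
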