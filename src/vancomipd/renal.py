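"""Traditional (trough-targeted) dosing arm: renal function and population equations.

This module reproduces the hospital-comparator workflow for vancomycin:
Cockcroft–Gault creatinine clearance (with a configurable policy cap),
population estimates of the one-compartment disposition parameters from
capped CrCL and body weight, and the initial maintenance dose obtained by
inverting the steady-state intermittent-infusion equation for a target
trough.

Cockcroft–Gault hospital practice varies in which body weight enters the
formula and whether the 0.85 female coefficient is applied, so the weight
handling is an explicit ``variant``. Ideal-body-weight variants use the
Devine formula with the result rounded to 0.1 kg before entering the CrCL
formula — the convention of common clinical calculators and of the hospital
workflow this arm mirrors.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from .pk import DomainError, PKParameters, RegimenSpec, steady_state_concentration

__all__ = [
    "Sex",
    "PatientRecord",
    "CockcroftGaultVariant",
    "RenalFunction",
    "DoseRoundingPolicy",
    "ideal_body_weight",
    "cockcroft_gault",
    "cap_crcl",
    "population_parameters",
    "solve_dose_for_trough",
]

#: default hospital-policy ceiling on CrCL for dose-related calculations, mL/min
DEFAULT_CRCL_CAP = 120.0

#: default trough target, mg/L — midpoint of the traditional 15–20 mg/L range
DEFAULT_TROUGH_TARGET = 17.5

_CM_PER_INCH = 2.54


class Sex(str, enum.Enum):
    female = "female"
    male = "male"


@dataclass(frozen=True)
class PatientRecord:
    """Covariates for one patient: age (years), sex, height (cm), actual body
    weight (kg) and serum creatinine (mg/dL)."""

    patient_id: str
    age: float
    sex: Sex
    height: float
    weight: float
    serum_creatinine: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        if self.age < 0:
            raise DomainError(f"age must be non-negative, got {self.age}")
        if self.height <= 0 or self.weight <= 0:
            raise DomainError("height and weight must be positive")
        if self.serum_creatinine <= 0:
            raise DomainError(f"serum creatinine must be positive, got {self.serum_creatinine}")


class CockcroftGaultVariant(str, enum.Enum):
    """Weight / sex-coefficient handling in the Cockcroft–Gault formula.

    ``ideal_weight_no_sex_coefficient`` — ideal body weight, 0.85 female
    coefficient omitted; the hospital-comparator default reverse-engineered
    from the case workflow. The remaining variants are the standard ones.
    """

    ideal_weight_no_sex_coefficient = "ideal_weight_no_sex_coefficient"
    ideal_weight = "ideal_weight"
    actual_weight = "actual_weight"
    adjusted_weight = "adjusted_weight"


@dataclass(frozen=True)
class RenalFunction:
    """Estimated creatinine clearance before (``crcl_raw``) and after
    (``crcl_capped``) the policy cap, with the variant used. ``display`` is
    the integer mL/min shown to clinicians (truncated); full precision is
    retained internally."""

    crcl_raw: float
    crcl_capped: float
    variant: CockcroftGaultVariant

    @property
    def display(self) -> int:
        return math.floor(self.crcl_raw)


@dataclass(frozen=True)
class DoseRoundingPolicy:
    """Institutional dose rounding: increment (mg) and direction."""

    increment: float = 250.0
    mode: str = "nearest"  # nearest | up | down

    def __post_init__(self) -> None:
        if self.increment <= 0:
            raise DomainError(f"increment must be positive, got {self.increment}")
        if self.mode not in ("nearest", "up", "down"):
            raise DomainError(f"unknown rounding mode {self.mode!r}")

    def round(self, dose: float) -> float:
        n = dose / self.increment
        if self.mode == "nearest":
            k = math.floor(n + 0.5)  # half rounds up, not to even
        elif self.mode == "up":
            k = math.ceil(n - 1e-12)
        else:
            k = math.floor(n + 1e-12)
        return k * self.increment

    @classmethod
    def for_weight(cls, weight: float, mode: str = "nearest") -> "DoseRoundingPolicy":
        """Default institutional policy: nearest 250 mg at >= 40 kg, nearest
        10 mg below (rounding conventions vary by institution; this is
        configuration, not doctrine)."""
        return cls(increment=250.0 if weight >= 40.0 else 10.0, mode=mode)


def ideal_body_weight(height: float, sex: Sex) -> float:
    """Devine ideal body weight (kg) from height (cm).

    female: 45.5 + 2.3·(height_in − 60); male: 50 + 2.3·(height_in − 60).
    Heights implying a negative IBW are rejected.
    """
    if height <= 0:
        raise DomainError(f"height must be positive, got {height}")
    inches = height / _CM_PER_INCH
    base = 45.5 if Sex(sex) is Sex.female else 50.0
    ibw = base + 2.3 * (inches - 60.0)
    if ibw <= 0:
        raise DomainError(f"height {height} cm implies non-positive ideal body weight")
    return ibw


def _cg_weight(patient: PatientRecord, variant: CockcroftGaultVariant) -> float:
    if variant is CockcroftGaultVariant.actual_weight:
        return patient.weight
    ibw = round(ideal_body_weight(patient.height, patient.sex), 1)  # calculator convention
    if variant in (
        CockcroftGaultVariant.ideal_weight,
        CockcroftGaultVariant.ideal_weight_no_sex_coefficient,
    ):
        return ibw
    if variant is CockcroftGaultVariant.adjusted_weight:
        # adjusted body weight: IBW + 0.4 × (actual − IBW), floored at IBW
        return ibw + 0.4 * max(patient.weight - ibw, 0.0)
    raise DomainError(f"unsupported Cockcroft-Gault variant {variant!r}")


def cockcroft_gault(
    patient: PatientRecord,
    variant: CockcroftGaultVariant = CockcroftGaultVariant.ideal_weight_no_sex_coefficient,
    cap: float = DEFAULT_CRCL_CAP,
) -> RenalFunction:
    """Cockcroft–Gault creatinine clearance, mL/min: (140 − age)·W / (72·SCr),
    ×0.85 for females unless the variant omits the coefficient.

    ``cap`` applies the hospital policy ceiling for dose-related calculations;
    the raw estimate is retained for display.
    """
    variant = CockcroftGaultVariant(variant)
    if patient.age >= 140:
        raise DomainError(f"age {patient.age} outside Cockcroft-Gault support (< 140 y)")
    w = _cg_weight(patient, variant)
    crcl = (140.0 - patient.age) * w / (72.0 * patient.serum_creatinine)
    if patient.sex is Sex.female and variant is not CockcroftGaultVariant.ideal_weight_no_sex_coefficient:
        crcl *= 0.85
    return RenalFunction(crcl_raw=crcl, crcl_capped=cap_crcl(crcl, cap), variant=variant)


def cap_crcl(crcl: float, cap: float = DEFAULT_CRCL_CAP) -> float:
    """Apply the policy ceiling: min(CrCL, cap). Idempotent and monotone."""
    if crcl < 0:
        raise DomainError(f"CrCL must be non-negative, got {crcl}")
    return min(crcl, cap)


def population_parameters(crcl_capped: float, weight: float) -> PKParameters:
    """Population one-compartment parameters of the simplified dosing equations.

    Vd = 0.65 L/kg × weight; ke = 0.00083 × CrCL + 0.0044 h⁻¹ (CrCL in mL/min,
    capped per policy); CL = ke × Vd.
    """
    if crcl_capped < 0 or weight <= 0:
        raise DomainError("CrCL must be non-negative and weight positive")
    vd = 0.65 * weight
    ke = 0.00083 * crcl_capped + 0.0044
    return PKParameters.one_compartment_from_ke(ke=ke, Vd=vd)


def solve_dose_for_trough(
    params: PKParameters,
    target_trough: float,
    interval: float,
    infusion_duration: float,
    rounding: DoseRoundingPolicy | None = None,
) -> tuple[float, float]:
    """Invert the steady-state equation for the dose achieving a target trough.

    By linearity in dose, the raw dose is target / Css(τ; D=1). Returns
    (raw_dose, rounded_dose); the raw dose satisfies the round-trip
    Css(raw_dose, τ) = target to full numerical precision.
    """
    if target_trough < 0:
        raise DomainError(f"target trough must be non-negative, got {target_trough}")
    if target_trough == 0:
        return 0.0, 0.0
    unit = steady_state_concentration(
        params, RegimenSpec(dose=1.0, interval=interval, infusion_duration=infusion_duration), interval
    )
    raw = target_trough / unit
    rounding = rounding or DoseRoundingPolicy()
    return raw, rounding.round(raw)
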