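"""Reduced-order pressure-gradient models and severity grading.

The core of the package is an algebraic power law relating the peak-systolic
transvalvular pressure gradient (TPG, mmHg) to the peak-systolic volume flow
rate Q (l/s) and the aortic valve area AVA (cm^2):

    TPG = a * Q**b * AVA**(-c)

with default coefficients (a, b, c) = (185.5, 1.483, 1.385) obtained by
calibrating the law against high-fidelity flow simulations (see the
:mod:`ctgrad.calibration` module for refitting).  The module also provides
the simplified Bernoulli model used in Doppler echocardiography
(TPG = 4 v^2, v in m/s), the flow correction applied in the presence of
mitral insufficiency, and binary stenosis-severity grading against a
maximum-gradient threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Union

from .errors import DomainError, ValidationError
from .units import ml_per_s_to_l_per_s

__all__ = [
    "ModelCoefficients",
    "DEFAULT_COEFFICIENTS",
    "MIGrade",
    "MI_REDUCTION_FRACTIONS",
    "SeverityGrade",
    "SEVERITY_THRESHOLD_MMHG",
    "tpg_power_law",
    "tpg_power_law_ml_per_s",
    "tpg_bernoulli",
    "apply_mi_correction",
    "grade_severity",
]


@dataclass(frozen=True)
class ModelCoefficients:
    """Coefficients (a, b, c) of TPG = a * Q**b * AVA**(-c).

    ``a`` carries units mmHg * (l/s)**(-b) * cm**(2c); ``b`` and ``c`` are
    dimensionless.  ``c`` is stored as a positive magnitude and applied with
    a negative sign, so larger orifices always give smaller gradients.
    """

    a: float = 185.5
    b: float = 1.483
    c: float = 1.385

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            value = getattr(self, name)
            if not value > 0:
                raise ValidationError(
                    f"coefficient {name!r} must be positive, got {value!r}"
                )

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelCoefficients":
        try:
            return cls(a=float(d["a"]), b=float(d["b"]), c=float(d["c"]))
        except KeyError as exc:
            raise ValidationError(f"coefficient file missing key {exc}") from exc

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ModelCoefficients":
        return cls.from_dict(json.loads(Path(path).read_text()))


DEFAULT_COEFFICIENTS = ModelCoefficients()

#: Maximum-gradient threshold (mmHg) separating the severe from the
#: non-severe side; 64 mmHg corresponds to a peak jet velocity of 4 m/s
#: under the simplified Bernoulli relation.
SEVERITY_THRESHOLD_MMHG = 64.0


class MIGrade(str, Enum):
    """Mitral-insufficiency grade from retrospective Doppler reports."""

    NONE = "none"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"

    @classmethod
    def parse(cls, label: Union[str, "MIGrade"]) -> "MIGrade":
        if isinstance(label, cls):
            return label
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            valid = ", ".join(g.value for g in cls)
            raise ValidationError(
                f"unknown mitral-insufficiency grade {label!r}; expected one of {valid}"
            ) from None


#: Fraction of the LV volume change assumed to regurgitate through the mitral
#: valve, hence removed from the aortic flow: 10 / 30 / 50 % for mild /
#: moderate / severe insufficiency (the lower thresholds of multimodal MI
#: grading).  Supplied as a default so recalibrated tables can be passed in.
MI_REDUCTION_FRACTIONS: Mapping[MIGrade, float] = {
    MIGrade.NONE: 0.0,
    MIGrade.MILD: 0.10,
    MIGrade.MODERATE: 0.30,
    MIGrade.SEVERE: 0.50,
}


@dataclass(frozen=True)
class SeverityGrade:
    """Binary stenosis grade relative to a maximum-TPG threshold."""

    label: str  # "above_threshold" or "below_threshold"
    threshold: float

    @property
    def is_above(self) -> bool:
        return self.label == "above_threshold"


def tpg_power_law(
    q_ls: float,
    ava_cm2: float,
    coeffs: ModelCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """Pressure gradient (mmHg) from flow ``q_ls`` (l/s) and area ``ava_cm2`` (cm^2).

    Strictly increasing in flow and strictly decreasing in valve area.
    Zero flow maps to exactly 0 mmHg (0**b = 0 for b > 0); negative flow or
    a non-positive area is outside the model's domain.
    """
    if q_ls < 0:
        raise DomainError(f"flow rate must be non-negative, got {q_ls} l/s")
    if not ava_cm2 > 0:
        raise DomainError(f"valve area must be positive, got {ava_cm2} cm^2")
    if q_ls == 0:
        return 0.0
    return coeffs.a * q_ls**coeffs.b * ava_cm2 ** (-coeffs.c)


def tpg_power_law_ml_per_s(
    q_mls: float,
    ava_cm2: float,
    coeffs: ModelCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """Same model with flow given in ml/s, as measured from LV volumes."""
    return tpg_power_law(ml_per_s_to_l_per_s(q_mls), ava_cm2, coeffs)


def tpg_bernoulli(v_ms: float) -> float:
    """Simplified Bernoulli gradient (mmHg) from peak jet velocity (m/s): 4 v^2."""
    if v_ms < 0:
        raise DomainError(f"velocity must be non-negative, got {v_ms} m/s")
    return 4.0 * v_ms**2


def apply_mi_correction(
    q_mls: float,
    grade: Union[str, MIGrade],
    reduction_fractions: Mapping[MIGrade, float] = MI_REDUCTION_FRACTIONS,
) -> float:
    """Reduce aortic flow (ml/s) for the mitral-insufficiency grade.

    Part of the LV volume change exits backward through an insufficient
    mitral valve, so the flow derived from the volume curve overestimates
    the aortic flow; the correction removes the grade's regurgitation
    fraction (defaults 0/10/30/50 %).
    """
    if q_mls < 0:
        raise DomainError(f"flow rate must be non-negative, got {q_mls} ml/s")
    g = MIGrade.parse(grade)
    fraction = reduction_fractions[g]
    return q_mls * (1.0 - fraction)


def grade_severity(
    tpg_mmhg: float, threshold: float = SEVERITY_THRESHOLD_MMHG
) -> SeverityGrade:
    """Grade a gradient against the maximum-TPG threshold (default 64 mmHg).

    A gradient exactly at the threshold grades as ``above_threshold``: the
    clinical velocity criterion is v >= 4 m/s, and 4*(4)^2 = 64 mmHg lies on
    the severe side.
    """
    if tpg_mmhg < 0:
        raise DomainError(f"pressure gradient must be non-negative, got {tpg_mmhg}")
    if not threshold > 0:
        raise ValidationError(f"threshold must be positive, got {threshold}")
    label = "above_threshold" if tpg_mmhg >= threshold else "below_threshold"
    return SeverityGrade(label=label, threshold=threshold)
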