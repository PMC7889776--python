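"""Formula-based lean-body-mass estimators and BMI arithmetic.

Two predictive LBM formulas are implemented:

* James (height in cm, weight in kg)::

      men:   LBM = 1.10*BW - 128*(BW/H)^2
      women: LBM = 1.07*BW - 148*(BW/H)^2

* Janmahasatian ("Janma"), a BMI-based hyperbolic form::

      men:   LBM = 9270*BW / (6680 + 216*BMI)
      women: LBM = 9270*BW / (8780 + 244*BMI)

The James formula is quadratic in weight at fixed height, so its LBM/weight
fraction falls linearly with BMI and turns *negative*-sloped past a critical
BMI of 10^4*a/(2b) (a, b the sex coefficients): ~42.97 for men, ~36.15 for
women. Above that point heavier patients are assigned *less* lean mass, the
known failure mode motivating BMI-robust alternatives.
"""

from __future__ import annotations

import warnings

from .types import DXARecord, LBMEstimate, SubjectRecord, bmi_from

# (a, b) in LBM = a*BW - b*(BW/H_cm)^2
_JAMES_COEFFS: dict[str, tuple[float, float]] = {"M": (1.10, 128.0), "F": (1.07, 148.0)}
# (num, c0, c1) in LBM = num*BW / (c0 + c1*BMI)
_JANMA_COEFFS: dict[str, tuple[float, float, float]] = {
    "M": (9270.0, 6680.0, 216.0),
    "F": (9270.0, 8780.0, 244.0),
}


def _check_sex(sex: str) -> str:
    if sex not in ("M", "F"):
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    return sex


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index in kg/m^2 from weight (kg) and height (cm)."""
    return bmi_from(weight, height)


def lbm_james(sex: str, weight: float, height: float) -> float:
    """James lean body mass (kg); height in cm.

    A negative result (possible at extreme BMI) is returned unchanged with a
    ``UserWarning`` — clipping would hide the model's documented failure mode.
    """
    _check_sex(sex)
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be > 0")
    a, b = _JAMES_COEFFS[sex]
    lbm = a * weight - b * (weight / height) ** 2
    if lbm < 0:
        warnings.warn(
            f"James LBM is negative ({lbm:.2f} kg) for sex={sex}, "
            f"weight={weight} kg, height={height} cm (BMI beyond the model's "
            f"critical value {james_critical_bmi(sex):.1f})",
            UserWarning,
            stacklevel=2,
        )
    return lbm


def lbm_janma(sex: str, weight: float, bmi: float) -> float:
    """Janmahasatian lean body mass (kg) from weight (kg) and BMI (kg/m^2)."""
    _check_sex(sex)
    if weight <= 0 or bmi <= 0:
        raise ValueError("weight and bmi must be > 0")
    num, c0, c1 = _JANMA_COEFFS[sex]
    return num * weight / (c0 + c1 * bmi)


def james_critical_bmi(sex: str) -> float:
    """BMI at which James LBM, as a function of weight at fixed height, peaks.

    With LBM = a*BW - b*(BW/H)^2 and H in cm, d(LBM)/d(BW) = 0 at
    BW* = a*H^2/(2b), i.e. BMI* = BW*/(H/100)^2 = 10^4*a/(2b) — independent
    of height. ~42.97 for men, ~36.15 for women.
    """
    a, b = _JAMES_COEFFS[_check_sex(sex)]
    return 1.0e4 * a / (2.0 * b)


def dxa_lean_fraction(record: DXARecord, weight: float) -> float:
    """DXA lean fraction in percent: 100 * covered non-fat mass / body weight."""
    if weight <= 0:
        raise ValueError("weight must be > 0")
    return 100.0 * record.nonfat_mass / weight


def lbm_estimate(method: str, subject: SubjectRecord) -> LBMEstimate:
    """Evaluate a formula-based LBM method for a subject as an LBMEstimate."""
    if method == "james":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            lbm = lbm_james(subject.sex, subject.weight, subject.height)
    elif method == "janma":
        lbm = lbm_janma(subject.sex, subject.weight, subject.bmi)
    else:
        raise ValueError(f"formula-based methods are 'james' and 'janma', got {method!r}")
    return LBMEstimate(
        method=method,
        lbm=lbm,
        fraction=100.0 * lbm / subject.weight,
        flagged=lbm < 0,
    )
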