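"""CPD ELISA standard-curve fitting and inverse prediction.

Cyclobutane pyrimidine dimers (CPDs) in extracted DNA are quantified by a
competitive ELISA: absorbances of a CPD-DNA dilution series define a
standard curve, and sample absorbances are inverted through the fitted
curve. The default model is the four-parameter logistic

    y(x) = d + (a - d) / (1 + (x/c)^b)

(a: zero-dose response, d: upper asymptote, c: mid-point EC50, b: slope),
with a straight line as fallback for narrow, locally linear ranges. Sample
concentrations are reported in the units of the kit standard per the fixed
4 µg/mL DNA input; absorbances outside the monotone range are flagged
rather than extrapolated, and sub-blank absorbances are reported as
not detected (concentration 0), the behaviour of true dark controls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "StandardPoint",
    "StandardCurve",
    "CPDMeasurement",
    "fit_standard_curve",
    "invert_standard_curve",
]


@dataclass(frozen=True)
class StandardPoint:
    concentration: float  # kit-standard units
    absorbance: float  # OD

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


@dataclass(frozen=True)
class StandardCurve:
    model: str  # "linear" | "four_parameter_logistic"
    parameters: dict
    residual_sd: float
    r_squared: float
    inversion_range: tuple[float, float]  # absorbance interval with a unique inverse

    def predict(self, concentration) -> np.ndarray:
        x = np.asarray(concentration, float)
        p = self.parameters
        if self.model == "linear":
            return p["intercept"] + p["slope"] * x
        return p["d"] + (p["a"] - p["d"]) / (1.0 + (x / p["c"]) ** p["b"])


@dataclass(frozen=True)
class CPDMeasurement:
    sample_id: str
    absorbance: float
    cpd_concentration: float  # standard units per 4 µg/mL DNA; nan if out of range high
    out_of_range: bool
    not_detected: bool = False


def _4pl(x, a, d, c, b):
    return d + (a - d) / (1.0 + (x / c) ** b)


def fit_standard_curve(
    points: Sequence[StandardPoint], model: str = "four_parameter_logistic"
) -> StandardCurve:
    """Least-squares fit of the standard curve; monotonicity is verified.

    Linear fits need >=2 distinct concentrations, 4PL fits >=4.
    """
    x = np.array([p.concentration for p in points], float)
    y = np.array([p.absorbance for p in points], float)
    n_distinct = len(np.unique(x))
    if model == "linear":
        if n_distinct < 2:
            raise ValueError("linear fit needs >=2 distinct concentrations")
        slope, intercept = np.polyfit(x, y, 1)
        if slope <= 0:
            raise ValueError("fitted standard curve is not increasing")
        params = {"intercept": float(intercept), "slope": float(slope)}
        yhat = intercept + slope * x
        lo, hi = float(y.min()), float(y.max())
        inv_range = (min(lo, float(intercept)), hi)
    elif model == "four_parameter_logistic":
        if n_distinct < 4:
            raise ValueError("4PL fit needs >=4 distinct concentrations")
        xpos = x[x > 0]
        p0 = (float(y.min()), float(y.max()), float(np.median(xpos)), 1.0)
        popt, _ = curve_fit(_4pl, x, y, p0=p0, maxfev=20000)
        a, d, c, b = map(float, popt)
        if not (d > a and b > 0 and c > 0):
            raise ValueError("fitted 4PL is not monotone increasing")
        params = {"a": a, "d": d, "c": c, "b": b}
        yhat = _4pl(x, *popt)
        inv_range = (a, d)  # open interval between the asymptotes
    else:
        raise ValueError(f"unknown model {model!r}")
    resid = y - yhat
    dof = max(len(y) - len(params), 1)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    curve = StandardCurve(
        model=model,
        parameters=params,
        residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        r_squared=r2,
        inversion_range=inv_range,
    )
    return curve


def invert_standard_curve(
    curve: StandardCurve, absorbance: float, sample_id: str = ""
) -> CPDMeasurement:
    """Map a sample absorbance back to a CPD concentration.

    Absorbances at or below the blank response are reported as not detected
    (concentration 0, flagged); absorbances at or above the upper end of the
    monotone range are flagged out-of-range with a NaN concentration — the
    curve is never extrapolated.
    """
    lo, hi = curve.inversion_range
    p = curve.parameters
    if absorbance <= lo:
        return CPDMeasurement(sample_id, absorbance, 0.0, out_of_range=True, not_detected=True)
    if absorbance >= hi:
        return CPDMeasurement(sample_id, absorbance, float("nan"), out_of_range=True)
    if curve.model == "linear":
        xhat = (absorbance - p["intercept"]) / p["slope"]
    else:
        a, d, c, b = p["a"], p["d"], p["c"], p["b"]
        xhat = c * ((a - d) / (absorbance - d) - 1.0) ** (1.0 / b)
    return CPDMeasurement(sample_id, absorbance, float(xhat), out_of_range=False)
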