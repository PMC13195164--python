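"""Fluence-response inactivation kinetics.

Log reductions L = log10(C0/C) are computed per replicate from a survival
curve, a linear model L = kf*F (+ intercept) is fitted per replicate over the
low-fluence range where first-order kinetics hold, and an origin-constrained
quadratic L = a*F^2 + b*F captures tailing over the full fluence range. The
fitted rate constant kf (cm^2/mJ) is inverted into the UV fluence required
for a target log reduction, F = L_target / kf, rounded half-up to one
decimal as in standard fluence-requirement tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Observation",
    "SurvivalCurve",
    "LogReductionSeries",
    "LinearKineticFit",
    "PolyKineticFit",
    "FluenceRequirement",
    "log_reduction",
    "fit_linear_kinetics",
    "fit_polynomial_kinetics",
    "required_fluence",
    "build_fluence_table",
]


@dataclass(frozen=True)
class Observation:
    """One plate-count observation on a survival curve."""

    fluence: float  # mJ/cm^2
    replicate: int
    concentration: float  # CFU/mL; for censored points, the detection limit
    censored: bool = False


@dataclass
class SurvivalCurve:
    """Fluence-indexed viable concentrations for one organism/strain/wavelength."""

    organism: str
    strain: str
    wavelength: int  # nm
    observations: list[Observation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(o.fluence < 0 for o in self.observations):
            raise ValueError("fluences must be non-negative")
        reps = self.replicates()
        for r in reps:
            zero = [o for o in self.observations if o.replicate == r and o.fluence == 0]
            if not zero:
                raise ValueError(f"replicate {r} has no F=0 observation")
            if any(o.concentration <= 0 or o.censored for o in zero):
                raise ValueError(f"replicate {r} has no positive uncensored C0")

    def replicates(self) -> list[int]:
        return sorted({o.replicate for o in self.observations})

    def c0(self, replicate: int) -> float:
        for o in self.observations:
            if o.replicate == replicate and o.fluence == 0 and not o.censored:
                return o.concentration
        raise KeyError(replicate)

    def log_reductions(self, detection_limit: float | None = None) -> "LogReductionSeries":
        """Convert to per-replicate log reductions; censored flags carried over."""
        fl, reps, ls, cens = [], [], [], []
        for o in self.observations:
            c0 = self.c0(o.replicate)
            if o.censored:
                limit = detection_limit if detection_limit is not None else o.concentration
                val, c = log_reduction(c0, 0.0, detection_limit=limit)
            else:
                val, c = log_reduction(c0, o.concentration)
            fl.append(o.fluence)
            reps.append(o.replicate)
            ls.append(val)
            cens.append(c)
        return LogReductionSeries(
            fluences=np.asarray(fl, float),
            replicates=np.asarray(reps, int),
            L=np.asarray(ls, float),
            censored=np.asarray(cens, bool),
        )


@dataclass
class LogReductionSeries:
    """Log10 reductions per fluence and replicate.

    Censored entries hold a lower bound on L (count below detection limit).
    """

    fluences: np.ndarray
    replicates: np.ndarray
    L: np.ndarray
    censored: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.fluences)
        if not (len(self.replicates) == len(self.L) == len(self.censored) == n):
            raise ValueError("field lengths differ")


@dataclass(frozen=True)
class LinearKineticFit:
    """First-order rate constant kf = mean of per-replicate OLS slopes."""

    kf: float  # cm^2/mJ
    kf_sd: float  # sample sd across replicates; nan with a single replicate
    intercept: float  # pooled-fit intercept, log10 units
    r_squared: float  # pooled fit
    fluence_cutoff: float  # mJ/cm^2
    n_replicates: int = 2


@dataclass(frozen=True)
class PolyKineticFit:
    """Origin-constrained quadratic L = a*F^2 + b*F over the full fluence range."""

    a: float  # cm^4/mJ^2
    b: float  # cm^2/mJ
    r_squared: float

    def predict(self, fluence):
        f = np.asarray(fluence, float)
        return self.a * f**2 + self.b * f


@dataclass(frozen=True)
class FluenceRequirement:
    """UV fluence needed for a target log reduction, rounded to one decimal."""

    target_log: float
    required_fluence: float  # mJ/cm^2


def log_reduction(
    C0: float, C: float, detection_limit: float | None = None
) -> tuple[float, bool]:
    """Log10 reduction L = log10(C0/C).

    Zero counts (C = 0) are reported against the plating detection limit as a
    censored lower bound L >= log10(C0/detection_limit).

    Returns
    -------
    (L, censored)
    """
    if C0 <= 0:
        raise ValueError("C0 must be positive")
    if C < 0:
        raise ValueError("C must be non-negative")
    if C == 0:
        if detection_limit is None or detection_limit <= 0:
            raise ValueError("detection_limit required for zero counts")
        return float(np.log10(C0 / detection_limit)), True
    return float(np.log10(C0 / C)), False


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R^2 of an ordinary least-squares line."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), r2


def fit_linear_kinetics(
    series: LogReductionSeries, fluence_cutoff: float = 6.0
) -> LinearKineticFit:
    """Fit first-order kinetics on the low-fluence linear range.

    Censored points are excluded. Each replicate gets its own OLS line (free
    intercept); kf is the mean of the replicate slopes and kf_sd their sample
    standard deviation. R^2 comes from the pooled fit over all retained points.
    """
    if fluence_cutoff <= 0:
        raise ValueError("fluence_cutoff must be positive")
    keep = (~series.censored) & (series.fluences <= fluence_cutoff)
    f, L, rep = series.fluences[keep], series.L[keep], series.replicates[keep]
    if len(np.unique(f)) < 3:
        raise ValueError("need >=3 distinct uncensored fluences within the cutoff")
    slopes = []
    for r in np.unique(rep):
        m = rep == r
        if len(np.unique(f[m])) < 2:
            continue
        slopes.append(_ols(f[m], L[m])[0])
    if not slopes:
        raise ValueError("no replicate with >=2 distinct fluences")
    _, intercept, r2 = _ols(f, L)
    kf = float(np.mean(slopes))
    kf_sd = float(np.std(slopes, ddof=1)) if len(slopes) > 1 else float("nan")
    return LinearKineticFit(
        kf=kf,
        kf_sd=kf_sd,
        intercept=intercept,
        r_squared=r2,
        fluence_cutoff=fluence_cutoff,
        n_replicates=len(slopes),
    )


def fit_polynomial_kinetics(
    series: LogReductionSeries, fluence_max: float = 14.0
) -> PolyKineticFit:
    """Origin-constrained quadratic fit L = a*F^2 + b*F over the tailing range."""
    keep = (~series.censored) & (series.fluences <= fluence_max)
    f, L = series.fluences[keep], series.L[keep]
    if len(np.unique(f)) < 3:
        raise ValueError("need >=3 distinct uncensored fluences")
    X = np.column_stack([f**2, f])
    coef, _, rank, _ = np.linalg.lstsq(X, L, rcond=None)
    if rank < 2:
        raise ValueError("rank-deficient design (degenerate fluences)")
    resid = L - X @ coef
    ss_tot = float(np.sum((L - L.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return PolyKineticFit(a=float(coef[0]), b=float(coef[1]), r_squared=r2)


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def required_fluence(kf: float, target_log: float) -> FluenceRequirement:
    """UV fluence for a target log reduction: F = target / kf, half-up, 1 dp."""
    if kf <= 0:
        raise ValueError("kf must be positive")
    if target_log <= 0:
        raise ValueError("target_log must be positive")
    return FluenceRequirement(
        target_log=target_log, required_fluence=_round_half_up(target_log / kf, 1)
    )


def build_fluence_table(
    fits: Mapping[tuple, LinearKineticFit | float] | pd.DataFrame,
    targets: Sequence[float] = (2, 4, 6),
) -> pd.DataFrame:
    """Required-fluence table, one row per (organism, strain, wavelength).

    ``fits`` maps (organism, strain, wavelength_nm) to a LinearKineticFit or a
    bare kf, or is a DataFrame with columns organism/strain/wavelength_nm/kf.
    """
    if isinstance(fits, pd.DataFrame):
        fits = {
            (r.organism, r.strain, int(r.wavelength_nm)): float(r.kf)
            for r in fits.itertuples()
        }
    if not fits:
        raise ValueError("no fits supplied")
    rows = []
    for (organism, strain, wl), fit in fits.items():
        kf = fit.kf if isinstance(fit, LinearKineticFit) else float(fit)
        row = {"organism": organism, "strain": strain, "wavelength_nm": wl, "kf": kf}
        for t in targets:
            row[f"fluence_{t:g}log"] = required_fluence(kf, t).required_fluence
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(["wavelength_nm", "organism", "strain"])
    return out.reset_index(drop=True)
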