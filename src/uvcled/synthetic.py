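"""Synthetic inputs with the statistical structure the analysis assumes.

Four generators cover the pipeline's input types:

* survival curves — two-population inactivation model
  ``C(F) = C0 * [(1-p) * 10^(-kf*F) + p * 10^(-rho*kf*F)]`` where a shielded
  (e.g. aggregated) fraction ``p`` is inactivated at the reduced rate
  ``rho*kf``, observed through Poisson plate counts with serial dilution and
  a detection limit; this reproduces the log-linear-with-tailing shape of
  measured fluence-response curves,
* reactivation counts — post-UV concentrations multiplied by
  ``10^recovery`` on a configurable incubation schedule,
* microscopy scenes — fields of rod or coccus cells rendered into phase,
  membrane, DNA, SYTO9 and PI channels with ground-truth masks; a
  condensation parameter ``kappa`` in [0, 1] morphs each cell's DNA signal
  from a homogeneous nucleoid (kappa=0) to a single bright sub-cellular
  focus with a dim remainder (kappa=1), so the expected per-cell intensity
  skewness increases monotonically with kappa,
* ELISA standard curves — linear or four-parameter-logistic absorbance
  responses with optional Gaussian noise.

All generators take one explicit integer seed and are bit-reproducible.
Draw orders are documented per function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .imaging import ChannelStack, LabelMask
from .kinetics import Observation, SurvivalCurve
from .reactivation import ReactivationObservation

__all__ = [
    "InactivationModelParams",
    "PlatingProtocol",
    "SceneSpec",
    "SyntheticScene",
    "survival_model",
    "simulate_survival_curve",
    "simulate_reactivation_counts",
    "render_scene",
    "simulate_standard_curve",
    "counts_to_dataframe",
]


@dataclass(frozen=True)
class InactivationModelParams:
    """Two-population UV inactivation model parameters.

    kf_sensitive: first-order fluence rate constant (cm^2/mJ) of the bulk
    population; p: shielded fraction in [0, 1); rho: factor in [0, 1)
    multiplying kf for the shielded subpopulation; C0: initial concentration
    (CFU/mL). p and rho default to placeholder values — the shielded
    fraction of real suspensions has not been measured.
    """

    kf_sensitive: float
    p: float = 1e-6
    rho: float = 0.1
    C0: float = 1e8

    def __post_init__(self) -> None:
        if self.kf_sensitive <= 0:
            raise ValueError("kf_sensitive must be positive")
        if not 0 <= self.p < 1:
            raise ValueError("p must be in [0, 1)")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.C0 <= 0:
            raise ValueError("C0 must be positive")


@dataclass(frozen=True)
class PlatingProtocol:
    """Serial-dilution plate counting protocol.

    dilution_factors are powers of ten (1 = undiluted). Counts above
    ``countable_max`` are treated as too-numerous-to-count and the next
    dilution is used. The detection limit is the concentration equivalent of
    one colony on an undiluted plate.
    """

    dilution_factors: tuple[float, ...] = (1e0, 1e1, 1e2, 1e3, 1e4, 1e5, 1e6, 1e7)
    plated_volume: float = 0.1  # mL
    replicate_plates: int = 2
    countable_max: int = 300

    def __post_init__(self) -> None:
        if self.plated_volume <= 0:
            raise ValueError("plated_volume must be positive")
        if self.replicate_plates < 1:
            raise ValueError("replicate_plates must be >= 1")
        if sorted(self.dilution_factors) != list(self.dilution_factors):
            raise ValueError("dilution_factors must be sorted ascending")

    @property
    def detection_limit(self) -> float:
        """CFU/mL equivalent of 1 colony at the lowest dilution."""
        return min(self.dilution_factors) / self.plated_volume


def survival_model(params: InactivationModelParams, fluence) -> np.ndarray:
    """Expected viable concentration C(F) of the two-population model."""
    f = np.asarray(fluence, float)
    kf = params.kf_sensitive
    return params.C0 * (
        (1 - params.p) * 10.0 ** (-kf * f) + params.p * 10.0 ** (-params.rho * kf * f)
    )


def _observe_concentration(
    C: float, plating: PlatingProtocol, rng: np.random.Generator
) -> tuple[float, bool, float, float]:
    """One Poisson plating observation of a true concentration.

    Draw order: Poisson counts for every dilution (ascending), each with
    ``replicate_plates`` plates. The lowest dilution whose mean count is
    countable (<= countable_max) is reported; if every plate there is empty
    the observation is censored at the detection limit.

    Returns (estimated CFU/mL, censored, mean plate count, dilution factor).
    """
    counts = {
        d: rng.poisson(C * plating.plated_volume / d, size=plating.replicate_plates)
        for d in plating.dilution_factors
    }
    chosen = plating.dilution_factors[-1]
    for d in plating.dilution_factors:
        if counts[d].mean() <= plating.countable_max:
            chosen = d
            break
    mean_count = float(counts[chosen].mean())
    if mean_count == 0.0:
        return plating.detection_limit, True, 0.0, chosen
    return mean_count * chosen / plating.plated_volume, False, mean_count, chosen


def simulate_survival_curve(
    params: InactivationModelParams,
    fluences: Sequence[float],
    plating: PlatingProtocol | None = None,
    seed: int | None = 0,
    noise: bool = True,
    n_replicates: int = 2,
    organism: str = "E. coli",
    strain: str = "environmental",
    wavelength: int = 265,
) -> SurvivalCurve:
    """Simulate a fluence-response survival curve.

    With ``noise=False`` the observed concentrations equal the model exactly
    (no plating). With noise, each (replicate, fluence) cell is observed by
    Poisson serial-dilution plating; draw order is replicate-major, then
    fluence in the given order.
    """
    fluences = list(fluences)
    if not fluences:
        raise ValueError("empty fluence list")
    if sorted(fluences) != fluences or fluences[0] != 0:
        raise ValueError("fluences must be sorted and include 0 first")
    plating = plating or PlatingProtocol()
    rng = np.random.default_rng(seed)
    expected = survival_model(params, fluences)
    obs: list[Observation] = []
    for rep in range(1, n_replicates + 1):
        for f, C in zip(fluences, expected):
            if noise:
                conc, censored, _, _ = _observe_concentration(C, plating, rng)
            else:
                conc, censored = float(C), C < plating.detection_limit
                if censored:
                    conc = plating.detection_limit
            obs.append(Observation(fluence=f, replicate=rep, concentration=conc, censored=censored))
    return SurvivalCurve(organism=organism, strain=strain, wavelength=wavelength, observations=obs)


DEFAULT_RECOVERY_SCHEDULE: Mapping[float, float] = {0.0: 0.0, 2.0: 0.0, 18.0: 1.0}


def simulate_reactivation_counts(
    params: InactivationModelParams,
    recovery_log: float,
    condition: str,
    times: Sequence[float] = (0.0, 2.0, 18.0),
    fluence: float = 14.0,
    plating: PlatingProtocol | None = None,
    schedule: Mapping[float, float] | None = None,
    seed: int | None = 0,
    noise: bool = True,
    n_replicates: int = 2,
    wavelength: int = 265,
) -> tuple[list[ReactivationObservation], float]:
    """Simulate post-UV incubation counts for one light/dark condition.

    The concentration at time t equals the post-UV concentration times
    ``10^(schedule[t] * recovery_log)``; the default schedule applies the
    full recovery at 18 h only (repair saturating late in incubation).
    Draw order: replicate-major, then times in the given order.

    Returns (observations, pre-UV C0) — C0 is needed to express recoveries
    as log reductions.
    """
    if recovery_log < 0:
        raise ValueError("recovery_log must be non-negative")
    if condition not in ("light", "dark"):
        raise ValueError("condition must be 'light' or 'dark'")
    schedule = dict(schedule) if schedule is not None else dict(DEFAULT_RECOVERY_SCHEDULE)
    plating = plating or PlatingProtocol()
    rng = np.random.default_rng(seed)
    C_uv = float(survival_model(params, fluence))
    obs: list[ReactivationObservation] = []
    for rep in range(1, n_replicates + 1):
        for t in times:
            if t not in schedule:
                raise ValueError(f"no schedule entry for time {t} h")
            C = C_uv * 10.0 ** (schedule[t] * recovery_log)
            if noise:
                conc, censored, _, _ = _observe_concentration(C, plating, rng)
            else:
                conc, censored = C, False
            obs.append(
                ReactivationObservation(
                    wavelength=wavelength,
                    condition=condition,
                    time_h=t,
                    concentration=conc,
                    replicate=rep,
                    censored=censored,
                )
            )
    return obs, params.C0


# --------------------------------------------------------------------------
# microscopy scene rendering
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered microscopy field.

    kappa in [0, 1] controls nucleoid condensation: 0 renders a spatially
    homogeneous DNA signal, 1 concentrates the signal into a Gaussian focus
    covering about 10% of the cell area. pi_positive_prob is the per-cell
    probability of the membrane-compromised (PI-positive, SYTO9-quenched)
    state. Default geometry approximates stationary-phase rods imaged at
    100x on an EMCCD (0.1 µm/px).
    """

    image_shape: tuple[int, int] = (512, 512)
    pixel_size: float = 0.1  # µm/px
    n_cells: int = 400
    morphology: str = "rod"  # "rod" | "coccus"
    length_um: float = 2.0  # rod length (tip to tip); ignored for coccus
    width_um: float = 0.8  # rod width / coccus diameter
    kappa: float = 0.0
    pi_positive_prob: float = 0.008
    background_level: float = 10.0
    gaussian_noise_sd: float = 10.0
    shot_noise: bool = True
    seed: int = 0
    min_gap_px: int = 2
    max_attempts_per_cell: int = 200

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0 <= self.kappa <= 1:
            raise ValueError("kappa must be in [0, 1]")
        if not 0 <= self.pi_positive_prob <= 1:
            raise ValueError("pi_positive_prob must be in [0, 1]")
        if self.morphology not in ("rod", "coccus"):
            raise ValueError("morphology must be 'rod' or 'coccus'")


@dataclass
class SyntheticScene:
    """Rendered channels plus ground truth (mask and per-cell table)."""

    channels: dict[str, np.ndarray]
    truth_mask: np.ndarray  # int labels, 0 = background
    truth_table: pd.DataFrame  # label, kappa, pi_state, row, col, theta
    spec: SceneSpec

    def __post_init__(self) -> None:
        mask_labels = set(np.unique(self.truth_mask)) - {0}
        table_labels = set(self.truth_table["label"].tolist())
        if mask_labels != table_labels:
            raise ValueError("truth_mask and truth_table labels differ")

    def to_stack(self, metadata: dict | None = None) -> ChannelStack:
        return ChannelStack(
            channels={k: v.copy() for k, v in self.channels.items()},
            pixel_size=self.spec.pixel_size,
            metadata=metadata or {},
        )

    def truth_label_mask(self) -> LabelMask:
        return LabelMask(self.truth_mask.copy())


# expected photon counts per stain (before background and noise)
_CELL_INTENSITY = {
    "phase_bg": 200.0,
    "phase_cell": 80.0,
    "membrane_rim": 150.0,
    "membrane_interior": 20.0,
    "dna": 150.0,
    "syto9_live": 150.0,
    "syto9_quenched": 15.0,
    "pi_positive": 150.0,
    "pi_negative": 5.0,
}


def _cell_footprint(spec: SceneSpec, theta: float) -> np.ndarray:
    """Boolean footprint of one cell in a local patch (capsule or disk)."""
    w_px = spec.width_um / spec.pixel_size
    r = w_px / 2.0
    if spec.morphology == "coccus":
        half = int(math.ceil(r)) + 1
        yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
        return yy**2 + xx**2 <= r**2
    l_px = spec.length_um / spec.pixel_size
    seg = max(l_px - w_px, 0.0) / 2.0  # half-length of the capsule axis segment
    half = int(math.ceil(seg + r)) + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    # distance from (x, y) to the axis segment along direction theta
    ax, ay = math.cos(theta), math.sin(theta)
    t = np.clip(xx * ax + yy * ay, -seg, seg)
    d2 = (xx - t * ax) ** 2 + (yy - t * ay) ** 2
    return d2 <= r**2


def _place_cells(
    spec: SceneSpec, rng: np.random.Generator
) -> tuple[np.ndarray, pd.DataFrame]:
    """Rejection-sample non-overlapping cells fully inside the frame.

    Draw order per cell attempt: row, col, theta. Raises RuntimeError after
    ``max_attempts_per_cell * n_cells`` total failed attempts.
    """
    shape = spec.image_shape
    labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)  # placed cells dilated by min_gap
    gap = np.ones((2 * spec.min_gap_px + 1,) * 2, dtype=bool)
    rows_out = []
    budget = spec.max_attempts_per_cell * max(spec.n_cells, 1)
    attempts = 0
    for lab in range(1, spec.n_cells + 1):
        placed = False
        while not placed:
            attempts += 1
            if attempts > budget:
                raise RuntimeError(
                    f"cell placement failed after {budget} attempts "
                    f"({lab - 1}/{spec.n_cells} placed); lower n_cells or density"
                )
            r0 = rng.uniform(0, shape[0])
            c0 = rng.uniform(0, shape[1])
            theta = rng.uniform(0, math.pi)
            foot = _cell_footprint(spec, theta)
            half = foot.shape[0] // 2
            ri, ci = int(round(r0)), int(round(c0))
            if (
                ri - half < 1
                or ci - half < 1
                or ri + half + 1 > shape[0] - 1
                or ci + half + 1 > shape[1] - 1
            ):
                continue
            sl = (slice(ri - half, ri + half + 1), slice(ci - half, ci + half + 1))
            if occupied[sl][foot].any():
                continue
            labels[sl][foot] = lab
            occupied[sl] |= ndi.binary_dilation(foot, structure=gap)
            rows_out.append({"label": lab, "row": ri, "col": ci, "theta": theta})
            placed = True
    table = pd.DataFrame(rows_out, columns=["label", "row", "col", "theta"])
    return labels, table


def render_scene(spec: SceneSpec) -> SyntheticScene:
    """Render one multi-channel field with ground truth.

    Draw order: cell placement (row, col, theta per attempt), per-cell
    PI states, per-cell focus positions, then noise channel by channel in
    the order phase, membrane, dna, syto9, pi (Poisson first, then Gaussian).
    """
    rng = np.random.default_rng(spec.seed)
    labels, table = _place_cells(spec, rng)
    shape = spec.image_shape
    n = spec.n_cells

    pi_state = rng.random(n) < spec.pi_positive_prob if n else np.zeros(0, bool)
    table = table.assign(kappa=spec.kappa, pi_state=pi_state)

    I = _CELL_INTENSITY
    bg = spec.background_level
    phase = np.full(shape, I["phase_bg"], float)
    membrane = np.full(shape, bg, float)
    dna = np.full(shape, bg, float)
    syto9 = np.full(shape, bg, float)
    pi_ch = np.full(shape, bg, float)

    cells = labels > 0
    phase[cells] = I["phase_cell"]
    # membrane rim: footprint minus its erosion
    interior = ndi.binary_erosion(cells, structure=np.ones((3, 3), bool))
    membrane[cells] = bg + I["membrane_rim"]
    membrane[interior] = bg + I["membrane_interior"]

    objects = ndi.find_objects(labels)
    for k in range(n):
        lab = k + 1
        sl = objects[lab - 1]
        sel = labels[sl] == lab
        area = int(sel.sum())
        # DNA: homogeneous component plus a Gaussian focus (~10% of the area)
        base = I["dna"]
        patch = np.zeros(sel.shape)
        patch[sel] = base * (1.0 - spec.kappa)
        if spec.kappa > 0 and area > 0:
            rr, cc = np.nonzero(sel)
            j = rng.integers(len(rr))
            fr, fc = rr[j], cc[j]
            # focus tightens with condensation: ~30% of the cell area at
            # kappa->0 down to ~10% at kappa=1, so the expected intensity
            # skewness increases strictly with kappa (skewness is affine-
            # invariant, so the mixture weight alone would not separate
            # kappa levels in the noiseless limit)
            area_fraction = 0.3 - 0.2 * spec.kappa
            sigma2 = area_fraction * area / (4.0 * math.pi)
            amp = area / (2.0 * math.pi * sigma2)  # conserves total signal
            d2 = (np.arange(sel.shape[0])[:, None] - fr) ** 2 + (
                np.arange(sel.shape[1])[None, :] - fc
            ) ** 2
            patch[sel] += base * spec.kappa * amp * np.exp(-d2[sel] / (2.0 * sigma2))
        dna[sl][sel] = bg + patch[sel]
        if pi_state[k]:
            syto9[sl][sel] = bg + I["syto9_quenched"]
            pi_ch[sl][sel] = bg + I["pi_positive"]
        else:
            syto9[sl][sel] = bg + I["syto9_live"]
            pi_ch[sl][sel] = bg + I["pi_negative"]

    channels = {"phase": phase, "membrane": membrane, "dna": dna, "syto9": syto9, "pi": pi_ch}
    for name in ("phase", "membrane", "dna", "syto9", "pi"):
        arr = channels[name]
        if spec.shot_noise:
            arr = rng.poisson(arr).astype(float)
        if spec.gaussian_noise_sd > 0:
            arr = arr + rng.normal(0.0, spec.gaussian_noise_sd, size=arr.shape)
        channels[name] = np.clip(arr, 0.0, None)

    table = table[["label", "kappa", "pi_state", "row", "col", "theta"]]
    return SyntheticScene(channels=channels, truth_mask=labels, truth_table=table, spec=spec)


# --------------------------------------------------------------------------
# ELISA standard curves
# --------------------------------------------------------------------------


def _standard_response(model_params: Mapping, x: np.ndarray) -> np.ndarray:
    model = model_params.get("model", "linear")
    if model == "linear":
        slope = model_params["slope"]
        if slope <= 0:
            raise ValueError("linear standard curve requires positive slope")
        return model_params["intercept"] + slope * x
    if model == "4pl":
        a, d, c, b = (model_params[k] for k in ("a", "d", "c", "b"))
        if not (d > a and b > 0 and c > 0):
            raise ValueError("4PL must be increasing: require d > a, b > 0, c > 0")
        return d + (a - d) / (1.0 + (x / c) ** b)
    raise ValueError(f"unknown model {model!r}")


def simulate_standard_curve(
    model_params: Mapping,
    standard_concentrations: Sequence[float],
    noise_sd: float = 0.0,
    seed: int | None = 0,
    replicates: int = 1,
) -> pd.DataFrame:
    """Simulate ELISA standard absorbances (strictly monotone when noiseless).

    ``model_params`` is ``{"model": "linear", "intercept", "slope"}`` or
    ``{"model": "4pl", "a", "d", "c", "b"}`` with response
    ``y = d + (a - d) / (1 + (x/c)^b)``. Draw order: one Gaussian per
    (replicate, concentration), replicate-major.
    """
    x = np.asarray(standard_concentrations, float)
    if len(x) == 0 or np.any(x <= 0):
        raise ValueError("standard concentrations must be positive")
    if np.any(np.diff(x) <= 0):
        raise ValueError("standard concentrations must be strictly increasing")
    rng = np.random.default_rng(seed)
    rows = []
    y0 = _standard_response(model_params, x)
    for rep in range(1, replicates + 1):
        y = y0 + rng.normal(0.0, noise_sd, size=len(x)) if noise_sd > 0 else y0
        for xi, yi in zip(x, y):
            rows.append({"concentration": xi, "absorbance": float(yi), "replicate": rep})
    return pd.DataFrame(rows)


def counts_to_dataframe(
    curve: SurvivalCurve, condition: str = "", time_h: float = 0.0
) -> pd.DataFrame:
    """Survival curve as the canonical long-format observation table."""
    rows = [
        {
            "organism": curve.organism,
            "strain": curve.strain,
            "wavelength_nm": curve.wavelength,
            "fluence_mJcm2": o.fluence,
            "replicate": o.replicate,
            "condition": condition,
            "time_h": time_h,
            "concentration_cfu_ml": o.concentration,
            "censored": o.censored,
        }
        for o in curve.observations
    ]
    return pd.DataFrame(rows)
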