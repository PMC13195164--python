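"""Readers and writers for the pipeline's on-disk formats.

Count tables use one long-format CSV schema
(organism,strain,wavelength_nm,fluence_mJcm2,replicate,condition,time_h,
count,dilution,plated_volume_mL); concentrations are recovered as
count * dilution / plated_volume, and zero counts are censored at the
row's dilution-specific detection limit. Scenes are written as per-channel
16-bit grayscale TIFFs plus a 16-bit label TIFF and a truth CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .imaging import ChannelStack, LabelMask
from .kinetics import Observation, SurvivalCurve
from .reactivation import ReactivationObservation
from .synthetic import SyntheticScene

COUNTS_COLUMNS = [
    "organism",
    "strain",
    "wavelength_nm",
    "fluence_mJcm2",
    "replicate",
    "condition",
    "time_h",
    "count",
    "dilution",
    "plated_volume_mL",
]

__all__ = [
    "COUNTS_COLUMNS",
    "survival_to_counts_df",
    "write_counts_csv",
    "read_counts_csv",
    "counts_df_to_curves",
    "read_reactivation_csv",
    "write_scene",
    "read_scene_stack",
]


def survival_to_counts_df(
    curve: SurvivalCurve,
    plated_volume: float = 0.1,
    countable_max: float = 300.0,
    condition: str = "",
    time_h: float = 0.0,
) -> pd.DataFrame:
    """Express a survival curve as the raw plate-count CSV schema.

    Each concentration is written at the lowest power-of-ten dilution whose
    count would be countable (<= countable_max); counts stay fractional so
    the conversion round-trips exactly. Censored observations get count 0
    at the dilution implied by their detection limit.
    """
    rows = []
    for o in curve.observations:
        if o.censored:
            count, dilution = 0.0, max(o.concentration * plated_volume, 1.0)
        else:
            raw = o.concentration * plated_volume
            exp = max(0, int(np.ceil(np.log10(raw / countable_max))) if raw > countable_max else 0)
            dilution = 10.0**exp
            count = raw / dilution
        rows.append(
            {
                "organism": curve.organism,
                "strain": curve.strain,
                "wavelength_nm": curve.wavelength,
                "fluence_mJcm2": o.fluence,
                "replicate": o.replicate,
                "condition": condition,
                "time_h": time_h,
                "count": count,
                "dilution": dilution,
                "plated_volume_mL": plated_volume,
            }
        )
    return pd.DataFrame(rows, columns=COUNTS_COLUMNS)


def write_counts_csv(df: pd.DataFrame, path: str | Path) -> None:
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    df[COUNTS_COLUMNS].to_csv(path, index=False)


def read_counts_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def counts_df_to_curves(df: pd.DataFrame) -> dict[tuple, SurvivalCurve]:
    """Group a counts table into SurvivalCurves keyed by (organism, strain, wavelength)."""
    curves: dict[tuple, SurvivalCurve] = {}
    for key, g in df.groupby(["organism", "strain", "wavelength_nm"], sort=True):
        obs = []
        # iterrows, not itertuples: "count" collides with the namedtuple method
        for _, r in g.iterrows():
            censored = r["count"] == 0
            conc = (
                r["dilution"] / r["plated_volume_mL"]
                if censored
                else r["count"] * r["dilution"] / r["plated_volume_mL"]
            )
            obs.append(
                Observation(
                    fluence=float(r["fluence_mJcm2"]),
                    replicate=int(r["replicate"]),
                    concentration=float(conc),
                    censored=bool(censored),
                )
            )
        organism, strain, wl = key
        curves[(organism, strain, int(wl))] = SurvivalCurve(
            organism=organism, strain=strain, wavelength=int(wl), observations=obs
        )
    return curves


def read_reactivation_csv(path: str | Path) -> list[ReactivationObservation]:
    """Load reactivation observations from the counts CSV schema."""
    df = read_counts_csv(path)
    out = []
    for _, r in df.iterrows():
        censored = r["count"] == 0
        conc = (
            r["dilution"] / r["plated_volume_mL"]
            if censored
            else r["count"] * r["dilution"] / r["plated_volume_mL"]
        )
        out.append(
            ReactivationObservation(
                wavelength=int(r["wavelength_nm"]),
                condition=str(r["condition"]),
                time_h=float(r["time_h"]),
                concentration=float(conc),
                replicate=int(r["replicate"]),
                censored=bool(censored),
            )
        )
    return out


def _to_uint16(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(arr), 0, 65535).astype(np.uint16)


def write_scene(scene: SyntheticScene, out_dir: str | Path, prefix: str = "scene") -> dict:
    """Write per-channel 16-bit TIFFs, the label TIFF and the truth CSV.

    Returns a manifest dict (also written as ``<prefix>_manifest.json``)
    mapping channel names to file names.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"channels": {}, "pixel_size_um": scene.spec.pixel_size}
    for name, arr in scene.channels.items():
        fn = f"{prefix}_{name}.tif"
        tifffile.imwrite(out / fn, _to_uint16(arr))
        manifest["channels"][name] = fn
    tifffile.imwrite(out / f"{prefix}_labels.tif", _to_uint16(scene.truth_mask))
    manifest["labels"] = f"{prefix}_labels.tif"
    truth = scene.truth_table.copy()
    truth.to_csv(out / f"{prefix}_truth.csv", index=False)
    manifest["truth"] = f"{prefix}_truth.csv"
    with open(out / f"{prefix}_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_scene_stack(
    manifest_path: str | Path, metadata: dict | None = None
) -> tuple[ChannelStack, LabelMask | None]:
    """Load a stack (and truth labels, if present) from a scene manifest."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    channels = {
        name: tifffile.imread(base / fn).astype(float)
        for name, fn in manifest["channels"].items()
    }
    stack = ChannelStack(
        channels=channels,
        pixel_size=float(manifest.get("pixel_size_um", 1.0)),
        metadata=metadata or {},
    )
    mask = None
    if "labels" in manifest:
        arr = tifffile.imread(base / manifest["labels"])
        mask = LabelMask(arr.astype(np.int32))
    return stack, mask
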