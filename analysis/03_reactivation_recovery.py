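"""Quantify photoreactivation and dark repair from simulated incubation counts.

Emulates the repair assay: exposure to 14 mJ/cm^2 at each wavelength, then
incubation under light or dark with replating at 0/2/18 h. Recovery is
configured to zero everywhere except ~0.5 log dark repair at 260 nm and
~0.46 log photoreactivation at 265 nm, the only recoveries seen in the
assays being emulated. Writes results/recovery.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from uvcled import reactivation, synthetic

OUT = Path("results")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0

CONFIGURED_RECOVERY = {  # (wavelength, condition) -> log10 recovery at 18 h
    (260, "dark"): 0.5,
    (265, "light"): 0.46,
}


def main() -> None:
    OUT.mkdir(exist_ok=True)
    # kf chosen so 14 mJ/cm^2 leaves ~5 log reduction (the level the repair
    # assays start from), i.e. ~10^3 CFU/mL of countable survivors
    params = synthetic.InactivationModelParams(kf_sensitive=0.35, C0=1e8)
    rows = []
    for i, wl in enumerate((255, 260, 265, 270, 280)):
        for j, condition in enumerate(("light", "dark")):
            target = CONFIGURED_RECOVERY.get((wl, condition), 0.0)
            obs, C0 = synthetic.simulate_reactivation_counts(
                params, target, condition, seed=SEED + 10 * i + j, wavelength=wl
            )
            for t in (2.0, 18.0):
                res = reactivation.compute_recovery(obs, C0, t)
                rows.append(
                    {
                        "wavelength_nm": wl,
                        "condition": condition,
                        "time_h": t,
                        "configured_log": target if t == 18.0 else 0.0,
                        "delta_log": round(res.delta_log, 3),
                        "classification": reactivation.classify_repair(res),
                    }
                )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "recovery.csv", index=False)
    print("Recovery (delta log) after incubation, by wavelength and condition:")
    print(df.to_string(index=False))
    configured = df[df.configured_log > 0]
    print("\nConfigured recoveries and their measured classifications:")
    for _, r in configured.iterrows():
        print(
            f"  {r.wavelength_nm} nm {r.condition} @18 h: configured "
            f"{r.configured_log} -> measured {r.delta_log} ({r.classification})"
        )
    print(
        "A 0.5-log recovery sits exactly at the 'substantial' threshold, so "
        "plating noise can tip its label either way; unconfigured conditions "
        "fluctuate around zero within counting error."
    )


if __name__ == "__main__":
    main()
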