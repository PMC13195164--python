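"""Simulate fluence-response experiments and refit the inactivation kinetics.

For each organism/wavelength, survival curves are generated from the
two-population model using the published environmental rate constant as the
generating kf (duplicate biological replicates, Poisson serial-dilution
plate counts, fluences 0-14 mJ/cm^2), then the linear (<= 6 mJ/cm^2) and
origin-constrained quadratic (<= 14 mJ/cm^2) fits are recomputed. Writes
results/survival_counts.csv and results/kinetic_fits.csv and prints the
input-vs-refit comparison.
"""

import sys
from pathlib import Path

import pandas as pd

from uvcled import io, kinetics, published, synthetic

OUT = Path("results")
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(exist_ok=True)
    frames, rows = [], []
    for i, (_, r) in enumerate(published.environmental_kf_table().iterrows()):
        params = synthetic.InactivationModelParams(kf_sensitive=float(r["kf"]))
        curve = synthetic.simulate_survival_curve(
            params,
            [0, 1, 2, 3, 4, 6, 8, 10, 12, 14],
            seed=SEED + i,
            organism=str(r["organism"]),
            strain=str(r["strain"]),
            wavelength=int(r["wavelength_nm"]),
        )
        frames.append(io.survival_to_counts_df(curve))
        series = curve.log_reductions()
        lin = kinetics.fit_linear_kinetics(series)
        poly = kinetics.fit_polynomial_kinetics(series)
        rows.append(
            {
                "organism": r["organism"],
                "wavelength_nm": int(r["wavelength_nm"]),
                "kf_input": r["kf"],
                "kf_refit": round(lin.kf, 3),
                "kf_sd": round(lin.kf_sd, 3),
                "r_squared": round(lin.r_squared, 3),
                "poly_a": round(poly.a, 4),
                "poly_b": round(poly.b, 3),
            }
        )
    io.write_counts_csv(pd.concat(frames, ignore_index=True), OUT / "survival_counts.csv")
    fits = pd.DataFrame(rows)
    fits.to_csv(OUT / "kinetic_fits.csv", index=False)
    print("Refitted rate constants (input kf vs. recovered kf ± sd):")
    print(fits.to_string(index=False))
    worst = (fits.kf_refit - fits.kf_input).abs().div(fits.kf_input).max()
    print(f"\nWorst relative deviation of refitted kf: {100 * worst:.1f}%")
    print(
        "Refitted slopes sit below the generating kf where the shielded "
        "subpopulation's shoulder falls inside the 6 mJ/cm^2 window (fastest "
        "kinetics affected most); noiseless single-population refits are exact."
    )
    print("All quadratic coefficients negative (tailing):", bool((fits.poly_a < 0).all()))


if __name__ == "__main__":
    main()
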