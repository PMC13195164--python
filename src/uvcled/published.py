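"""Published fluence-based inactivation rate constants used as pipeline inputs.

Rate constants kf (cm^2/mJ, slope of the log-reduction vs. fluence line up to
6 mJ/cm^2), their between-replicate standard deviations and the linear-fit R^2
for the environmental *E. coli* and *E. faecium* isolates at the five UV-C LED
wavelengths. These are the printed inputs from which the required-fluence
table (2-log / 4-log / 6-log) is derived.
"""

from __future__ import annotations

import pandas as pd

#: organism, strain, wavelength_nm, kf (cm^2/mJ), kf_sd, r_squared
ENVIRONMENTAL_KF_ROWS = [
    ("E. coli", "environmental", 255, 1.202, 0.065, 0.955),
    ("E. coli", "environmental", 260, 1.120, 0.047, 0.949),
    ("E. coli", "environmental", 265, 1.624, 0.056, 0.926),
    ("E. coli", "environmental", 270, 1.030, 0.024, 0.917),
    ("E. coli", "environmental", 280, 0.959, 0.053, 0.992),
    ("E. faecium", "environmental", 255, 1.019, 0.002, 0.939),
    ("E. faecium", "environmental", 260, 1.126, 0.001, 0.954),
    ("E. faecium", "environmental", 265, 1.136, 0.015, 0.951),
    ("E. faecium", "environmental", 270, 1.111, 0.026, 0.957),
    ("E. faecium", "environmental", 280, 1.109, 0.012, 0.965),
]

#: Reported PI-positive cell fractions (percent, mean over three images) by
#: UV fluence at 265 nm; used as defaults for the scene generator.
PI_POSITIVE_PCT_BY_FLUENCE = {0: 0.8, 14: 2.9, 40: 5.1, 100: 5.5, 200: 5.7}


def environmental_kf_table() -> pd.DataFrame:
    """Return the environmental-strain kf table as a DataFrame."""
    return pd.DataFrame(
        ENVIRONMENTAL_KF_ROWS,
        columns=["organism", "strain", "wavelength_nm", "kf", "kf_sd", "r_squared"],
    )
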