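# uvcled

Analysis pipeline for UV-C LED water disinfection experiments on the
drinking-water indicator bacteria *Escherichia coli* and *Enterococcus
faecium*: fluence-response inactivation kinetics, photoreactivation and
dark-repair quantification, single-cell fluorescence-microscopy metrics of
nucleoid reorganization and membrane integrity, and CPD ELISA calibration.
Every stage is driven by synthetic-data generators with ground truth, so
the whole pipeline is testable end to end without any raw data.

## The science in brief

**Inactivation kinetics.** Viable counts under UV follow first-order
kinetics in fluence: the log reduction `L = log10(C0/C)` grows linearly,
`L = kf · F`, with `F` the UV fluence (mJ/cm²) and `kf` the fluence-based
inactivation rate constant (cm²/mJ). Real curves tail off at high fluence;
the package models this with a two-population mixture in which a shielded
fraction `p` (e.g. aggregated cells) is inactivated at a reduced rate
`ρ·kf`:

```
C(F) = C0 · [(1 − p) · 10^(−kf·F) + p · 10^(−ρ·kf·F)]
```

Linear fits on the low-fluence range (≤ 6 mJ/cm²) give `kf` per replicate
(reported as mean ± sd); an origin-constrained quadratic
`L = a·F² + b·F` captures the tailing over the full range (≤ 14 mJ/cm²,
`a < 0` for concave curves). Inverting `F = L/kf` yields the fluence
required for 2-, 4- and 6-log inactivation.

**Repair.** After exposure, incubation under visible light allows
photolyase-mediated photoreactivation, incubation in the dark allows
light-independent repair. Recovery is `Δlog = L(0 h) − L(t)` and is
classified none (< 0.1 log), limited (≤ 0.5 log) or substantial.

**Single-cell imaging.** Cells are segmented from multi-channel
fluorescence images (classical smoothing → Otsu → watershed); the skewness
`g₁ = m₃/m₂^{3/2}` of each cell's DAPI pixel-intensity distribution
quantifies nucleoid condensation (homogeneous DNA → g₁ ≈ 0; a bright
condensed focus → g₁ > 0). PI-positive (membrane-compromised) cells are
scored from the SYTO9/PI stain pair: positives are PI-bright and
SYTO9-quenched.

**CPD ELISA.** Cyclobutane pyrimidine dimers are quantified by inverting
sample absorbances through a fitted standard curve (four-parameter
logistic by default, linear fallback); sub-blank absorbances are reported
not detected.

## Worked example

Derive the required-fluence table from the environmental-strain rate
constants:

```python
from uvcled import kinetics, published

table = kinetics.build_fluence_table(published.environmental_kf_table())
print(table[table.wavelength_nm == 265].to_string(index=False))
```

```
  organism         strain  wavelength_nm    kf  fluence_2log  fluence_4log  fluence_6log
   E. coli  environmental            265 1.624           1.2           2.5           3.7
E. faecium  environmental            265 1.136           1.8           3.5           5.3
```

At 265 nm — the wavelength closest to the DNA absorption maximum, and the
most effective tested — a 4-log reduction of environmental *E. coli* needs
only 2.5 mJ/cm². Simulate an experiment and recover the rate constant:

```python
from uvcled import kinetics, synthetic

params = synthetic.InactivationModelParams(kf_sensitive=1.624, p=0.0)
curve = synthetic.simulate_survival_curve(params, [0, 1, 2, 3], noise=False)
fit = kinetics.fit_linear_kinetics(curve.log_reductions())
print(f"kf = {fit.kf:.3f} cm²/mJ")   # kf = 1.624 cm²/mJ
```

The numbered scripts under `analysis/` run the full study: `01` simulates
and refits survival curves, `02` builds the fluence-requirement table,
`03` quantifies light/dark recovery, `04` renders microscopy scenes and
computes the skewness and PI-fraction summaries (writing a box plot per
condition), `05` fits and inverts the CPD standard curve. Each writes its
tables under `results/` and prints what it found, e.g. `04` reports mean
per-cell DNA skewness rising from −1.18 (pre-exposure) to 3.77 (post-UV,
condensed nucleoids) and PI-positive fractions increasing with fluence
(0.85 ± 0.14 % at 0 mJ/cm² to 6.65 ± 0.83 % at 200 mJ/cm² in one run).

A `uvcled` console command exposes the same stages
(`simulate`, `fit-kinetics`, `fluence-table`, `reactivation`,
`analyze-images`, `cpd`, `report`) over CSV/TIFF/JSON inputs.

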