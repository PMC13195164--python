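# Methods

## Inactivation model

Survival under UV-C is modelled as a two-population mixture,

    C(F) = C0 · [(1 − p) · 10^(−kf·F) + p · 10^(−ρ·kf·F)],

with `kf` (cm²/mJ) the first-order fluence rate constant of the bulk
population, `p ∈ [0, 1)` a shielded fraction and `ρ ∈ [0, 1)` its rate
reduction factor. This is the simplest mechanism that reproduces the
concave ("tailing") log-survival curves seen when dense suspensions
aggregate: the log reduction follows `L ≈ kf·F` at low fluence and
plateaus at `−log10(p)` when `ρ = 0`. The shielded fraction of real
suspensions has not been measured; the defaults `p = 1e−6`, `ρ = 0.1` are
placeholders chosen so that tailing appears near the 6-log level, and both
closed forms (single-exponential limit at `p = 0`, plateau law) are
asserted in the tests.

Plate counts are Poisson with expectation `C · V / d` for plated volume
`V` (default 0.1 mL, duplicate plates) and ten-fold dilution factor `d`;
the lowest dilution with a mean count ≤ 300 is scored (too-numerous-to-
count practice) and all-zero plates are censored at the detection limit
(one colony on an undiluted plate). Censored points are excluded from
fits, never substituted.

## Kinetic fits

- Linear range (default cutoff 6 mJ/cm²): ordinary least squares with a
  free intercept per replicate; `kf` is the mean of replicate slopes,
  `kf_sd` their sample standard deviation, and R² comes from the pooled
  fit. The free intercept absorbs small early-dose shoulders; the
  required-fluence inversion uses `L/kf` alone, which reproduces every
  published environmental required-fluence value from the published rate
  constants.
- Full range (default 14 mJ/cm²): `L = a·F² + b·F`, constrained through
  the origin because `L(0) = 0` by definition; `a < 0` diagnoses tailing.
- Required fluences are rounded half-up to one decimal, matching the
  convention of published requirement tables.

Noiseless single-population refits recover `kf` to machine precision;
under Poisson plating at `C0 = 1e8` CFU/mL the mean relative bias over 100
seeds is far below 5%. When the generating model includes the shielded
subpopulation, refitted slopes fall below the generating `kf` for the
fastest kinetics (the shoulder enters the fitted window) — visible in
`analysis/01`, and expected rather than a defect.

## Reactivation

Recovery is `Δlog = L(0 h) − L(t)` with `L` computed against the pre-UV
concentration; replicate concentrations are averaged before logs, and
negative values (continued decay) are reported. Classification: `none`
below 0.1 log (the floor absorbs duplicate-plate counting noise at
10²–10⁸ CFU/mL), `limited` up to the threshold, `substantial` strictly
above it. The threshold defaults to 0.5 log because recoveries of about
half a log are, in the assays emulated here, still described as limited —
hence `substantial` requires exceeding 0.5, not reaching it. A configured
recovery of exactly 0.5 log therefore sits on the boundary and plating
noise can tip its label either way (shown honestly by `analysis/03`).
The generator applies the configured recovery on a schedule over the
sampled times {0, 2, 18} h; the default applies it fully at 18 h only.

## Scene rendering

Scenes emulate widefield EMCCD fluorescence imaging of stained bacteria at
0.1 µm/px: rods are capsules (default 2.0 × 0.8 µm) and cocci disks,
placed by rejection sampling with a 2-px gap, fully inside the frame
(bounded attempts; failure raises). Channels: phase (dark cells on bright
background), membrane (bright rim, as with FM4-64), DNA (DAPI), SYTO9 and
PI. Expected intensities are treated as photon counts; Poisson shot noise
plus additive Gaussian read noise (sd 10) over a background of 10 gives
SNR ≈ 10 on a cell signal of 150.

The condensation parameter `κ ∈ [0, 1]` splits each cell's DNA signal into
a homogeneous component with weight `1 − κ` and a Gaussian focus with
weight `κ` at a random position inside the cell (total signal conserved).
Because skewness is affine-invariant, mixture weight alone cannot separate
κ levels in the noiseless limit, so the focus also tightens with κ — from
~30% of the cell area as κ → 0 to ~10% at κ = 1 — making the expected
per-cell skewness strictly increasing in κ. PI-positive cells (Bernoulli
with probability `pi_positive_prob`) are rendered PI-bright with quenched
SYTO9, emulating the stain flip of membrane-compromised cells; the default
per-fluence probabilities are the measured fractions (0.8% at 0 mJ/cm² up
to 5.7% at 200 mJ/cm²).

What the generator does **not** emulate: optical PSF blur, 3-D structure,
aggregates/biofilms, cell-to-cell brightness variation, uneven
illumination, filamentation. Passing tests therefore demonstrate that the
measurement pipeline is correct on images with known truth, not that the
segmentation would meet the same accuracy on real micrographs.

## Image analysis

Segmentation is classical: Gaussian smoothing (σ = 1 px) → Otsu threshold
→ hole filling (a stained rim becomes a solid cell) → distance-transform
watershed (markers from smoothed-distance peaks, min separation 10 px) →
area filter (min 30 px) → border-object removal. It substitutes for the
deep-learning tool typically used for this task so that no trained weights
need to be bundled and accuracy is checkable against rendered ground truth
(recall/precision ≥ 0.9, mean IoU ≥ 0.7 at default density). Externally
produced label masks can be imported instead (integer TIFF, relabelled
contiguous, connectivity validated).

Skewness is the population-moment `g₁ = m₃ / m₂^{3/2}` over all pixels of
the whole-cell mask, on raw intensities (background subtraction is left to
configuration); zero-variance cells return 0 with a flag rather than NaN.
Note that segmentation masks slightly overhang the true cell boundary, so
dim rim pixels give homogeneous-nucleoid cells a small negative skew
(≈ −1.2 at κ = 0 in the analysis runs); the κ-monotonicity of the pipeline
is unaffected.

PI classification: a cell is positive when its PI-channel mean exceeds
max(Otsu over per-cell PI means, configurable absolute floor) **and** its
PI mean, normalized by the channel's image-wide maximum, exceeds its
normalized SYTO9 mean. The dominance clause makes all-negative fields
robust (Otsu on a unimodal distribution otherwise splits noise).
Summaries report the PI fraction in percent per image and mean ± sample sd
across ≥ 2 images per condition.

## ELISA

The standard curve defaults to the four-parameter logistic
`y = d + (a − d)/(1 + (x/c)^b)` (increasing: `d > a`, `b > 0`), fitted by
nonlinear least squares with data-driven starting values; a linear model
is available for narrow ranges. Inversion uses the closed-form inverse on
the monotone range only: absorbances at/above the upper asymptote are
flagged out-of-range (never extrapolated), absorbances at/below the blank
response are reported not detected with concentration 0 — the behaviour
expected of dark controls. Outputs stay in the kit-standard's units per
the fixed 4 µg/mL DNA input; no unit conversion is invented.

## Problem sizes and determinism

Analysis and acceptance runs use 3 images × ~250–400 cells per condition
at 512 × 512 px, 100 seeds for bias estimates and 8-point fluence grids —
sizes at which the stochastic checks are stable while a full run completes
in well under a minute. Every stochastic operation takes one explicit
integer seed (`numpy.random.default_rng`) and documents its draw order;
identical seeds give bit-identical outputs.

## Known limitations

- The shielded-fraction parameters (`p`, `ρ`) are unmeasured placeholders;
  only the qualitative tailing behaviour is meaningful.
- Per-cell condensation is uniform within a scene (`κ` is a scene-level
  control, recorded per cell in the truth table).
- The PI rule's thresholds are data-driven per image; absolute-intensity
  calibration across instruments is out of scope.
- Required-fluence inversion assumes strict first-order kinetics; it is
  meaningful only within the fluence range used for the linear fit.
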