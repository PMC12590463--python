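# Methods

This note documents the models, defaults and numerical choices behind
`pifir`, and what the synthetic world does and does not establish.

## Spectral model

Component spectra are sums of pseudo-Voigt bands
`a·[(1−m)·G(ν; c, w) + m·L(ν; c, w)]` with shared FWHM `w` for the Gaussian
and Lorentzian parts and mixing `m`.  Default band table (centers in cm⁻¹ /
FWHM / amplitude):

| component        | bands                                              | mix |
|------------------|----------------------------------------------------|-----|
| glycan           | 1060/80/1.0, 1107/30/0.25, 1220/40/0.2            | 0.3 |
| amide, unbound   | 1653/17/0.9, 1540/12/0.7, 1510/12/0.25            | 0.0 |
| amide, H-bonded  | 1624/22/0.9, 1560/11/0.5, 1528/9/0.4              | 0.0 |
| membrane lipid   | 1740/25/0.3                                        | 0.0 |
| contaminant      | copy of glycan (streak artifact)                   | 0.3 |

Band *positions* are the experimentally printed values.  Widths and
amplitudes are generator defaults (the literature gives positions, not
shapes) chosen under one self-consistency rule, fixed before any test was
written: a position the generator plants must be recoverable to the 1 cm⁻¹
reporting grid by ideal analysis.  Broad Lorentzian wings of neighbouring
bands (1624 next to 1653; 1528 next to 1540) otherwise displace the
recoverable extrema by 1–2 cm⁻¹, which the measured spectra evidently do not
suffer — their amide II features are sharp.  Hence the narrow, Gaussian
amide bands, with the bound amide I kept broader (22) than the unbound (17)
one.  All of it is overridable via `BandSpec`/`build_component_spectrum`.

The hydrogen-bond shift knobs `amideI_shift` / `amideII_shift` replace the
bound amide I (or the bound amide II pair) by a single band at
`1653 − shift` (or `1540 + shift`) with the *unbound* width and amplitude,
so shift-recovery experiments compare like with like.

## Composition model and stated world

Each on-cell pixel carries a protein fraction `p` and a bound fraction `β`
of that protein: `f_amide = p(1−β)`, `f_bound = pβ`, `f_glycan = 0.85 − p`,
`f_lipid = 0.05` (total absorbing fraction 0.90; the rest is substrate).
Region statistics (mean ± sd, clipped):

| region           | p           | β           | sampling weight |
|------------------|-------------|-------------|-----------------|
| intact / control | 0.18 ± 0.04 | 0.12 / 0.00 | 16 / 13 of 64   |
| damage patch     | 0.62 ± 0.08 | 0.35 ± 0.06 | 15              |
| bound piecrust   | 0.48 ± 0.08 | 0.88 ± 0.05 | 20              |

The default point-spectra experiment draws 51 treated and 13 control
spectra, stratified 20:15:16 over bound/damage/intact regions.  The two
latent axes (`p`: glycan↔protein; `β`: unbound↔bound) were decoupled
deliberately — damage and bound regions share similar `p` — so that the
ensemble reproduces the qualitative covariance structure of the measured
system: PC1 is the glycan-vs-amide axis (all controls negative), PC2 the
hydrogen-bond substitution contrast, and the treated-minus-control
difference spectrum is dominated by the 1624 cm⁻¹ bound band with only a
slight unbound amide increase.  Configurations in which the bound stratum is
simultaneously the most protein-rich collapse both contrasts onto PC1 and
do not reproduce the reported loading structure; this is a property of the
system, not a tuning artifact, and is documented here because a user
building custom scenes will meet it.

## Optics, noise and artifacts

* **Anisotropy**: `A = clamp(1 − a·ĝ, [0.2, 1.8])` with `ĝ` the directional
  derivative of the height along the illumination azimuth, normalized by
  its scene maximum; defaults `a = 0.5`, azimuth 30°.  The literature
  demonstrates the effect but does not quantify it; the linear gradient
  model is the simplest form reproducing front-dark/back-bright shading and
  exact frequency independence (`A` multiplies every wavenumber equally, so
  two-frequency ratios cancel it to machine precision).
* **Noise**: per-pixel/per-bin multiplicative log-normal `exp(N(0, 0.05))`
  plus additive `N(0, 0.02·mean signal)` — generic detector models; the
  real noise spectrum is not published.
* **Power envelope**: point spectra are multiplied by a smooth synthetic
  QCL power curve (`0.25 + 0.75·exp(−((ν−1350)/320)²/2)`), which the
  preprocessing divides out again using the attached reference; it never
  falls below the 5 % clip threshold on the default axis, so trimming is
  exercised by dedicated fixtures instead.
* **Artifacts** (all off by default, applied drift → streaks → overshoot →
  fixed-f1): per-row gain `exp(N(0, σ))`; contaminant streaks on every
  k-th row; additive overshoot proportional to the positive fast-scan
  height derivative; multiplicative `1 + b·h/h_max` emulating
  topography-correlated detection-frequency modulation.  The physics behind
  the last one (resonance tracking) is out of scope; only its signature is
  modelled.

Topography: ellipsoidal capsule (default 300 nm tall), optional
circumferential fibril ripple (period 2× the 6–9 nm filament width),
transverse septum with cos² depression and raised piecrust rims, Gaussian
damage depressions.  Scan geometry: rows = slow scan, columns = fast scan,
origin top-left, azimuth counterclockwise from +columns.

## Preprocessing choices

"2-11-11" smoothing is read as order 2, window 11, **two passes**; the
single-pass reading is `sg_passes=1`.  The constant background is the mean
of the lowest-decile intensities (robust to band coverage).  Clipped
calibration bins are trimmed to the longest contiguous valid run, not
interpolated — mirroring the practice of restricting hyperspectra to one
QCL chip range.  Smoothing precedes normalization by default
(`smooth_before_normalize`).  Drift correction uses medians for robustness
against overshoot spikes and preserves within-row ratios exactly.

## Chemometrics choices

PCA is mean-centered only; spectra are already L2-normalized and variance
scaling would inflate noise bins.  Signs are fixed by orienting every
loading against the treated-minus-control difference spectrum (largest
|element| positive as the label-free fallback); the PC1-score tie at
exactly 0 falls to the glycan subgroup, since positive scores define the
amide group.  Combined multi-cube PCA concatenates pixel rows with no
per-cube re-centering, giving one loading set and per-cube score maps.
Default k = 5 retained components.

## Feature extraction choices

Extrema use topographic prominence with a default floor of 5 % of the
window's maximum absolute value, and 3-point parabolic sub-bin refinement
(adequate at 1 cm⁻¹ sampling; unbiased to < 0.5 cm⁻¹ over ±30 cm⁻¹ planted
shifts).  The peak-pair shift estimator is preferred; the windowed
cross-correlation alternative carries a small truncation bias (≤ 0.5 cm⁻¹
in tests).  The interaction score is the simplest scale-invariant statistic
implementing "1624 enhanced relative to 1655 and 1540"; reference weights,
halfwidth (± 2 cm⁻¹) and threshold (0.15) are configuration keys, and
ε = 10⁻³·max(cube) guards substrate pixels (score → −1).

Registration is translation-only at integer pixels by exhaustive normalized
cross-correlation on mean-subtracted height maps (subsequent scans of one
position differ mainly by drift); the peak Pearson correlation is reported
and anything below 0.2 fails loudly rather than guessing.

## What a green test establishes — and what it does not

The generator reproduces the *statistical and spectral structure* the
analysis assumes: mixture linearity, frequency-independent anisotropy,
band positions/shifts, subgroup covariance structure, artifact signatures.
It does not model electromagnetic tip–sample coupling, AFM dynamics, tip
convolution, drying effects or real biological heterogeneity; absolute
amplitudes are plausible rather than measured.  Passing tests therefore
establish that the *pipeline* recovers what was planted under realistic
noise — not that the instrument physics is simulated.

Two empirical notes from the validation runs: the anisotropy-cancellation
bounds (hue–A |corr| < 0.1 with single-frequency intensity–A |corr| > 0.5)
hold on the homogeneous untreated-cell scene, where shading dominates the
raw contrast; on the strongly heterogeneous treated scene composition
variance dilutes both correlations, so the exact per-pixel ratio
cancellation (10⁻¹⁰) is asserted there instead.  The PC1-sign subgroup
split assigns > 80 % of bound/damage positions to the amide class at the
fixed validation seed; across arbitrary seeds that fraction fluctuates
around ~0.8 because the bound stratum deliberately sits near the PC1
boundary (see the composition table).

## Known limitations

Integer-pixel registration only; no rotation or non-rigid alignment.  No
baseline-curvature correction (the measured spectra need only a constant
background).  No spectral unmixing or abundance estimation.  Proprietary
instrument file formats are not read; I/O covers delimited spectra tables,
float TIFF scans and HDF5 / TIFF-directory cubes.
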