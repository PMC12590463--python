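# pifir

Analysis toolkit for **PiF-IR** — mid-infrared photoinduced-force microscopy —
imaging of bacterial cell surfaces, built around the study of vancomycin
binding to the *Bacillus subtilis* cell wall.

PiF-IR records the photoinduced tip–sample force under pulsed, tunable
mid-IR illumination and reaches ~5 nm chemical resolution.  Its data come in
three shapes: point spectra S(ν) on selected positions, single-frequency scan
maps, and hyperspectral cubes (x, y, ν).  This package implements the full
analysis chain for all three, plus a synthetic-scene generator that emulates
the measurement — cell topography, illumination-direction anisotropy,
component-mixture spectra, detector noise and the characteristic scan
artifacts — so every stage is testable against known ground truth without
instrument data.

## The science in brief

* **Anisotropy compensation.** On a curved cell the illumination direction
  modulates PiF intensity (front dark, back bright) *independently of
  wavenumber*.  Merging two single-frequency scans into one RGB image —
  glycan band ν = 1060 cm⁻¹ into R+B (pink), amide band ν = 1520 cm⁻¹ into G
  (green) — cancels the modulation: hue encodes relative absorption.
* **Preprocessing.** Spectra are calibrated against the QCL power spectrum
  (bins below 5 % of its peak are clipped), the constant background is
  removed, a Savitzky–Golay filter (order 2, window 11, two passes) smooths,
  and an L2 vector normalization makes spectra comparable.
  Scan maps get a line-by-line (slow-scan) median drift correction.
* **Chemometrics.** Mean-centered PCA over all spectra.  PC1 shows the
  anticorrelated variation of the amide bands (~1653 / 1540 cm⁻¹) versus the
  broad glycan band (~1060 cm⁻¹); untreated-control spectra sit at negative
  PC1 scores and treated spectra split into an "amide" (PC1 > 0) and a
  "glycan" subgroup.  PC2 carries the hydrogen-bond substitution signature:
  a sharp dip at 1653 cm⁻¹ next to a broader peak at 1624 cm⁻¹ (amide I
  red-shifts ~20 cm⁻¹ on H-bond formation) and peaks at 1560/1528 cm⁻¹ with
  dips at 1540/1510 cm⁻¹ (amide II blue-shifts ~10 cm⁻¹).
* **Localization.** In hyperspectral cubes, three narrow bands
  (1655 ± 2 → blue, 1624 ± 2 → red, 1540 ± 2 → green) render bound regions
  reddish; the scale-invariant interaction score
  `I₁₆₂₄ / (½(I₁₆₅₅ + I₁₅₄₀) + ε) − 1` thresholded at 0.15 yields a binding
  mask that is scored against ground truth (precision / recall / IoU).

## Worked example

```python
from pifir.scene import make_cell_scene, sample_point_spectra
from pifir.preprocess import preprocess_spectra
from pifir.chemometrics import (assemble_matrix, fit_pca, orient_loadings,
                                smooth_components, treated_minus_control)
from pifir.features import find_extrema
from pifir.spectra import Spectrum

spectra, _ = sample_point_spectra(make_cell_scene("treated", seed=1),
                                  make_cell_scene("control", seed=2), seed=3)
matrix = assemble_matrix(spectra=preprocess_spectra(spectra))
diff = treated_minus_control(matrix)
model = smooth_components(orient_loadings(fit_pca(matrix, 5), diff))
peak = find_extrema(Spectrum(matrix.axis, diff.values), (1600, 1680)).best("peak")
print(round(peak["position"], 1))
pc2 = Spectrum(model.axis, model.loading(2))
print(round(find_extrema(pc2, (1600, 1680)).best("dip")["position"], 1))
```

prints

```
1623.9
1653.1
```

— the treated-minus-control difference spectrum peaks at the bound amide I
band (1624 cm⁻¹), and PC2 dips at the unbound amide I position (1653 cm⁻¹):
the hydrogen-bond signature recovered from 64 synthetic spectra.  The
`examples/` directory holds one short narrative script per capability
(scene building, preprocessing, merges, PCA, shift recovery, localization,
full pipeline); each prints the numbers it computes and what they mean.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default synthetic world at the given master seed, runs the
complete chain from scratch (simulate → preprocess → difference spectrum /
PCA → extrema; plus the two shift-recovery experiments) and writes the six
recovered band-signature quantities — difference-spectrum peak position, the
three PC2 extremum positions, and the two hydrogen-bond shift magnitudes —
as JSON, each rounded to the 1 cm⁻¹ reporting grid.
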