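# nirhsi

Shipboard near-infrared hyperspectral imaging (NIR-HSI) analysis of
net-collected marine microplastics: particle segmentation, sizing, polymer
classification, and survey statistics, with a fully ground-truthed
synthetic-data generator so every stage is testable without instrument data.

## The problem

Surface-net tows in the open ocean collect floating particles — mostly
weathered fragments of the buoyant commodity polymers polyethylene (PE),
polypropylene (PP), and polystyrene (PS), mixed with natural material
(pumice, carapace, wood, algae). Identifying each particle's polymer by
FTIR or Raman microscopy is slow and often defeated by fluorescence. A
benchtop NIR line-scan camera (900–1700 nm, 224 bands, 640 samples per
line) images a whole mounting bed in minutes, and the reflectance spectra
carry narrow polymer-diagnostic features — a PE peak near 1540 nm, PP
troughs near 1196 and 1215 nm — that broad-sloped natural spectra lack.

`nirhsi` implements that measurement chain:

1. **Reflectance calibration** — raw counts `I` with white/dark references
   `W`, `D`: `R = (I − D) / (W − D)` per sample column and band, clipped to
   `[0, 1.5]`; minimal ENVI (header + binary) I/O in BIL/BIP/BSQ.
2. **Segmentation** — flatten the cube to the per-pixel mean spectrum,
   detect the 10-mm scale bar (sets mm/pixel), then Sobel-gradient
   watershed seeded from an Otsu split of the flat image.
3. **Morphometry** — particle length and width as caliper extents along the
   SVD principal axes of the pixel cloud; area and sub-pixel contour
   perimeter, all in millimetres.
4. **Classification** — each particle's pooled, mean-normalised spectrum is
   encoded as a binary vector of prescribed peak/trough presences and
   scored by a 100-tree random forest. The vote fraction `P_rf` per class
   is a certainty score; per-class cutoffs are chosen on tenfold
   cross-validated ROC curves to maximise the true positive rate while the
   estimated false positive rate stays ≤ 5%. Particles clearing no cutoff
   are reported `other`.
5. **Survey statistics** — tow concentrations (particles/m³ from flowmeter
   volumes, clogged tows excluded from ranges), polymer proportions, and
   size spectra: lengths binned into nine log-spaced classes over
   0.3–40 mm, counts normalised by bin width (`n/Δl`), and for lengths
   ≥ 2 mm the power-law exponent α of `n/Δl ∝ l^(−α)` fitted by log–log
   least squares (a truncated-distribution MLE is included as a
   cross-check).

## Worked example

Render a synthetic scan of five particles of known material, train on a
synthetic reference library, and process the scan end to end:

```python
from nirhsi.synth import (SceneSpec, ParticleSpec, BarSpec,
                          synth_cube, make_reference_library)
from nirhsi.classify import evaluate_library, train_forest, ThresholdPolicy
from nirhsi.pipeline import process_cube

particles = tuple(
    ParticleSpec("disk", (12,), (60 + 20 * (i % 2), 80 + 110 * i), m)
    for i, m in enumerate(["HDPE", "PP", "PS", "pumice", "LDPE"])
)
scene = SceneSpec(shape=(200, 640), particles=particles,
                  bar=BarSpec(length_px=500), noise_sd=0.005, seed=3)
cube, truth_labels, truth = synth_cube(scene)

library = make_reference_library(seed=1)
X, y = library.feature_matrix()
_, report = evaluate_library(X, y, k=10, seed=0, target_fpr=0.05)
model = train_forest(X, y, seed=0)
policy = ThresholdPolicy({c: report[c]["threshold"] for c in ("PE", "PP", "PS")})

frame, scale, _ = process_cube(cube, model, policy)
print("mm/pixel:", scale.mm_per_pixel)
print(frame[["id", "length_mm", "width_mm", "area_mm2", "class", "p_rf_PE"]]
      .round(3).to_string(index=False))
```

which prints

```
mm/pixel: 0.02
 id  length_mm  width_mm  area_mm2 class  p_rf_PE
  1        0.5       0.5     0.176    PE      1.0
  2        0.5       0.5     0.176    PS      0.0
  3        0.5       0.5     0.176    PE      1.0
  4        0.5       0.5     0.176    PP      0.0
  5        0.5       0.5     0.176 other      0.0
```

The 500-px bar maps to 0.02 mm/pixel, each 12-px-radius disk measures
0.5 mm, and every class call matches the planted material (HDPE/LDPE
collapse to PE; pumice is non-polymer, hence `other`). On this library the
cross-validated AUC is 1.0 for all classes.

Fitting a size spectrum to 20 000 lengths drawn from a truncated `l^-3.41`
law on [2, 40] mm:

```python
from nirhsi.synth import sample_power_law
from nirhsi.survey import bin_size_distribution, fit_power_law

lengths = sample_power_law(3.41, 2.0, 40.0, 20_000, rng=0)
print(fit_power_law(bin_size_distribution(lengths)).summary())
```

```
Power-law size spectrum fit (n/dl ~ l^-alpha)
  alpha     : 3.425 +/- 0.072 (OLS slope se)
  fit range : 2.64 - 40 mm (5 bins)
  R^2       : 0.9987
```

The generating exponent is recovered within one standard error.

The same workflow is available from the shell: `nirhsi simulate`,
`nirhsi process`, `nirhsi evaluate`, and `nirhsi survey` (see `--help`).
The package also ships the cruise tow table (27 North Atlantic gyre tows)
used by `nirhsi survey` when no tow CSV is given.

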