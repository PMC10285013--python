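# Methods

This note records the models, defaults, and design choices behind each
stage of the pipeline, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing its
output. No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Sensor model and reflectance calibration

The cube container assumes a push-broom line scanner: `(lines, samples,
bands)` with the band axis last, 0-based `(line, sample)` coordinates, and
a default wavelength grid of 224 evenly spaced centres on [900, 1700] nm.
Pixel pitch is never hard-coded: the nominal optics of such cameras do not
pin it down reliably, so physical scale always comes from the 10-mm
reference bar imaged in each scan (or an explicit `mm_per_pixel`
override).

Reflectance uses the standard flat-field correction `R = (I − D)/(W − D)`
with per-sample-column white/dark frames `(S × B)`; a single reference
spectrum `(B,)` broadcasts across columns. Elements with `W ≤ D` cannot be
calibrated; they are set to 0 and counted in a warning rather than
aborting a scan. `R` is clipped to `[0, clip_max]` with `clip_max = 1.5`
to bound specular glints. The correction is invariant under a common
positive gain on `I`, `W`, `D`.

ENVI serialisation covers exactly what the workflow needs: ASCII
`key = value` headers, BIL/BIP/BSQ interleaves (BIL written by default, as
line-scan native), uint16 raw counts and float32 reflectance, little
endian. Round-trips are bit-exact and tested for all three interleaves.

## Segmentation

Watershed operates on one channel, so the cube is flattened to the
per-pixel mean spectrum. The flooding surface is the Sobel gradient
magnitude (3×3 horizontal/vertical difference kernels). Markers come from
an Otsu two-class split of the flat image with a safety margin: pixels
below `t − m_lo` seed the background (one marker), pixels above `t + m_hi`
seed the foreground (one marker per connected component), where each
margin is 10% of the distance from the threshold to the corresponding
class mean. The per-side formulation matters: when the intensity histogram
has an empty gap, Otsu's threshold can sit at the very edge of the
background mode, and a margin measured from the full class-mean gap would
leave one side without seeds.

Two further numerical guards:

- *Blank images.* Otsu always returns a threshold, even on pure noise. We
  compute Otsu's effectiveness statistic η (between-class variance over
  total variance): splitting unimodal sensor noise tops out near 0.64
  while genuinely bimodal scenes score above 0.9, so η < 0.8 is treated as
  "no foreground" and yields zero regions.
- *Scale-bar detection* binarises at the midpoint of the two Otsu class
  means rather than at the raw threshold, so single noisy background
  pixels cannot attach to the bar and inflate its bounding box.

The bar is the unique bright region touching the configured image edge
(default bottom) with bounding-box aspect ratio ≥ 5; zero candidates raise
a calibration-missing error and several raise an ambiguity error listing
the candidates. `mm_per_pixel = 10 mm / bar extent` along the long axis.

Regions below `min_area_px = 20` pixels are discarded (speckle
suppression; adjust with pixel pitch). Connectivity is 8-neighbour.
Surviving regions are renumbered in raster order of their first pixel so
label ids are deterministic. Particles whose edges touch merge into one
region — an accepted limitation of single-channel segmentation; splitting
them (e.g. full-spectrum segmentation) is out of scope. A
`invert_contrast` flag handles particles darker than the mounting
background; the default assumes the matte black bed is darker than any
particle. Segmentation is invariant to adding a constant to the image.

## Morphometry

Length and width are caliper extents: centre the region's pixel
coordinates, take the two right singular vectors of the coordinate matrix
as principal directions, and measure `(max − min projection) + 1` pixel
along each, ordering so length ≥ width. The `+1 px` pixel-centre
convention makes a single pixel one pixel long and an axis-aligned N-pixel
row exactly N pixels. Extent (not a singular-value multiple) was chosen
because the measured quantity is a caliper length across the particle;
for rasterised rectangles at arbitrary angles the recovered sides are
within one pixel of truth (exactly 45° can alias the short axis by
slightly more than a pixel — a property of the pixel lattice, not of the
estimator).

Area is `pixel count × (mm/px)²`. Perimeter is the length of the 0.5-level
marching-squares contour after a light Gaussian anti-aliasing of the mask
(σ = 1 px): on a raw binary mask the contour is a staircase that
overestimates smooth boundaries by 6–9%, while the anti-aliased contour
tracks a rasterised circle to within ~0.5% (tested against 2πr).

## Spectral features and encoding

Per-particle spectra are band-wise means over the region's pixels, then
divided by their spectral mean ("normalised to the average reflectance"),
making everything downstream invariant to illumination gain. Extrema are
local maxima/minima with topographic prominence ≥ `prominence_min = 0.01`
(normalised units), endpoints excluded; troughs are peaks of the negated
spectrum. Before peak picking, a quadratic Savitzky–Golay filter over 7
bands suppresses residual noise: band-wise noise well below the prominence
threshold otherwise still throws spurious prominence-crossing extrema
(with iid noise of sd only `prominence_min/3`, most spectra acquire at
least one), while windows much wider than 7 bands begin to merge the PP
troughs at 1196 and 1215 nm, which are only ~5 bands apart. Those two
troughs remain deliberately marginal — separating them is genuinely hard
at this spectral sampling, and the defaults preserve that difficulty
rather than engineering it away.

The feature vector is binary: bit *j* is set iff an extremum of the
matching kind lies within ± `halfwidth_nm = 8` of region *j*'s centre.
The default schema holds the three polyolefin windows (PE peak 1540 nm;
PP troughs 1196 and 1215 nm) plus a PS peak window at 1680 nm — an
aromatic C–H overtone region — added by this package because PS would
otherwise have no encodable feature; the schema is data-driven (JSON) and
users can supply their own regions. HDPE and LDPE are collapsed to one PE
class at library load, as their NIR spectra are indistinguishable here.

## Classification

A 100-tree random forest (Gini splits, bootstrap resampling, no depth
limit, seed plumbed end-to-end) is trained on the one-hot library
encodings. Unlimited depth keeps leaves pure, so the forest's class
probabilities are exactly tree-vote fractions `P_rf`, which sum to 1 and
serve as prediction-certainty scores. The feature space is tiny and
binary, so these conventional hyperparameters are not sensitive.

Accuracy is estimated by stratified tenfold cross-validation (folds shrink
with a warning if the smallest class has fewer than k members). One-vs-rest
ROC curves sweep `P_rf > t` over the observed score values; TPR/FPR are
non-decreasing along the sweep, the endpoints (0,0) and (1,1) are always
present, and AUC is the trapezoid area, which equals the Mann–Whitney
U statistic divided by `n₊n₋` (tested against scipy on tied, discrete
scores). The final curve point uses cutoff 0 with assign-everything
semantics — the "max-`P_rf` wins, no threshold" decision rule reported
alongside thresholded operation.

The operating cutoff per class maximises TPR subject to the
cross-validated FPR estimate ≤ `target_fpr = 0.05` (read as "not above");
ties on TPR resolve to the lowest FPR, then the smallest cutoff. If no
point qualifies the class gets a never-assign sentinel (cutoff just above
1). At prediction time, among polymer classes whose score exceeds their
cutoff the highest `P_rf` wins (ties break PE → PP → PS); otherwise the
particle is `other`. The `other` class is evaluated symmetrically, with
its own ROC and threshold.

## Survey statistics

Tow concentration is `total particles / flowmeter volume (m³)`, unrounded
internally; presentation rounds half-up to 3 decimals. Tows flagged as
clogged (flowmeter blocked by weed) are excluded from min/max range
summaries because their volumes are unreliable. The packaged cruise table
transcribes 27 North Atlantic gyre tows — station, position, volume, total
count, the printed concentration, and the clogged flag only, since the
per-polymer count columns of the typeset source cannot be reconstructed
unambiguously. The packaged Raman cross-check breakdown (250 PE, 31 PP,
16 non-polymer, 53 not evaluable, of 350) supports the validation
arithmetic: the not-evaluable share is 15.1%.

Size spectra use nine logarithmically spaced bins spanning the net mesh
(0.3 mm) to 40 mm. Log spacing is essential twice over: it matches the
log–log presentation, and it makes the binned log–log regression exactly
unbiased for a power law (the ratio of a bin's integral mass to
`Δl · g^(−α)`, with `g` the geometric bin centre, is the same constant for
every bin of constant log width, so the offset is absorbed by the
intercept). Counts are per half-open bin `[e_i, e_{i+1})`; out-of-range
lengths are tallied separately, never silently dropped.

The exponent fit regresses `log(n/Δl)` on `log g` by ordinary least
squares, with α = −slope and its standard error from the regression.
Eligible bins are non-empty and — by default — have their *lower edge* at
or above `l_min_fit = 2 mm`. The alternative centre rule
(`edge_rule="center"`) admits one bin only partially covered when lengths
are truncated at 2 mm; its depressed `n/Δl` biases α low by ~0.3 in the
sampling experiments, so the whole-bin rule is the default. Empty bins are
dropped (log undefined); zero-replacement is deliberately rejected. A
truncated-density maximum-likelihood estimator is provided as an
independent cross-check of the binned OLS estimate. At the study scale
(20 000 lengths on [2, 40] mm), the fitted exponent recovers the
generating values 3.41 and 2.80 within 2 fitted standard errors for a
fixed seed and within 0.05 in the mean over 20 seeds, with ±2 se coverage
≥ 80% (the 5-point OLS standard error is itself noisy, so per-seed
coverage is not the nominal 95%).

## Synthetic data: what it emulates, and what it does not

Material spectra are a smooth low-order polynomial baseline plus signed
Gaussian features: PE carries its 1540 nm peak and the weak 1215 nm trough
it shares with PP; PP carries the 1196/1215 nm troughs; PS a 1680 nm peak;
the natural materials (pumice-like rising slope, carapace-like decline
above ~1300 nm, broad woody curve) are smooth and monotone, so their only
contract — no extrema inside any schema window — holds by construction.
Amplitudes and widths are free generator parameters chosen so the
diagnostic features are detectable under the default detector settings
while the PP trough pair stays marginal; they are not measured values.
Reference libraries emulate real reference measurements as means over
`n_pixel_draws = 100` single-pixel spectra with per-band sensor noise
`noise_sd = 0.02` (reflectance units), i.e. library-spectrum noise
`0.002` per band — the same pooling the pipeline applies to particles.

Scenes place disks, ellipses, or wobbly blobs of chosen material on a
0.05-reflectance background (matte black mounting bed), with particle
reflectances in [0.3, 0.9], a broadband 0.9-reflectance bar, per-band
Gaussian noise (default sd 0.005), and a truth table of labels and SVD
extents. An inverse-calibration helper converts a reflectance scene into
a uint16 raw cube plus white/dark frames with a mild spatial vignette so
the per-column calibration path is exercised.

Particle lengths come from inverse-CDF sampling of the truncated density
∝ `l^(−α)` on `[l_min, l_max]` (log-uniform closed form at α = 1), with
the uniforms injectable for quantile tests. Synthetic tow tables use
20-minute-tow volumes of 25–340 m³, lognormal station concentrations
around 0.5 particles/m³, and a PE-dominated polymer mix.

Not emulated: radiometric effects (stray light, spectral smile/keystone),
weathering-induced spectral change, biofouling, translucent particles,
fibres as a shape class, and overlapping-particle splitting. Passing tests
on synthetic scenes therefore demonstrate the correctness of the
algorithms under the stated noise model, not field performance on real
spectra; published per-class detection rates depend on instrument spectra
that cannot be regenerated here, and the corresponding tests assert the
method's structural properties (ROC monotonicity, AUC ≡ Mann–Whitney,
perfect separation on noiseless libraries, FPR-constrained thresholds)
instead.

## Determinism and problem sizes

Every stochastic component takes an explicit seed or `numpy` Generator;
fixed seeds give byte-identical CV reports, cubes, libraries, and tow
tables. Default test problem sizes — 200×640 scenes, 48-spectrum
libraries, 20 000-length samples, 20-seed recovery sweeps — were chosen as
the smallest scales at which the statistical assertions are stable.
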