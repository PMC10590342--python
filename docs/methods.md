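# Methods

## Imaging model

Each axial CT slice is an integer raster plus an affine rescale to
Hounsfield units, `HU = pixel × slope + intercept` (air ≈ −1000 HU, water
0 HU).  A series is a stack of slices strictly ordered by z position;
geometry (row/column pixel spacing, slice thickness) is kept per slice
because clinical stacks mix thicknesses (1–8 mm is typical at L3), and
volume integration must respect the per-slice value.

The mid-L3 slice is clinically chosen by a trained grader; that judgement
cannot be computed from pixels alone, so `mid_index` is an explicit input.
Its default is the median slice by z (the lower of the two central slices
for even counts — an arbitrary but fixed tie-break).

DICOM I/O is a deliberately small built-in reader/writer covering
uncompressed little-endian single-frame files (explicit and implicit VR).
Sequences, compression and big-endian files are rejected with explicit
errors rather than mis-read.

## Segmentation stand-in

Learned segmentation models are out of scope; the built-in segmenter exists
so the measurement chain can be validated end to end, and real model output
can be substituted via mask files.  The rule set:

1. body region = largest connected component with HU > `body_threshold`
   (default −500 HU), holes filled;
2. SM = body pixels in the muscle window −29…+150 HU;
3. the SM mask is morphologically closed (disk radius 3 px) and filled; the
   filled region is "inside the muscle wall";
4. VAT = adipose pixels (−150…−50 HU) inside the wall; SAT = adipose pixels
   (−190…−30 HU) in the body but outside the wall.

VAT and SAT overlap in HU, so geometry — not radiodensity — separates them;
this mirrors how human readers work.  The HU windows are the widely used
Alberta-protocol conventions and are configurable.  Masks are binary,
pairwise disjoint by construction, and a QC flag is raised when any
compartment touches the raster border (a proxy for tissue extending beyond
the field of view; the clinical exclusion decision remains a human call).

## Measurements

* area (cm²) = pixel count × row spacing × column spacing / 100.  Row and
  column spacings are multiplied separately so anisotropic rasters are
  handled correctly.
* 2D radiodensity (HU) = arithmetic mean of HU under the mask; an empty
  mask yields an *undefined* value (None), never zero.
* index (cm²/m²) = area / height²; absent without a height.
* volume (cm³) = Σ over slices of area × thickness/10, per-slice thickness.
* 3D radiodensity = unweighted mean of per-slice mean HU.  This follows the
  conventional slice-mean formula literally even though a volume-weighted
  mean is arguably more physical; the weighted variant exists behind
  `weighted=True` and is off by default.  Slices with an empty mask are
  skipped and the count of contributing slices is recorded.

BSA is always an input (registry value); no BSA formula is implemented.

## Group statistics

Mann–Whitney U is two-sided, exact for groups ≤ 25 without ties, otherwise
the tie-corrected normal approximation with continuity correction (scipy).
The 2×2 sex-by-DLT test is a Pearson chi-square with Yates continuity
correction by default — the correction choice is pinned by a regression
test — with `correction=False` available.  Quartiles use linear
interpolation; the convention is recorded in every run log because IQRs are
not comparable across quartile rules.

## Discrimination

AUC is computed by pair counting (identical to the trapezoidal area under
the empirical ROC, ties included) and its CI by DeLong's nonparametric
placement-value method, truncated to [0, 1].

The comparison **direction is fixed per analysis** (default: higher value
predicts non-DLT, the natural orientation for muscle mass).  Auto-flipping
would fold every AUC above 0.5 and hide measurements that separate in the
"wrong" direction; a measurement that does so simply shows AUC < 0.5.
`auto_direction=True` opts into flipping.

Cut-points maximise Youden's J over candidate thresholds placed at
midpoints between adjacent distinct observed values plus ±∞ (maximum
accuracy available via `criterion="accuracy"`).  Ties on the objective are
broken toward higher specificity, then the lower threshold; a curve with
J = 0 everywhere is flagged degenerate and returns its lowest candidate.
Classification at the boundary is fixed: value ≥ threshold goes to the
"higher" class.  All of these choices are arbitrary where the literature is
silent; they are fixed and logged so results are bit-reproducible.

Published sarcopenia cut-offs (e.g. sex-specific SMI thresholds) can be
evaluated as fixed, non-fitted classifiers via `threshold_classifier`.

## Synthetic data

**Phantom.**  Nested cylinders: VAT disc (default radius 60 mm), SM ring
(60–80 mm), SAT ring (80–100 mm), air outside; default 11 slices × 5 mm on
a 512×512 raster at 0.8 mm spacing; per-compartment HU are Gaussian (means
SM +40, VAT −91, SAT −104 — typical of patient data — SD 10; air −1000).
Radii may taper linearly along z.  The generator returns exact analytic
areas and volumes, so measured-vs-truth discrepancies isolate pixelation
error, which shrinks as spacing decreases (tested at two resolutions).
What a green phantom test does **not** establish: performance on real
anatomy — phantoms have no organs, bowel gas, contrast, beam hardening or
non-convex muscle geometry, which is why external masks are first-class.

**Cohort.**  Per sex (defaults 106 F / 97 M, DLT prevalence 69% / 48%),
DLT labels are Bernoulli draws and each measurement is normal within each
DLT stratum.  The DLT-stratum mean and SD per measurement come from
published colorectal-cohort medians and IQRs (SD = IQR/1.349 under
normality); the non-DLT mean is offset so the closed-form binormal AUC
equals a per-measurement target, with 3D SM volume the strongest
discriminator in both sexes (true AUC 0.66 F / 0.64 M) and BSA near-null
(0.49 F / 0.58 M).  Age is drawn with near-identical strata (it is a
covariate, not a discrimination target).  Heights are N(1.61, 0.065) m (F)
and N(1.75, 0.07) m (M) — unremarkable adult values chosen once.
Measurements are drawn independently given the label; real measurements are
strongly correlated (e.g. SMI is literally area/height²), so the simulator
validates marginal ROC behaviour, not joint models.  All generation is
seed-deterministic.

At the default cohort size the per-measurement AUC has sampling SE ≈ 0.06,
larger than the true gap between the best and second-best measurement in
males (0.64 vs 0.61): recovery of the true ordering is therefore tested at
20 000 patients per sex, where the gap is ≈5 SE — a power calculation, not
a tuned number.

## Numerical notes

* The HU conversion is exact in float64; the phantom writer rounds HU to
  the nearest stored integer, so round-trip HU agree to ±0.5 × slope.
* Empty masks propagate as None through 2D and 3D radiodensities; volumes
  of empty compartments are 0, not undefined.
* DeLong SE of a degenerate (all-ties) curve is 0; the CI collapses onto
  the AUC.

## Known limitations

* The threshold segmenter is a validation stand-in, not a clinical
  segmentation method; intermuscular adipose tissue is not separated.
* Multi-frame DICOM, compressed transfer syntaxes and non-axial
  orientations are unsupported.
* No kVp-dependent HU correction is applied (tube voltage varies 100–140
  kVp across scanners; the measurement chain treats HU as calibrated).
* No multivariable modelling, survival analysis or multiple-testing
  correction; the analysis is deliberately per-measurement.
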