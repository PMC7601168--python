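# Methods

This note documents the models and procedures implemented in `fluortex`, the
parameter defaults and why they were chosen, the synthetic data the test
suite runs on, and the package's known limitations.

## Problem setting

Direct-fluorescence visualization of the oral cavity renders healthy mucosa
bright (it fluoresces under ~400 nm excitation) and dysplastic tissue dark
(it absorbs the excitation).  The package classifies fixed-size super-pixels
of such images into *standard* vs. *anomalous* tissue so that anomalous
regions can be proposed as biopsy sites.  The unit of analysis is the
super-pixel, not the pixel: a biopsy needs a coherent region, and texture
statistics need a window to be estimated on.

## Edge detection: Deriche–Canny

The gradient is computed with Deriche's recursive filters: smoothing kernel
`s(x) = k(α|x|+1)e^(−α|x|)` (normalized to unit sum) in one axis and
derivative kernel `d(x) = −c·x·e^(−α|x|)` (normalized to unit ramp response)
in the other, each realized as a causal + anticausal second-order recursion
(`scipy.signal.lfilter` runs the recursions; the coefficients are derived in
`edges.py` and the impulse response is tested against the analytic kernels).
α defaults to 1.0 — roughly a 1-pixel-scale detector, a reasonable middle
ground given that the aperture rim, the main structure we need, is a
high-contrast circle.  Borders are reflect-padded before filtering.

Canny post-processing uses bilinear-interpolated non-maximum suppression.
An earlier 4-sector (0°/45°/90°/135°) neighbor-pick variant left
double-width runs where a curved edge crosses a sector boundary (a planted
circle's ring came out ~18 % longer than 2πr); interpolating the
magnitude along the true gradient direction fixes this (~11 % over 2πr,
the residual being the inherent excess of an 8-connected digital circle).
The ahead/behind comparison is deliberately asymmetric (`>` ahead, `≥`
behind) so the two-pixel plateau of an ideal step edge thins to exactly one
pixel.  Hysteresis thresholds default to the 70th/90th percentiles of the
nonzero gradient magnitude — percentile thresholds adapt to overall image
contrast and behave consistently across synthetic and natural scenes.

## Device removal: circular Hough transform

Candidate radii span [0.30, 0.48]·min(H, W): the aperture dominates the
frame when present, and the upper bound keeps the full circle inside the
image.  The accumulator is normalized by circumference length
(`skimage.transform.hough_circle` with `normalize=True`), so a hit's score
is the fraction of its circumference supported by edge pixels.  A circle is
accepted when the best score reaches 0.35 — high enough that the wiggly
contours of tissue texture never accumulate it (measured false-circle rate
0/20 on device-absent scenes, with best spurious scores around 0.15), low
enough to tolerate a partially occluded rim.  On acceptance the frame is
cropped to the circle's bounding square (clipped at image borders), the
exterior set to 0, and an `usable` mask recorded; windows touching the
blanked exterior are excluded downstream rather than letting the artificial
black region masquerade as ultra-dark tissue.  Only the single best circle
is used — the imaging geometry has one aperture.

## Quadtree super-pixels and the labeling rule

Fixed-depth quadtree subdivision of an image whose sides are multiples of
the 64-pixel leaf is identical to uniform 64×64 tiling; the implementation
tiles directly and a literal recursive subdivision is kept in the test
oracle to pin the equivalence.  Sides that are not multiples of 64 are
conceptually zero-padded bottom/right and the overhanging windows flagged
invalid.  A 1792×1792 frame yields a 28×28 grid (784 windows).

A window is labeled *anomalous* only if every one of its 4096 pixels lies
in the ground-truth lesion mask; a single standard pixel makes it
*standard*.  The rule is asymmetric on purpose: a proposed biopsy window
should contain lesion tissue only.  Its corollary, relied on throughout the
tests, is monotonicity — growing the lesion mask can only turn standard
windows anomalous, never the reverse.

## Texture features

The co-occurrence matrix keeps all 256 gray levels (no requantization — the
diagnostic texture differences are subtle intensity variations that
quantization would erase) at the single offset (0, 1): 0°, distance 1.
Other angles are exposed through the `offset` argument but are not part of
the default configuration.  Accumulation is symmetric (each pair counted in
both orders), making the matrix symmetric and the two marginals identical.

The ten features follow Haralick's standard definitions (natural log,
0·log 0 := 0, 0-based gray levels so the diagonal-sum index runs 0..510 and
the cross-sum index 0..255).  Several published restatements of these
formulas contain typographical corruptions (contrast with `|i−j| = 0`
inside the sum, IDM with `(i+j)²`, correlation over `σxσ`, a sign-less sum
entropy); the implementation uses the standard forms — sum variance is
centered on sum entropy (f8), per Haralick's original definition — and
every feature is verified against an independent literal-summation oracle
to 1e−10 relative error.  A constant window has zero marginal spread; its
correlation is reported as 0 with a `degenerate` flag rather than NaN.
Difference entropy and the first information measure of correlation are
available behind the `extra` flag for rankings that use them.

## Feature ranking

Each feature is scored univariately by Δ² = (μ₁−μ₂)²/C with the
size-weighted pooled *population* covariance C = (n₁C₁+n₂C₂)/(n₁+n₂) — the
weighting is implemented exactly in this form, and the univariate score
equals the multivariate Mahalanobis separation βᵀ(μ₁−μ₂), β = C⁻¹(μ₁−μ₂),
when run on one feature (cross-checked in the tests).  Δ² is invariant
under affine rescaling of a feature, so the wildly different scales of the
ten features (entropies ~1, sum variance ~10⁴) do not distort the ranking.
Ties break toward the canonical feature order; a zero-variance feature with
unequal means ranks first with an infinite score and a warning.  The
default selection keeps the top 8 — adding weakly separating features to a
nearest-neighbor classifier dilutes the distance metric, so the prefix
length is capped rather than using all ten — and the full sweep over 1..10
is always available for choosing the cutoff on a given dataset.

## Classification and evaluation

KNN with k = 1 by default ("nearest neighbor"), Euclidean distance on
z-scored features; standardization parameters are fit on the training fold
only, and zero-variance training features are dropped with a warning.  The
KNN is implemented directly (distances via `scipy.spatial.distance.cdist`)
because majority ties must break toward the anomalous class — the
clinically conservative direction — which off-the-shelf classifiers do not
express.

Evaluation is grouped leave-one-image-out: within each group, every image
is held out once and the classifier trains on the group's remaining images
(a `within_group=False` flag trains on all other images instead).  Super
pixels of the test image therefore never appear in their own training fold;
a dedicated test constructs a dataset where leakage would be detectable
with certainty.  Per-fold confusion counts give sensitivity, specificity
and accuracy; a fold without anomalous windows has undefined sensitivity,
reported as NaN and excluded from the mean ± sd aggregate.

## Synthetic scenes

The generator emulates exactly the two statistics the GLCM features respond
to, not the appearance of mucosa:

| parameter | default | meaning |
|---|---|---|
| background_mean | 180 | bright fluorescing mucosa (8-bit) |
| background_sd | 10 | background texture amplitude |
| background_smoothness | 6 px | Gaussian correlation length (smooth) |
| anomaly_mean | 60 | dark absorbing lesion |
| variance_multiplier | 6 | lesion local variance / background |
| anomaly_smoothness | 1 px | rough lesion texture |
| blob_count / area_fraction | 2 / 0.20 | lesion number and coverage |
| device_fill / rim | 5 / 235, 3 px | aperture exterior and rim |

Both textures are Gaussian-smoothed white noise rescaled to exact
mean/variance, so every scene is bit-reproducible from its seed.  Lesion
supports are disks anchored at the centers of randomly chosen super-pixel
cells, radius calibrated analytically to the target area fraction and
floored at 0.72× the cell side.  The anchoring guarantees at least one
fully-anomalous super-pixel per scene (so per-fold sensitivity is always
defined), mirroring a clinical set where every included image shows a
biopsy-sized lesion; the calibration keeps the realized lesion fraction
within ±0.05 of the target.  When a device circle is planted, the bright
rim is drawn just *inside* the true radius so the dominant rim-to-black
edge lies exactly on it, and lesions are restricted to cells whose blob
stays inside the aperture.

What the generator does **not** model: illumination falloff and specular
highlights, salivary reflections, anatomical structure (teeth, tongue
dorsum papillae), gradual lesion margins, or inter-patient variability.
Consequently the synthetic benchmark is nearly separable — the grouped CV
reaches 100 % with the default statistics — and passing it demonstrates
that the pipeline's machinery (windowing, features, ranking, grouped CV,
leakage control) is correct, **not** that comparable accuracy would be
achieved on real images, where class overlap is far larger and
fold-to-fold spread substantial.

Scenes used by the tests and the acceptance script are 256 px (16 windows)
rather than full 1792 px frames, keeping the suite fast; the 1792-px
geometry is exercised directly by the quadtree checks.

## Numerical choices and degenerate inputs

* GLCM normalization is checked to 1e−9; features of an empty/too-small
  window raise geometry errors rather than returning silently.
* Hysteresis with `low > high` and invalid Hough radius ranges raise
  parameter errors; an empty edge map yields an empty hit list (absence of
  a device is a valid outcome, not an error).
* Metrics with zero denominators are NaN-flagged, never 0-filled.
* All stochastic stages consume `numpy.random.default_rng` children of a
  single user-supplied seed.

## Limitations

* The Deriche α, hysteresis percentiles and Hough score floor were chosen
  for the synthetic scenes' contrast regime; clinical deployments should
  re-examine them on real frames (all are config keys).
* Only the 0° distance-1 GLCM offset is used by default; multi-angle
  averaging is exposed but unvalidated.
* The quadtree is fixed-depth by design; content-adaptive subdivision and
  overlapping windows are out of scope.
* Single-aperture geometry: multiple device circles in one frame are not
  handled.
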