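# Methods

This note documents the measurement model, the numerical choices, the
synthetic-data model and its limits, and the open design decisions the
package resolves. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate and intensity conventions

Images are 8-bit (0–255), x = column, y = row, origin top-left; pixel (x, y)
spans the unit square [x, x+1) × [y, y+1). A polygon ROI rasterizes to the
set of pixels whose centers (x+0.5, y+0.5) lie strictly inside the polygon —
a deterministic rule that a brute-force point-in-polygon scan can audit.
16-bit input images are rejected rather than rescaled, because any rescaling
convention would silently move every threshold; the workflow is defined on
8-bit displays. RGB→gray conversion is the unweighted channel mean rounded
half-up (the plain 8-bit conversion of standard raster tools), not luma
weighting.

## Maximum-entropy thresholding

Both the B-mode and the Doppler branch binarize with the Kapur
maximum-entropy rule: the threshold t ∈ [0, 254] maximizes the sum of the
within-class Shannon entropies of the normalized histogram split at t.
Numerical choices:

* natural log (the base cannot change the argmax);
* zero-probability bins contribute nothing; candidates that leave either
  class empty are inadmissible;
* ties break toward the smallest t, making results platform-stable;
* foreground is *strictly above* t;
* the histogram is taken over ROI pixels only, matching a workflow in which
  the operator thresholds within the traced nerve.

A histogram with fewer than two occupied bins is degenerate. Callers choose
the fallback: the FR pipeline reports 0 with a `degenerate` flag (so batch
runs survive pathological frames), and Doppler signal selection returns an
empty mask, because a frame with no flow signal is a legitimate clinical
observation, not an error.

A property worth knowing when interpreting results: on a histogram with one
dominant *broad* cluster, the entropy criterion prefers to cut ~1–2 SD into
that cluster's near tail rather than exactly between clusters, because the
split buys mixture entropy. The practical consequence is a small
tail-chopping bias in area fractions — positive when the background
dominates, negative when the foreground does. The recovery tests quantify
this (see below); it stays within a few percentage points whenever the
intensity classes are narrow relative to their separation, which is the
regime the method operates in on log-compressed display imagery.

## B-mode pipeline (FR, CSA, CSR)

Order of operations: grayscale → invert → background subtraction → ROI
histogram → maximum-entropy threshold → binarize. Inverting *first* is
load-bearing: the background estimator is a grayscale opening, which removes
bright features narrower than its structuring element, so fascicles must be
bright (inverted) when it runs. The suite demonstrates that swapping the
order flattens the signal away entirely on a two-level phantom; the
alternative order remains available (`background_before_invert=True`) for
sensitivity analysis.

The background estimator is a disk opening of radius 50 px by default — the
common neighborhood-size default of desktop image tools, exposed as
`--rolling-ball-radius`. The disk uses a fast sequence decomposition; the
classic parabolic rolling-ball estimate is available as
`method="rolling_ball"`. A radius exceeding both image dimensions is a
parameter error.

CSA is the rasterized ROI pixel count times the pixel-area calibration
(default 0.004017 mm²/px, the probe/depth setting the default study
conditions emulate; always overridable). CSR divides the per-subject mean
affected CSA by the mean unaffected CSA; the emulated study averaged six
frames per side, but any n ≥ 1 is accepted.

## Doppler pipeline (VR, MPR, high-velocity proportion)

The four difference maps (G−R, B−G, G−B, R−G, saturating at 0) are exactly
zero wherever R = G = B, so the grayscale background can never contribute
signal — the suite asserts this null exactly on random gray frames. Design
decisions:

* one threshold per *merged* map (fast, slow), not per class — the merged
  projections are what get binarized, and direction is discarded anyway;
* the slow-flow correction is a mask-domain set difference (slow \ fast)
  applied after signal selection; an intensity-domain variant (subtract the
  fast map before thresholding) is available as `correct_intensities=True`;
* particle filtering uses 8-connectivity with a minimum size of 1 px
  (i.e. no filtering) by default, since no size cutoff is part of the
  method's definition; `--min-particle-px` exposes it;
* fast mask and corrected slow mask are disjoint by construction, so
  high + corrected-low = total always — a continuously asserted invariant;
* the high-velocity proportion is reported as a fraction in [0, 1] and is
  undefined (None) when no signal was found.

Palette structure makes fast-flow pixels bleed into the slow maps (a cyan
pixel has B−G > 0); this is exactly why the correction exists. The converse
direction matters too: a slow-flow palette whose green channel exceeds its
red channel would bleed into the *fast* map, where no correction is defined,
and the entropy threshold then absorbs the slow pixels into the fast mask.
The test suite pins both behaviors with noiseless fixtures verified against
an independent per-pixel stage oracle.

## Synthetic data: what it emulates and what it does not

**B-mode phantom.** Bright background (mean 200) with multiplicative
Rayleigh speckle (scale 0.02 of the mean), plus additive Gaussian display
noise (SD 5) on every tissue class — the constant-width residual texture a
log-compressed, persistence-smoothed scanner display shows. Fascicles are
dark ellipses (mean 30) whose union is bisection-scaled to the requested
area fraction within 1% relative; the bright epineurium is drawn as a ring
just *outside* the ROI, because the ROI traces the inner epineurium boundary
and the fascicle/interfascicular contrast is what FR measures. The default
ROI is an octagon whose inradius (~44 px in a 128×128 frame) is below the
50 px background-subtraction radius, so the background estimate always sees
tissue outside any fascicle.

**Doppler phantom.** Grayscale speckle background (R = G = B exactly) with
disk-blob overlays painted to exact per-class pixel budgets. Palette anchors
are (R, G, B) = (5, 190, 235) for light blue and (45, 15, 195) for dark
blue, with light/dark red their exact R↔B mirrors; per-pixel variation is a
common-mode brightness offset (0–19) added to all three channels. This
models the overlay as what it physically is — a digitally composited palette
LUT running along a brightness ramp — and it makes the channel differences
class-wise constant, while every class-defining channel ordering (light blue
G>R, dark blue B>G, light red G>B, dark red R>G) holds for every draw. The
dark-class green channel stays below both other channels, so slow-flow
pixels contribute nothing to the fast maps. Because the red palettes are
exact channel mirrors sharing the same jitter draws, direction carries no
information at all, and the direction-independence test can demand *exact*
equality.

**Cohorts.** Subject-level truth fractions are truncated normals per site;
frames scatter around the subject value (SD 0.02). Default site means are
the package's clinical reference values — VR 43.26 / 14.14 / 17.72%
(neuroma / unaffected / healthy control), MPR 54.15 / 14.22%
(control / denervated muscle), FR 87.87 / 50.66 / 54.31%, CSR 2.20 (range
~1.0–3.4), high-velocity proportions 0.36 / 0.390 / 0.328 / 0.875 / 0.454.
Subject SDs (0.04–0.08 for VR/MPR, 0.06 for FR) are chosen to match the
reported spreads (e.g. healthy-control VR ranging ~10.5–25.9%); they are
model choices, not reported statistics.

**Limits.** The generator does not model acoustic physics (PSF, attenuation,
shadowing), vendor-specific palettes, color-bar/annotation chrome, partial-
volume blending at overlay edges, or operator ROI variability. Passing the
recovery tests therefore shows the *algorithm chain* is correct and unbiased
under the stated image model — not that the ratios are accurate on any
particular scanner's output.

## Recovery behavior and problem sizes

On the synthetic grid (128×128 frames, octagonal ROI of 6,444 px):

* VR and high-velocity proportion recover ground truth exactly over painted
  fractions {0.05, 0.15, 0.45} × fast-class mixes {0.16, 0.33, 0.56}
  (tolerances asserted: mean ≤ 2 pp and ≤ 0.05);
* FR recovers within 5 pp per frame over fractions {0.2, 0.5, 0.8} × 20
  seeds, with the tail-chopping bias described above: slightly positive at
  low fractions, slightly negative at high ones, near zero at 0.5.

The statistics layer is calibrated on 1,000 null-cohort draws (rejection
rate asserted within 5% ± 2 pp) and powered on 200 cohort draws at the
default study conditions (omnibus p ≤ 0.001 plus correct mean ordering in
≥ 95% of runs; with the emulated effect sizes the separation is essentially
total). `scripts/acceptance.py` uses these same sizes and additionally
renders 50 subjects × 2 frames per site at 96×96 for the full image-pipeline
cohort means — Monte-Carlo estimates of each site's expected measurement,
where more subjects only shrink estimator noise. These sizes keep a complete
run at desk scale while leaving every rate estimate with comfortably small
Monte-Carlo error.

## Statistics layer decisions

The normality gate is deterministic by sample size (D'Agostino–Pearson
requires n ≥ 8; Shapiro–Wilk covers 3 ≤ n < 8; below 3 the nonparametric
route is forced), because the emulated study names both tests without a
selection rule and its groups span n = 4–9. Dunn post hoc p-values are
Bonferroni-adjusted (the conventional default for "Dunn's multiple
comparison"); the Dunn z statistics use pooled mean ranks with tie
correction. All group tests are two-sided and unpaired. A cohort in which
every value is identical reports p = 1 with no stars rather than failing
inside a normality test. These choices are surfaced in each report's
`notes` field so a reader can audit which route ran.
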