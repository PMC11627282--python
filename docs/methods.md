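# Methods

## Problem and measurement model

`lidcontour` quantifies upper-eyelid contour from frontal periocular
photographs that have been manually landmark-annotated (pupil center,
nasal/temporal limbus, lateral canthus, traced upper-lid-margin
polyline, for both eyes). The use case is ptosis-repair outcome
analysis in unilateral disease, where the non-ptotic fellow eyelid is
the natural symmetry reference: the classic MRD1 (pupil center to lid
margin, vertically) describes only the central lid, so the package
measures the *whole* margin.

Two descriptors are computed per eyelid:

1. **Multiple MRD1s** — the margin height sampled at ten fixed
   horizontal positions, every 2 mm from 8 mm nasal to 10 mm temporal
   of the pupil center (labels N8, N6, N4, N2, MRD1, T2 … T10). The
   value at x = 0 is MRD1 itself.
2. **Marginal peak point** — the signed (x, y) of the highest margin
   point, the idealization of raising a horizontal ruler until it is
   tangent to the lid; x < 0 means the peak lies nasal of the
   mid-pupillary line.

## Normalization

Measurements are made in a canonical frame constructed per photo:

* **Tilt.** The signed angle of the line through the two lateral
  canthi, folded to (−90°, 90°]; all landmarks are rigidly rotated by
  its negation about the inter-canthal midpoint. The center of rotation
  is arbitrary (any rigid center is equivalent after pupil-centering);
  the midpoint keeps both eyes symmetric in frame.
* **Scale.** mm/px = WTW(sex) / pixel distance between the limbus
  landmarks, with the population white-to-white corneal diameters
  11.77 mm (male) and 11.64 mm (female). Calibration is per-eye by
  default; `calibration="mean"` averages the two eyes' scales.
* **Frame.** Margin pixels are mapped to
  `(p − pupil_center) · scale`, the raster y axis is flipped once here
  (downstream heights are y-up, so negative heights mean "margin below
  pupil center"), and the x axis is oriented temporal-positive using
  the sign of (canthus x − pupil x) rather than the left/right label —
  robust to mirrored exports and making the two eyes directly
  comparable. The margin is sorted by x; consecutive x within 1e−9 mm
  are collapsed to their mean y (hand tracing can double back); the
  result must be strictly increasing in x.

Interpolation along the margin is linear. Heights requested outside the
traced margin's support are *missing* (NaN), never extrapolated — short
palpebral fissures may simply not reach +10 mm.

## Peak detection

On a piecewise-linear margin the maximum is attained at a vertex. Near-
ties are handled deterministically: vertices within 1e−6 mm of the
maximum form contact runs, and if a run spans more than the tolerance
in x the peak x is the midpoint of the widest run (the manual tangent
procedure presumes a unique contact point and defines no tie-break).
No smoothing is applied; the worked examples on published group-mean
contours are vertex-exact either way.

## Cohort statistics

Per position, and per peak coordinate, two two-sided **paired** Student
t-tests are run: change (pre vs. post, within the ptotic eye) and
symmetry (post vs. fellow). Pairing is forced by the within-patient
design. α = 0.05 by default. Missing values are removed pairwise; the
reported n per test never exceeds the cohort size. Degenerate inputs:
identical samples give t = 0, p = 1; zero-variance nonzero differences
report p at the machine floor with an `underflow` flag; fewer than two
complete pairs is an error. No multiple-testing correction is applied
across the ten positions by default, matching how such per-position
tables are conventionally reported; Holm step-down is available
(`correction="holm"`). Group summaries use the sample SD (n−1); two
arms pool into a "total" column by n-weighted means. Whether fellow
eyes should instead be treated as an independent sample is unsettled in
this design; the paired form is the default here.

The fellow eyelid is measured on the preoperative photograph by default
(the non-operated eye is assumed stable); `fellow_source="postop"`
switches to the postoperative one.

## Synthetic data generator

Because no patient photographs accompany studies of this kind, the
generator produces full cohorts with exact ground truth.

* **Contour family**: piecewise parabola
  `y = peak_y − c_side (x − peak_x)²` with independent nasal/temporal
  curvatures on a support running from a nasal canthus (−13 mm) to a
  temporal canthus (+15 mm). This is the simplest family reproducing an
  asymmetric drooped arch (published fellow-eye means drop faster
  temporally than nasally); it is a test harness, not a biomechanical
  claim. Defaults: ptotic baseline peak (−1.2, 1.6) mm for the
  levator-advancement-like arm, (0.0, 1.2) for the Muller's-muscle-like
  arm; fellow (−0.3, 3.0); curvatures ≈ 0.022–0.036 mm⁻¹ fitted to the
  published group-mean rows.
* **Surgery models**: `uniform` adds `effect_mm` everywhere (default
  1.1 mm); `center_weighted` adds
  `effect_mm · exp(−(x−center)²/(2·w²))` with taper width w = 5 mm and
  effect 1.0 mm by default — the "dome tent" vs. "bell tent" contrast
  between a continuous suture line and a single central suture.
* **Photo synthesis**: pupils are placed 60 mm apart at a configurable
  magnification (default 10 px/mm); limbus landmarks are one
  white-to-white diameter apart; lateral canthi sit at the temporal end
  of each contour's support, 0.5 mm below the pupil line in the
  untilted head for both eyes (the inter-canthal line is the tilt
  reference, so it must be level at zero tilt). Everything is rigidly
  rotated by the head tilt, then Gaussian noise is added: isotropic
  `landmark_sd_px` on point landmarks and vertical `margin_sd_mm` on
  each margin vertex. The sampled margin polyline includes the ten grid
  positions and the exact peak as vertices (uniform samples within
  0.01 mm of these are dropped so flat-vertex neighbourhoods cannot
  create spurious plateaus); noise-free, the measured profile and peak
  therefore equal the analytic ground truth to better than 1e−6 mm at
  any tilt within ±15° and scale within 3–30 px/mm.
* **Cohorts**: per patient, baseline contour parameters are jittered
  (peak x and y: normal, sd 0.8 mm, giving baseline MRD1 spreads of
  the order reported for such cohorts, ~1 mm; curvatures: log-normal,
  sd 0.15) and the postoperative contour applies the surgery model to
  the *same* baseline — a genuinely paired design in which
  between-patient shape variation cancels from the paired differences
  and only annotation noise remains. Each photo draws its own head tilt
  (normal, sd 3°). Sub-seeds come from `SeedSequence.spawn`, so any
  single patient is reproducible in isolation. Sex is drawn 69% male
  (22 of 32 in the motivating cohort), ptotic side 50/50.

What the generator does **not** emulate: real margin-tracing error is
smooth and correlated along the lid rather than vertex-independent;
lens/perspective distortion, eyelash occlusion, notching and
three-dimensional lid geometry are absent; pupil size and gaze are
fixed. Passing tests therefore validate the *geometry and statistics*
of the pipeline, not robustness to real-photograph segmentation
difficulty — annotation quality remains the responsibility of the
annotator.

## Numerical choices

* Linear margin interpolation is the default and what all headline
  numbers use; it commutes with the rigid normalization.
* Peak plateau tolerance 1e−6 mm; midpoint tie-break (above).
* Composite (post-surgery) analytic peaks are located by a 2001-point
  scan plus bounded scalar minimization (xatol 1e−10).
* Duplicate-x collapse threshold 1e−9 mm.
* Test problem sizes: cohort simulations in the test suite use 16
  patients per arm with 240-vertex margins, 20 seeds for
  pattern-recovery properties and 10,000 replicates for t-test
  calibration — sizes chosen so the full suite exercises every chain at
  the study's own scale while remaining quick on one CPU.

## Known limitations

* The ten-position grid and the peak are two-dimensional summaries; no
  3-D contour information is represented.
* Group-mean profiles treated as contours (the worked examples) carry
  no within-group variance; their peak is exactly the largest printed
  mean.
* With a center-weighted effect of 1.0 mm and annotation noise of
  0.5 mm, the expected elevation at the ±8 mm positions (~0.28 mm) sits
  in a low-power regime at n = 16 (per-position power ≈ 0.3): single
  simulated cohorts will sometimes flag edge positions as significant
  and sometimes miss central ones near the band edge. The qualitative
  center-vs-canthus contrast is robust in expectation, not in every
  16-patient draw — which mirrors how such cohort sizes behave in
  practice.
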