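# Methods

## Arena model

The arena is annotated offline as a set of four-corner well polygons and
per-well food circles, in image coordinates (0-based pixel centers,
origin top-left, y down). Corners are stored clockwise in the screen
sense; counter-clockwise input is reordered on construction.
Point-to-well assignment is boundary-inclusive; a point on an edge
shared by two wells is assigned to the lexicographically smaller well id
so the map is a deterministic partial function. Validation distinguishes
hard errors (missing/duplicate ids, corners outside the frame,
nonpositive radius, food center outside its well) from warning-grade
findings (food circle poking beyond the well outline, overlapping
polygons at shared walls): the feeding port sits at the bottom center of
the well and annotation jitter there is expected, and wall-sharing
polygons occur in real camera views, so neither aborts a run.

## Detection

Binarization is background subtraction against a per-well, per-pixel
temporal median of frames sampled evenly across the session (default 11
samples; at least 3). The median recovers the unoccluded backlight value
at any pixel the fly occupies in fewer than half the samples, and a
per-well model absorbs static shading differences between wells and
cameras. A pixel is foreground iff it lies inside the well polygon and
is strictly darker than background − δ; δ defaults to 25 on the 0–255
scale, chosen as roughly a third of the contrast of a fly blob (80
levels in the synthetic scenes) so that moderate illumination drift
neither splits the silhouette nor admits background texture.

Connected components default to 8-connectivity — fly silhouettes at
plate-camera resolution are thin, and 4-connectivity fragments legs —
and the largest component is retained if it reaches `min_area` = 8 px,
which rejects dust specks while keeping a small or defocused fly. Area
ties break toward the component whose top-left-most pixel comes first in
row-major order. Frames with no qualifying component yield
`found=False` rather than an error: flies do hide under the food port.

## Measures

The food-interaction flag is computed per pixel exactly as defined: 1
only when *every* silhouette pixel lies within the circle radius of the
circle center (boundary inclusive), not merely the centroid. Inter-frame
distance is the Euclidean centroid displacement; when either centroid is
missing the contribution is 0 and the gap is counted on the series,
keeping every frame in the interval denominator so that interval
food-fractions and distances remain comparable across wells with
different gap burdens. Intervals are aligned to frame 0 and default to
120 s; a trailing shorter interval is emitted with `partial=True`
instead of being dropped. Distance normalization to relative units
divides by the maximum per-interval distance over the whole compared
cohort by default (a per-fly scope is available), since only a global
maximum makes the unit comparable across flies.

## Feeding-bout denoising

A feeding burst of 7 sips × 0.13 s spans 0.91 s, i.e. 30 × 0.91 = 27.3
frames at 30 fps; the integer threshold is its floor, 27 frames, with 10
frames as the minimum genuine departure from food. Denoising applies two
passes once each, in this order: (1) close every interior 0-run shorter
than 10 frames, (2) remove every remaining 1-run shorter than 27 frames.
Closing gaps first reconstructs bursts interrupted by one-frame
detection blinks before judging their length; the reverse order would
discard the fragments first. Leading and trailing 0-runs are never
closed (no bracketing feeding run on one side). One application already
satisfies both run-length constraints, so the operation is idempotent —
asserted on random series against an independent single-frame-flip
reference implementation.

One caution on parameter intuition: the flagged time after denoising is
monotone *increasing* in `min_off_frames` (a wider gap-closing window
can only add frames) and monotone decreasing in `min_on_frames`.
Lowering `min_off_frames` is not a "gentler" setting — it can remove
entire bouts whose fragments are no longer merged.

## Statistics

Group comparisons use the two-sided **unpaired** Mann–Whitney rank-sum
test. (Field reports sometimes label this "Wilcoxon signed rank"; the
paired signed-rank test does not apply to cohorts of different flies, so
the unpaired test is what is implemented.) The null p-value is exact by
enumeration when n₁+n₂ ≤ 12 with no ties, and otherwise uses the normal
approximation with tie and continuity corrections; identical constant
samples return p = 1. Tests run in 10-min windows — 15–25, 25–35, 35–45,
45–55 min, half-open so the list partitions 15–55 min — and are adjusted
by the Benjamini–Hochberg step-up across the windows of one comparison
(family size 4, or fewer when windows lack data; empty windows are
reported as missing, never silently dropped).

The unit of analysis defaults to the fly: each fly's per-frame measure
is pooled to one mean per window before ranking, avoiding
pseudo-replication across thousands of autocorrelated frames. A
per-frame mode exists for sensitivity analysis. Trend curves are lowess
(locally weighted linear regression) with span 0.25 of the data,
evaluated on a 200-point grid.

## Consumption

The dye assays are linear in the Beer–Lambert range, so the standard
curve is an ordinary least-squares line `signal = slope·amount +
intercept`; the fit warns below r² = 0.95. Quantification inverts the
curve, optionally after subtracting a blank signal, divides by flies
per well, and clamps negative inversions to 0 with a warning (signals
below the curve's zero point are reader noise around a blank). Rates
divide by the feeding duration in hours — 0.10 µL over 2 h is
0.05 µL/h. Dead or damaged wells are excluded through the plate map's
`alive` flag, which is scored visually at the bench, and every exclusion
is reported alongside the retained wells.

## Synthetic sessions

The generator emulates the NIR-backlit scene: uniform background
(intensity 200), one flat-shaded dark ellipse per well (half-axes
5 × 3 px, 80 levels dark), optional specks of 1–4 px (always below the
detector's 8 px minimum area), no motion blur or optics. Behavior is a
two-state Markov chain per fly, roam ↔ at-food, with per-frame
transition probabilities (defaults 0.01 and 0.005, i.e. mean roam and
feed dwells of ~3.3 s and ~6.7 s — busy enough to exercise every code
path in a 2-min session). While at food the centroid walks confined
inside the food circle shrunk by the blob half-extent + 1 px, and while
roaming it is reflected within the well and kept outside the circle
expanded by the same margin, so the ground-truth state and the
per-pixel enclosure flag agree by construction. An optional burst
overlay chops at-food periods into 27-frame on-blocks separated by
5-frame gaps, reproducing the sip-burst texture the bout denoiser is
built for, and a flip-noise helper corrupts flags at a stated rate.

The default test scale is 8 wells of 160 × 160 px for 2 min at 30 fps —
a desk-scale session that exercises the full pipeline in well under a
minute. Statistical calibration runs use flag-level chains only (no
rendering): 24 flies per group, 100 repeats, 35 min at 30 fps so that
the first two default test windows carry data; cohorts separated in
at-food occupancy 0.6 vs 0.1 (mean feed dwell 10 s) measure power, and
identical 0.35-occupancy cohorts measure size.

What the synthetic scenes deliberately omit — and what passing tests
therefore do not demonstrate about real video: nonuniform illumination
and vignetting, motion blur, flies climbing walls or hiding under the
port (persistent `found=False` stretches), multi-fly wells, moisture
fog, and inter-camera brightness differences beyond what the per-well
background model absorbs. Recovery rates on synthetic sessions are
upper bounds on real-data performance.

## Numerical and interface choices

- Layout JSON stores coordinates with `repr(float)`, so save→load
  round-trips are exact.
- All randomness flows through `numpy.random.default_rng` with explicit
  integer seeds; identical seeds give identical sessions, and rendering
  noise uses a stream derived from (seed, 1) so speck settings never
  perturb behavior.
- Binarization uses a strict inequality: intensity exactly equal to
  background − δ stays background.
- The CLI computes all output tables before writing any, so a failing
  stage leaves no partial CSVs; every run writes `provenance.json`
  (tool version + full config echo + seed).

## Known limitations

No Z-axis inference (distances are image-plane pixels, reported in
relative units when normalized), no multi-fly identity tracking within
a well, no sip-level event detection below the burst floor, and no
modeling of dye transit kinetics — the feeding/clearance schedule is a
wet-lab protocol, not computation. Container-video input depends on the
imageio plugins available in the environment; the image-sequence
directory format is the first-class input.
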