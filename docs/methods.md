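# Methods

## The detection problem

A rodent on an elevated platform is surrounded by monitors showing a
virtual cylinder of vertical sinusoidal stripes rotating at constant
speed. If the animal perceives the grating it tracks it with slow,
smooth head-and-neck movements in the stimulus direction. An overhead
camera films the platform; an operator keeps a red cross on the animal's
head. The task is to decide, per stimulus presentation, whether a
tracking movement occurred and in which direction.

Head shape is not constant in the image — the animal pitches its head up
and down, which changes its projected outline — so template correlation
and centroid trackers fail. The pipeline instead detects the *wake* of
the movement: the set of pixels that the (dark) head newly covers
relative to a short history of frames, analogous to a ship's wake betraying
its course.

## Pipeline

For frame *j* (RGB, any size ≥ the analysis window):

1. **Cross localisation.** The cross is the argmax of (red − green);
   ties break in row-major scan order, and a frame with no positive red
   surplus is flagged rather than failed. The cross is re-detected every
   frame (the operator moves it); a config switch freezes it at frame 0.
2. **Window.** The frame is converted to grayscale with the ITU-R BT.601
   luma weights (0.2989, 0.5870, 0.1140) and a 200 × 200 px window is cut
   around the cross. Near borders the window is shifted to stay inside
   the frame, never padded, so window statistics remain comparable. The
   10 previous grayscale frames are re-cropped at the *current* cross
   position.
3. **Wake image.** With A the current window and B the sum of the 10
   previous windows, each unit-maximum normalized (an all-zero raster
   maps to all-zero), the wake is
   `majority((B_norm − A_norm) > 0.25)`, where `majority` sets a pixel
   iff ≥ 5 of its 3×3 neighborhood (zero-padded at borders) are set.
   The positive difference selects pixels bright throughout the history
   and dark now, i.e. newly covered by the head. Frames 0–9 of a video
   have no full history and yield no classification.
4. **Object selection.** Wake pixels are partitioned into 8-connected
   components; each is summarised by its moment-equivalent ellipse (see
   below). A frame yields a tracking sample only when
   * no object at all has minor axis > 15 px (excessive-movement switch:
     whole-body motion, evaluated on the unfiltered object list),
   * after keeping objects with major axis > 30 px, minor axis in
     [3, 8) px and eccentricity > 0.99, **exactly one** object survives,
   * the surviving object's centroid radial coordinate (measured from
     the window origin; a config option re-bases it on the cross) changed
     by < 3 px against the last frame that produced a surviving object.
     The first surviving frame of a video is kept by convention. The gate
     uses the absolute difference; a config switch restores the literal
     signed comparison of the original formulation.
5. **Stimulus gating.** The series `sum(mean(history) − A)` (no
   unit-maximum normalization) spikes when the stimulus appears or
   disappears. Local maxima above median + 3·MAD whose prominence
   exceeds 18·MAD are taken as switches; consecutive peaks alternate
   on/off, an unpaired final peak opens an interval to the video end, and
   with no peaks the whole video counts as stimulus-on. The prominence
   requirement exists because plain median + 3·MAD is routinely exceeded
   by Gaussian baseline maxima (≈ 2σ), while genuine flashes are
   whole-window luminance steps orders of magnitude larger; a flash-free
   video must fall back to whole-on rather than fragment. Samples outside
   on-intervals are suppressed.
6. **Events.** Maximal runs of same-sign orientations are grouped,
   merging same-direction runs separated by ≤ 5 zero frames (the
   detector otherwise splits long bouts); runs shorter than 6 samples
   (0.2 s at 30 fps) are discarded. Positive orientation = clockwise,
   negative = counterclockwise; the magnitude carries no claim. An
   optional filter drops events contradicting a known stimulus direction
   (off by default).

## Moment-equivalent ellipse

For a pixel region, with x = column, y = −row (vertical axis up), the
second central moments are corrected by +1/12 per coordinate (each pixel
treated as a unit square):

    uxx = var(x) + 1/12,  uyy = var(y) + 1/12,  uxy = cov(x, y)

The ellipse with these normalized moments has

    common = sqrt((uxx − uyy)² + 4 uxy²)
    major  = 2√2 · sqrt(uxx + uyy + common)
    minor  = 2√2 · sqrt(uxx + uyy − common)
    ecc    = sqrt(1 − (minor/major)²)

and orientation in (−90°, 90°] from the branch arctangent of the
principal direction, positive counterclockwise. The +1/12 correction
matters: without it a single pixel has zero-length axes and the 3-px
minor-axis criterion would change meaning (a single pixel here has axes
2/√3 ≈ 1.1547). These conventions reproduce the environment the
selection thresholds were tuned in; the test suite checks them against
an independent eigendecomposition oracle to 10⁻⁹ relative error.

## Why [3, 8) px: stimulus-geometry calibration

With the wake center r = 50 px from the cross, one pixel of arc subtends
atan(1/50) ≈ 1.146°. A 12 deg/s stimulus at 0.0333 s/frame rotates
≈ 0.4°/frame, so a head tracking it sweeps 12 · 0.0333 · 10 ≈ 4.0° ≈
3.5 px over one 10-frame wake. Allowing for detection latency and
movement overshoot gives the working band: minor axis ≥ 3 px (below:
tremor) and < 8 px (above: gross movement), with > 15 px vetoing the
whole frame. `pixel_angle_scale`, `stimulus_rotation_per_frame` and
`expected_wake_minor_semiaxis` expose this arithmetic.

## Visual-function protocol math

* **Michelson contrast** (L_max − L_min)/(L_max + L_min); at the screen
  luminances 150 and 0.20 cd/m² this is 0.9973.
* **Contrast sensitivity** is the reciprocal of the lowest contrast that
  elicits tracking (CS 30 ↔ 3.3%).
* **Staircase.** VA: start at 0.042 cycles/deg (full contrast), step up
  by 0.150 cycles/deg until the first non-detection. CS: descend the
  ladder 100%, 75%, 50%, 25%, 12.5%, 6.2%, then continued halving.
  Afterwards the (last detected, first undetected) bracket is repeatedly
  bisected, re-labelling after each probe, until its width is at most the
  tolerance (default 0.01 cycles/deg, 0.005 contrast); the reported
  threshold is the last *detected* value, a conservative choice matching
  the definition of VA as the highest frequency still tracked. The
  bracket always contains the true threshold of a deterministic
  observer, so the error is bounded by the tolerance; bracket-width
  termination is this package's choice, as is the error raised when the
  observer never stops detecting within the probe budget.
* **Age trends.** Ordinary least squares (scipy.stats.linregress) with
  R² = 1 − SS_res/SS_tot. A zero-variance response is returned as a
  perfect horizontal fit (R² = 1) with a `degenerate` flag rather than a
  0/0; zero variance in age raises. On the wild-type group means
  (0.542, 0.539, 0.535 cycles/deg at P30/P90/P180) the fit prints as
  intercept 0.5433, slope −5 × 10⁻⁵/day at one significant figure,
  R² 0.9989.

## Synthetic scenes

The generator renders what the detector assumes: a dark elliptical head
(intensity 60) on a brighter platform (200), its center `head_offset` =
50 px from a drawn red cross, pointing radially away from it, swept about
the cross at the stimulus speed during a bout and static otherwise.
Edges get ~1 px analytic anti-aliasing so the 0.35 px/frame motion at
12 deg/s produces smooth intensity changes; i.i.d. Gaussian intensity
noise (σ = 3 on the 0–255 scale) is added per frame; the cross carries a
small green residue on its arms so the red−green argmax is unique at its
center. Defaults: 480 × 640 frames, 30 fps, 100 frames with one bout over
frames 20–79, bout speed easing in linearly over 8 frames.

Choices made where the design was open, and why:

* **Head semi-axes 25 × 6 px (radial × tangential).** The wake crescent
  of a wider head (e.g. 25 × 12) curves enough that its moment-ellipse
  minor axis (~8.8 px) and eccentricity (~0.986) fall outside the
  detector's own criteria; 25 × 6 yields wake minor axes of ~5.3–5.7 px
  and eccentricity ~0.994, comfortably inside the band the calibration
  arithmetic predicts.
* **Initial bearing north.** The wake ellipse is then near vertical, and
  clockwise vs counterclockwise sweeps land on opposite sides of the
  ±90° orientation wrap, so the *sign* of the orientation encodes the
  direction stably over tens of degrees of drift. (With an east-pointing
  head the sign would flip whenever the sweep crossed the horizontal.)
* **Speed ease-in.** A strict step to full speed is unphysical; the
  8-frame linear ramp also keeps the forming wake below the 3-px
  criterion while the history still contains the static head.
* **No stimulus flashes.** The default scene carries no on/off luminance
  steps, so the gating falls back to whole-video-on; the switch logic is
  exercised separately on constructed intensity series.

`perturb` injects the described failure modes: `rebound` (opposite
back-turn after the bout), `split` (motionless gaps inside a bout),
`tremor` (sub-criterion oscillation, default 0.5 px of arc), and
`translation` (whole-scene jump that trips the excessive-movement veto).
A `vertical_bob` parameter modulates the projected head size to emulate
up-down head movement.

What the generator does **not** emulate: fur texture, shadows and
illumination gradients, the body of the animal, spontaneous locomotion,
operator cross-placement error, and stimulus on/off flashes by default.
Passing tests therefore demonstrate the pipeline's logic and its
behavior under controlled geometry and noise — not performance on real
animal video, for which observer-annotated recordings remain necessary.

## Event-level evaluation

One annotated stimulus = one event. The detector's verdict for a
stimulus interval is the direction of the longest detected event
overlapping it (the detector may split one bout; the split affects
motion range, not presence or direction), or none. Verdict pairs map to
success (both none, or both tracking in the same direction), false
positive (software only), false negative (observer only) and wrong
(opposite directions) — an exhaustive and mutually exclusive taxonomy.
Percentages are reported with one decimal. Inter-observer agreement
splits disagreements into opposite-direction and presence components.

## Numerical and degenerate-input conventions

* Unit-maximum normalization guards all-zero rasters (no division).
* `connected_components` defaults to 8-connectivity; 4 is available.
* Orientation of a circularly symmetric region is reported as 0 (the
  branch formula's num = den = 0 case); tests compare orientations only
  when the axes differ.
* Event grouping: `min_len` = 6 frames. The wake needs `history_len`
  frames to form and to decay, and during those transients the crescent
  is thicker toward its outer end (linear velocity grows with radius),
  tilting its ellipse a few degrees toward the trailing side — so the
  first few samples of a bout can carry the opposite sign until the
  accumulated rotation overtakes the tilt. Runs shorter than about half
  the history are therefore formation artifacts, not bouts.
* Radial-gate state never expires: the "previous" radial coordinate is
  the last surviving wake's, however long ago.

## Known limitations

* Direction is read from the orientation *sign*, which only separates
  the two directions while the wake ellipse stays near the vertical; a
  rebound (opposite back-turn) is visible to the detector only once the
  head recrosses its starting bearing. The synthetic rebound scenes are
  set up accordingly.
* The published headline agreement rates (~78% software-observer, 91%
  between observers) were measured on rat videos that were never
  deposited; they are format examples here, not reproducible targets.
* The detector processes one marked animal; there is no multi-animal or
  cross-placement logic.
* Per-frame decision logging (`-vv`) reports which gate rejected each
  frame; it is diagnostic output, not part of the published algorithm.
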