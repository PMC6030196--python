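# oktrack

Objective detection of optokinetic tracking in rodents from overhead video.

Optokinetic tracking — the smooth, reflexive head movement a rodent makes
while following a rotating grating — is the standard behavioral readout of
visual acuity (VA) and contrast sensitivity (CS) in rats and mice, and the
workhorse test for models of retinal degeneration such as the pigmented
P23H rat. The test's weakness is that a human has to decide, stimulus by
stimulus, whether the animal tracked. `oktrack` replaces that judgment
with a deterministic image-analysis pipeline, and bundles the protocol
math and evaluation tools around it:

* **wake detection** — each frame is compared against the sum of its 10
  predecessors inside a 200 × 200 px window centered on the operator's red
  cross; pixels where the normalized history-minus-current difference
  exceeds 0.25 form the motion "wake", smoothed with a 3×3 majority filter:

  `WAKE = majority((B_norm − A_norm) > 0.25)`

* **morphological classification** — connected wake objects are reduced to
  their moment-equivalent ellipses; a frame yields a tracking sample only
  if **exactly one** object has major axis > 30 px, minor axis in [3, 8) px
  and eccentricity > 0.99, no object has minor axis > 15 px (whole-body
  motion veto), and the object's centroid radial coordinate moved < 3 px
  since the last wake;
* **direction calling** — the sign of the surviving ellipse's orientation
  over time gives the rotation direction (positive = clockwise), and
  contiguous same-sign samples are grouped into tracking events;
* **stimulus gating** — peaks of the un-normalized window intensity mark
  stimulus appearance/disappearance and restrict classification to
  stimulus-on intervals;
* **evaluation** — event-level comparison against observer annotations
  with the four-outcome taxonomy (success / false positive / false
  negative / wrong direction);
* **visual-function math** — Michelson contrast `(L_max − L_min)/(L_max +
  L_min)`, CS = 1/threshold, staircase (method-of-limits) threshold
  estimation, VA-versus-age least-squares trends, and the stimulus-geometry
  calibration that explains the 3–8 px wake criterion;
* **synthetic ground truth** — a scene generator that renders a dark
  head-like ellipse sweeping about a marked center at the stimulus speed,
  with per-frame ground truth, so the full pipeline is testable without
  animal data.

## Worked example

Generate a clockwise synthetic test video, run the detector, and check the
stimulus-geometry arithmetic:

```sh
$ oktrack synth --out demo_video --direction cw --seed 7
100 frames -> demo_video

$ oktrack track --video demo_video --out demo_out
1 event(s) -> demo_out
```

`demo_out/events.json` then contains

```json
{
  "events": [
    {
      "start_frame": 31,
      "end_frame": 81,
      "direction": "clockwise",
      "n_samples": 51,
      "mean_abs_orientation": 79.6173294791302
    }
  ],
  "on_intervals": [[10, 99]]
}
```

The generated bout spans frames 20–79; the detector reports it from frame
31 (the wake needs ~10 frames of history to form after motion starts) to
frame 81 (the wake takes a moment to unwind), in the correct direction.
`on_intervals` covers the whole analyzable range because this video has no
stimulus on/off luminance flashes. Per-frame orientations, centroids and
gate decisions are in `demo_out/samples.csv`.

```sh
$ oktrack calibrate
{
  "pixel_angle_scale_deg_per_px": 1.1458,
  "stimulus_rotation_per_frame_deg": 0.3996,
  "expected_wake_minor_semiaxis_px": 3.49
}
```

At the default geometry (head 50 px from the cross, 12 deg/s stimulus,
30 fps, 10-frame wake) one pixel of arc subtends ≈ 1.15°, the stimulus
rotates ≈ 0.4° between frames, and a tracking head should sweep ≈ 3.5 px
per wake — which is why wakes with a minor axis below 3 px are treated as
tremor and above 8 px as gross movement.

Other commands: `oktrack evaluate` (detector events vs observer CSV),
`oktrack staircase` (threshold demo on a simulated observer). The same
functionality is available as a library; see `docs/methods.md` for the
model details.

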