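"""Wake classification and direction calling.

Given the per-frame wake mask, the classifier keeps at most one candidate
object per frame and reads the tracking direction off the sign of its
moment-ellipse orientation over time:

1. excessive-movement switch — if ANY wake object (before filtering) has a
   minor axis > 15 px the whole frame is whole-body motion, not head
   tracking, and is discarded;
2. morphology — keep objects with major axis > 30 px and minor axis in
   [3, 8) px (the head sweep over a 10-frame wake at 12 deg/s produces a
   ~3.5 px minor semi-axis; smaller wakes are tremors, larger ones gross
   movements);
3. eccentricity — keep objects with eccentricity > 0.99 (the wake is a
   thin elongated sliver);
4. single-object control — if anything but exactly one object survives,
   the frame yields no sample;
5. radial gate — a head rotation keeps the wake centroid at a roughly
   constant radial coordinate, so samples whose radial coordinate jumps by
   >= 3 px against the previous surviving wake are rejected.

Positive orientation means clockwise tracking, negative counterclockwise;
only the sign is meaningful, not the magnitude.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np

from .imaging import RegionProperties, connected_components, region_properties, to_grayscale
from .wake import (
    CrossCenter,
    IntensitySample,
    build_wake,
    crop_window,
    detect_cross_center,
    read_frames,
    stimulus_switch,
)

__all__ = [
    "ClassifierConfig",
    "TrackingSample",
    "TrackingEvent",
    "TrackerResult",
    "select_wake_object",
    "selection_verdict",
    "radial_gate",
    "detect_events",
    "run_tracker",
]

log = logging.getLogger("oktrack.classify")

CLOCKWISE = "clockwise"
COUNTERCLOCKWISE = "counterclockwise"


@dataclass
class ClassifierConfig:
    """Thresholds of the wake classifier (pixel units unless noted)."""

    major_min: float = 30.0  # strict >
    minor_low: float = 3.0  # inclusive >=
    minor_high: float = 8.0  # strict <
    excessive_minor: float = 15.0  # strict >
    eccentricity_min: float = 0.99  # strict >
    radial_gate: float = 3.0  # strict <
    wake_threshold: float = 0.25
    history_len: int = 10
    window_size: int = 200
    connectivity: int = 8
    #: gate on |dR| (documented intent); False reproduces the literal
    #: signed comparison dR < radial_gate of the original script.
    absolute_radial_diff: bool = True
    #: measure the centroid radial coordinate from the window origin
    #: (script-literal) or from the cross at the window center.
    radial_origin: str = "window"  # "window" | "cross"
    #: re-detect the cross every frame; when False it is frozen at frame 0.
    track_cross: bool = True
    #: drop events whose direction contradicts a known stimulus direction.
    stimulus_direction_check: bool = False
    stimulus_direction: Optional[str] = None
    peak_gain: float = 3.0
    max_gap: int = 5
    min_len: int = 6

    def __post_init__(self) -> None:
        if not (0 < self.minor_low < self.minor_high <= self.excessive_minor):
            raise ValueError("need 0 < minor_low < minor_high <= excessive_minor")
        for name in ("major_min", "radial_gate", "wake_threshold", "eccentricity_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.history_len < 1 or self.window_size < 2:
            raise ValueError("history_len >= 1 and window_size >= 2 required")
        if self.radial_origin not in ("window", "cross"):
            raise ValueError("radial_origin must be 'window' or 'cross'")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, mapping: dict) -> "ClassifierConfig":
        known = {k: v for k, v in mapping.items() if k in cls.__dataclass_fields__}
        unknown = set(mapping) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)


@dataclass(frozen=True)
class TrackingSample:
    """Per-frame classifier verdict.

    ``orientation`` is 0 when no tracking was detected on the frame;
    ``gated`` marks samples rejected by the radial gate, ``stimulus_off``
    samples suppressed outside stimulus-on intervals.
    """

    frame_index: int
    orientation: float = 0.0
    centroid: Optional[tuple[float, float]] = None
    radial: float = 0.0
    gated: bool = False
    stimulus_off: bool = False

    @property
    def tracking(self) -> bool:
        return self.orientation != 0.0


@dataclass(frozen=True)
class TrackingEvent:
    """A contiguous bout of same-direction tracking samples."""

    start_frame: int
    end_frame: int
    direction: str
    n_samples: int
    mean_abs_orientation: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrackerResult:
    samples: list[TrackingSample]
    events: list[TrackingEvent]
    intensity: list[IntensitySample]
    on_intervals: list[tuple[int, int]]
    cross_centers: list[CrossCenter] = field(default_factory=list)


def selection_verdict(
    regions: Sequence[RegionProperties], config: ClassifierConfig | None = None
) -> tuple[Optional[RegionProperties], str]:
    """Selection result plus the gate that rejected the frame.

    Reasons: "selected", "empty", "excessive", "criteria" (nothing passed
    the axis/eccentricity filters), "multi-object".
    """
    config = config or ClassifierConfig()
    if not regions:
        return None, "empty"
    if any(r.minor_axis_length > config.excessive_minor for r in regions):
        return None, "excessive"
    candidates = [
        r
        for r in regions
        if r.major_axis_length > config.major_min
        and config.minor_low <= r.minor_axis_length < config.minor_high
        and r.eccentricity > config.eccentricity_min
    ]
    if len(candidates) == 1:
        return candidates[0], "selected"
    return None, "criteria" if not candidates else "multi-object"


def select_wake_object(
    regions: Sequence[RegionProperties], config: ClassifierConfig | None = None
) -> Optional[RegionProperties]:
    """Apply the morphological selection criteria to one frame's objects.

    The excessive-movement switch scans the *unfiltered* object list; the
    single-object control returns None unless exactly one candidate passes
    both the axis-length and eccentricity criteria.
    """
    return selection_verdict(regions, config)[0]


def radial_gate(
    sample: TrackingSample,
    previous_radial: Optional[float],
    config: ClassifierConfig | None = None,
) -> TrackingSample:
    """Zero a sample whose centroid radial coordinate jumped too far.

    ``previous_radial`` is the radial coordinate of the most recent frame
    that produced a surviving object, or None at the start of a video (the
    first surviving frame is kept by convention).
    """
    config = config or ClassifierConfig()
    if not sample.tracking or previous_radial is None:
        return sample
    diff = sample.radial - previous_radial
    if not config.absolute_radial_diff:
        passed = diff < config.radial_gate
    else:
        passed = abs(diff) < config.radial_gate
    if passed:
        return sample
    return replace(sample, orientation=0.0, gated=True)


def detect_events(
    samples: Sequence[TrackingSample], max_gap: int = 5, min_len: int = 6
) -> list[TrackingEvent]:
    """Group per-frame samples into direction-labelled tracking events.

    Maximal runs of nonzero-orientation samples with a consistent sign are
    found; same-direction runs separated by <= ``max_gap`` zero frames are
    merged (the detector otherwise splits long bouts); runs with fewer than
    ``min_len`` samples are discarded.

    The default ``min_len`` of 6 frames (0.2 s at 30 fps) is about half the
    wake history: the wake needs ``history_len`` frames to form and to
    unwind, and during those transients its ellipse orientation reflects
    the still-static history rather than the tracking direction, so
    shorter runs are formation artifacts (or rebound flicks), not bouts.
    """
    runs: list[list[TrackingSample]] = []
    for s in samples:
        if not s.tracking:
            continue
        if runs:
            prev = runs[-1][-1]
            same_sign = (s.orientation > 0) == (prev.orientation > 0)
            if same_sign and s.frame_index - prev.frame_index - 1 <= max_gap:
                runs[-1].append(s)
                continue
        runs.append([s])
    events = []
    for run in runs:
        if len(run) < min_len:
            continue
        direction = CLOCKWISE if run[0].orientation > 0 else COUNTERCLOCKWISE
        events.append(
            TrackingEvent(
                start_frame=run[0].frame_index,
                end_frame=run[-1].frame_index,
                direction=direction,
                n_samples=len(run),
                mean_abs_orientation=float(
                    np.mean([abs(s.orientation) for s in run])
                ),
            )
        )
    return events


def run_tracker(video, config: ClassifierConfig | None = None) -> TrackerResult:
    """Run the full detection pipeline on a video.

    Per frame: locate the cross, convert to grayscale, crop the analysis
    window (the 10-frame history is re-cropped at the current cross
    position), build the wake, label its objects, apply the selection
    criteria and the radial gate; then suppress samples outside
    stimulus-on intervals and group the survivors into events.  Output is
    deterministic for identical input.
    """
    config = config or ClassifierConfig()
    frames = read_frames(video)
    if len(frames) < config.history_len + 1:
        raise ValueError(
            f"video has {len(frames)} frames; need at least {config.history_len + 1}"
        )

    gray_history: deque[np.ndarray] = deque(maxlen=config.history_len)
    samples: list[TrackingSample] = []
    intensity: list[IntensitySample] = []
    cross_centers: list[CrossCenter] = []
    previous_radial: Optional[float] = None
    frozen_center: Optional[CrossCenter] = None

    for j, frame in enumerate(frames):
        frame = np.asarray(frame)
        if config.track_cross or frozen_center is None:
            center = detect_cross_center(frame, frame_index=j)
            if frozen_center is None:
                frozen_center = center
        if not config.track_cross:
            center = replace(frozen_center, frame_index=j)
        cross_centers.append(center)
        gray = to_grayscale(frame)

        if len(gray_history) == config.history_len:
            current_win = crop_window(gray, center, config.window_size)
            history_wins = [
                crop_window(g, center, config.window_size) for g in gray_history
            ]
            wake, isample = build_wake(
                current_win, history_wins, config.wake_threshold, frame_index=j
            )
            intensity.append(isample)
            regions = [
                region_properties(c)
                for c in connected_components(wake.mask, config.connectivity)
            ]
            selected, reason = selection_verdict(regions, config)
            if selected is not None:
                cx, cy = selected.centroid
                if config.radial_origin == "cross":
                    half = config.window_size / 2.0
                    cx, cy = cx - half, cy - half
                sample = TrackingSample(
                    frame_index=j,
                    orientation=selected.orientation,
                    centroid=selected.centroid,
                    radial=math.hypot(cx, cy),
                )
                sample = radial_gate(sample, previous_radial, config)
                previous_radial = sample.radial
                if sample.gated:
                    reason = "radial"
            else:
                sample = TrackingSample(frame_index=j)
            if log.isEnabledFor(logging.DEBUG):
                log.debug(
                    "frame %d: %s (%d wake object(s))", j, reason, len(regions)
                )
            samples.append(sample)
        gray_history.append(gray)

    on_intervals = stimulus_switch(intensity, peak_gain=config.peak_gain)
    samples = _suppress_off_stimulus(samples, on_intervals)
    events = detect_events(samples, max_gap=config.max_gap, min_len=config.min_len)
    if config.stimulus_direction_check and config.stimulus_direction:
        events = [e for e in events if e.direction == config.stimulus_direction]
    return TrackerResult(
        samples=samples,
        events=events,
        intensity=intensity,
        on_intervals=on_intervals,
        cross_centers=cross_centers,
    )


def _suppress_off_stimulus(
    samples: list[TrackingSample], on_intervals: list[tuple[int, int]]
) -> list[TrackingSample]:
    out = []
    for s in samples:
        if s.tracking and not any(a <= s.frame_index <= b for a, b in on_intervals):
            s = replace(s, orientation=0.0, stimulus_off=True)
        out.append(s)
    return out


def samples_to_frame(samples: Sequence[TrackingSample]):
    """Per-frame samples as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "frame_index": [s.frame_index for s in samples],
            "orientation_deg": [s.orientation for s in samples],
            "centroid_x": [s.centroid[0] if s.centroid else np.nan for s in samples],
            "centroid_y": [s.centroid[1] if s.centroid else np.nan for s in samples],
            "radial": [s.radial for s in samples],
            "gated": [s.gated for s in samples],
            "stimulus_off": [s.stimulus_off for s in samples],
        }
    )
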