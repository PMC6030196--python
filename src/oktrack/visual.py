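"""Visual-function protocol math: contrast, staircases, trends, calibration.

Visual acuity (VA) is the highest spatial frequency (cycles/deg) of a
full-contrast rotating grating that still elicits optokinetic tracking;
contrast sensitivity (CS) is the reciprocal of the lowest Michelson
contrast that does so at a fixed spatial frequency.  Both thresholds are
found with a method of limits: step the stimulus parameter until the
response flips, then repeatedly bisect the bracketing interval.

The calibration helpers relate the stimulus geometry to the expected wake
shape: with the head ~50 px from the rotation marker, one pixel of arc
subtends atan(1/50) ~ 1.15 deg, so a 12 deg/s stimulus followed for a
10-frame wake (0.333 s) sweeps ~3.5 px — the origin of the [3, 8) px
minor-axis selection criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import math

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationParams",
    "VisualThreshold",
    "AgeTrend",
    "michelson_contrast",
    "contrast_sensitivity",
    "staircase_threshold",
    "fit_age_trend",
    "pixel_angle_scale",
    "stimulus_rotation_per_frame",
    "expected_wake_minor_semiaxis",
]

#: Contrast ladder of the CS test, as fractions of the starting contrast:
#: 100%, 75%, 50%, 25%, 12.5%, 6.2%, then continued halving.
CONTRAST_LADDER = (1.0, 0.75, 0.5, 0.25, 0.125, 0.062)


@dataclass(frozen=True)
class CalibrationParams:
    """Stimulus/acquisition geometry (defaults: 12 deg/s cylinder, 30 fps,
    10-frame wake, head ~50 px from the red cross)."""

    stimulus_speed: float = 12.0  # deg/s
    frame_interval: float = 0.0333  # s
    wake_frames: int = 10
    cross_radius: float = 50.0  # px

    def __post_init__(self) -> None:
        if min(
            self.stimulus_speed, self.frame_interval, self.wake_frames, self.cross_radius
        ) <= 0:
            raise ValueError("all calibration parameters must be positive")


@dataclass(frozen=True)
class VisualThreshold:
    """A measured threshold; for kind='contrast', sensitivity = 1/value."""

    kind: str  # "acuity" | "contrast"
    value: float
    sensitivity: Optional[float] = None
    history: tuple = ()

    def history_to_csv(self, path) -> None:
        """Write the staircase session as a (value, detected) CSV."""
        import pandas as pd

        pd.DataFrame(self.history, columns=["value", "detected"]).to_csv(
            path, index=False
        )


@dataclass(frozen=True)
class AgeTrend:
    """OLS line value = slope*age + intercept with its R^2."""

    slope: float
    intercept: float
    r_squared: float
    degenerate: bool = False

    def to_json(self, path) -> None:
        import json
        from dataclasses import asdict
        from pathlib import Path

        Path(path).write_text(json.dumps(asdict(self), indent=2))


def michelson_contrast(l_max: float, l_min: float) -> float:
    """(L_max - L_min) / (L_max + L_min) of the grating luminances."""
    if l_min < 0 or l_max <= 0:
        raise ValueError("luminances must be non-negative with l_max > 0")
    if l_max < l_min:
        raise ValueError("l_max must be >= l_min")
    return (l_max - l_min) / (l_max + l_min)


def contrast_sensitivity(threshold: float) -> float:
    """Reciprocal of the contrast threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("contrast threshold must lie in (0, 1]")
    return 1.0 / threshold


def staircase_threshold(
    observer: Callable[[float], bool],
    start: float,
    step: float = 0.150,
    direction: str = "increase",
    tolerance: float = 0.01,
    kind: str = "acuity",
    max_steps: int = 200,
) -> VisualThreshold:
    """Method-of-limits threshold with a bisection refinement phase.

    Phase 1 moves the stimulus parameter from a detectable ``start`` until
    the first non-detection: for ``direction='increase'`` (VA) in fixed
    increments of ``step``; for ``direction='decrease'`` (CS) down the
    contrast ladder 100%, 75%, 50%, 25%, 12.5%, 6.2%, ... of ``start``.
    Phase 2 repeatedly probes the midpoint of the (last detected, first
    undetected) bracket, relabelling the bracket, until its width is
    <= ``tolerance``; the threshold reported is the last detected value.

    Raises RuntimeError if the observer never stops detecting within
    ``max_steps`` phase-1 probes (no threshold inside the tested range).
    """
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    if start <= 0 or step <= 0 or tolerance <= 0:
        raise ValueError("start, step and tolerance must be positive")
    history: list[tuple[float, bool]] = []

    def probe(v: float) -> bool:
        seen = bool(observer(v))
        history.append((v, seen))
        return seen

    if not probe(start):
        raise ValueError("starting stimulus must be detectable")

    detected = start
    undetected = None
    if direction == "increase":
        v = start
        for _ in range(max_steps):
            v = v + step
            if probe(v):
                detected = v
            else:
                undetected = v
                break
    else:
        ladder = [start * f for f in CONTRAST_LADDER[1:]]
        v = ladder[-1]
        while len(ladder) < max_steps:
            v = v / 2.0
            ladder.append(v)
        for v in ladder:
            if probe(v):
                detected = v
            else:
                undetected = v
                break
    if undetected is None:
        raise RuntimeError(
            "observer detected every probed stimulus; no threshold in range"
        )

    while abs(undetected - detected) > tolerance:
        mid = 0.5 * (detected + undetected)
        if probe(mid):
            detected = mid
        else:
            undetected = mid

    sensitivity = 1.0 / detected if kind == "contrast" else None
    return VisualThreshold(
        kind=kind, value=detected, sensitivity=sensitivity, history=tuple(history)
    )


def fit_age_trend(ages, values) -> AgeTrend:
    """Ordinary least-squares line through (age, VA) points.

    R^2 = 1 - SS_res/SS_tot; a zero-variance response (SS_tot = 0) is a
    perfect horizontal fit and is returned as R^2 = 1 with the
    ``degenerate`` flag set.
    """
    ages = np.asarray(ages, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if ages.shape != values.shape or ages.ndim != 1:
        raise ValueError("ages and values must be equal-length 1-D sequences")
    if len(ages) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(ages) == 0:
        raise ValueError("ages have zero variance; the slope is undefined")
    if np.ptp(values) == 0:
        return AgeTrend(slope=0.0, intercept=float(values[0]), r_squared=1.0,
                        degenerate=True)
    res = stats.linregress(ages, values)
    return AgeTrend(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def pixel_angle_scale(calib: CalibrationParams | None = None) -> float:
    """Degrees of head rotation per pixel of arc at the wake radius:
    atan(1 px / cross_radius).  ~1.15 deg/px at the default 50 px."""
    calib = calib or CalibrationParams()
    return math.degrees(math.atan(1.0 / calib.cross_radius))


def stimulus_rotation_per_frame(calib: CalibrationParams | None = None) -> float:
    """Stimulus rotation between consecutive frames, in degrees
    (~0.40 deg at 12 deg/s and 0.0333 s)."""
    calib = calib or CalibrationParams()
    return calib.stimulus_speed * calib.frame_interval


def expected_wake_minor_semiaxis(calib: CalibrationParams | None = None) -> float:
    """Expected minor semi-axis of the wake ellipse, in pixels.

    The stimulus (hence a tracking head) sweeps speed * interval * frames
    degrees over one wake; dividing by the per-pixel angle gives the arc
    length in pixels (~3.5 px at defaults), which is why wakes with a
    minor axis below 3 px are treated as tremor and above 8 px as gross
    movement.
    """
    calib = calib or CalibrationParams()
    sweep_deg = calib.stimulus_speed * calib.frame_interval * calib.wake_frames
    return sweep_deg / pixel_angle_scale(calib)
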