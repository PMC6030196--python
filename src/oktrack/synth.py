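"""Ground-truth synthetic video generator.

Renders the scene the tracker expects: an overhead view of a brighter
platform with a dark head-like ellipse whose center sits at a fixed radial
offset from a marked rotation center (the operator's red cross).  During a
tracking bout the head sweeps around that center at the stimulus speed,
leaving between frames exactly the curved intensity "wake" the detector
thresholds.  Every video comes with its frame-by-frame ground truth, so
each pipeline stage can be tested without animal data.

Geometry notes
--------------
* The head ellipse points radially (snout away from the rotation center),
  with its center ``head_offset`` px out — the published geometry puts the
  wake ~50 px from the cross.
* The default initial bearing is "north" (toward the top of the frame).
  The wake's moment ellipse is then near-vertical, and clockwise vs
  counterclockwise sweeps fall on opposite sides of the +/-90 deg
  orientation wrap, so the orientation *sign* encodes the direction
  stably over long sweeps (positive = clockwise, as the detector
  expects).
* Bearings are measured in degrees with the vertical image axis pointing
  up; "clockwise" is the direction an observer of the video sees, i.e.
  decreasing bearing.
* Edges are rendered with ~1 px analytic anti-aliasing so sub-pixel
  motion (0.35 px/frame at 12 deg/s) produces smooth intensity changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = ["SceneSpec", "GroundTruth", "generate_scene", "perturb", "write_frames"]

CLOCKWISE = "clockwise"
COUNTERCLOCKWISE = "counterclockwise"


@dataclass
class SceneSpec:
    """Parameters of one synthetic overhead scene.

    Defaults emulate the published acquisition: 480x640 frames at 30 fps,
    a 12 deg/s stimulus, the head ~50 px from the cross, and a 2 s
    tracking bout embedded in an otherwise static video.
    """

    frame_size: tuple[int, int] = (480, 640)  # (rows, cols)
    head_semi_axes: tuple[float, float] = (25.0, 6.0)  # (radial, tangential) px
    head_offset: float = 50.0  # px from rotation center
    angular_speed: float = 12.0  # deg/s
    direction: str = "none"  # clockwise | counterclockwise | none
    frame_rate: float = 30.0
    n_frames: int = 100
    motion_start: int = 20  # first frame of the bout
    motion_stop: int = 80  # first frame after the bout
    ramp_frames: int = 8  # linear speed ease-in at bout start (0 = step)
    initial_bearing: float = 90.0  # deg, y-up; 90 = toward top of frame
    vertical_bob: float = 0.0  # fractional head-size modulation amplitude
    bob_freq: float = 1.0  # Hz
    noise_sd: float = 3.0  # Gaussian intensity noise, 0-255 scale
    background_level: float = 200.0
    head_level: float = 60.0
    cross_arm: int = 5  # half-length of the red cross arms, px
    center: Optional[tuple[float, float]] = None  # rotation center (row, col)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.direction not in (CLOCKWISE, COUNTERCLOCKWISE, "none"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.head_level >= self.background_level:
            raise ValueError("head must be darker than the background")
        if self.center is None:
            self.center = (self.frame_size[0] / 2.0, self.frame_size[1] / 2.0)
        reach = self.head_offset + max(self.head_semi_axes) + 2
        r, c = self.center
        if (
            r - reach < 0
            or c - reach < 0
            or r + reach > self.frame_size[0]
            or c + reach > self.frame_size[1]
        ):
            raise ValueError("head geometry does not fit inside the frame")
        if not 0 < self.motion_start <= self.motion_stop <= self.n_frames:
            raise ValueError("need 0 < motion_start <= motion_stop <= n_frames")


@dataclass
class GroundTruth:
    """Per-frame truth accompanying a generated video."""

    bearing_deg: list[float]
    events: list[dict]  # {"start", "end", "direction"} (inclusive frames)
    cross_position: list[tuple[int, int]]  # (row, col) per frame
    frame_rate: float

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["cross_position"] = [tuple(p) for p in d["cross_position"]]
        return cls(**d)


def bearing_profile(spec: SceneSpec) -> np.ndarray:
    """Ground-truth head bearing per frame, degrees (y-up convention).

    The bout speed eases in linearly over ``ramp_frames`` (a head does not
    step to full speed instantaneously); past the ramp the increment is
    ``angular_speed / frame_rate`` per frame.
    """
    bearings = np.full(spec.n_frames, spec.initial_bearing, dtype=np.float64)
    if spec.direction == "none":
        return bearings
    step = spec.angular_speed / spec.frame_rate
    if spec.direction == CLOCKWISE:
        step = -step  # clockwise on screen = decreasing y-up bearing
    t = np.arange(spec.n_frames)
    in_bout = (t >= spec.motion_start) & (t < spec.motion_stop)
    factor = np.ones(spec.n_frames)
    if spec.ramp_frames > 0:
        factor = np.minimum((t - spec.motion_start + 1) / spec.ramp_frames, 1.0)
    increments = np.where(in_bout, step * factor, 0.0)
    return bearings + np.cumsum(increments)


def generate_scene(
    spec: SceneSpec, bearing_override: Optional[Sequence[float]] = None
) -> tuple[list[np.ndarray], GroundTruth]:
    """Render the frame sequence and its ground truth.

    Deterministic for a given spec (and seed).  ``bearing_override``
    substitutes an arbitrary per-frame bearing profile (used by
    :func:`perturb`); the ground-truth events are then derived from it.
    """
    if bearing_override is not None:
        bearings = np.asarray(bearing_override, dtype=np.float64)
        if len(bearings) != spec.n_frames:
            raise ValueError("bearing override length must equal n_frames")
    else:
        bearings = bearing_profile(spec)
    rng = np.random.default_rng(spec.rng_seed)
    frames = []
    cross_rc = (int(round(spec.center[0])), int(round(spec.center[1])))
    dt = 1.0 / spec.frame_rate
    for j in range(spec.n_frames):
        scale = 1.0
        if spec.vertical_bob:
            scale = 1.0 + spec.vertical_bob * np.sin(
                2.0 * np.pi * spec.bob_freq * j * dt
            )
        frames.append(_render_frame(spec, bearings[j], scale, rng))
    truth = GroundTruth(
        bearing_deg=[float(b) for b in bearings],
        events=_events_from_bearings(bearings),
        cross_position=[cross_rc] * spec.n_frames,
        frame_rate=spec.frame_rate,
    )
    return frames, truth


def _events_from_bearings(bearings: np.ndarray, tol: float = 1e-9) -> list[dict]:
    """Contiguous constant-sign motion intervals of a bearing profile.

    Frame j is "moving" when the bearing changes from j-1 to j; an event's
    start is the first moving frame.
    """
    db = np.diff(bearings)
    events = []
    current = None
    for j, d in enumerate(db, start=1):
        if abs(d) <= tol:
            sign = 0
        else:
            sign = 1 if d > 0 else -1
        if current is not None and sign == current["sign"]:
            current["end"] = j
            continue
        if current is not None and current["sign"] != 0:
            events.append(current)
        current = {"start": j, "end": j, "sign": sign}
    if current is not None and current["sign"] != 0:
        events.append(current)
    return [
        {
            "start": e["start"],
            "end": e["end"],
            "direction": COUNTERCLOCKWISE if e["sign"] > 0 else CLOCKWISE,
        }
        for e in events
        if e["sign"] != 0
    ]


def _render_frame(
    spec: SceneSpec, bearing_deg: float, head_scale: float, rng: np.random.Generator
) -> np.ndarray:
    h, w = spec.frame_size
    gray = np.full((h, w), spec.background_level, dtype=np.float64)
    if spec.noise_sd > 0:
        gray += rng.normal(0.0, spec.noise_sd, size=(h, w))

    # Head ellipse center in (row, col); bearing measured y-up.
    th = np.deg2rad(bearing_deg)
    cr = spec.center[0] - spec.head_offset * np.sin(th)
    cc = spec.center[1] + spec.head_offset * np.cos(th)
    a1 = spec.head_semi_axes[0] * head_scale  # radial
    a2 = spec.head_semi_axes[1] * head_scale  # tangential

    pad = int(np.ceil(max(a1, a2) + 3))
    r0, r1 = max(int(cr) - pad, 0), min(int(cr) + pad + 1, h)
    c0, c1 = max(int(cc) - pad, 0), min(int(cc) + pad + 1, w)
    rr, cc_grid = np.mgrid[r0:r1, c0:c1]
    # Local math coordinates relative to the head center.
    x = cc_grid - cc
    y = -(rr - cr)
    ur, vr = np.cos(th), np.sin(th)  # radial unit vector (x, y)
    pu = x * ur + y * vr  # radial component
    pv = -x * vr + y * ur  # tangential component
    g = np.sqrt((pu / a1) ** 2 + (pv / a2) ** 2)
    # ~1 px analytic anti-aliasing from the gradient of the implicit fn.
    with np.errstate(divide="ignore", invalid="ignore"):
        grad = np.sqrt((pu / a1**2) ** 2 + (pv / a2**2) ** 2) / np.maximum(g, 1e-9)
    coverage = np.clip(0.5 - (g - 1.0) / np.maximum(grad, 1e-9), 0.0, 1.0)
    patch = gray[r0:r1, c0:c1]
    gray[r0:r1, c0:c1] = patch + (spec.head_level - spec.background_level) * coverage

    gray = np.clip(gray, 0, 255)
    frame = np.repeat(gray[:, :, None], 3, axis=2)

    # Red cross at the rotation center.  Arms carry a small green residue
    # so that red - green peaks uniquely at the center pixel (argmax
    # detection would otherwise tie along the arms).
    crr, crc = int(round(spec.center[0])), int(round(spec.center[1]))
    arm = spec.cross_arm
    rs = slice(max(crr - arm, 0), min(crr + arm + 1, h))
    cs = slice(max(crc - arm, 0), min(crc + arm + 1, w))
    for channel, arm_val, center_val in ((0, 255.0, 255.0), (1, 40.0, 0.0), (2, 0.0, 0.0)):
        frame[rs, crc, channel] = arm_val
        frame[crr, cs, channel] = arm_val
        frame[crr, crc, channel] = center_val
    return frame.astype(np.uint8)


def perturb(spec: SceneSpec, mode: str, **params) -> tuple[list[np.ndarray], GroundTruth]:
    """Generate a scene with one of the described failure modes injected.

    rebound      : after the bout, a short opposite-direction turn
                   (``rebound_frames``, default 12; same speed).
    split        : motionless gaps inside the bout (``gap_starts`` frame
                   offsets from motion_start, ``gap_len`` frames each).
    tremor       : replaces the bout with a small oscillation of amplitude
                   ``amplitude_px`` (default 0.5) of arc at the head
                   offset, period ``period_frames`` (default 6).
    translation  : whole-body jump — the entire scene (head + cross)
                   shifts by ``shift_px`` (default 30) columns at frame
                   ``at_frame`` (default mid-bout).
    """
    if mode == "rebound":
        n_reb = int(params.get("rebound_frames", 12))
        bearings = bearing_profile(spec)
        step = spec.angular_speed / spec.frame_rate
        if spec.direction == CLOCKWISE:
            step = -step
        stop = spec.motion_stop
        for k in range(n_reb):
            j = stop + k
            if j >= spec.n_frames:
                break
            bearings[j:] -= step  # opposite direction
        return generate_scene(spec, bearing_override=bearings)
    if mode == "split":
        gap_starts = params.get("gap_starts", (20,))
        gap_len = int(params.get("gap_len", 4))
        bearings = bearing_profile(spec)
        for g in gap_starts:
            j0 = spec.motion_start + int(g)
            j1 = min(j0 + gap_len, spec.n_frames)
            if j0 >= spec.n_frames:
                continue
            hold = bearings[j0 - 1]
            shift = bearings[j1 - 1] - hold if j1 <= spec.n_frames else 0.0
            bearings[j0:j1] = hold
            bearings[j1:] -= shift
        return generate_scene(spec, bearing_override=bearings)
    if mode == "tremor":
        amp_px = float(params.get("amplitude_px", 0.5))
        period = int(params.get("period_frames", 6))
        amp_deg = np.rad2deg(amp_px / spec.head_offset)
        bearings = np.full(spec.n_frames, spec.initial_bearing)
        t = np.arange(spec.n_frames)
        osc = amp_deg * np.sin(2.0 * np.pi * t / period)
        moving = (t >= spec.motion_start) & (t < spec.motion_stop)
        bearings = bearings + np.where(moving, osc, 0.0)
        frames, truth = generate_scene(spec, bearing_override=bearings)
        truth.events = []  # oscillation is sub-criterion noise, not tracking
        return frames, truth
    if mode == "translation":
        shift = int(params.get("shift_px", 30))
        at = int(params.get("at_frame", (spec.motion_start + spec.motion_stop) // 2))
        frames, truth = generate_scene(spec)
        shifted = []
        for j, f in enumerate(frames):
            if j >= at:
                f = np.roll(f, shift, axis=1)
                if shift > 0:
                    f[:, :shift] = f[:, shift : shift + 1]
                else:
                    f[:, shift:] = f[:, shift - 1 : shift]
            shifted.append(f)
        truth.cross_position = [
            (r, c + shift) if j >= at else (r, c)
            for j, (r, c) in enumerate(truth.cross_position)
        ]
        return shifted, truth
    raise ValueError(f"unknown perturbation mode {mode!r}")


def write_frames(frames: Sequence[np.ndarray], outdir) -> list[Path]:
    """Write frames as numbered PNGs readable by the tracker."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for j, frame in enumerate(frames):
        p = outdir / f"frame_{j:05d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths
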