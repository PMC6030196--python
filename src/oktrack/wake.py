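"""Per-frame front end: red-cross localisation, window cropping, wake images.

A rodent is filmed from above while an operator keeps a red cross on its
head.  Motion between a frame and its recent history leaves a "wake":
pixels that were background over most of the last 10 frames but are covered
by the (dark) head now.  The wake is the only motion signature the
classifier sees, which makes the method robust to the vertical head
movements that defeat correlation- and centroid-based trackers.

Pipeline per frame j (with a 10-frame history of cropped grayscale windows):

    A      = cropped gray frame j                 A_norm = A / max(A)
    B      = sum of the 10 previous windows       B_norm = B / max(B)
    WAKE   = majority_smooth((B_norm - A_norm) > threshold)

The un-normalised intensity series sum(mean(history) - A) spikes when the
stimulus appears or disappears on the surrounding monitors; those peaks act
as a control switch restricting classification to stimulus-on intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import find_peaks

from .imaging import majority_smooth

__all__ = [
    "CrossCenter",
    "WakeImage",
    "IntensitySample",
    "detect_cross_center",
    "crop_window",
    "build_wake",
    "stimulus_switch",
    "read_frames",
]


@dataclass(frozen=True)
class CrossCenter:
    """Position of the operator's red cross in full-frame coordinates."""

    row: int
    col: int
    frame_index: int = 0
    #: False when no red surplus exists anywhere (max(red - green) <= 0);
    #: the argmax position is still reported, per the degenerate-tie rule.
    marker_found: bool = True

    @property
    def position(self) -> tuple[int, int]:
        return (self.row, self.col)


@dataclass(frozen=True)
class WakeImage:
    """Binary wake mask for one frame, in window coordinates."""

    mask: np.ndarray
    frame_index: int


@dataclass(frozen=True)
class IntensitySample:
    """sum(mean(history) - current) over the window — zero on a static scene."""

    frame_index: int
    total_intensity: float


def detect_cross_center(frame: np.ndarray, frame_index: int = 0) -> CrossCenter:
    """Locate the red cross as the argmax of (red - green).

    Ties are broken in row-major scan order (first occurrence).  When the
    maximum is <= 0 the frame carries no red marker; the position is still
    returned with ``marker_found=False`` rather than failing.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB frame, got {frame.shape}")
    diff = frame[..., 0].astype(np.int64) - frame[..., 1].astype(np.int64)
    flat = int(np.argmax(diff))
    row, col = np.unravel_index(flat, diff.shape)
    return CrossCenter(
        row=int(row),
        col=int(col),
        frame_index=frame_index,
        marker_found=bool(diff[row, col] > 0),
    )


def crop_window(
    gray: np.ndarray, center: CrossCenter | tuple[int, int], window_size: int = 200
) -> np.ndarray:
    """Crop a square window around the cross, clamped inside the frame.

    The window is shifted (never padded) when the cross sits near a border,
    so the output is always ``window_size`` x ``window_size``.
    """
    gray = np.asarray(gray)
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    h, w = gray.shape[:2]
    if h < window_size or w < window_size:
        raise ValueError(
            f"frame ({h}x{w}) smaller than window ({window_size}x{window_size})"
        )
    row, col = center.position if isinstance(center, CrossCenter) else center
    half = window_size // 2
    r0 = int(np.clip(row - half, 0, h - window_size))
    c0 = int(np.clip(col - half, 0, w - window_size))
    return gray[r0 : r0 + window_size, c0 : c0 + window_size]


def _unit_norm(raster: np.ndarray) -> np.ndarray:
    m = raster.max()
    if m <= 0:
        return np.zeros_like(raster, dtype=np.float64)
    return raster.astype(np.float64) / m


def build_wake(
    current: np.ndarray,
    history: Sequence[np.ndarray],
    threshold: float = 0.25,
    frame_index: int = 0,
) -> tuple[WakeImage, IntensitySample]:
    """Build the wake mask and intensity sample for one frame.

    ``history`` holds the 10 previous cropped grayscale windows (most
    recent last; order is immaterial since only the sum is used).  Both the
    current window and the history sum are unit-max normalised before
    differencing, so the wake is invariant to global intensity scaling; an
    all-zero raster normalises to all-zero rather than dividing by zero.
    """
    current = np.asarray(current, dtype=np.float64)
    if not history:
        raise ValueError("history of previous windows is required")
    for hframe in history:
        if np.asarray(hframe).shape != current.shape:
            raise ValueError("history window shape mismatch with current window")
    b = np.sum(np.asarray(history, dtype=np.float64), axis=0)
    diff = _unit_norm(b) - _unit_norm(current)
    wake = majority_smooth(diff > threshold)
    total = float(np.sum(b / len(history) - current))
    return (
        WakeImage(mask=wake, frame_index=frame_index),
        IntensitySample(frame_index=frame_index, total_intensity=total),
    )


def stimulus_switch(
    series: Sequence[IntensitySample], peak_gain: float = 3.0
) -> list[tuple[int, int]]:
    """Infer stimulus-on frame intervals from intensity peaks.

    Peaks are strict local maxima exceeding median + ``peak_gain`` * MAD of
    the series; consecutive peaks alternate stimulus appearance and
    disappearance (an unpaired final peak opens an interval lasting to the
    end).  With no peaks the entire video is treated as stimulus-on.

    Stimulus flashes raise the summed window intensity far above the
    baseline (a whole-window luminance step), while baseline noise maxima
    sit only a few MAD up.  Peaks are therefore additionally required to
    have a prominence of at least 6*``peak_gain``*MAD — far beyond what
    Gaussian baseline fluctuations reach, and far below any real on/off
    flash — so a flash-free noisy series cleanly falls back to
    whole-video-on.

    Returns a list of inclusive ``(on_start, on_end)`` frame-index pairs.
    """
    if len(series) < 3:
        raise ValueError("intensity series must have at least 3 samples")
    frames = np.array([s.frame_index for s in series])
    values = np.array([s.total_intensity for s in series], dtype=np.float64)
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    peaks, _ = find_peaks(
        values, height=med + peak_gain * mad, prominence=6.0 * peak_gain * mad
    )
    if len(peaks) == 0:
        return [(int(frames[0]), int(frames[-1]))]
    intervals: list[tuple[int, int]] = []
    for i in range(0, len(peaks) - 1, 2):
        intervals.append((int(frames[peaks[i]]), int(frames[peaks[i + 1]])))
    if len(peaks) % 2 == 1:
        intervals.append((int(frames[peaks[-1]]), int(frames[-1])))
    return intervals


# ---------------------------------------------------------------------------
# Frame input


_FRAME_EXTS = (".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg")


def read_frames(source) -> list[np.ndarray]:
    """Materialise a video as a list of (H, W, 3) uint8 frames.

    Accepts an ndarray stack ``(T, H, W, 3)``, an iterable of frames, a
    directory of numbered image frames, or a video file (the latter needs
    an imageio video plugin such as ffmpeg to be available).
    """
    if isinstance(source, np.ndarray):
        if source.ndim != 4 or source.shape[3] != 3:
            raise ValueError("frame stack must have shape (T, H, W, 3)")
        return list(source)
    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.is_dir():
            files = sorted(
                p for p in path.iterdir() if p.suffix.lower() in _FRAME_EXTS
            )
            if not files:
                raise ValueError(f"no image frames found in {path}")
            import imageio.v3 as iio

            return [_ensure_rgb(iio.imread(p)) for p in files]
        if not path.exists():
            raise FileNotFoundError(path)
        try:
            import imageio.v3 as iio

            return [_ensure_rgb(f) for f in iio.imiter(path)]
        except Exception as exc:  # no video plugin, corrupt file, ...
            raise ValueError(
                f"could not read video file {path}: {exc}; "
                "a directory of PNG frames is always supported"
            ) from exc
    if isinstance(source, Iterable):
        return [_ensure_rgb(np.asarray(f)) for f in source]
    raise TypeError(f"unsupported video source: {type(source)!r}")


def _ensure_rgb(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 2:
        frame = np.stack([frame] * 3, axis=-1)
    if frame.ndim == 3 and frame.shape[2] == 4:
        frame = frame[..., :3]
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"cannot interpret frame of shape {frame.shape} as RGB")
    return frame
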