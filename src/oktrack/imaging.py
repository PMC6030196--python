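"""Binary-image primitives with MATLAB-compatible conventions.

The original detector was built on MATLAB's Image Processing Toolbox,
and its selection thresholds were tuned under that toolbox's conventions,
which differ from the usual Python ones in three places that matter:

* ``rgb2gray`` uses the ITU-R BT.601 luma weights (0.2989, 0.5870, 0.1140),
  not the BT.709 weights used by scikit-image.
* ``regionprops`` adds a +1/12 per-pixel extent correction to each variance
  term before deriving the moment-equivalent ellipse, so a single pixel has
  axes of length 2/sqrt(3) ~ 1.1547 rather than 0.  The 3-px minor-axis
  selection criterion depends on this convention.
* ``Orientation`` is measured from the horizontal axis with the vertical
  image coordinate treated as pointing up, in degrees in (-90, 90].

These functions reproduce that behaviour exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "BT601_WEIGHTS",
    "RegionProperties",
    "to_grayscale",
    "majority_smooth",
    "connected_components",
    "region_properties",
]

#: ITU-R BT.601 luma weights for (red, green, blue); they sum to 0.9999
#: exactly as in MATLAB's rgb2gray.
BT601_WEIGHTS = (0.2989, 0.5870, 0.1140)

_STRUCTURE_8 = np.ones((3, 3), dtype=bool)
_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class RegionProperties:
    """Shape descriptors of one connected pixel region.

    The ellipse quantities refer to the ellipse with the same normalized
    second central moments as the region (with the +1/12 per-pixel
    correction).  ``centroid`` is ``(x, y)`` = (column, row), 0-based.
    """

    area: int
    major_axis_length: float
    minor_axis_length: float
    eccentricity: float
    orientation: float
    centroid: tuple[float, float]


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Convert an RGB raster to grayscale with the BT.601 luma weights.

    Parameters
    ----------
    frame : ndarray, shape (H, W, 3)
        Channel order (red, green, blue); any numeric dtype.

    Returns
    -------
    ndarray, shape (H, W), float64
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(
            f"expected an (H, W, 3) RGB raster, got shape {frame.shape}"
        )
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite intensities")
    w = np.asarray(BT601_WEIGHTS, dtype=np.float64)
    # Renormalize so achromatic input is exactly invariant (the weights sum
    # to 0.9999; MATLAB's integer rounding hides the difference).
    w = w / w.sum()
    return frame.astype(np.float64) @ w


def majority_smooth(mask: np.ndarray) -> np.ndarray:
    """Majority morphological filter on a binary mask.

    A pixel of the output is 1 iff at least 5 of the 9 pixels in its 3x3
    neighborhood (itself included; out-of-bounds neighbors count as 0) are
    1 — MATLAB's ``bwmorph(..., 'majority')``.
    """
    mask = _as_binary(mask)
    counts = ndimage.convolve(
        mask.astype(np.uint8), np.ones((3, 3), dtype=np.uint8), mode="constant", cval=0
    )
    return counts >= 5


def connected_components(mask: np.ndarray, connectivity: int = 8) -> list[np.ndarray]:
    """Partition the 1-pixels of a binary mask into connected components.

    Returns a list of ``(n_i, 2)`` integer arrays of (row, col) coordinates,
    one per component, in label-scan order.  Default connectivity is 8
    (MATLAB's ``bwconncomp`` default).
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    mask = _as_binary(mask)
    structure = _STRUCTURE_8 if connectivity == 8 else _STRUCTURE_4
    labels, n = ndimage.label(mask, structure=structure)
    return [np.argwhere(labels == i) for i in range(1, n + 1)]


def region_properties(coords: np.ndarray) -> RegionProperties:
    """Moment-equivalent-ellipse descriptors of one pixel region.

    Parameters
    ----------
    coords : (N, 2) array of integer (row, col) pixel coordinates.

    Notes
    -----
    Each pixel is treated as a unit square, adding 1/12 to each variance
    term.  Orientation is the angle (degrees, in (-90, 90]) between the
    horizontal axis and the ellipse major axis, positive when the major
    axis is tilted counterclockwise with the vertical image coordinate
    pointing up.
    """
    coords = np.asarray(coords)
    if coords.size == 0:
        raise ValueError("empty region")
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (N, 2) array of (row, col) pairs")

    rows = coords[:, 0].astype(np.float64)
    cols = coords[:, 1].astype(np.float64)
    # Math coordinates: x right, y up.
    x = cols
    y = -rows
    xbar = x.mean()
    ybar = y.mean()
    dx = x - xbar
    dy = y - ybar
    uxx = (dx @ dx) / len(x) + 1.0 / 12.0
    uyy = (dy @ dy) / len(y) + 1.0 / 12.0
    uxy = (dx @ dy) / len(x)

    common = math.sqrt((uxx - uyy) ** 2 + 4.0 * uxy**2)
    major = 2.0 * math.sqrt(2.0) * math.sqrt(uxx + uyy + common)
    minor = 2.0 * math.sqrt(2.0) * math.sqrt(max(uxx + uyy - common, 0.0))
    ecc = math.sqrt(1.0 - (minor / major) ** 2)

    # MATLAB's branch formula; note atan (not atan2) so the result stays in
    # (-90, 90], with the den == 0 limit mapping to +/-90.
    if uyy > uxx:
        num = uyy - uxx + common
        den = 2.0 * uxy
    else:
        num = 2.0 * uxy
        den = uxx - uyy + common
    if num == 0.0 and den == 0.0:
        orientation = 0.0
    elif den == 0.0:
        orientation = 90.0 if num > 0 else -90.0
    else:
        orientation = math.degrees(math.atan(num / den))

    return RegionProperties(
        area=int(len(x)),
        major_axis_length=major,
        minor_axis_length=minor,
        eccentricity=ecc,
        orientation=orientation,
        centroid=(float(cols.mean()), float(rows.mean())),
    )


def _as_binary(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype == bool:
        return mask
    uniq = np.unique(mask)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError("mask values must be in {0, 1}")
    return mask.astype(bool)
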