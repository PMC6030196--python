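"""Imaging primitives against closed forms and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oktrack.imaging import (
    connected_components,
    majority_smooth,
    region_properties,
    to_grayscale,
)

SINGLE_PIXEL_AXIS = 2.0 / math.sqrt(3.0)  # moment ellipse of one unit square


# ---------------------------------------------------------------------------
# oracles


def flood_fill_components(mask, connectivity=8):
    """Brute-force BFS partition of a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(mask)
    comps = []
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if not mask[r, c] or seen[r, c]:
                continue
            stack, comp = [(r, c)], set()
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                comp.add((rr, cc))
                for dr, dc in nbrs:
                    r2, c2 = rr + dr, cc + dc
                    if (
                        0 <= r2 < mask.shape[0]
                        and 0 <= c2 < mask.shape[1]
                        and mask[r2, c2]
                        and not seen[r2, c2]
                    ):
                        seen[r2, c2] = True
                        stack.append((r2, c2))
            comps.append(comp)
    return comps


def moment_ellipse_oracle(coords):
    """Axes/eccentricity/orientation from an eigendecomposition of the
    corrected second-central-moment matrix (independent of the branch
    formula used by the implementation)."""
    coords = np.asarray(coords, dtype=float)
    x = coords[:, 1]
    y = -coords[:, 0]
    cov = np.cov(np.stack([x, y]), bias=True) + np.eye(2) / 12.0
    evals, evecs = np.linalg.eigh(cov)
    major = 4.0 * math.sqrt(evals[1])
    minor = 4.0 * math.sqrt(evals[0])
    vx, vy = evecs[:, 1]
    theta = math.degrees(math.atan2(vy, vx))
    if theta <= -90.0:
        theta += 180.0
    elif theta > 90.0:
        theta -= 180.0
    ecc = math.sqrt(1.0 - (minor / major) ** 2)
    return major, minor, ecc, theta


def majority_oracle(mask):
    mask = np.asarray(mask, dtype=int)
    padded = np.pad(mask, 1)
    out = np.zeros_like(mask)
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            out[r, c] = padded[r : r + 3, c : c + 3].sum() >= 5
    return out.astype(bool)


# ---------------------------------------------------------------------------
# grayscale


def test_grayscale_achromatic_identity():
    for v in (0, 17, 128, 255):
        frame = np.full((4, 5, 3), v, dtype=np.uint8)
        assert np.allclose(to_grayscale(frame), v)


def test_grayscale_pure_red_bt601():
    frame = np.zeros((2, 2, 3), dtype=np.uint8)
    frame[..., 0] = 255
    assert int(round(to_grayscale(frame)[0, 0])) == 76


def test_grayscale_rejects_non_rgb():
    with pytest.raises(ValueError):
        to_grayscale(np.zeros((4, 5)))
    with pytest.raises(ValueError):
        to_grayscale(np.zeros((4, 5, 4)))


# ---------------------------------------------------------------------------
# majority smoothing


def test_majority_isolated_pixel_removed():
    mask = np.zeros((5, 5), dtype=bool)
    mask[2, 2] = True
    assert not majority_smooth(mask).any()


def test_majority_3x3_block_becomes_plus():
    mask = np.zeros((7, 7), dtype=bool)
    mask[2:5, 2:5] = True
    out = majority_smooth(mask)
    # center and edge-centers survive (>=5 neighbors); corners (4) do not
    expected = np.zeros_like(mask)
    expected[3, 3] = True
    expected[2, 3] = expected[4, 3] = expected[3, 2] = expected[3, 4] = True
    assert np.array_equal(out, expected)


def test_majority_matches_exhaustive_oracle(rng):
    for _ in range(20):
        mask = rng.random((12, 15)) < 0.5
        assert np.array_equal(majority_smooth(mask), majority_oracle(mask))


@pytest.mark.parametrize(
    "shape",
    ["rect4", "rect57", "disk4"],
)
def test_majority_idempotent_on_solid_blobs(shape):
    mask = np.zeros((15, 15), dtype=bool)
    if shape == "rect4":
        mask[3:7, 3:7] = True
    elif shape == "rect57":
        mask[3:8, 3:10] = True
    else:
        rr, cc = np.mgrid[0:15, 0:15]
        mask = (rr - 7) ** 2 + (cc - 7) ** 2 <= 16
    once = majority_smooth(mask)
    assert np.array_equal(majority_smooth(once), once)


# ---------------------------------------------------------------------------
# connected components


def test_components_empty_mask():
    assert connected_components(np.zeros((4, 4), dtype=bool)) == []


def test_components_diagonal_connectivity():
    mask = np.zeros((4, 4), dtype=bool)
    mask[1, 1] = mask[2, 2] = True
    assert len(connected_components(mask, connectivity=8)) == 1
    assert len(connected_components(mask, connectivity=4)) == 2


@pytest.mark.parametrize("connectivity", [4, 8])
def test_components_match_flood_fill(rng, connectivity):
    for _ in range(10):
        mask = rng.random((20, 20)) < 0.35
        got = {frozenset(map(tuple, comp)) for comp in connected_components(mask, connectivity)}
        want = {frozenset(comp) for comp in flood_fill_components(mask, connectivity)}
        assert got == want


# ---------------------------------------------------------------------------
# region properties


def test_single_pixel_region():
    rp = region_properties(np.array([[7, 3]]))
    assert rp.area == 1
    assert rp.major_axis_length == pytest.approx(SINGLE_PIXEL_AXIS, abs=1e-12)
    assert rp.minor_axis_length == pytest.approx(SINGLE_PIXEL_AXIS, abs=1e-12)
    assert rp.eccentricity == 0.0
    assert rp.centroid == (3.0, 7.0)


def test_horizontal_line_region():
    coords = np.array([[5, c] for c in range(10)])
    rp = region_properties(coords)
    # uxx = (10^2 - 1)/12 + 1/12, uyy = 1/12 -> major = 2*sqrt(2)*sqrt(uxx + uyy + (uxx - uyy))
    assert rp.major_axis_length == pytest.approx(math.sqrt(8 * 200 / 12), rel=1e-12)
    assert rp.major_axis_length == pytest.approx(11.547, abs=1e-3)
    assert rp.minor_axis_length == pytest.approx(SINGLE_PIXEL_AXIS, abs=1e-12)
    assert rp.eccentricity == pytest.approx(0.99499, abs=1e-5)
    assert rp.orientation == 0.0


def test_vertical_line_orientation_is_90():
    coords = np.array([[r, 4] for r in range(12)])
    assert region_properties(coords).orientation == 90.0


def test_3x30_rectangle():
    coords = np.array([[r, c] for r in range(3) for c in range(30)])
    rp = region_properties(coords)
    assert rp.major_axis_length == pytest.approx(34.64, abs=0.01)
    assert rp.minor_axis_length == pytest.approx(3.464, abs=0.001)
    assert rp.eccentricity == pytest.approx(0.99499, abs=1e-5)


def test_empty_region_rejected():
    with pytest.raises(ValueError):
        region_properties(np.empty((0, 2)))


def test_region_properties_match_eigen_oracle(rng):
    """Implementation vs an independent eigendecomposition, 100 random masks."""
    checked = 0
    while checked < 100:
        mask = rng.random((12, 12)) < 0.3
        comps = connected_components(mask)
        for coords in comps:
            rp = region_properties(coords)
            major, minor, ecc, theta = moment_ellipse_oracle(coords)
            assert rp.major_axis_length == pytest.approx(major, rel=1e-9)
            assert rp.minor_axis_length == pytest.approx(minor, rel=1e-9)
            assert rp.eccentricity == pytest.approx(ecc, abs=1e-9)
            if major - minor > 1e-9:  # orientation undefined for circles
                assert rp.orientation == pytest.approx(theta, abs=1e-6)
        checked += len(comps)


def test_rotation_by_90_swaps_orientation_only(rng):
    for _ in range(20):
        mask = rng.random((9, 9)) < 0.4
        if not mask.any():
            continue
        coords = np.argwhere(mask)
        rp = region_properties(coords)
        # rotate 90 deg counterclockwise: (r, c) -> (n-1-c, r)
        rot = np.stack([mask.shape[1] - 1 - coords[:, 1], coords[:, 0]], axis=1)
        rq = region_properties(rot)
        assert rq.area == rp.area
        assert rq.major_axis_length == pytest.approx(rp.major_axis_length, rel=1e-12)
        assert rq.minor_axis_length == pytest.approx(rp.minor_axis_length, rel=1e-12)
        assert rq.eccentricity == pytest.approx(rp.eccentricity, abs=1e-12)
        if rp.major_axis_length - rp.minor_axis_length > 1e-9:
            expected = rp.orientation + 90.0
            if expected > 90.0:
                expected -= 180.0
            assert rq.orientation == pytest.approx(expected, abs=1e-6)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.sets(
        st.tuples(st.integers(0, 14), st.integers(0, 14)), min_size=1, max_size=40
    )
)
def test_region_invariants_hold_for_arbitrary_pixel_sets(pixels):
    """Axis ordering, eccentricity range, orientation range, translation
    invariance of the shape descriptors."""
    coords = np.array(sorted(pixels))
    rp = region_properties(coords)
    assert rp.area == len(pixels)
    assert rp.major_axis_length >= rp.minor_axis_length > 0
    assert 0.0 <= rp.eccentricity < 1.0
    assert -90.0 < rp.orientation <= 90.0
    shifted = region_properties(coords + [7, 11])
    assert shifted.major_axis_length == pytest.approx(rp.major_axis_length, rel=1e-12)
    assert shifted.orientation == pytest.approx(rp.orientation, abs=1e-9)


def test_eccentricity_identity(rng):
    for _ in range(30):
        mask = rng.random((8, 8)) < 0.45
        for coords in connected_components(mask):
            rp = region_properties(coords)
            expected = math.sqrt(
                1.0 - (rp.minor_axis_length / rp.major_axis_length) ** 2
            )
            assert rp.eccentricity == pytest.approx(expected, abs=1e-14)
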