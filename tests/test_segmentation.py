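"""Boundary search: contrast enhancement, gradient costs, shortest paths."""
import dataclasses
import itertools

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from choroquant import (
    SegmentationConfig,
    enhance_contrast,
    gradient_cost,
    segment_choroid,
    shortest_path_boundary,
)
from tests.conftest import noise_free_bscan


# -- enhance_contrast -------------------------------------------------------

def test_clahe_constant_image_unchanged():
    img = np.full((64, 64), 0.4)
    np.testing.assert_array_equal(enhance_contrast(img), img)


def test_clahe_output_range():
    rng = np.random.default_rng(0)
    img = rng.uniform(0, 1, (80, 120))
    out = enhance_contrast(img, tile_px=32)
    assert out.min() >= 0.0 and out.max() <= 1.0


def test_clahe_preserves_step_contrast():
    img = np.zeros((64, 64))
    img[32:] = 1.0
    out = enhance_contrast(img, tile_px=64, clip_limit=1.0)
    assert out[40:].min() - out[:24].max() >= 0.9  # step not washed out


# -- gradient_cost ----------------------------------------------------------

def test_gradient_cost_locates_step_edge():
    img = np.zeros((30, 8))
    img[15:] = 1.0  # dark above, bright below
    cost = gradient_cost(img, "dark-to-bright", sigma_px=1.0)
    rows = cost.argmin(axis=0)
    assert np.all(np.abs(rows - 14.5) <= 1.0)


def test_gradient_cost_polarity_flip():
    img = np.zeros((30, 8))
    img[:15] = 1.0  # bright above, dark below
    cost = gradient_cost(img, "bright-to-dark", sigma_px=1.0)
    rows = cost.argmin(axis=0)
    assert np.all(np.abs(rows - 14.5) <= 1.0)


def test_gradient_cost_matches_finite_difference_oracle():
    rng = np.random.default_rng(3)
    img = rng.uniform(0, 1, (6, 6))
    sm = gaussian_filter(img, 1.5, mode="nearest")
    # brute-force central differences, one cell at a time
    grad = np.empty_like(sm)
    for c in range(6):
        grad[0, c] = sm[1, c] - sm[0, c]
        grad[5, c] = sm[5, c] - sm[4, c]
        for r in range(1, 5):
            grad[r, c] = (sm[r + 1, c] - sm[r - 1, c]) / 2.0
    expected = grad.max() - grad
    np.testing.assert_allclose(
        gradient_cost(img, "dark-to-bright", sigma_px=1.5), expected, atol=1e-12
    )


# -- shortest_path_boundary -------------------------------------------------

def _enumerate_min_cost(cost, max_jump):
    rows, cols = cost.shape
    best = np.inf
    for path in itertools.product(range(rows), repeat=cols):
        if any(abs(path[i + 1] - path[i]) > max_jump for i in range(cols - 1)):
            continue
        best = min(best, sum(cost[path[i], i] for i in range(cols)))
    return best


def test_shortest_path_follows_zero_row():
    cost = np.full((12, 9), 5.0)
    cost[7] = 0.0
    np.testing.assert_array_equal(shortest_path_boundary(cost, 2), np.full(9, 7))


def test_shortest_path_worked_example():
    cost = np.array([[1, 9, 9, 1], [9, 1, 1, 9], [5, 5, 5, 5]], dtype=float)
    path = shortest_path_boundary(cost, max_jump=1)
    np.testing.assert_array_equal(path, [0, 1, 1, 0])
    assert cost[path, np.arange(4)].sum() == 4


def test_shortest_path_single_column():
    cost = np.array([[3.0], [1.0], [2.0]])
    np.testing.assert_array_equal(shortest_path_boundary(cost, 1), [1])


@pytest.mark.parametrize("max_jump", [1, 2])
@pytest.mark.parametrize("seed", range(6))
def test_shortest_path_equals_exhaustive_enumeration(seed, max_jump):
    rng = np.random.default_rng(seed)
    rows, cols = rng.integers(2, 7, size=2)
    cost = rng.uniform(0, 10, (rows, cols))
    path = shortest_path_boundary(cost, max_jump)
    assert np.all(np.abs(np.diff(path)) <= max_jump)
    total = cost[path, np.arange(cols)].sum()
    assert total == pytest.approx(_enumerate_min_cost(cost, max_jump))


def test_shortest_path_rejects_bad_input():
    with pytest.raises(ValueError):
        shortest_path_boundary(np.empty((0, 0)), 1)
    with pytest.raises(ValueError):
        shortest_path_boundary(np.array([[1.0, -2.0]]), 1)
    with pytest.raises(ValueError):  # fully masked column
        shortest_path_boundary(np.array([[np.inf], [np.inf]]), 1)


# -- segment_choroid --------------------------------------------------------

def test_segmentation_accuracy_noise_free(small_cohort):
    """Both boundaries land within 2 px RMS of truth on clean sections."""
    cfg = SegmentationConfig().scaled(0.5)
    err_up, err_lo = [], []
    for e in small_cohort:
        for angle in (0, 90):
            scan = noise_free_bscan(e, angle)
            seg = segment_choroid(scan, cfg)
            gt = scan.ground_truth
            err_up.append(seg.upper_row - gt.upper_row)
            err_lo.append(seg.lower_row - gt.lower_row)
    for err in (np.concatenate(err_up), np.concatenate(err_lo)):
        assert np.sqrt((err.astype(float) ** 2).mean()) <= 2.0


def test_segmentation_translation_equivariance(eye):
    """Shifting the tissue down by k rows shifts both boundaries by k."""
    cfg = dataclasses.replace(SegmentationConfig().scaled(0.5), use_clahe=False)
    scan = noise_free_bscan(eye, 0)
    base = segment_choroid(scan, cfg)

    k = 20
    shifted_pixels = np.empty_like(scan.pixels)
    shifted_pixels[k:] = scan.pixels[:-k]
    shifted_pixels[:k] = scan.pixels[0]  # extend vitreous upward
    shifted = dataclasses.replace(scan, pixels=shifted_pixels)
    moved = segment_choroid(shifted, cfg)
    np.testing.assert_array_equal(moved.upper_row, base.upper_row + k)
    np.testing.assert_array_equal(moved.lower_row, base.lower_row + k)


def test_segmentation_invariants_hold(eye):
    cfg = SegmentationConfig().scaled(0.5)
    seg = segment_choroid(noise_free_bscan(eye, 30), cfg)
    assert np.all(seg.upper_row < seg.lower_row)
    assert np.all(np.abs(np.diff(seg.lower_row)) <= cfg.max_jump)
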