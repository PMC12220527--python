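"""Speckle statistics, frame averaging and the signal-strength index."""
import dataclasses

import numpy as np
import pytest

from choroquant import acquire_bscan, signal_strength, simulate_frame
from choroquant.acquisition import _display_compress, frame_seed_sequence
from choroquant.config import AcquisitionParams
from choroquant.phantom import render_radial_section


def _params(**kw):
    base = dict(speckle_corr_px=0.0, read_noise_sd=0.0, jitter_sd_um=0.0, seed=5)
    base.update(kw)
    return AcquisitionParams(**base)


def test_speckle_is_unit_mean():
    s = np.full((200, 200), 0.6)
    frame = simulate_frame(s, _params(), frame_seed=1)
    assert frame.mean() == pytest.approx(0.36, rel=0.02)


def test_single_frame_speckle_contrast_is_unity():
    """Fully developed speckle: SD equals mean in a homogeneous region."""
    s = np.full((100, 100), 0.5)
    vals = np.concatenate(
        [simulate_frame(s, _params(), frame_seed=i).ravel() for i in range(3)]
    )
    contrast = vals.std() / vals.mean()
    assert contrast == pytest.approx(1.0, abs=0.05)


def test_zero_reflectivity_gives_zero_frame():
    frame = simulate_frame(np.zeros((10, 10)), _params(), frame_seed=0)
    assert np.all(frame == 0.0)


def test_averaging_follows_inverse_sqrt_n():
    """Residual contrast of an N-frame average scales as N^(-1/2)."""
    s = np.full((150, 150), 0.5)
    contrasts = {}
    for n in (4, 64):
        acc = np.zeros_like(s)
        for i in range(n):
            acc += simulate_frame(s, _params(), frame_seed=1000 * n + i)
        avg = acc / n
        contrasts[n] = avg.std() / avg.mean()
    ratio = contrasts[64] / contrasts[4]
    assert ratio == pytest.approx(0.25, rel=0.20)


def test_acquire_single_frame_matches_simulate(eye):
    refl, gt = render_radial_section(eye, 0, 12.6, 40.0)
    params = _params(n_frames=1)
    scan = acquire_bscan(refl, gt, params, axial_um=12.6, lateral_um=40.0)
    frame = simulate_frame(refl, params, frame_seed_sequence(params.seed, 0))
    np.testing.assert_allclose(scan.pixels, _display_compress(frame, params))


def test_acquire_is_deterministic(eye):
    refl, gt = render_radial_section(eye, 0, 12.6, 40.0)
    params = _params(n_frames=4)
    a = acquire_bscan(refl, gt, params, axial_um=12.6, lateral_um=40.0)
    b = acquire_bscan(refl, gt, params, axial_um=12.6, lateral_um=40.0)
    np.testing.assert_array_equal(a.pixels, b.pixels)


def test_different_seeds_share_ground_truth_without_jitter(eye):
    refl, gt = render_radial_section(eye, 0, 12.6, 40.0)
    a = acquire_bscan(refl, gt, _params(n_frames=4, seed=1),
                      axial_um=12.6, lateral_um=40.0)
    b = acquire_bscan(refl, gt, _params(n_frames=4, seed=2),
                      axial_um=12.6, lateral_um=40.0)
    np.testing.assert_array_equal(a.ground_truth.lower_row, b.ground_truth.lower_row)
    assert not np.array_equal(a.pixels, b.pixels)


def test_averaging_is_mean_preserving():
    """The expected averaged intensity equals the single-frame expectation."""
    s = np.full((120, 120), 0.5)
    acc = np.zeros_like(s)
    for i in range(32):
        acc += simulate_frame(s, _params(), frame_seed=i)
    assert (acc / 32).mean() == pytest.approx(0.25, rel=0.02)


def test_signal_strength_bounds_and_monotonicity(eye):
    refl, gt = render_radial_section(eye, 0, 12.6, 40.0)
    noise_free = acquire_bscan(refl, gt, _params(n_frames=1), axial_um=12.6,
                               lateral_um=40.0)
    clean = dataclasses.replace(noise_free, pixels=_display_compress(refl**2,
                                                                     _params()))
    assert signal_strength(clean) == pytest.approx(10.0, abs=0.3)

    strengths = {}
    for n in (4, 64):
        vals = []
        for seed in range(3):
            p = AcquisitionParams(n_frames=n, jitter_sd_um=0.0, seed=seed)
            vals.append(acquire_bscan(refl, gt, p, axial_um=12.6,
                                      lateral_um=40.0).signal_strength)
        strengths[n] = np.mean(vals)
    assert 0.0 <= strengths[4] <= 10.0
    assert strengths[64] >= strengths[4]


def test_signal_strength_floors_at_zero():
    noisy = np.random.default_rng(0).uniform(0, 1, (100, 100))
    from choroquant.acquisition import BScan

    scan = BScan(pixels=noisy, axial_um=12.6, lateral_um=40.0, angle_deg=0, n_avg=1)
    assert signal_strength(scan, sigma_ref=0.01) == 0.0
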