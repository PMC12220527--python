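"""Speckle, frame averaging and display formation for simulated B-scans.

The simulator implements fully developed speckle: per-frame intensity is
``I = S^2 * E`` with ``E`` unit-mean exponential, optionally spatially
correlated by Gaussian filtering (renormalised back to unit mean), plus
additive read noise clipped at zero.  Averaging N independent frames drops
the speckle contrast of a homogeneous region by 1/sqrt(N), which is the
physical lever behind the whole frame-averaging study.  The averaged
intensity is log-compressed for display, as is conventional for OCT.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import AcquisitionParams
from .phantom import GroundTruth

# sub-stream tags of the per-acquisition seed
_JITTER_STREAM = 0
_FRAME_STREAM = 1


@dataclass
class BScan:
    """One display-scaled averaged B-scan with acquisition metadata."""

    pixels: np.ndarray  # (rows, cols) float in [0, 1]
    axial_um: float
    lateral_um: float
    angle_deg: int
    n_avg: int
    signal_strength: float = float("nan")
    eye_id: str = ""
    repeat_id: int = 0
    seed: int = 0
    jitter_cols: int = 0
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if not np.all(np.isfinite(px)) or px.min() < 0:
            raise ValueError("B-scan pixels must be finite and non-negative")


def frame_seed_sequence(seed: int, frame_index: int) -> np.random.SeedSequence:
    """Seed of frame ``frame_index`` within the acquisition seeded ``seed``."""
    return np.random.SeedSequence([int(seed), _FRAME_STREAM, int(frame_index)])


def simulate_frame(reflectivity, params: AcquisitionParams, frame_seed) -> np.ndarray:
    """One raw speckled intensity frame from a noise-free reflectivity map.

    ``frame_seed`` may be an int or a :class:`numpy.random.SeedSequence`.
    """
    s = np.asarray(reflectivity, dtype=float)
    if s.min() < 0:
        raise ValueError("reflectivity must be non-negative")
    rng = np.random.default_rng(frame_seed)
    e = rng.exponential(1.0, size=s.shape)
    if params.speckle_corr_px > 0:
        e = gaussian_filter(e, params.speckle_corr_px, mode="reflect")
        e /= e.mean()
    i = s**2 * e
    if params.read_noise_sd > 0:
        i = i + rng.normal(0.0, params.read_noise_sd, size=s.shape)
    return np.clip(i, 0.0, None)


def _display_compress(intensity, params: AcquisitionParams) -> np.ndarray:
    scale = np.log1p(params.display_ref / params.log_eps)
    d = np.log1p(intensity / params.log_eps) / scale
    return np.clip(d, 0.0, 1.0)


def _shift_columns(arr, shift: int):
    """Shift columns by ``shift`` (positive = rightward), replicating edges."""
    if shift == 0:
        return arr.copy()
    idx = np.clip(np.arange(arr.shape[-1]) - shift, 0, arr.shape[-1] - 1)
    return arr[..., idx]


def acquire_bscan(
    reflectivity,
    ground_truth: Optional[GroundTruth],
    params: AcquisitionParams,
    *,
    axial_um: float,
    lateral_um: float,
    angle_deg: int = 0,
    eye_id: str = "",
    repeat_id: int = 0,
) -> BScan:
    """Average ``params.n_frames`` speckled frames into one display B-scan.

    One lateral fixation offset (drawn per acquisition, rounded to whole
    columns) is shared by all frames; frames are otherwise independent.
    The returned scan carries the jitter-shifted ground truth when one is
    supplied, and its signal-strength index.
    """
    params.validate()
    s = np.asarray(reflectivity, dtype=float)
    jit_rng = np.random.default_rng(
        np.random.SeedSequence([int(params.seed), _JITTER_STREAM])
    )
    jitter_cols = 0
    if params.jitter_sd_um > 0:
        jitter_cols = int(round(jit_rng.normal(0.0, params.jitter_sd_um) / lateral_um))
    s_shift = _shift_columns(s, jitter_cols)

    n = params.n_frames
    # per-frame seeds; the Gaussian correlation filter is applied to the
    # whole stack at once (axis 0 untouched), bit-identical to per-frame calls
    rngs = [np.random.default_rng(frame_seed_sequence(params.seed, i)) for i in range(n)]
    e = np.empty((n,) + s_shift.shape)
    for i, rng in enumerate(rngs):
        e[i] = rng.exponential(1.0, size=s_shift.shape)
    if params.speckle_corr_px > 0:
        e = gaussian_filter(e, (0, params.speckle_corr_px, params.speckle_corr_px),
                            mode="reflect")
        e /= e.mean(axis=(1, 2), keepdims=True)
    i_stack = s_shift[None] ** 2 * e
    if params.read_noise_sd > 0:
        for i, rng in enumerate(rngs):
            i_stack[i] += rng.normal(0.0, params.read_noise_sd, size=s_shift.shape)
    i_avg = np.clip(i_stack, 0.0, None).mean(axis=0)

    gt = None
    if ground_truth is not None:
        gt = GroundTruth(
            upper_row=_shift_columns(ground_truth.upper_row, jitter_cols),
            lower_row=_shift_columns(ground_truth.lower_row, jitter_cols),
            lumen_mask=_shift_columns(ground_truth.lumen_mask, jitter_cols),
        )
    scan = BScan(
        pixels=_display_compress(i_avg, params),
        axial_um=axial_um,
        lateral_um=lateral_um,
        angle_deg=angle_deg,
        n_avg=n,
        eye_id=eye_id,
        repeat_id=repeat_id,
        seed=int(params.seed),
        jitter_cols=jitter_cols,
        ground_truth=gt,
    )
    scan.signal_strength = signal_strength(
        scan, sigma_ref=params.sigma_ref, bg_rows_frac=params.bg_rows_frac
    )
    return scan


def signal_strength(bscan: BScan, sigma_ref: float = 0.25,
                    bg_rows_frac: float = 0.08) -> float:
    """Device-style 0–10 quality index from residual vitreous noise.

    ``10 * clip(1 - sd_background / sigma_ref, 0, 1)`` where the background
    SD is measured over the top rows of the image (vitreous).  Acquisitions
    scoring below 6 are conventionally excluded and retaken.
    """
    rows = max(2, int(bg_rows_frac * bscan.pixels.shape[0]))
    sd_bg = float(np.std(bscan.pixels[:rows]))
    return 10.0 * float(np.clip(1.0 - sd_bg / sigma_ref, 0.0, 1.0))
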