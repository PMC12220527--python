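"""Niblack local thresholding of the segmented choroid.

Lumina appear dark and stroma bright on OCT, so the classic Niblack rule
``T(x, y) = m(x, y) + k * s(x, y)`` with a negative ``k`` separates the two
compartments: pixels strictly below their local threshold are luminal.
Window statistics are exact (box filtering with reflect padding), not
integral-image approximations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .segmentation import ChoroidSegmentation
from .volumetrics import LUMEN, OUTSIDE, STROMA


@dataclass(frozen=True)
class BinaryChoroidMask:
    """Per-pixel labels inside the choroid band: 0 lumen, 1 stroma, 2 outside."""

    labels: np.ndarray
    window_px: int
    k: float
    eye_id: str = ""
    repeat_id: int = 0
    n_avg: int = 0

    @property
    def lumen_count(self) -> int:
        return int((self.labels == LUMEN).sum())

    @property
    def stroma_count(self) -> int:
        return int((self.labels == STROMA).sum())

    @property
    def inside_count(self) -> int:
        return int((self.labels != OUTSIDE).sum())


def niblack_threshold_map(image, window_px: int, k: float) -> np.ndarray:
    """Exact per-pixel Niblack threshold ``m + k*s`` over a centred window.

    ``s`` is the population SD over the ``window_px`` x ``window_px``
    neighbourhood with reflect padding at the borders.
    """
    img = np.asarray(image, dtype=float)
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    if window_px > min(img.shape):
        raise ValueError(
            f"window {window_px} larger than image {img.shape}"
        )
    m = uniform_filter(img, window_px, mode="reflect")
    m2 = uniform_filter(img * img, window_px, mode="reflect")
    s = np.sqrt(np.clip(m2 - m * m, 0.0, None))
    return m + k * s


def binarize_choroid(image, seg: ChoroidSegmentation, window_px: int = 31,
                     k: float = -0.2, **provenance) -> BinaryChoroidMask:
    """Classify choroid pixels into lumen (dark) and stroma (bright).

    Threshold statistics are computed on the full image so border windows
    are well defined; the strict inequality ``pixel < T`` sends constant
    regions to stroma.
    """
    img = np.asarray(image, dtype=float)
    upper = np.asarray(seg.upper_row)
    lower = np.asarray(seg.lower_row)
    if img.shape[1] != upper.shape[0]:
        raise ValueError("image and segmentation have mismatched columns")
    if np.all(lower <= upper):
        raise ValueError("degenerate segmentation: empty choroid band")
    t_map = niblack_threshold_map(img, window_px, k)
    depth_idx = np.arange(img.shape[0])[:, None]
    inside = (depth_idx >= upper[None, :]) & (depth_idx < lower[None, :])
    labels = np.full(img.shape, OUTSIDE, dtype=np.uint8)
    labels[inside] = np.where(img[inside] < t_map[inside], LUMEN, STROMA)
    return BinaryChoroidMask(labels=labels, window_px=window_px, k=k, **provenance)
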