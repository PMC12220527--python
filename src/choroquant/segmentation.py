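"""Choroidal boundary segmentation: CLAHE, gradient costs, shortest paths.

The upper boundary (RPE-Bruch's membrane junction) is found as the lower
edge of the brightest ridge in the image; the lower boundary (the
choroidal-scleral interface, CSI) as the strongest gradient edge of the
configured polarity inside a depth window below the upper boundary.  Both
searches are exact column-to-column dynamic programs with a bounded
per-column jump, i.e. discrete shortest paths across the image.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import exposure

from .acquisition import BScan
from .config import SegmentationConfig

_BIG = np.inf


@dataclass(frozen=True)
class ChoroidSegmentation:
    """Per-column boundary rows; the choroid band is [upper_row, lower_row)."""

    upper_row: np.ndarray
    lower_row: np.ndarray
    max_jump: int = 2
    #: True when the interface was judged indistinct and re-called
    #: conservatively (the low-confidence path of the CSI search)
    low_confidence: bool = False

    def __post_init__(self):
        up = np.asarray(self.upper_row)
        lo = np.asarray(self.lower_row)
        if up.shape != lo.shape:
            raise ValueError("boundary arrays must have equal length")
        if np.any(up >= lo):
            bad = np.nonzero(up >= lo)[0]
            raise ValueError(f"upper boundary at/below lower boundary at columns {bad[:5]}")
        for b in (up, lo):
            if np.any(np.abs(np.diff(b)) > self.max_jump):
                raise ValueError("boundary violates the max_jump smoothness bound")

    @property
    def thickness_px(self) -> np.ndarray:
        return np.asarray(self.lower_row) - np.asarray(self.upper_row)


def enhance_contrast(image, tile_px: int = 64, clip_limit: float = 0.01) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation on a [0, 1] image."""
    img = np.asarray(image, dtype=float)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("expected a grayscale image in [0, 1]")
    if np.ptp(img) == 0:
        return img.copy()
    kernel = (min(tile_px, img.shape[0]), min(tile_px, img.shape[1]))
    return exposure.equalize_adapthist(img, kernel_size=kernel, clip_limit=clip_limit)


def gradient_cost(image, polarity: str = "dark-to-bright", sigma_px: float = 2.0) -> np.ndarray:
    """Non-negative cost map whose minima lie on edges of one polarity.

    The image is Gaussian-smoothed at ``sigma_px`` and differentiated along
    rows (central differences); the signed gradient is flipped according to
    ``polarity`` and subtracted from its maximum so costs are >= 0.
    """
    img = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    smoothed = gaussian_filter(img, sigma_px, mode="nearest") if sigma_px > 0 else img
    grad = np.gradient(smoothed, axis=0)
    if polarity == "dark-to-bright":
        signed = grad
    elif polarity == "bright-to-dark":
        signed = -grad
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    return signed.max() - signed


def shortest_path_boundary(cost, max_jump: int = 2) -> np.ndarray:
    """Exact minimum-cost left-to-right path with bounded row jumps.

    Minimises ``sum_c cost[row_c, c]`` over all paths with
    ``|row_{c+1} - row_c| <= max_jump``; start and end rows are free.
    Dynamic programming; ties resolved toward the smaller row index.
    Columns whose cost is entirely infinite are inadmissible.
    """
    c = np.asarray(cost, dtype=float)
    if c.ndim != 2 or c.size == 0:
        raise ValueError("cost must be a non-empty 2D map")
    if np.any(np.isnan(c)) or np.any(c < 0):
        raise ValueError("cost must be non-negative and NaN-free")
    if max_jump < 1:
        raise ValueError("max_jump must be >= 1")
    rows, cols = c.shape
    bad = np.nonzero(~np.isfinite(c).any(axis=0))[0]
    if bad.size:
        raise ValueError(f"no admissible path: columns {bad[:8].tolist()} fully masked")

    offsets = range(-max_jump, max_jump + 1)
    dist = c[:, 0].copy()
    ptr = np.zeros((cols, rows), dtype=np.int8)
    for col in range(1, cols):
        # candidate predecessor values, ordered by increasing predecessor row
        stack = np.full((2 * max_jump + 1, rows), _BIG)
        for k, d in enumerate(offsets):
            lo, hi = max(0, -d), rows - max(0, d)
            stack[k, lo:hi] = dist[lo + d : hi + d]
        best = stack.argmin(axis=0)  # first minimum = smallest predecessor row
        dist = stack[best, np.arange(rows)] + c[:, col]
        ptr[col] = best - max_jump
    path = np.empty(cols, dtype=int)
    path[-1] = int(dist.argmin())  # first minimum = smallest row
    for col in range(cols - 1, 0, -1):
        path[col - 1] = path[col] + ptr[col, path[col]]
    return path


def _gauss_kernel(sigma_px: float) -> np.ndarray:
    n = int(np.ceil(4 * max(sigma_px, 0.5))) + 2
    x = np.arange(-n, n + 1)
    g = np.exp(-0.5 * (x / max(sigma_px, 1e-6)) ** 2)
    return g / g.sum()


def _gradient_noise_gain(sigma_ax_px: float, sigma_lat_px: float,
                         noise_corr_px: float) -> float:
    """Gain from the vertical-difference noise estimate to the noise SD of
    the smoothed vertical gradient.

    Both operators are separable, so for noise with Gaussian autocorrelation
    of scale ``noise_corr_px`` the gain is a ratio of discrete kernel l2
    norms: noise ~ G_c * white, estimator measures ``||D * G_c|| / sqrt(2)``
    per axis, the gradient sees ``||dG_ax * G_c|| * ||G_lat * G_c||``.
    """
    g_n = _gauss_kernel(noise_corr_px) if noise_corr_px > 0 else np.array([1.0])
    dg_ax = np.convolve(_gauss_kernel(sigma_ax_px), [0.5, 0.0, -0.5])
    num_ax = np.linalg.norm(np.convolve(dg_ax, g_n))
    num_lat = np.linalg.norm(np.convolve(_gauss_kernel(sigma_lat_px), g_n))
    den_ax = np.linalg.norm(np.convolve([1.0, -1.0], g_n)) / np.sqrt(2)
    den_lat = np.linalg.norm(g_n)
    return float((num_ax * num_lat) / (den_ax * den_lat))


def segment_choroid(bscan: BScan, cfg: SegmentationConfig = SegmentationConfig()) -> ChoroidSegmentation:
    """Delineate both choroidal boundaries on one B-scan.

    Two sequential searches on the (optionally CLAHE-enhanced) image:

    1. upper boundary: a ridge path through maximal brightness locates the
       RPE band; its lower edge (a fixed pixel offset below the ridge
       centre) is taken as the RPE-Bruch's junction;
    2. lower boundary: a gradient path of the configured CSI polarity,
       restricted to a depth window below the upper boundary.
    """
    img = bscan.pixels
    if cfg.use_clahe:
        img = enhance_contrast(img, cfg.clahe_tile_px, cfg.clahe_clip)
    # smooth only along columns for the ridge search: the RPE band is a few
    # rows thick and axial smoothing would dilute it below the broad sclera
    ridge_img = gaussian_filter(img, (cfg.rpe_sigma_ax_px, cfg.sigma_px),
                                mode="nearest")
    ridge_cost = ridge_img.max() - ridge_img
    ridge = shortest_path_boundary(ridge_cost, cfg.max_jump)
    upper = ridge + cfg.rpe_offset_px

    rows = img.shape[0]
    w_lo = upper + max(1, int(np.ceil(cfg.lower_min_um / bscan.axial_um)))
    w_hi = upper + int(np.floor(cfg.lower_max_um / bscan.axial_um))
    w_hi = np.minimum(w_hi, rows - 1)
    empty = np.nonzero(w_lo > w_hi)[0]
    if empty.size:
        raise ValueError(
            f"lower-boundary window empty at columns {empty[:8].tolist()}"
        )
    csi_img = img if cfg.csi_use_clahe else bscan.pixels
    csi_smoothed = gaussian_filter(
        csi_img,
        (cfg.csi_sigma_ax_um / bscan.axial_um, cfg.csi_sigma_lat_um / bscan.lateral_um),
        mode="nearest",
    )
    grad = np.gradient(csi_smoothed, axis=0)
    if cfg.csi_polarity == "bright-to-dark":
        grad = -grad
    elif cfg.csi_polarity != "dark-to-bright":
        raise ValueError(f"unknown polarity {cfg.csi_polarity!r}")
    depth_idx = np.arange(rows)[:, None]
    in_window = (depth_idx >= w_lo[None, :]) & (depth_idx <= w_hi[None, :])
    csi_cost = grad.max() - grad
    masked = np.where(in_window, csi_cost, _BIG)
    lower = shortest_path_boundary(masked, cfg.max_jump)
    low_confidence = False
    shift = 0
    if cfg.csi_confidence_kappa > 0:
        # Conservative edge call under noise: rows whose gradient response
        # is within kappa * (estimated gradient-noise SD) of the path's
        # response are statistically indistinguishable, so the boundary is
        # reported at the shallowest of them ("the last pixel distinctly
        # brighter than the choroid").  Noise-free this is the path itself;
        # at low frame averaging it recedes a pixel or two into the choroid,
        # which is what shaves thickness off poorly averaged scans.
        # noise is estimated just below the detected interface: the sclera
        # is structure-free, so its lateral pixel differences track pure
        # speckle + read noise (falling as 1/sqrt(N)); lateral differences
        # are immune to the axial attenuation trend
        below = (depth_idx >= lower[None, :] + 3) & (depth_idx <= lower[None, :] + 28)
        diffs = np.diff(csi_img, axis=1)[below[:, :-1]]
        sigma_pix = 1.4826 * np.median(np.abs(diffs - np.median(diffs))) / np.sqrt(2)
        corr_px = _estimate_noise_corr(csi_img, below, cfg.csi_noise_corr_px)
        sigma_grad = sigma_pix * _gradient_noise_gain(
            cfg.csi_sigma_ax_um / bscan.axial_um,
            cfg.csi_sigma_lat_um / bscan.lateral_um,
            corr_px,
        )
        # crispness gate: if the median column's gradient already drops by
        # more than the confidence width one pixel above the path, the
        # interface is distinct everywhere and the call is left untouched;
        # otherwise the whole scan is re-called conservatively
        cols_idx = np.arange(grad.shape[1])
        d1 = grad[lower, cols_idx] - grad[np.maximum(lower - 1, 0), cols_idx]
        if np.median(d1) <= cfg.csi_confidence_kappa * sigma_grad:
            # indistinct interface: re-call the whole boundary with one
            # coherent conservative shift (the median of the per-column
            # confidence walks), rather than column-by-column, so the call
            # stays smooth and unbiased by local vessel texture
            low_confidence = True
            walked = _confidence_walk_up(grad, lower, w_lo,
                                         cfg.csi_confidence_kappa * sigma_grad)
            shift = min(int(round(np.median(lower - walked))), cfg.csi_max_shift_px)
    lower = np.minimum(lower + int(round(cfg.csi_offset_um / bscan.axial_um)),
                       rows - 1)
    if cfg.csi_trim_overshoot:
        # per-column bisection against the scleral brightness removes any
        # residual overshoot of the path into the sclera before the
        # conservative shift is applied on top
        lower = _trim_sclera_overshoot(csi_img, lower, depth_idx)
        lower = _lipschitz_project(lower, cfg.max_jump)
    if shift:
        lower = np.maximum(lower - shift, w_lo)
    upper = np.minimum(upper, lower - 1)
    return ChoroidSegmentation(upper_row=upper, lower_row=lower,
                               max_jump=cfg.max_jump,
                               low_confidence=low_confidence)


def _trim_sclera_overshoot(img, lower, depth_idx) -> np.ndarray:
    """One-row bisection refinement of the interface call per column.

    The decision level is midway between the scan's scleral brightness
    (median just below the boundary) and its basal-choroid brightness
    (median a few rows above it), on a lightly smoothed image.  A column
    moves up one row when the pixel above the boundary is already scleral,
    and down one row when the boundary pixel itself is still choroidal —
    a symmetric rule, so noise does not bias the refined call.
    """
    sm = gaussian_filter(img, (1.5, 1.5), mode="nearest")
    rows = img.shape[0]
    below = (depth_idx >= lower[None, :] + 2) & (depth_idx <= lower[None, :] + 10)
    above = (depth_idx >= lower[None, :] - 5) & (depth_idx <= lower[None, :] - 2)
    s_lvl = np.median(sm[below])
    c_lvl = np.median(sm[above])
    if s_lvl <= c_lvl:  # no scleral contrast to judge by
        return lower
    # trim only where the pixel above is unambiguously scleral; the high
    # threshold keeps speckle from faking sclera on poorly averaged scans
    tau = c_lvl + 0.75 * (s_lvl - c_lvl)
    cols = np.arange(img.shape[1])
    probe_up = sm[np.clip(lower - 1, 0, rows - 1), cols] > tau
    return np.clip(np.where(probe_up, lower - 1, lower), 1, rows - 1)


def _estimate_noise_corr(img, region, fallback: float) -> float:
    """Speckle grain (Gaussian correlation scale, px) from the lateral
    lag-1 autocorrelation of a structure-free region.

    For noise smoothed by a Gaussian of scale s the autocorrelation at lag
    d is exp(-d^2 / (4 s^2)), so s = sqrt(-1 / (4 ln rho_1)).
    """
    cnt = region.sum(axis=1, keepdims=True)
    sums = np.where(region, img, 0.0).sum(axis=1, keepdims=True)
    row_mean = np.divide(sums, cnt, out=np.zeros(sums.shape), where=cnt > 0)
    resid = np.where(region, img - row_mean, np.nan)
    def _lag_corr(lag: int) -> float | None:
        a = resid[:, :-lag].ravel()
        b = resid[:, lag:].ravel()
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() < 100:
            return None
        a, b = a[ok], b[ok]
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        return float((a * b).sum() / denom) if denom > 0 else None

    # the lag-1/lag-2 ratio cancels any white (uncorrelated) noise floor:
    # rho_d = w * exp(-d^2 / (4 s^2))  =>  s^2 = 3 / (4 ln(rho_1 / rho_2))
    r1, r2 = _lag_corr(1), _lag_corr(2)
    if r1 is None or r2 is None or not 0.0 < r2 < r1 < 1.0:
        return fallback
    return float(np.clip(np.sqrt(3.0 / (4.0 * np.log(r1 / r2))), 0.3, 6.0))


def _confidence_walk_up(grad, path, floor_row, tol) -> np.ndarray:
    """Per column, walk up from ``path`` while the gradient stays within
    ``tol`` of the path row's gradient (contiguously)."""
    out = path.copy()
    for c in range(grad.shape[1]):
        ref = grad[path[c], c] - tol
        q = path[c]
        while q - 1 >= floor_row[c] and grad[q - 1, c] >= ref:
            q -= 1
        out[c] = q
    return out


def _lipschitz_project(path, max_jump: int) -> np.ndarray:
    """Smallest pointwise-largest path under ``path`` obeying the jump bound
    (forward/backward running-minimum passes)."""
    out = path.astype(int).copy()
    for c in range(1, out.size):
        out[c] = min(out[c], out[c - 1] + max_jump)
    for c in range(out.size - 2, -1, -1):
        out[c] = min(out[c], out[c + 1] + max_jump)
    return out
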