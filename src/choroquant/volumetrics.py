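"""Radial-scan volumetrics: from per-scan masks to 3D choroidal metrics.

One 18-line radial acquisition samples the macula on 36 half-meridians.
Per scan we measure areas and column profiles inside the ±3 mm window; the
eye-level volumes come from the polar sector quadrature

    V = dtheta * sum_m  integral_0^R f_m(r) r dr,     dtheta = 2*pi/36,

with f = t (thickness) for TCV and f = l (lumen column height) for LV.
SV = TCV − LV, CVI = LV/TCV, and CT is the uniform-in-r mean of the
thickness profile over the disc (the radial pattern samples the subfovea
densely, so the plain profile mean is the natural thickness summary).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DISC_RADIUS_UM, RADIAL_ANGLES_DEG


@dataclass(frozen=True)
class ScanMetrics:
    """Areas and profiles of one B-scan inside the ±3 mm window."""

    la_mm2: float
    sa_mm2: float
    tca_mm2: float
    angle_deg: int
    r_um: np.ndarray  # signed radius of each window column (µm)
    t_um: np.ndarray  # thickness profile
    l_um: np.ndarray  # lumen column-height profile

    @property
    def cvi_2d(self) -> float:
        return self.la_mm2 / self.tca_mm2 if self.tca_mm2 > 0 else float("nan")


@dataclass(frozen=True)
class EyeMetrics:
    """3D choroidal parameters of one eye at one averaging level."""

    lv_mm3: float
    sv_mm3: float
    tcv_mm3: float
    ct_um: float
    cvi: float
    n_avg: int
    repeat_id: int
    eye_id: str = ""


LUMEN, STROMA, OUTSIDE = 0, 1, 2


def scan_metrics(mask, seg, axial_um: float, lateral_um: float,
                 center_col: int, angle_deg: int = 0) -> ScanMetrics:
    """Measure one binarized scan inside the 6 mm fovea-centred window.

    ``mask`` holds per-pixel labels (0 lumen, 1 stroma, 2 outside); ``seg``
    provides ``upper_row``/``lower_row`` per column.  Areas are pixel counts
    times the pixel area; profiles are per-column µm heights.
    """
    labels = np.asarray(mask.labels if hasattr(mask, "labels") else mask)
    rows, cols = labels.shape
    if not 0 <= center_col < cols:
        raise ValueError(f"center column {center_col} outside image (0..{cols - 1})")
    r_all = (np.arange(cols) - center_col) * lateral_um
    window = np.abs(r_all) <= DISC_RADIUS_UM + 1e-9
    if not np.any(window):
        raise ValueError("empty ±3 mm window")
    wcols = np.nonzero(window)[0]
    lumen_counts = (labels[:, wcols] == LUMEN).sum(axis=0)
    inside_counts = (labels[:, wcols] != OUTSIDE).sum(axis=0)
    px_area = axial_um * lateral_um
    la = lumen_counts.sum() * px_area * 1e-6
    tca = inside_counts.sum() * px_area * 1e-6
    t = (np.asarray(seg.lower_row) - np.asarray(seg.upper_row))[wcols] * axial_um
    l = lumen_counts * axial_um
    return ScanMetrics(
        la_mm2=float(la),
        sa_mm2=float(tca - la),
        tca_mm2=float(tca),
        angle_deg=angle_deg,
        r_um=r_all[wcols],
        t_um=t.astype(float),
        l_um=l.astype(float),
    )


def _half_meridian_quadrature(r_um, f_um) -> float:
    """Trapezoid integral of f(r)·r over one half-meridian, anchored at 0."""
    order = np.argsort(r_um)
    r = r_um[order]
    f = f_um[order]
    if r.size == 0:
        return 0.0
    if r[0] > 0:  # the pole carries zero weight; anchor the rule there
        r = np.concatenate([[0.0], r])
        f = np.concatenate([[0.0], f])
    return float(np.trapezoid(f * r, r))


def eye_metrics(scans, n_avg: int = 0, repeat_id: int = 0, eye_id: str = "") -> EyeMetrics:
    """Integrate 18 radial scans into LV, SV, TCV, CT and CVI.

    Each scan contributes its positive radii to meridian ``angle`` and its
    negative radii to meridian ``angle + 180``.
    """
    angles = [s.angle_deg for s in scans]
    expected = list(RADIAL_ANGLES_DEG)
    missing = sorted(set(expected) - set(angles))
    dupes = sorted({a for a in angles if angles.count(a) > 1})
    if missing or dupes:
        raise ValueError(
            f"need the 18 radial angles 0..170 step 10; missing={missing}, duplicate={dupes}"
        )
    dtheta = 2.0 * np.pi / 36.0
    tcv = 0.0
    lv = 0.0
    t_all = []
    for s in scans:
        for sign in (1, -1):
            sel = sign * s.r_um > 0
            tcv += _half_meridian_quadrature(np.abs(s.r_um[sel]), s.t_um[sel])
            lv += _half_meridian_quadrature(np.abs(s.r_um[sel]), s.l_um[sel])
        t_all.append(s.t_um)
    tcv *= dtheta * 1e-9
    lv *= dtheta * 1e-9
    ct = float(np.concatenate(t_all).mean())
    return EyeMetrics(
        lv_mm3=lv,
        sv_mm3=tcv - lv,
        tcv_mm3=tcv,
        ct_um=ct,
        cvi=lv / tcv if tcv > 0 else float("nan"),
        n_avg=n_avg,
        repeat_id=repeat_id,
        eye_id=eye_id,
    )
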