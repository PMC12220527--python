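"""Per-scan areas and the radial sector quadrature."""
import dataclasses

import numpy as np
import pytest

from choroquant import eye_metrics, scan_metrics, true_eye_metrics
from choroquant.config import RADIAL_ANGLES_DEG
from choroquant.segmentation import ChoroidSegmentation
from choroquant.volumetrics import LUMEN, OUTSIDE, STROMA, ScanMetrics


def _mask_and_seg(cols=320, upper=10, lower=25, lumen_rows=0):
    labels = np.full((60, cols), OUTSIDE, dtype=np.uint8)
    labels[upper:lower] = STROMA
    if lumen_rows:
        labels[upper : upper + lumen_rows] = LUMEN
    seg = ChoroidSegmentation(np.full(cols, upper), np.full(cols, lower))

    class M:
        pass

    m = M()
    m.labels = labels
    return m, seg


def test_scan_area_arithmetic():
    """301 columns x 15 rows x (20 x 20 µm... ) -> plain pixel arithmetic."""
    m, seg = _mask_and_seg(cols=320, upper=10, lower=25)
    sm = scan_metrics(m, seg, axial_um=20.0, lateral_um=20.0, center_col=160)
    n_window = 301  # |(c-160)*20| <= 3000
    assert sm.tca_mm2 == pytest.approx(15 * n_window * 400 * 1e-6)
    assert sm.la_mm2 == 0.0
    assert sm.sa_mm2 == sm.tca_mm2


def test_scan_half_lumen_fraction():
    m, seg = _mask_and_seg(cols=320, upper=10, lower=30, lumen_rows=10)
    sm = scan_metrics(m, seg, axial_um=10.0, lateral_um=20.0, center_col=160)
    assert sm.cvi_2d == pytest.approx(0.5)


def test_scan_partition_random_mask():
    rng = np.random.default_rng(5)
    m, seg = _mask_and_seg(cols=300, upper=5, lower=40)
    band = m.labels != OUTSIDE
    m.labels[band] = rng.choice([LUMEN, STROMA], size=band.sum())
    sm = scan_metrics(m, seg, axial_um=12.6, lateral_um=40.0, center_col=150)
    assert sm.la_mm2 + sm.sa_mm2 == pytest.approx(sm.tca_mm2, abs=1e-12)


def test_scan_center_out_of_image():
    m, seg = _mask_and_seg()
    with pytest.raises(ValueError):
        scan_metrics(m, seg, 12.6, 40.0, center_col=999)


def _uniform_scans(t_um=300.0, l_um=0.0, lateral=20.0, n_cols=301):
    r = (np.arange(n_cols) - n_cols // 2) * lateral
    scans = []
    for a in RADIAL_ANGLES_DEG:
        scans.append(
            ScanMetrics(
                la_mm2=0.0, sa_mm2=0.0, tca_mm2=1.0, angle_deg=a,
                r_um=r, t_um=np.full(n_cols, t_um), l_um=np.full(n_cols, l_um),
            )
        )
    return scans


def test_uniform_thickness_closed_form():
    m = eye_metrics(_uniform_scans(300.0))
    assert m.tcv_mm3 == pytest.approx(np.pi * 9.0 * 0.3, rel=5e-3)
    assert m.cvi == 0.0
    assert m.ct_um == pytest.approx(300.0)


def test_half_lumen_gives_cvi_half_exactly():
    m = eye_metrics(_uniform_scans(300.0, l_um=150.0))
    assert m.cvi == pytest.approx(0.5, abs=1e-12)


def test_missing_and_duplicate_angles_rejected():
    scans = _uniform_scans()
    with pytest.raises(ValueError, match="missing"):
        eye_metrics(scans[:-1])
    bad = scans[:-1] + [dataclasses.replace(scans[0])]
    with pytest.raises(ValueError, match="duplicate"):
        eye_metrics(bad)


def test_scale_equivariance():
    base = eye_metrics(_uniform_scans(280.0, 120.0))
    doubled = eye_metrics(_uniform_scans(560.0, 240.0))
    assert doubled.tcv_mm3 == pytest.approx(2 * base.tcv_mm3)
    assert doubled.lv_mm3 == pytest.approx(2 * base.lv_mm3)
    assert doubled.ct_um == pytest.approx(2 * base.ct_um)
    assert doubled.cvi == pytest.approx(base.cvi)


def test_quadrature_convergence_under_refinement():
    coarse = eye_metrics(_uniform_scans(300.0, lateral=40.0, n_cols=151))
    fine = eye_metrics(_uniform_scans(300.0, lateral=20.0, n_cols=301))
    assert coarse.tcv_mm3 == pytest.approx(fine.tcv_mm3, rel=5e-3)


def test_true_profiles_reproduce_true_metrics(eye):
    """Feeding the phantom's own profiles through the measurement quadrature
    recovers the analytic metrics — the cross-module consistency check."""
    lateral = 20.0
    n_cols = 301  # spans exactly the ±3 mm analysis window
    r_signed = (np.arange(n_cols) - n_cols // 2) * lateral
    scans = []
    for a in RADIAL_ANGLES_DEG:
        theta = np.where(r_signed >= 0, np.deg2rad(a), np.deg2rad(a + 180))
        t = eye.thickness(np.abs(r_signed), theta)
        l = np.empty(n_cols)
        pos = r_signed > 0
        neg = r_signed < 0
        l[pos] = eye.lumen_height(a // 10, r_signed[pos])
        l[neg] = eye.lumen_height((a + 180) // 10, -r_signed[neg])
        l[n_cols // 2] = 0.0
        scans.append(ScanMetrics(0.0, 0.0, 1.0, a, r_signed, t, l))
    measured = eye_metrics(scans)
    tm = true_eye_metrics(eye)
    assert measured.tcv_mm3 == pytest.approx(tm.tcv_mm3, rel=0.01)
    assert measured.lv_mm3 == pytest.approx(tm.lv_mm3, rel=0.01)
    assert measured.cvi == pytest.approx(tm.cvi, rel=0.01)
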