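"""Digital eye phantoms for the radial SS-OCT simulator.

An :class:`EyePhantom` is a parametric cross-sectional model of the posterior
eye: a smooth choroidal thickness field ``T(r, theta)`` over the 9 mm scan
field and a "wagon wheel" of vessel-lumen ellipses attached to the 36
half-meridians of the 18-line radial scan pattern.  Each half-meridian owns
its own lumina, so every radial section slices a well-defined geometry and
the analytic sector quadrature over the 6 mm fovea-centred disc is exact for
the luminal volume.

Depth is measured downwards from the upper choroidal boundary (the
RPE-Bruch's membrane junction); the choroid occupies the half-open pixel row
interval ``[upper_row, lower_row)`` with the choroidal-scleral interface at
``lower_row``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (
    DISC_RADIUS_UM,
    NATIVE_AXIAL_UM,
    NATIVE_LATERAL_UM,
    RADIAL_ANGLES_DEG,
    SCAN_DEPTH_UM,
    SCAN_WIDTH_UM,
    PhantomSpec,
)
from .volumetrics import EyeMetrics

N_MERIDIANS = 36
SECTOR_RAD = 2.0 * np.pi / N_MERIDIANS

#: number of rows occupied by the bright RPE band
RPE_ROWS = 3

#: truncation bounds of the per-eye thickness / vascularity draws
MIN_EYE_CT_UM = 100.0
CVI_BOUNDS = (0.3, 0.9)

#: overshoot tolerance on the realised luminal fraction of one eye
CVI_PLACEMENT_TOL = 0.008
#: keep adding lumina until the fraction is within this of its target
_CVI_STOP_DEFICIT = 0.0025
_MAX_PLACEMENT_ATTEMPTS = 60_000


@dataclass(frozen=True)
class GroundTruth:
    """True boundaries and lumen mask of one rendered section."""

    upper_row: np.ndarray  # (cols,) int, first choroid row
    lower_row: np.ndarray  # (cols,) int, first sclera row
    lumen_mask: np.ndarray  # (rows, cols) bool

    def __post_init__(self):
        if np.any(self.upper_row >= self.lower_row):
            raise ValueError("upper boundary must lie above lower boundary")


@dataclass
class EyePhantom:
    """One synthetic eye: thickness field plus lumen geometry."""

    eye_id: str
    spec: PhantomSpec
    t_eye_um: float  # thickness amplitude before radial/angular modulation
    sampled_ct_um: float
    sampled_cvi: float
    #: per-ellipse arrays, all length n_ellipses
    meridian: np.ndarray  # int in [0, 36)
    rc_um: np.ndarray  # radial centre
    depth_frac: np.ndarray  # centre depth as fraction of local thickness
    a_um: np.ndarray  # lateral (radial) semi-axis
    b_um: np.ndarray  # axial semi-axis
    true_metrics: EyeMetrics | None = None
    realized_cvi: float = float("nan")
    #: thickness texture harmonics: columns (amp, n_theta, phi, k_r, psi)
    texture: np.ndarray | None = None

    # -- thickness field ---------------------------------------------------
    def thickness(self, r_um, theta_rad):
        """Choroidal thickness T(r, theta) in µm (vectorised).

        A smooth base profile (foveal dome with a mild horizontal tilt)
        times the eye's random low-order texture; the texture is what makes
        two scans at slightly different cyclotorsion angles disagree.
        """
        p1, p2 = self.spec.ct_profile_params
        r_um = np.asarray(r_um, dtype=float)
        theta_rad = np.broadcast_to(np.asarray(theta_rad, dtype=float), r_um.shape)
        rr = r_um / self.spec.field_radius_um
        mod = 1.0 + p1 * np.cos(theta_rad) * rr + p2 * rr**2
        if self.texture is not None and self.texture.size:
            tau = np.zeros_like(rr)
            for amp, n, phi, k_r, psi in self.texture:
                tau += amp * np.cos(n * theta_rad + phi) * np.cos(k_r * rr + psi)
            mod *= 1.0 + np.clip(tau, -0.2, 0.2)
        return self.t_eye_um * mod

    # -- lumen chords ------------------------------------------------------
    def lumen_intervals(self, m: int, r_um: np.ndarray):
        """Merged lumen depth intervals for half-meridian ``m``.

        Returns ``(starts, ends)`` arrays of shape (n_intervals_max, len(r))
        padded with ``(inf, -inf)``; intervals are measured in µm below the
        upper boundary and clipped to the in-band margin.
        """
        r_um = np.asarray(r_um, dtype=float)
        sel = self.meridian == m
        t_loc = self.thickness(r_um, m * SECTOR_RAD)
        if not np.any(sel):
            empty = np.full((1, r_um.size), np.inf)
            return empty, -empty
        starts, ends = _ellipse_chords(
            r_um,
            t_loc,
            self.rc_um[sel],
            self.depth_frac[sel],
            self.a_um[sel],
            self.b_um[sel],
            self.spec.lumen_margin_frac,
            self.spec.lumen_bottom_margin_frac,
        )
        return _merge_intervals(starts, ends)

    def lumen_height(self, m: int, r_um: np.ndarray) -> np.ndarray:
        """Total lumen chord height l(r) in µm for half-meridian ``m``."""
        s, e = self.lumen_intervals(m, np.asarray(r_um, dtype=float))
        return union_lengths(s, e)


# ---------------------------------------------------------------------------
# interval helpers (vectorised over the radius grid)
# ---------------------------------------------------------------------------

def _ellipse_chords(r_um, t_loc, rc, dc, a, b, margin_frac, bottom_margin_frac=None):
    """Vertical chord intervals of each ellipse at each radius.

    Shapes: ellipses along axis 0, radii along axis 1.  Invalid chords are
    encoded as (inf, -inf).
    """
    u = (r_um[None, :] - rc[:, None]) / a[:, None]
    inside = np.abs(u) < 1.0
    with np.errstate(invalid="ignore"):
        h = b[:, None] * np.sqrt(np.clip(1.0 - u**2, 0.0, None))
    zc = dc[:, None] * t_loc[None, :]
    if bottom_margin_frac is None:
        bottom_margin_frac = margin_frac
    lo = margin_frac * t_loc[None, :]
    hi = (1.0 - bottom_margin_frac) * t_loc[None, :]
    z0 = np.maximum(zc - h, lo)
    z1 = np.minimum(zc + h, hi)
    valid = inside & (z1 > z0)
    starts = np.where(valid, z0, np.inf)
    ends = np.where(valid, z1, -np.inf)
    return starts, ends


def _merge_intervals(starts, ends):
    """Sort per-column intervals by start; keep padding at the tail."""
    order = np.argsort(starts, axis=0)
    return np.take_along_axis(starts, order, 0), np.take_along_axis(ends, order, 0)


def union_lengths(starts, ends) -> np.ndarray:
    """Per-column total length of the union of the (sorted) intervals."""
    if starts.shape[0] == 0:
        return np.zeros(starts.shape[1])
    prev = np.maximum.accumulate(
        np.vstack([np.full((1, ends.shape[1]), -np.inf), ends[:-1]]), axis=0
    )
    contrib = np.clip(ends - np.maximum(starts, prev), 0.0, None)
    return np.where(np.isfinite(contrib), contrib, 0.0).sum(axis=0)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _truncated_normal(rng, mean, sd, lo, hi, max_tries=10_000):
    if sd == 0:
        if not lo < mean < hi:
            raise ValueError(f"mean {mean} outside truncation bounds ({lo}, {hi})")
        return mean
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo < x < hi:
            return x
    raise RuntimeError("truncated normal sampling failed")


def _thickness_norm(spec: PhantomSpec) -> float:
    """Disc-average of the thickness modulation (uniform-in-r CT definition)."""
    p1, p2 = spec.ct_profile_params
    r = np.linspace(0.0, DISC_RADIUS_UM, 601) / spec.field_radius_um
    th = np.arange(N_MERIDIANS) * SECTOR_RAD
    mod = 1.0 + p1 * np.cos(th)[:, None] * r[None, :] + p2 * r[None, :] ** 2
    return float(mod.mean())


def make_cohort(spec: PhantomSpec, n_eyes: int) -> list[EyePhantom]:
    """Draw ``n_eyes`` phantoms from the population described by ``spec``.

    Per-eye thickness is Normal(mean_ct_um, sd_ct_um^2) truncated above
    100 µm; per-eye luminal fraction is Normal(target_cvi, sd_cvi^2)
    truncated to (0.3, 0.9).  Lumina are placed sequentially (a marked
    Poisson-style process, depth stratified) until the realised luminal
    fraction over the 6 mm disc is within ±0.01 of the eye's draw.
    Deterministic given ``spec.seed``.
    """
    if n_eyes < 1:
        raise ValueError("n_eyes must be >= 1")
    spec.validate()
    eyes = []
    for i in range(n_eyes):
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 7, i]))
        ct = _truncated_normal(rng, spec.mean_ct_um, spec.sd_ct_um, MIN_EYE_CT_UM, np.inf)
        cvi = _truncated_normal(rng, spec.target_cvi, spec.sd_cvi, *CVI_BOUNDS)
        eyes.append(_build_eye(spec, f"eye{i:03d}", ct, cvi, rng))
    return eyes


def _sample_ellipse(rng, spec: PhantomSpec, t_typical: float):
    """One candidate lumen: meridian, radial centre, depth, semi-axes."""
    m = int(rng.integers(0, N_MERIDIANS))
    # uniform per unit radius along each meridian plane, so the luminal
    # fraction has no radial trend and the fovea is vascularised too
    rc = rng.uniform(0.02 * spec.field_radius_um, spec.field_radius_um)
    margin = spec.lumen_margin_frac
    bottom = spec.lumen_bottom_margin_frac
    stratum = rng.uniform()
    if stratum < spec.inner_layer_weight:
        # small vessels of the inner third (choriocapillaris/Sattler side)
        rad_lo, rad_hi = spec.vessel_radius_ranges_um[0]
        radius = rng.uniform(rad_lo, rad_hi)
        a = radius * rng.uniform(1.2, 2.2)
        b = radius * rng.uniform(0.55, 0.95)
        b = min(b, 0.5 * t_typical * (1 - margin - bottom) * 0.32)
        d_lo, d_hi = margin + b / t_typical, 1.0 / 3.0
        dc = rng.uniform(d_lo, max(d_lo, d_hi))
    elif stratum < spec.inner_layer_weight + (1 - spec.inner_layer_weight) * spec.base_aligned_frac:
        # flat wide vessels tiling the basal sheet (Haller's layer)
        b = rng.uniform(*spec.base_vessel_b_um)
        a = b * rng.uniform(5.0, 8.0)  # wide and flat: tiles the basal sheet
        dc = 1.0 - bottom - b / t_typical
    else:
        # mid-depth outer vessels, kept above a relatively stromal
        # transition zone at mid_depth_top_frac
        rad_lo, rad_hi = spec.vessel_radius_ranges_um[1]
        radius = rng.uniform(rad_lo, rad_hi)
        a = radius * rng.uniform(1.2, 2.2)
        b = radius * rng.uniform(0.55, 0.95)
        b = min(b, 0.5 * t_typical * (1 - margin - bottom) * 0.5)
        d_lo = 1.0 / 3.0
        d_hi = max(d_lo, spec.mid_depth_top_frac - b / t_typical)
        dc = d_lo + (d_hi - d_lo) * rng.uniform() ** spec.outer_depth_bias
    return m, rc, dc, a, b


def _build_eye(spec: PhantomSpec, eye_id: str, ct: float, cvi: float, rng) -> EyePhantom:
    from .volumetrics import EyeMetrics  # local alias; dataclass only

    t_eye = ct / _thickness_norm(spec)
    eye = EyePhantom(
        eye_id=eye_id,
        spec=spec,
        t_eye_um=t_eye,
        sampled_ct_um=ct,
        sampled_cvi=cvi,
        meridian=np.empty(0, dtype=int),
        rc_um=np.empty(0),
        depth_frac=np.empty(0),
        a_um=np.empty(0),
        b_um=np.empty(0),
    )
    k = int(spec.ct_texture_harmonics)
    if k > 0 and spec.ct_texture_amp > 0:
        amp_k = 2.0 * spec.ct_texture_amp / np.sqrt(k)
        eye.texture = np.column_stack([
            amp_k * rng.normal(0.0, 1.0, k) / np.sqrt(2.0),
            rng.integers(2, 8, k).astype(float),
            rng.uniform(0.0, 2 * np.pi, k),
            rng.uniform(7.0, 19.0, k),
            rng.uniform(0.0, 2 * np.pi, k),
        ])
    # fraction bookkeeping on an occupancy grid (10 µm radial x 2 µm axial
    # cell centres) over the 6 mm disc; kept incremental so each candidate
    # costs only its own footprint.  The committed geometry stays analytic;
    # the grid is pure accounting.
    dr, dz = 10.0, 2.0
    r_mid = np.arange(dr / 2, DISC_RADIUS_UM, dr)
    nr = r_mid.size
    t_grid = np.empty((N_MERIDIANS, nr))
    for m in range(N_MERIDIANS):
        t_grid[m] = eye.thickness(r_mid, m * SECTOR_RAD)
    nz = int(np.ceil(t_grid.max() / dz))
    z_mid = (np.arange(nz) + 0.5) * dz
    occ = np.zeros((N_MERIDIANS, nr, nz), dtype=bool)
    cell_w = r_mid * dr * dz  # volume weight of one occupied cell (µm³ / dθ)
    tcv_occ = float((t_grid * r_mid * dr).sum())

    def _chord_cells(m, rc, dc, a, b):
        """Boolean footprint of one candidate on meridian ``m``'s grid."""
        i0 = max(0, int(np.floor((rc - a) / dr)))
        i1 = min(nr, int(np.ceil((rc + a) / dr)))
        if i1 <= i0:
            return i0, i1, None
        rr = r_mid[i0:i1]
        t_loc = t_grid[m, i0:i1]
        s, e = _ellipse_chords(rr, t_loc, np.array([rc]), np.array([dc]),
                               np.array([a]), np.array([b]),
                               spec.lumen_margin_frac,
                               spec.lumen_bottom_margin_frac)
        cells = (z_mid[None, :] >= s[0][:, None]) & (z_mid[None, :] < e[0][:, None])
        return i0, i1, cells

    cols: dict[str, list] = {"m": [], "rc": [], "dc": [], "a": [], "b": []}
    frac = 0.0
    attempts = 0
    while frac < cvi - _CVI_STOP_DEFICIT:
        attempts += 1
        if attempts > _MAX_PLACEMENT_ATTEMPTS:
            raise RuntimeError(
                f"could not reach luminal fraction {cvi:.3f} for {eye_id} "
                f"after {_MAX_PLACEMENT_ATTEMPTS} placement attempts"
            )
        m, rc, dc, a, b = _sample_ellipse(rng, spec, t_eye)
        i0, i1, cells = _chord_cells(m, rc, dc, a, b)
        if cells is not None:
            new = cells & ~occ[m, i0:i1]
            inc = float((new.sum(axis=1) * cell_w[i0:i1]).sum()) / tcv_occ
            if frac + inc > cvi + CVI_PLACEMENT_TOL:
                shrink = max(0.2, np.sqrt(max(cvi - frac, 0.0) / inc) * 0.9)
                a, b = a * shrink, b * shrink
                i0, i1, cells = _chord_cells(m, rc, dc, a, b)
                if cells is None:
                    continue
                new = cells & ~occ[m, i0:i1]
                inc = float((new.sum(axis=1) * cell_w[i0:i1]).sum()) / tcv_occ
                if frac + inc > cvi + CVI_PLACEMENT_TOL:
                    continue
            occ[m, i0:i1] |= cells
            frac += inc
        cols["m"].append(m)
        cols["rc"].append(rc)
        cols["dc"].append(dc)
        cols["a"].append(a)
        cols["b"].append(b)
    eye.meridian = np.asarray(cols["m"], dtype=int)
    eye.rc_um = np.asarray(cols["rc"], dtype=float)
    eye.depth_frac = np.asarray(cols["dc"], dtype=float)
    eye.a_um = np.asarray(cols["a"], dtype=float)
    eye.b_um = np.asarray(cols["b"], dtype=float)
    eye.true_metrics = true_eye_metrics(eye)
    eye.realized_cvi = eye.true_metrics.cvi
    if abs(eye.realized_cvi - cvi) > 0.01:
        raise RuntimeError(
            f"realised luminal fraction {eye.realized_cvi:.4f} of {eye_id} "
            f"misses its target {cvi:.4f}"
        )
    return eye


# ---------------------------------------------------------------------------
# analytic metrics
# ---------------------------------------------------------------------------

def true_eye_metrics(eye: EyePhantom, dr_um: float = 5.0) -> EyeMetrics:
    """Analytic sector quadrature of the phantom over the 6 mm disc.

    TCV integrates the smooth thickness field, LV the per-meridian union of
    lumen chords; SV is TCV − LV exactly and CVI their ratio.  CT is the
    uniform-in-r mean of the thickness profile over the disc.
    """
    r = np.arange(0.0, DISC_RADIUS_UM + 1e-9, dr_um)
    tcv = 0.0
    lv = 0.0
    ct_sum = 0.0
    for m in range(N_MERIDIANS):
        t_loc = eye.thickness(r, m * SECTOR_RAD)
        l_loc = eye.lumen_height(m, r)
        tcv += np.trapezoid(t_loc * r, r)
        lv += np.trapezoid(l_loc * r, r)
        ct_sum += t_loc.mean()
    tcv *= SECTOR_RAD * 1e-9  # µm³ -> mm³
    lv *= SECTOR_RAD * 1e-9
    return EyeMetrics(
        lv_mm3=lv,
        sv_mm3=tcv - lv,
        tcv_mm3=tcv,
        ct_um=ct_sum / N_MERIDIANS,
        cvi=lv / tcv,
        n_avg=0,
        repeat_id=-1,
        eye_id=eye.eye_id,
    )


def voxelized_eye_metrics(eye: EyePhantom, dr_um: float = 5.0, dtheta_deg: float = 2.5,
                          dz_um: float = 2.0) -> EyeMetrics:
    """Brute-force polar voxelisation of the phantom (test oracle).

    Sums voxel volumes on a dense (r, theta, z) grid; independent of the
    trapezoid quadrature used by :func:`true_eye_metrics`.
    """
    r = np.arange(dr_um / 2, DISC_RADIUS_UM, dr_um)
    thetas = np.arange(dtheta_deg / 2, 360.0, dtheta_deg)
    tcv = 0.0
    lv = 0.0
    ct_vals = []
    for th in thetas:
        m = int(round(th / 10.0)) % N_MERIDIANS
        t_loc = eye.thickness(r, np.deg2rad(th))
        ct_vals.append(t_loc.mean())
        tcv += np.sum(t_loc * r) * dr_um
        s, e = eye.lumen_intervals(m, r)
        # count z-voxels whose centres fall in any lumen interval
        n_z = int(np.ceil(t_loc.max() / dz_um))
        z = (np.arange(n_z) + 0.5) * dz_um
        inside = ((z[None, None, :] >= s[:, :, None]) & (z[None, None, :] < e[:, :, None])).any(axis=0)
        inside &= z[None, :] < t_loc[:, None]
        lv += np.sum(inside.sum(axis=1) * dz_um * r) * dr_um
    dth = np.deg2rad(dtheta_deg)
    tcv *= dth * 1e-9
    lv *= dth * 1e-9
    return EyeMetrics(
        lv_mm3=lv, sv_mm3=tcv - lv, tcv_mm3=tcv,
        ct_um=float(np.mean(ct_vals)), cvi=lv / tcv,
        n_avg=0, repeat_id=-1, eye_id=eye.eye_id,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_radial_section(
    eye: EyePhantom,
    angle_deg: int,
    axial_um: float = NATIVE_AXIAL_UM,
    lateral_um: float = NATIVE_LATERAL_UM,
    angle_offset_deg: float = 0.0,
    lumen_scale: float = 1.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render the noise-free reflectivity section at one radial angle.

    Rows are depth (3 mm total), columns span the 9 mm scan through the
    fovea centre.  Layer order top to bottom: vitreous, retina, a 3-row
    bright RPE band, choroid (stroma with lumen ellipses), sclera.
    ``angle_offset_deg`` models the cyclotorsion of one chinrest mount: the
    thickness field is sampled at the rotated angle and the lumina are
    taken from the nearest stored half-meridian.
    """
    if angle_deg not in RADIAL_ANGLES_DEG:
        raise ValueError(
            f"angle {angle_deg} not on the 18-line radial grid {RADIAL_ANGLES_DEG}"
        )
    if axial_um <= 0 or lateral_um <= 0:
        raise ValueError("pixel spacings must be positive")
    rows = int(SCAN_DEPTH_UM // axial_um)
    cols = int(SCAN_WIDTH_UM // lateral_um)
    center = cols // 2
    x_um = (np.arange(cols) - center) * lateral_um
    eff = angle_deg + angle_offset_deg
    theta = np.where(x_um >= 0, np.deg2rad(eff), np.deg2rad(eff + 180))
    t_um = eye.thickness(np.abs(x_um), theta)

    refl = dict(eye.spec.layer_reflectivities)
    ilm = int(round(eye.spec.vitreous_depth_um / axial_um))
    rpe_top = ilm + int(round(eye.spec.retina_thickness_um / axial_um))
    upper = np.full(cols, rpe_top + RPE_ROWS, dtype=int)
    lower = upper + np.maximum(np.round(t_um / axial_um).astype(int), 1)
    if lower.max() >= rows:
        raise ValueError("choroid extends below the 3 mm scan depth")

    img = np.full((rows, cols), refl["vitreous"], dtype=float)
    depth_idx = np.arange(rows)[:, None]
    img[ilm:rpe_top, :] = refl["retina"]
    img[rpe_top : rpe_top + RPE_ROWS, :] = refl["rpe"]
    in_band = (depth_idx >= upper[None, :]) & (depth_idx < lower[None, :])
    img[in_band] = refl["stroma"]
    img[depth_idx >= lower[None, :]] = refl["sclera"]
    scs_rows = int(round(eye.spec.suprachoroid_um / axial_um))
    if scs_rows > 0:
        in_scs = (depth_idx >= lower[None, :]) & (depth_idx < (lower + scs_rows)[None, :])
        img[in_scs] = eye.spec.suprachoroid_reflectivity

    lumen_mask = np.zeros((rows, cols), dtype=bool)
    m_pos = int(round(eff / 10.0)) % N_MERIDIANS
    m_neg = int(round((eff + 180.0) / 10.0)) % N_MERIDIANS
    for sign, m in ((1, m_pos), (-1, m_neg)):
        side = np.nonzero(sign * x_um > 0)[0]
        if side.size == 0:
            continue
        s, e = eye.lumen_intervals(m, np.abs(x_um[side]))
        for k in range(s.shape[0]):
            valid = np.isfinite(s[k])
            for j in np.nonzero(valid)[0]:
                c = side[j]
                # pixel centres at (i + 0.5) * axial below the upper boundary
                r0 = upper[c] + int(np.ceil(s[k, j] / axial_um - 0.5))
                r1 = upper[c] + int(np.ceil(e[k, j] / axial_um - 0.5))
                r0 = max(r0, upper[c])
                r1 = min(r1, lower[c])
                if r1 > r0:
                    lumen_mask[r0:r1, c] = True
    img[lumen_mask] = np.clip(refl["lumen"] * lumen_scale, 0.0,
                              0.95 * refl["stroma"])
    if eye.spec.attenuation_len_um > 0:
        # beam attenuation below the RPE: deep structures return less signal
        z_below = (depth_idx - upper[None, :]) * axial_um
        img *= np.exp(-np.clip(z_below, 0.0, None) / eye.spec.attenuation_len_um)
    gt = GroundTruth(upper_row=upper, lower_row=lower, lumen_mask=lumen_mask)
    return img, gt
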