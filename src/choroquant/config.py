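"""Configuration objects for the quantification pipeline.

Every tunable default of the pipeline lives here (not scattered through the
algorithm code) so a study is fully described by one :class:`StudyConfig`,
which can be round-tripped through YAML.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Mapping

import yaml

#: the 18 radial scan angles of one macular radial acquisition (degrees)
RADIAL_ANGLES_DEG: tuple[int, ...] = tuple(range(0, 180, 10))

#: frame counts offered by the averaging protocol
STANDARD_FRAME_COUNTS: tuple[int, ...] = (4, 8, 16, 32, 64)

#: native sampling of the simulated instrument (µm per pixel)
NATIVE_AXIAL_UM: float = 6.3
NATIVE_LATERAL_UM: float = 20.0

#: field geometry: 9 mm scan width, 3 mm depth, metrics over a 6 mm disc
SCAN_WIDTH_UM: float = 9000.0
SCAN_DEPTH_UM: float = 3000.0
DISC_RADIUS_UM: float = 3000.0


def _default_reflectivities() -> dict[str, float]:
    # arbitrary amplitude units on [0, 1]; the RPE must be the brightest band
    # and the choroid-sclera contrast modest so that low-frame averaging
    # degrades localisation of the choroidal-scleral interface.
    return {
        "vitreous": 0.05,
        "retina": 0.35,
        "rpe": 0.95,
        "stroma": 0.55,
        "lumen": 0.12,
        "sclera": 0.75,
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Population-level description of a synthetic eye cohort.

    Thickness and vascularity are drawn per eye from truncated normals;
    geometry within an eye is a wagon-wheel arrangement of vessel-lumen
    ellipses on the 36 half-meridians of the 18-line radial pattern.
    """

    #: population mean sub-6-mm-disc choroidal thickness (µm)
    mean_ct_um: float = 288.0
    #: between-eye SD of choroidal thickness (µm)
    sd_ct_um: float = 65.0
    #: population mean luminal volume fraction (LV/TCV)
    target_cvi: float = 0.62
    #: between-eye SD of the luminal fraction
    sd_cvi: float = 0.03
    layer_reflectivities: Mapping[str, float] = field(
        default_factory=_default_reflectivities
    )
    #: (min, max) lumen semi-axis scale, inner third / outer two thirds (µm)
    vessel_radius_ranges_um: tuple[tuple[float, float], tuple[float, float]] = (
        (15.0, 45.0),
        (40.0, 110.0),
    )
    #: (cos-tilt coefficient, quadratic falloff) of the thickness profile
    ct_profile_params: tuple[float, float] = (0.05, -0.1)
    #: half-width of the lateral field the lumina populate (µm)
    field_radius_um: float = 4500.0
    #: depth of vitreous above the inner retinal surface (µm)
    vitreous_depth_um: float = 350.0
    #: thickness of the single retina slab (µm)
    retina_thickness_um: float = 200.0
    #: lumina keep this fraction of local thickness clear of the upper boundary
    lumen_margin_frac: float = 0.05
    #: clearance of the deepest lumina from the choroidal-scleral interface;
    #: kept thin so the basal layer is vessel-rich, as in Haller's layer
    lumen_bottom_margin_frac: float = 0.001
    #: 1/e depth of the beam attenuation below the RPE (µm); makes the
    #: choroidal-scleral contrast weak relative to speckle at low averaging
    attenuation_len_um: float = 600.0
    #: thickness and reflectivity of the dark suprachoroidal band between
    #: the choroid and the bright sclera (visible on real SS-OCT)
    suprachoroid_um: float = 0.0
    suprachoroid_reflectivity: float = 0.15
    #: fraction of lumen cross-section assigned to the inner (small-vessel) third
    inner_layer_weight: float = 0.32
    #: depth bias of the mid-depth outer vessels; < 1 crowds them downward
    outer_depth_bias: float = 1.0
    #: fraction of outer vessels forming the dense flat sheet resting on the
    #: basal margin, as Haller's vessels do on the sclera
    base_aligned_frac: float = 0.8
    #: axial semi-axis range of the flat basal sheet vessels (µm)
    base_vessel_b_um: tuple[float, float] = (12.0, 20.0)
    #: deepest centre depth (fraction of thickness) of mid-layer vessels;
    #: leaves a relatively stromal transition zone above the basal sheet
    mid_depth_top_frac: float = 0.9
    #: RMS amplitude of the smooth random thickness texture (fraction of
    #: thickness); what a remount's rotation offset resamples
    ct_texture_amp: float = 0.04
    #: number of random angular/radial harmonics forming the texture
    ct_texture_harmonics: int = 6
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.target_cvi < 1.0:
            raise ValueError(f"target_cvi must be in (0, 1), got {self.target_cvi}")
        if self.mean_ct_um <= 0:
            raise ValueError("mean_ct_um must be positive")
        refl = dict(self.layer_reflectivities)
        for name, val in refl.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"reflectivity {name}={val} outside [0, 1]")
        if refl["lumen"] >= refl["stroma"]:
            raise ValueError("lumen reflectivity must be below stroma reflectivity")
        if self.sd_ct_um < 0 or self.sd_cvi < 0:
            raise ValueError("between-eye SDs must be non-negative")


@dataclass(frozen=True)
class AcquisitionParams:
    """Per-acquisition simulator settings (one averaged B-scan)."""

    #: number of frames averaged; the protocol offers 4, 8, 16, 32, 64
    n_frames: int = 32
    #: Gaussian correlation length of the speckle field (pixels)
    speckle_corr_px: float = 2.0
    #: additive (read) noise SD in intensity units
    read_noise_sd: float = 0.004
    #: SD of the per-acquisition lateral fixation offset (µm)
    jitter_sd_um: float = 40.0
    #: SD of the cyclotorsion/fixation rotation offset drawn at each
    #: chinrest remount (degrees); shared by the 18 lines of one scan
    remount_rot_sd_deg: float = 4.0
    #: frame-registration efficiency per mount: the effective number of
    #: independently averaged frames is n_frames times a draw from
    #: Normal(mean, sd) clipped to [0.5, 1].  Imperfect registration is the
    #: dominant mount-to-mount quality fluctuation and hence the main
    #: within-subject error source for the boundary-dependent parameters.
    reg_efficiency_mean: float = 0.85
    reg_efficiency_sd: float = 0.16
    #: per-mount variation of the speckle grain (focus/tear-film quality);
    #: SD of a multiplicative factor on speckle_corr_px
    focus_corr_sd: float = 0.45
    #: per-mount relative variation of the lumen reflectivity (blood
    #: scattering changes with flow); jitters the lumen-threshold margin
    #: and hence the luminal/stromal split, without moving the boundaries
    lumen_reflect_sd: float = 0.25
    #: per-mount illumination gain SD (multiplies the reflectivity map);
    #: through the logarithmic display this shifts every tissue's distance
    #: to its local binarization threshold, so classification wobbles
    #: coherently from mount to mount
    gain_sd: float = 0.18
    #: offset of the logarithmic display compression
    log_eps: float = 0.01
    #: intensity mapped to display value 1.0
    display_ref: float = 1.0
    #: reference background SD for the signal-strength index (display units)
    sigma_ref: float = 0.25
    #: fraction of top rows treated as vitreous when estimating background SD
    bg_rows_frac: float = 0.08
    seed: int = 0

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.read_noise_sd < 0 or self.speckle_corr_px < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass(frozen=True)
class SegmentationConfig:
    #: Gaussian scale for smoothing / gradient computation (pixels)
    sigma_px: float = 2.0
    #: maximum row change of a boundary between adjacent columns
    max_jump: int = 2
    #: CLAHE tile edge (pixels, at native sampling) and clip limit
    clahe_tile_px: int = 64
    clahe_clip: float = 0.01
    use_clahe: bool = True
    #: run the CSI (lower-boundary) stage on the CLAHE image instead of the
    #: raw display image.  Adaptive equalisation renormalises local
    #: contrast, which distorts how edge evidence scales with frame
    #: averaging, so the raw image is the default for this stage.
    csi_use_clahe: bool = False
    #: axial smoothing for the RPE ridge search (kept small so the thin
    #: bright band is not diluted into the broad sclera)
    rpe_sigma_ax_px: float = 0.8
    #: rows from the RPE ridge centre down to the first choroid row
    rpe_offset_px: int = 2
    #: lower-boundary search window, measured below the upper boundary (µm)
    lower_min_um: float = 50.0
    lower_max_um: float = 800.0
    #: anisotropic smoothing for the CSI gradient (µm); broad enough to
    #: average out the vessel texture above the interface
    csi_sigma_ax_um: float = 80.0
    csi_sigma_lat_um: float = 1000.0
    #: localisation offset added to the CSI path (µm).  The gradient peak of
    #: the smoothed choroid-sclera transition sits slightly above the
    #: interface because the vessel texture brightens gradually toward the
    #: stromal strip at the choroid base; this constant recentres it.
    csi_offset_um: float = 11.0
    #: confidence width of the edge call, in units of the estimated
    #: gradient-noise SD.  The boundary is reported at the shallowest row
    #: statistically indistinguishable from the best edge response, so
    #: noisy (poorly averaged) scans call the interface a little shallow;
    #: 0 disables the adjustment.
    csi_confidence_kappa: float = 0.68
    #: assumed speckle grain (pixels) used when converting the pixel-level
    #: noise estimate into the gradient-noise level (fallback when the
    #: grain cannot be estimated from the image itself)
    csi_noise_corr_px: float = 2.0
    #: upper bound on the conservative re-call shift (pixels)
    csi_max_shift_px: int = 2
    #: pull the boundary up by one row wherever the pixel just above it is
    #: closer to the scleral brightness than to the basal choroid (removes
    #: residual overshoot of the gradient path into the sclera)
    csi_trim_overshoot: bool = True
    #: polarity of the choroidal-scleral edge; sclera brighter than stroma
    #: in the default phantom, hence dark-to-bright
    csi_polarity: str = "dark-to-bright"

    def scaled(self, scale: float) -> "SegmentationConfig":
        tile = max(8, int(round(self.clahe_tile_px * scale)))
        return replace(self, clahe_tile_px=tile)


@dataclass(frozen=True)
class BinarizationConfig:
    #: Niblack window edge (pixels, odd, at native sampling)
    window_px: int = 31
    #: Niblack coefficient; negative pulls the threshold below the local mean
    k: float = -0.1
    #: light isotropic despeckle (Gaussian sigma, pixels) applied to the
    #: image before thresholding; 0 disables
    presmooth_px: float = 0.0
    #: binarize the CLAHE-enhanced image instead of the raw display image
    use_enhanced: bool = False

    def scaled(self, scale: float) -> "BinarizationConfig":
        w = max(3, int(round(self.window_px * scale)))
        if w % 2 == 0:
            w += 1
        return replace(self, window_px=w)


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to run one frame-averaging study end to end."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    binarization: BinarizationConfig = field(default_factory=BinarizationConfig)
    levels: tuple[int, ...] = STANDARD_FRAME_COUNTS
    n_eyes: int = 22
    n_repeats: int = 2
    #: image-scale factor; 0.5 halves both sampling densities
    scale: float = 0.5
    master_seed: int = 0
    #: acquisitions with signal strength below this are re-drawn
    min_signal_strength: float = 6.0
    max_reacquisitions: int = 5

    def validate(self) -> None:
        if list(self.levels) != sorted(set(self.levels)):
            raise ValueError("levels must be strictly increasing")
        if not 0.0 < self.scale <= 1.0:
            raise ValueError("scale must be in (0, 1]")
        self.phantom.validate()
        self.acquisition.validate()

    @property
    def axial_um(self) -> float:
        return NATIVE_AXIAL_UM / self.scale

    @property
    def lateral_um(self) -> float:
        return NATIVE_LATERAL_UM / self.scale

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        if "phantom" in d:
            ph = dict(d["phantom"])
            if "vessel_radius_ranges_um" in ph:
                ph["vessel_radius_ranges_um"] = tuple(
                    tuple(r) for r in ph["vessel_radius_ranges_um"]
                )
            if "ct_profile_params" in ph:
                ph["ct_profile_params"] = tuple(ph["ct_profile_params"])
            if "base_vessel_b_um" in ph:
                ph["base_vessel_b_um"] = tuple(ph["base_vessel_b_um"])
            d["phantom"] = PhantomSpec(**ph)
        if "acquisition" in d:
            d["acquisition"] = AcquisitionParams(**d["acquisition"])
        if "segmentation" in d:
            d["segmentation"] = SegmentationConfig(**d["segmentation"])
        if "binarization" in d:
            d["binarization"] = BinarizationConfig(**d["binarization"])
        if "levels" in d:
            d["levels"] = tuple(d["levels"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
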