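"""End-to-end frame-averaging study on a synthetic cohort.

For every (eye, repeat, averaging level) the driver renders the eye's 18
radial sections, simulates an averaged acquisition per section (re-drawing
any acquisition whose signal strength falls below the exclusion gate),
segments, binarizes, and integrates the radial metrics into one
:class:`~choroquant.volumetrics.EyeMetrics` record.  Reliability statistics
per level and the repeated-measures ANOVA across levels are then computed
per parameter, together with the plateau level — the smallest averaging
level above which no Bonferroni-adjusted pairwise difference remains.

Seeds: acquisition seeds derive from the master seed through
``SeedSequence([master, eye_index, repeat, level, angle_index, attempt])``,
so every scan is reproducible in isolation.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import acquire_bscan
from .binarization import binarize_choroid
from .config import RADIAL_ANGLES_DEG, StudyConfig
from .phantom import EyePhantom, make_cohort, render_radial_section
from .segmentation import segment_choroid
from .stats import (
    AnovaResult,
    ReliabilityStats,
    RepeatPairs,
    bland_altman,
    rm_anova_with_pairwise,
)
from .volumetrics import EyeMetrics, eye_metrics, scan_metrics

log = logging.getLogger(__name__)

PARAMETERS = ("cvi", "lv_mm3", "sv_mm3", "tcv_mm3", "ct_um")


@dataclass
class StudyResult:
    config: StudyConfig
    metrics: pd.DataFrame  # one row per (eye, repeat, level)
    truth: pd.DataFrame  # one row per eye: analytic phantom metrics
    reliability: dict  # (parameter, level) -> ReliabilityStats
    anova: dict  # parameter -> AnovaResult (with pairwise table)
    plateau: dict  # parameter -> plateau level
    exclusions: list = field(default_factory=list)

    def level_table(self, parameter: str, reduce_repeats: bool = True) -> np.ndarray:
        """n_eyes x n_levels table for one parameter (repeat means by default)."""
        wide = self.metrics.pivot_table(
            index="eye_id", columns="n_avg", values=parameter,
            aggfunc="mean" if reduce_repeats else "first",
        )
        return wide[list(self.config.levels)].to_numpy()

    def repeat_pairs(self, parameter: str, level: int) -> RepeatPairs:
        sub = self.metrics[self.metrics.n_avg == level]
        wide = sub.pivot(index="eye_id", columns="repeat", values=parameter)
        return RepeatPairs(wide[0].to_numpy(), wide[1].to_numpy())


def _acquisition_seed(master: int, eye_idx: int, repeat: int, level: int,
                      angle_idx: int, attempt: int) -> int:
    ss = np.random.SeedSequence(
        [int(master), eye_idx, repeat, level, angle_idx, attempt]
    )
    return int(ss.generate_state(1)[0] % (2**31))


def measure_eye_level(
    eye: EyePhantom,
    cfg: StudyConfig,
    eye_idx: int,
    repeat: int,
    level: int,
    exclusions: list | None = None,
) -> EyeMetrics:
    """Acquire, segment, binarize and quantify one (eye, repeat, level).

    One chinrest mount per measurement: a single cyclotorsion offset is
    drawn for the whole 18-line scan, then each line gets its own speckle
    and lateral fixation jitter.
    """
    seg_cfg = cfg.segmentation.scaled(cfg.scale)
    bin_cfg = cfg.binarization.scaled(cfg.scale)
    mount_rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.master_seed), 5, eye_idx, repeat, level])
    )
    rot_deg = float(mount_rng.normal(0.0, cfg.acquisition.remount_rot_sd_deg))
    eta = float(np.clip(
        mount_rng.normal(cfg.acquisition.reg_efficiency_mean,
                         cfg.acquisition.reg_efficiency_sd), 0.5, 1.0))
    n_eff = max(2, int(round(level * eta)))
    focus = float(np.clip(mount_rng.normal(1.0, cfg.acquisition.focus_corr_sd),
                          0.5, 1.7))
    corr_px = cfg.acquisition.speckle_corr_px * focus
    gain = float(np.clip(mount_rng.normal(1.0, cfg.acquisition.gain_sd), 0.7, 1.3))
    lumen_scale = float(np.clip(
        mount_rng.normal(1.0, cfg.acquisition.lumen_reflect_sd), 0.6, 1.4))
    scans = []
    for angle_idx, angle in enumerate(RADIAL_ANGLES_DEG):
        refl, gt = render_radial_section(
            eye, angle, cfg.axial_um, cfg.lateral_um, angle_offset_deg=rot_deg,
            lumen_scale=lumen_scale,
        )
        refl = np.clip(refl * gain, 0.0, 1.0)
        for attempt in range(cfg.max_reacquisitions + 1):
            seed = _acquisition_seed(cfg.master_seed, eye_idx, repeat, level,
                                     angle_idx, attempt)
            params = replace(cfg.acquisition, n_frames=n_eff,
                             speckle_corr_px=corr_px, seed=seed)
            bscan = acquire_bscan(
                refl, gt, params,
                axial_um=cfg.axial_um, lateral_um=cfg.lateral_um,
                angle_deg=angle, eye_id=eye.eye_id, repeat_id=repeat,
            )
            if bscan.signal_strength >= cfg.min_signal_strength:
                break
            if exclusions is not None:
                exclusions.append(
                    {"eye_id": eye.eye_id, "repeat": repeat, "level": level,
                     "angle": angle, "attempt": attempt,
                     "signal_strength": bscan.signal_strength}
                )
        else:
            raise RuntimeError(
                f"signal strength below {cfg.min_signal_strength} after "
                f"{cfg.max_reacquisitions + 1} attempts ({eye.eye_id}, N={level})"
            )
        seg = segment_choroid(bscan, seg_cfg)
        source = bscan.pixels
        if bin_cfg.presmooth_px > 0:
            from scipy.ndimage import gaussian_filter
            source = gaussian_filter(source, bin_cfg.presmooth_px, mode="nearest")
        mask = binarize_choroid(source, seg, bin_cfg.window_px, bin_cfg.k,
                                eye_id=eye.eye_id, repeat_id=repeat, n_avg=level)
        center = bscan.pixels.shape[1] // 2
        scans.append(
            scan_metrics(mask, seg, cfg.axial_um, cfg.lateral_um, center, angle)
        )
    return eye_metrics(scans, n_avg=level, repeat_id=repeat, eye_id=eye.eye_id)


def detect_plateau(pairwise: list[dict], levels) -> int | str:
    """Smallest level L with no significant adjusted pair among levels >= L."""
    levels = sorted(levels)
    for lvl in levels:
        sig = [
            p for p in pairwise
            if p["level_i"] >= lvl and p["level_j"] >= lvl
            and p["p_bonferroni"] < 0.05
        ]
        if not sig:
            return lvl
    return "none"


def run_averaging_study(cfg: StudyConfig) -> StudyResult:
    """Run the full study described by ``cfg`` and assemble its statistics."""
    cfg.validate()
    cohort = make_cohort(
        replace(cfg.phantom, seed=int(
            np.random.SeedSequence([cfg.master_seed, 0]).generate_state(1)[0] % 2**31
        )),
        cfg.n_eyes,
    )
    records = []
    truth_rows = []
    exclusions: list = []
    failures = 0
    for eye_idx, eye in enumerate(cohort):
        tm = eye.true_metrics
        truth_rows.append(
            {"eye_id": eye.eye_id, "cvi": tm.cvi, "lv_mm3": tm.lv_mm3,
             "sv_mm3": tm.sv_mm3, "tcv_mm3": tm.tcv_mm3, "ct_um": tm.ct_um}
        )
        try:
            for repeat in range(cfg.n_repeats):
                for level in cfg.levels:
                    m = measure_eye_level(eye, cfg, eye_idx, repeat,
                                          level, exclusions)
                    records.append(
                        {"eye_id": eye.eye_id, "repeat": repeat, "n_avg": level,
                         "cvi": m.cvi, "lv_mm3": m.lv_mm3, "sv_mm3": m.sv_mm3,
                         "tcv_mm3": m.tcv_mm3, "ct_um": m.ct_um}
                    )
        except Exception:
            failures += 1
            log.exception("eye %s failed; dropping it", eye.eye_id)
            records = [r for r in records if r["eye_id"] != eye.eye_id]
            if failures > 0.1 * cfg.n_eyes:
                raise RuntimeError(
                    f"{failures} of {cfg.n_eyes} eyes failed; aborting study"
                )
    metrics = pd.DataFrame.from_records(records)
    truth = pd.DataFrame.from_records(truth_rows)
    result = StudyResult(
        config=cfg, metrics=metrics, truth=truth,
        reliability={}, anova={}, plateau={}, exclusions=exclusions,
    )
    for param in PARAMETERS:
        for level in cfg.levels:
            pairs = result.repeat_pairs(param, level)
            if param == "cvi":  # CoR for CVI is reported in percentage points
                pairs = RepeatPairs(pairs.m1 * 100.0, pairs.m2 * 100.0)
            result.reliability[(param, level)] = bland_altman(pairs)
        table = result.level_table(param)
        result.anova[param] = rm_anova_with_pairwise(table, list(cfg.levels))
        result.plateau[param] = detect_plateau(
            result.anova[param].pairwise, cfg.levels
        )
    return result


def averaging_study_summary(result: StudyResult) -> dict:
    """Headline numbers of one averaging study.

    Returns the CVI ANOVA p-value, the joint plateau of the three
    boundary-sensitive parameters (LV, TCV, CT), the SV plateau, the minimum
    ICC over all parameter/level cells, and the maximum CVI coefficient of
    repeatability in percentage points.
    """
    numeric = [result.plateau[p] for p in ("lv_mm3", "tcv_mm3", "ct_um")]
    joint = max(int(p) for p in numeric) if all(
        p != "none" for p in numeric) else "none"
    return {
        "cvi_anova_p": result.anova["cvi"].p_value,
        "volume_plateau_frames": joint,
        "sv_plateau_frames": result.plateau["sv_mm3"],
        "min_icc": min(rel.icc for rel in result.reliability.values()),
        "max_cvi_cor_pct": max(
            rel.cor for (param, _), rel in result.reliability.items()
            if param == "cvi"
        ),
    }


# ---------------------------------------------------------------------------
# output writing
# ---------------------------------------------------------------------------

def write_study_outputs(result: StudyResult, outdir) -> dict[str, Path]:
    """Write the study tables: metrics CSV, reliability (Table-1 analog),
    ANOVA/pairwise CSV, Bland-Altman JSON and the config snapshot."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["metrics"] = out / "metrics.csv"
    result.metrics.to_csv(paths["metrics"], index=False, float_format="%.8g")

    rows = []
    for (param, level), rel in result.reliability.items():
        rows.append({"parameter": param, "n_avg": level,
                     "icc": rel.icc, "cor": rel.cor, "sw": rel.sw})
    paths["reliability"] = out / "reliability.csv"
    pd.DataFrame(rows).to_csv(paths["reliability"], index=False, float_format="%.8g")

    arows = []
    for param, res in result.anova.items():
        arows.append({"parameter": param, "kind": "anova", "f": res.f_stat,
                      "df_num": res.df_num, "df_den": res.df_den,
                      "p": res.p_value, "plateau": result.plateau[param]})
        for pw in res.pairwise:
            arows.append({"parameter": param, "kind": "pairwise",
                          "level_i": pw["level_i"], "level_j": pw["level_j"],
                          "mean_diff": pw["mean_diff"], "p": pw["p_bonferroni"],
                          "stars": pw["stars"]})
    paths["anova"] = out / "anova_pairwise.csv"
    pd.DataFrame(arows).to_csv(paths["anova"], index=False, float_format="%.8g")

    ba = {
        f"{param}@N{level}": {
            "mean_diff": rel.ba_mean_diff,
            "loa": [rel.ba_loa_low, rel.ba_loa_high],
            "ci": [rel.ba_ci_low, rel.ba_ci_high],
        }
        for (param, level), rel in result.reliability.items()
    }
    paths["bland_altman"] = out / "bland_altman.json"
    paths["bland_altman"].write_text(json.dumps(ba, indent=2, sort_keys=True))

    paths["config"] = out / "study_config.yaml"
    result.config.to_yaml(paths["config"])

    paths["exclusions"] = out / "exclusions.json"
    paths["exclusions"].write_text(json.dumps(result.exclusions, indent=2))
    return paths
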