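"""Reading and writing of scans, masks and sidecar metadata.

Sections and B-scans travel as 16-bit grayscale TIFF plus a JSON sidecar;
binary masks as 8-bit PNG (0 lumen, 255 stroma, 128 outside); segmentations
as CSV.  The sidecar carries the sampling metadata needed to re-quantify a
scan without its generating phantom.
"""
from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .acquisition import BScan
from .binarization import BinaryChoroidMask
from .segmentation import ChoroidSegmentation
from .volumetrics import LUMEN, OUTSIDE, STROMA

_PNG_CODES = {LUMEN: 0, STROMA: 255, OUTSIDE: 128}


def save_bscan(bscan: BScan, path) -> Path:
    """Write a B-scan as 16-bit TIFF with a .json sidecar next to it."""
    path = Path(path)
    tifffile.imwrite(path, np.round(bscan.pixels * 65535).astype(np.uint16))
    sidecar = {
        "axial_um": bscan.axial_um,
        "lateral_um": bscan.lateral_um,
        "angle_deg": bscan.angle_deg,
        "n_avg": bscan.n_avg,
        "signal_strength": bscan.signal_strength,
        "eye_id": bscan.eye_id,
        "repeat_id": bscan.repeat_id,
        "seed": bscan.seed,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_bscan(path) -> BScan:
    path = Path(path)
    pixels = tifffile.imread(path).astype(float) / 65535.0
    meta = json.loads(path.with_suffix(".json").read_text())
    return BScan(
        pixels=pixels,
        axial_um=meta["axial_um"],
        lateral_um=meta["lateral_um"],
        angle_deg=meta["angle_deg"],
        n_avg=meta["n_avg"],
        signal_strength=meta.get("signal_strength", float("nan")),
        eye_id=meta.get("eye_id", ""),
        repeat_id=meta.get("repeat_id", 0),
        seed=meta.get("seed", 0),
    )


def save_section(reflectivity, meta: dict, path) -> Path:
    """Write a noise-free phantom section (same TIFF + sidecar convention)."""
    path = Path(path)
    tifffile.imwrite(path, np.round(np.clip(reflectivity, 0, 1) * 65535).astype(np.uint16))
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def save_segmentation(seg: ChoroidSegmentation, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "column": np.arange(len(seg.upper_row)),
            "upper_row": seg.upper_row,
            "lower_row": seg.lower_row,
        }
    ).to_csv(path, index=False)
    return path


def load_segmentation(path, max_jump: int = 2) -> ChoroidSegmentation:
    df = pd.read_csv(path)
    return ChoroidSegmentation(
        upper_row=df["upper_row"].to_numpy(),
        lower_row=df["lower_row"].to_numpy(),
        max_jump=max_jump,
    )


def save_mask(mask: BinaryChoroidMask, path) -> Path:
    path = Path(path)
    png = np.zeros(mask.labels.shape, dtype=np.uint8)
    for label, code in _PNG_CODES.items():
        png[mask.labels == label] = code
    iio.imwrite(path, png)
    sidecar = {"window_px": mask.window_px, "k": mask.k, "eye_id": mask.eye_id,
               "repeat_id": mask.repeat_id, "n_avg": mask.n_avg}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_mask(path) -> BinaryChoroidMask:
    path = Path(path)
    png = iio.imread(path)
    labels = np.full(png.shape, OUTSIDE, dtype=np.uint8)
    labels[png == _PNG_CODES[LUMEN]] = LUMEN
    labels[png == _PNG_CODES[STROMA]] = STROMA
    meta = json.loads(path.with_suffix(".json").read_text())
    return BinaryChoroidMask(labels=labels, window_px=meta["window_px"],
                             k=meta["k"], eye_id=meta.get("eye_id", ""),
                             repeat_id=meta.get("repeat_id", 0),
                             n_avg=meta.get("n_avg", 0))
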