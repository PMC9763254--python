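"""File containers: TIFF surface/height grids with JSON sidecars, CSV tables.

Layer surfaces are stored as a 2-page 32-bit float TIFF (page 0 = RPE,
page 1 = BM, values in um) with grid metadata in a ``<stem>.json`` sidecar;
drusen height maps as a single-page 32-bit TIFF with the same sidecar
convention.  Cohort manifests and measurement tables are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .quantify import DrusenMeasurement
from .segmentation import DrusenHeightMap, LayerSurfaces
from .synthetic import GroundTruthEye, analytic_drusen_volume


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_surfaces(path: str | Path, s: LayerSurfaces) -> Path:
    path = Path(path)
    tifffile.imwrite(
        path,
        np.stack([s.rpe_um, s.bm_um]).astype(np.float32),
        photometric="minisblack",
    )
    meta = {
        "bscan_spacing_um": s.bscan_spacing_um,
        "ascan_pitch_um": s.ascan_pitch_um,
        "axial_pitch_um": s.axial_pitch_um,
        "fovea_row": s.fovea_row,
        "fovea_col": s.fovea_col,
        "eye_id": s.eye_id,
        "meta": s.meta,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_surfaces(path: str | Path) -> LayerSurfaces:
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] != 2:
        raise ValueError("surface container must hold exactly 2 pages (RPE, BM)")
    meta = json.loads(_sidecar(path).read_text())
    return LayerSurfaces(
        rpe_um=pages[0].astype(float),
        bm_um=pages[1].astype(float),
        bscan_spacing_um=meta["bscan_spacing_um"],
        ascan_pitch_um=meta["ascan_pitch_um"],
        axial_pitch_um=meta["axial_pitch_um"],
        fovea_row=meta.get("fovea_row", 0.0),
        fovea_col=meta.get("fovea_col", 0.0),
        eye_id=meta.get("eye_id", ""),
        meta=meta.get("meta", {}),
    )


def write_height_map(path: str | Path, m: DrusenHeightMap) -> Path:
    path = Path(path)
    tifffile.imwrite(path, m.heights_um.astype(np.float32), photometric="minisblack")
    meta = {
        "bscan_spacing_um": m.bscan_spacing_um,
        "ascan_pitch_um": m.ascan_pitch_um,
        "axial_pitch_um": m.axial_pitch_um,
        "fovea_row": m.fovea_row,
        "fovea_col": m.fovea_col,
        "filtered": m.filtered,
        "eye_id": m.eye_id,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def read_height_map(path: str | Path) -> DrusenHeightMap:
    path = Path(path)
    heights = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    return DrusenHeightMap(
        heights_um=heights,
        bscan_spacing_um=meta["bscan_spacing_um"],
        ascan_pitch_um=meta["ascan_pitch_um"],
        axial_pitch_um=meta["axial_pitch_um"],
        fovea_row=meta.get("fovea_row", 0.0),
        fovea_col=meta.get("fovea_col", 0.0),
        filtered=meta.get("filtered", False),
        eye_id=meta.get("eye_id", ""),
    )


def cohort_manifest(eyes: list[GroundTruthEye]) -> pd.DataFrame:
    """Per-eye manifest with analytic ground-truth circle volumes."""
    rows = []
    for eye in eyes:
        rows.append(
            {
                "eye_id": eye.eye_id,
                "subject_id": eye.subject_id,
                "stage": eye.stage,
                "rpd_present": eye.rpd_present,
                "fovea_x_um": eye.fovea_x_um,
                "fovea_y_um": eye.fovea_y_um,
                "n_drusen": len(eye.bumps),
                "truth_volume_3mm_mm3": analytic_drusen_volume(eye, 3.0),
                "truth_volume_5mm_mm3": analytic_drusen_volume(eye, 5.0),
            }
        )
    return pd.DataFrame(rows)


MEASUREMENT_COLUMNS = [
    "eye_id", "subject_id", "stage", "rpd", "method",
    "volume_3mm_mm3", "volume_5mm_mm3",
]


def measurements_frame(
    records: list[tuple[GroundTruthEye, DrusenMeasurement]]
) -> pd.DataFrame:
    """Tidy measurements table: one row per eye x method."""
    rows = [
        {
            "eye_id": eye.eye_id,
            "subject_id": eye.subject_id,
            "stage": eye.stage,
            "rpd": eye.rpd_present,
            "method": m.method,
            "volume_3mm_mm3": m.volume_3mm_mm3,
            "volume_5mm_mm3": m.volume_5mm_mm3,
        }
        for eye, m in records
    ]
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
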