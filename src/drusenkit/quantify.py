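"""Drusen volumetry: circle volumes from filtered drusen height maps.

The clinical endpoint is drusen volume inside fovea-centered 3- and 5-mm
diameter circles (the 5-mm circle matches the grid used for Beckmann AMD
grading).  Sparse scan patterns sample the slow axis coarsely, so the
*filtered* drusen map is linearly interpolated across B-scans before
summation — drusen that fall between B-scans of a sparse raster are never
seen and cannot be recovered by interpolation, which is precisely the
mechanism that degrades medium-drusen sensitivity at low scan density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .segmentation import (
    DrusenHeightMap,
    LayerSurfaces,
    drusen_heights,
    estimate_rpe_offset,
    filter_small_components,
    floor_from_bm,
    floor_from_rpe_fit,
)

ALGORITHMS = ("bm_offset", "rpe_fit")


@dataclass(frozen=True)
class MeasureConfig:
    """Settings of the measurement pipeline."""

    min_height_px: int = 5
    fit_degree: int = 3
    fit_iterations: int = 5
    fit_tol_um: float = 5.0
    target_row_spacing_um: float | None = None  # None: keep the native spacing
    circle_diameters_mm: tuple[float, ...] = (3.0, 5.0)


@dataclass(frozen=True)
class DrusenMeasurement:
    eye_id: str
    method: str
    volume_3mm_mm3: float
    volume_5mm_mm3: float

    def __post_init__(self) -> None:
        if self.volume_3mm_mm3 < 0 or self.volume_5mm_mm3 < 0:
            raise ValueError("volumes must be >= 0")
        if self.volume_3mm_mm3 > self.volume_5mm_mm3 + 1e-12:
            raise ValueError("3-mm volume cannot exceed 5-mm volume")


def resample_enface(
    m: DrusenHeightMap, target_row_spacing_um: float
) -> DrusenHeightMap:
    """Linearly interpolate the height map along the slow (B-scan) axis.

    The fast axis is untouched.  The new grid is uniform at the target
    spacing over the original slow-axis span.
    """
    if m.shape[0] < 2:
        raise ValueError("resampling requires at least 2 B-scan rows")
    if not target_row_spacing_um > 0:
        raise ValueError("target spacing must be > 0")
    span = (m.shape[0] - 1) * m.bscan_spacing_um
    old_pos = np.arange(m.shape[0]) * m.bscan_spacing_um
    n_new = int(np.floor(span / target_row_spacing_um + 1e-9)) + 1
    new_pos = np.arange(n_new) * target_row_spacing_um
    idx = np.clip(np.searchsorted(old_pos, new_pos, side="right") - 1, 0, m.shape[0] - 2)
    frac = (new_pos - old_pos[idx]) / m.bscan_spacing_um
    h = (1 - frac)[:, None] * m.heights_um[idx] + frac[:, None] * m.heights_um[idx + 1]
    new_fovea_row = m.fovea_row * m.bscan_spacing_um / target_row_spacing_um
    return replace(
        m,
        heights_um=h,
        bscan_spacing_um=target_row_spacing_um,
        fovea_row=new_fovea_row,
    )


def volume_in_circle(
    m: DrusenHeightMap,
    center: tuple[float, float] | None = None,
    diameter_mm: float = 5.0,
) -> float:
    """Drusen volume (mm^3) inside a circle on the en-face grid.

    A node contributes height x row_spacing x A-scan pitch when its center
    lies within the circle (no partial-pixel weighting).  A circle larger
    than the grid is clipped with a warning.
    """
    if not diameter_mm > 0:
        raise ValueError("diameter_mm must be > 0")
    fr, fc = center if center is not None else (m.fovea_row, m.fovea_col)
    n_rows, n_cols = m.shape
    if not (0 <= fr <= n_rows - 1 and 0 <= fc <= n_cols - 1):
        raise ValueError("circle center lies outside the grid")
    r_um = diameter_mm * 1000 / 2
    dy = (np.arange(n_rows) - fr) * m.bscan_spacing_um
    dx = (np.arange(n_cols) - fc) * m.ascan_pitch_um
    if (
        fr * m.bscan_spacing_um < r_um
        or (n_rows - 1 - fr) * m.bscan_spacing_um < r_um
        or fc * m.ascan_pitch_um < r_um
        or (n_cols - 1 - fc) * m.ascan_pitch_um < r_um
    ):
        warnings.warn(
            f"{diameter_mm}-mm circle exceeds the grid; returning the clipped sum",
            stacklevel=2,
        )
    inside = (dy[:, None] ** 2 + dx[None, :] ** 2) <= r_um**2
    total_um3 = float(np.sum(m.heights_um[inside])) * m.bscan_spacing_um * m.ascan_pitch_um
    return total_um3 / 1e9


def segment(
    s: LayerSurfaces, algorithm: str, config: MeasureConfig = MeasureConfig()
) -> DrusenHeightMap:
    """Run one of the two segmentation algorithms and the component filter."""
    if algorithm == "bm_offset":
        floor = floor_from_bm(s, estimate_rpe_offset(s))
    elif algorithm == "rpe_fit":
        floor = floor_from_rpe_fit(
            s, degree=config.fit_degree, n_iter=config.fit_iterations,
            tol_um=config.fit_tol_um,
        )
    else:
        raise ValueError(f"unknown algorithm: {algorithm!r}")
    return filter_small_components(drusen_heights(s, floor), config.min_height_px)


def measure_eye(
    s: LayerSurfaces, algorithm: str, config: MeasureConfig = MeasureConfig()
) -> DrusenMeasurement:
    """Full measurement pipeline for one scan.

    floor -> heights -> component filter -> slow-axis resampling (if a
    target spacing is configured) -> fovea-centered circle volumes.  Fully
    automated: there are no manual-correction hooks.
    """
    m = segment(s, algorithm, config)
    if (
        config.target_row_spacing_um is not None
        and abs(config.target_row_spacing_um - m.bscan_spacing_um) > 1e-9
    ):
        m = resample_enface(m, config.target_row_spacing_um)
    vols = {d: volume_in_circle(m, diameter_mm=d) for d in config.circle_diameters_mm}
    return DrusenMeasurement(
        eye_id=s.eye_id,
        method=f"{s.meta.get('device', 'scan')}:{algorithm}",
        volume_3mm_mm3=vols.get(3.0, 0.0),
        volume_5mm_mm3=vols.get(5.0, 0.0),
    )
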