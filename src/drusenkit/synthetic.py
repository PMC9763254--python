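"""Synthetic OCT cohort generation with analytic ground-truth drusen.

Eyes are modeled in an en-face coordinate system (x = fast/A-scan axis,
y = slow/B-scan axis, um) with the fovea at the origin.  Each eye carries

* a smooth Bruch's membrane (BM) baseline (low-order 2-D polynomial),
* a physiologic BM-to-RPE offset,
* drusen as spherical caps lifting the RPE (closed-form volumes give an
  analytic ground truth), and
* optional reticular pseudodrusen (RPD): confluent deposits sitting ABOVE
  the RPE that segmentation algorithms capture only inconsistently.

``simulate_scan`` samples the surfaces on a device grid (B-scan spacing,
A-scan pitch, field of view) and applies the device's systematic drusen
height distortion, stochastic RPD capture, and per-node Gaussian surface
noise, producing the :class:`~drusenkit.segmentation.LayerSurfaces` input
of the segmentation stage.

Stage labels follow the Beckmann classification by maximal drusen
diameter: small <= 63 um (no AMD), medium 63-125 um (early AMD, eAMD),
large > 125 um (intermediate AMD, iAMD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segmentation import LayerSurfaces

STAGES = ("no_amd", "eamd", "iamd")

SMALL_MAX_UM = 63.0
MEDIUM_MAX_UM = 125.0


class UnknownStageError(ValueError):
    """Stage label outside {no_amd, eamd, iamd}."""


@dataclass(frozen=True)
class DrusenBump:
    """One druse, modeled as a spherical cap on the healthy RPE."""

    center_x_um: float
    center_y_um: float
    base_diameter_um: float
    height_um: float

    def __post_init__(self) -> None:
        if not self.base_diameter_um > 0:
            raise ValueError("base_diameter_um must be > 0")
        if not self.height_um > 0:
            raise ValueError("height_um must be > 0")
        if self.height_um > self.base_diameter_um / 2 + 1e-9:
            raise ValueError("spherical cap requires height <= base radius")

    @property
    def base_radius_um(self) -> float:
        return self.base_diameter_um / 2

    @property
    def volume_mm3(self) -> float:
        """Closed-form spherical-cap volume V = (pi h / 6)(3 a^2 + h^2)."""
        a, h = self.base_radius_um, self.height_um
        return float(np.pi * h / 6 * (3 * a * a + h * h)) / 1e9


@dataclass(frozen=True)
class RpdLesion:
    """A reticular pseudodrusen patch above the RPE (same cap geometry).

    Individual RPD lesions are ~100 um across but typically coalesce into
    confluent ribbons; a lesion here represents such a confluent patch, so
    default diameters are several hundred um.
    """

    center_x_um: float
    center_y_um: float
    diameter_um: float
    height_um: float

    def __post_init__(self) -> None:
        if not self.diameter_um > 0:
            raise ValueError("diameter_um must be > 0")
        if not self.height_um > 0:
            raise ValueError("height_um must be > 0")


@dataclass
class GroundTruthEye:
    eye_id: str
    subject_id: str
    stage: str
    rpd_present: bool
    fovea_x_um: float
    fovea_y_um: float
    bm_coeffs: np.ndarray  # [c00, c10, c01, c20, c02] on x/R, y/R with R=3000 um
    rpe_offset_um: float
    bumps: list[DrusenBump] = field(default_factory=list)
    rpd: list[RpdLesion] = field(default_factory=list)
    field_x_um: float = 9000.0
    field_y_um: float = 9000.0

    def bm_elevation(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        c = self.bm_coeffs
        u, v = np.asarray(x_um) / 3000.0, np.asarray(y_um) / 3000.0
        return c[0] + c[1] * u + c[2] * v + c[3] * u * u + c[4] * v * v

    def drusen_elevation(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Total drusen height above the healthy RPE (caps are additive)."""
        x_um, y_um = np.asarray(x_um, float), np.asarray(y_um, float)
        out = np.zeros(np.broadcast(x_um, y_um).shape)
        for b in self.bumps:
            out += cap_height(
                x_um - b.center_x_um, y_um - b.center_y_um,
                b.base_radius_um, b.height_um,
            )
        return out


@dataclass(frozen=True)
class DeviceProfile:
    """Scan-pattern and measurement-distortion parameters of one modality.

    ``family`` identifies the device/algorithm a scan pattern belongs to:
    RPD capture is consistent within a family (the same algorithm treats a
    lesion the same way on both of its scan patterns) and independent
    across families.
    """

    name: str
    n_bscans: int
    bscan_spacing_um: float
    ascan_pitch_um: float
    axial_pitch_um: float = 3.9
    field_x_um: float = 6000.0
    surface_noise_sd_um: float = 2.0
    bias_slope: float = 1.0
    bias_intercept_um: float = 0.0
    rpd_capture_prob: float = 0.5
    family: str = ""

    def __post_init__(self) -> None:
        if self.n_bscans < 2:
            raise ValueError("n_bscans must be >= 2")
        for name in ("bscan_spacing_um", "ascan_pitch_um", "axial_pitch_um"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.rpd_capture_prob <= 1:
            raise ValueError("rpd_capture_prob must be in [0, 1]")

    @property
    def field_y_um(self) -> float:
        return (self.n_bscans - 1) * self.bscan_spacing_um

    @property
    def n_ascans(self) -> int:
        return int(round(self.field_x_um / self.ascan_pitch_um)) + 1


# Default modality profiles.  Fields in um: the 30x25 deg dense raster spans
# ~8700 x 7250 um (241 B-scans, ~30 um apart), the 20x20 deg sparse raster
# ~5800 x 5800 um (25 B-scans, ~240 um apart) at ~290 um/deg, and the
# 200 x 200 macular cube covers 6 x 6 mm.  The cube modality carries a
# multiplicative drusen-height bias (slope 0.5) emulating the systematic
# inter-device difference; RPD patches are captured with probability 0.5
# per lesion per scan, independently across scans.
SPECTRALIS_DENSE = DeviceProfile(
    name="spectralis_dense", n_bscans=241, bscan_spacing_um=30.2,
    ascan_pitch_um=29.0, field_x_um=8700.0, family="spectralis",
    rpd_capture_prob=0.6,
)
SPECTRALIS_SPARSE = DeviceProfile(
    name="spectralis_sparse", n_bscans=25, bscan_spacing_um=241.7,
    ascan_pitch_um=29.0, field_x_um=5800.0, family="spectralis",
    rpd_capture_prob=0.6,
)
CIRRUS_CUBE = DeviceProfile(
    name="cirrus", n_bscans=200, bscan_spacing_um=6000.0 / 199,
    ascan_pitch_um=6000.0 / 199, field_x_um=6000.0,
    bias_slope=0.5, bias_intercept_um=0.0, family="cirrus",
    rpd_capture_prob=0.35,
)
DEFAULT_DEVICES = (SPECTRALIS_DENSE, SPECTRALIS_SPARSE, CIRRUS_CUBE)


@dataclass(frozen=True)
class StageModel:
    """Bump-count and size distributions of one AMD stage.

    Counts are ``base + Poisson(lam)``; diameters uniform on the class
    range; heights a uniform fraction of the diameter (cap geometry bounds
    the fraction at 0.5).
    """

    p_any: float = 1.0
    n_small_base: int = 0
    n_small_lam: float = 0.0
    n_medium_base: int = 0
    n_medium_lam: float = 0.0
    n_large_base: int = 0
    n_large_lam: float = 0.0
    #: gamma shape of a per-eye multiplier on the large-drusen rate
    #: (None: plain Poisson).  Gamma-mixed Poisson counts reproduce the
    #: strongly right-skewed, overdispersed drusen-volume distributions
    #: seen in intermediate AMD.
    count_dispersion: float | None = None
    small_d_range: tuple[float, float] = (30.0, SMALL_MAX_UM)
    medium_d_range: tuple[float, float] = (SMALL_MAX_UM + 0.5, MEDIUM_MAX_UM)
    large_d_range: tuple[float, float] = (150.0, 700.0)
    height_frac_range: tuple[float, float] = (0.20, 0.35)
    large_height_frac_range: tuple[float, float] = (0.20, 0.35)


DEFAULT_STAGE_MODELS: dict[str, StageModel] = {
    # ~70% of no-AMD eyes are drusen-free; the rest carry a few drupelets.
    "no_amd": StageModel(p_any=0.3, n_small_base=1, n_small_lam=1.5),
    "eamd": StageModel(n_small_lam=2.0, n_medium_base=1, n_medium_lam=3.0),
    "iamd": StageModel(n_medium_lam=4.0, n_large_base=1, n_large_lam=7.0,
                       count_dispersion=1.3),
}


@dataclass
class SimCohortConfig:
    n_per_stage: dict[str, int] = field(
        default_factory=lambda: {"no_amd": 25, "eamd": 25, "iamd": 60}
    )
    rpd_fraction_iamd: float = 0.4
    stage_models: dict[str, StageModel] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_MODELS)
    )
    devices: tuple[DeviceProfile, ...] = DEFAULT_DEVICES
    rng_seed: int = 0
    field_x_um: float = 9000.0
    field_y_um: float = 9000.0
    bump_extent_um: float = 2400.0  # bumps placed within this radius of the fovea
    rpd_n_base: int = 3
    rpd_n_lam: float = 5.0
    rpd_d_range: tuple[float, float] = (600.0, 1400.0)
    rpd_h_range: tuple[float, float] = (30.0, 70.0)
    #: total RPD patch volume as a fraction of the eye's soft-drusen volume
    #: (RPD burden tracks disease severity)
    rpd_load_factor: float = 1.2
    #: soft-drusen rate multiplier in RPD eyes (RPD eyes carry slightly
    #: lower soft-drusen volumes than RPD-free intermediate AMD eyes)
    rpd_soft_drusen_scale: float = 0.6
    min_rpd_height_um: float = 10.0

    def __post_init__(self) -> None:
        for stage, n in self.n_per_stage.items():
            if stage not in STAGES:
                raise UnknownStageError(stage)
            if n < 0:
                raise ValueError("stage counts must be >= 0")
        if not 0 <= self.rpd_fraction_iamd <= 1:
            raise ValueError("rpd_fraction_iamd must be in [0, 1]")


def cap_height(
    dx_um: np.ndarray, dy_um: np.ndarray, base_radius_um: float, height_um: float
) -> np.ndarray:
    """Height profile of a spherical cap at offsets (dx, dy) from its center."""
    a, h = base_radius_um, height_um
    r2 = np.asarray(dx_um, float) ** 2 + np.asarray(dy_um, float) ** 2
    sphere_r = (a * a + h * h) / (2 * h)
    out = np.sqrt(np.maximum(sphere_r**2 - r2, 0.0)) - (sphere_r - h)
    return np.where(r2 <= a * a, np.maximum(out, 0.0), 0.0)


def _draw_bumps(stage: str, model: StageModel, rng: np.random.Generator,
                extent_um: float, rate_scale: float = 1.0) -> list[DrusenBump]:
    if rng.random() >= model.p_any:
        return []
    specs: list[tuple[tuple[float, float], tuple[float, float]]] = []
    large_lam = model.n_large_lam * rate_scale
    if model.count_dispersion is not None and large_lam > 0:
        # gamma-mixed Poisson: per-eye severity multiplier with unit mean
        large_lam *= rng.gamma(model.count_dispersion, 1.0 / model.count_dispersion)
    n_small = model.n_small_base + rng.poisson(model.n_small_lam * rate_scale)
    n_medium = model.n_medium_base + rng.poisson(model.n_medium_lam * rate_scale)
    n_large = model.n_large_base + rng.poisson(large_lam)
    specs += [(model.small_d_range, model.height_frac_range)] * n_small
    specs += [(model.medium_d_range, model.height_frac_range)] * n_medium
    specs += [(model.large_d_range, model.large_height_frac_range)] * n_large
    bumps = []
    for d_range, f_range in specs:
        d = rng.uniform(*d_range)
        f = rng.uniform(*f_range)
        # uniform position on a disc around the fovea
        r = extent_um * np.sqrt(rng.random())
        theta = rng.uniform(0, 2 * np.pi)
        bumps.append(
            DrusenBump(
                center_x_um=r * np.cos(theta),
                center_y_um=r * np.sin(theta),
                base_diameter_um=d,
                height_um=min(f * d, d / 2),
            )
        )
    return bumps


def build_eye(
    stage: str,
    rng: np.random.Generator,
    config: SimCohortConfig,
    eye_id: str = "eye",
    subject_id: str = "subj",
    rpd_present: bool = False,
) -> GroundTruthEye:
    """Draw one ground-truth eye of the given Beckmann stage.

    The stage invariant on the maximal base diameter (<=63 for no AMD,
    63-125 for eAMD, >125 for iAMD) holds by construction of the stage's
    size-class counts.
    """
    if stage not in STAGES:
        raise UnknownStageError(f"unknown stage label: {stage!r}")
    model = config.stage_models[stage]
    rate_scale = config.rpd_soft_drusen_scale if rpd_present else 1.0
    bumps = _draw_bumps(stage, model, rng, config.bump_extent_um, rate_scale)
    rpd: list[RpdLesion] = []
    if rpd_present:
        n_rpd = config.rpd_n_base + rng.poisson(config.rpd_n_lam)
        raw: list[RpdLesion] = []
        for _ in range(n_rpd):
            r = config.bump_extent_um * np.sqrt(rng.random())
            theta = rng.uniform(0, 2 * np.pi)
            d = rng.uniform(*config.rpd_d_range)
            h = min(rng.uniform(*config.rpd_h_range), d / 2)
            raw.append(RpdLesion(r * np.cos(theta), r * np.sin(theta), d, h))
        # RPD burden tracks disease severity: scale patch heights so the
        # total patch volume is rpd_load_factor x the eye's drusen volume
        soft_vol = sum(b.volume_mm3 for b in bumps)
        raw_vol = sum(
            float(np.pi * l.height_um / 6
                  * (3 * (l.diameter_um / 2) ** 2 + l.height_um**2)) / 1e9
            for l in raw
        )
        if raw_vol > 0 and soft_vol > 0:
            scale = config.rpd_load_factor * soft_vol / raw_vol
            for lesion in raw:
                h = float(
                    np.clip(lesion.height_um * scale,
                            config.min_rpd_height_um, lesion.diameter_um / 2)
                )
                rpd.append(
                    RpdLesion(lesion.center_x_um, lesion.center_y_um,
                              lesion.diameter_um, h)
                )
    coeffs = np.array(
        [
            rng.uniform(50.0, 150.0),
            rng.uniform(-20.0, 20.0),
            rng.uniform(-20.0, 20.0),
            rng.uniform(-25.0, 10.0),
            rng.uniform(-25.0, 10.0),
        ]
    )
    return GroundTruthEye(
        eye_id=eye_id,
        subject_id=subject_id,
        stage=stage,
        rpd_present=rpd_present,
        fovea_x_um=0.0,
        fovea_y_um=0.0,
        bm_coeffs=coeffs,
        rpe_offset_um=rng.uniform(30.0, 40.0),
        bumps=bumps,
        rpd=rpd,
        field_x_um=config.field_x_um,
        field_y_um=config.field_y_um,
    )


def analytic_drusen_volume(
    eye: GroundTruthEye,
    circle_diameter_mm: float,
    center: tuple[float, float] | None = None,
    clip_grid_um: float = 4.0,
) -> float:
    """Ground-truth drusen volume (mm^3) inside a fovea-centered circle.

    Caps entirely inside the circle contribute their closed-form volume
    V = (pi h / 6)(3 a^2 + h^2); caps straddling the boundary are clipped by
    numeric integration on a fine grid; caps not overlapping the circle
    contribute nothing.
    """
    if not circle_diameter_mm > 0:
        raise ValueError("circle_diameter_mm must be > 0")
    cx, cy = center if center is not None else (eye.fovea_x_um, eye.fovea_y_um)
    r_circ = circle_diameter_mm * 1000 / 2
    total = 0.0
    for b in eye.bumps:
        d = np.hypot(b.center_x_um - cx, b.center_y_um - cy)
        a = b.base_radius_um
        if d + a <= r_circ:
            total += b.volume_mm3
        elif d - a >= r_circ:
            continue
        else:  # straddles the boundary: clip numerically
            g = clip_grid_um
            n = int(np.ceil(2 * a / g)) + 1
            xs = b.center_x_um + np.linspace(-a, a, n)
            ys = b.center_y_um + np.linspace(-a, a, n)
            xx, yy = np.meshgrid(xs, ys)
            hh = cap_height(xx - b.center_x_um, yy - b.center_y_um, a, b.height_um)
            inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_circ**2
            step = 2 * a / (n - 1)
            total += float(np.sum(hh * inside)) * step * step / 1e9
    return total


def _add_cap_on_grid(
    grid: np.ndarray, xs: np.ndarray, ys: np.ndarray,
    cx: float, cy: float, a: float, h: float,
) -> None:
    """Add one cap's height profile to a regular grid, in place.

    Only the cap's bounding window is evaluated (xs, ys are sorted).
    """
    i0, i1 = np.searchsorted(ys, [cy - a, cy + a])
    j0, j1 = np.searchsorted(xs, [cx - a, cx + a])
    if i0 == i1 or j0 == j1:
        return
    grid[i0:i1, j0:j1] += cap_height(
        xs[j0:j1][None, :] - cx, ys[i0:i1][:, None] - cy, a, h
    )


def simulate_scan(
    eye: GroundTruthEye,
    device: DeviceProfile,
    rng: np.random.Generator,
    rpd_captured: list[bool] | None = None,
) -> LayerSurfaces:
    """Sample an eye's surfaces on a device grid.

    BM = baseline + noise.  RPE = BM + physiologic offset + the device's
    distortion of the total measured elevation (``bias_slope * h +
    bias_intercept`` where h > 0, with h the drusen height plus the height
    of captured RPD patches — the algorithm's systematic error applies to
    everything it segments as an RPE elevation) + noise.  RPD capture is
    Bernoulli per lesion per scan (probability ``device.rpd_capture_prob``)
    unless an explicit ``rpd_captured`` mask is given; :func:`build_cohort`
    shares one mask across the scan patterns of a device family and draws
    families independently.
    """
    if device.field_x_um > eye.field_x_um or device.field_y_um > eye.field_y_um:
        raise ValueError("device field exceeds the eye's field")
    ys = eye.fovea_y_um + (
        np.arange(device.n_bscans) - (device.n_bscans - 1) / 2
    ) * device.bscan_spacing_um
    n_cols = device.n_ascans
    xs = eye.fovea_x_um + (np.arange(n_cols) - (n_cols - 1) / 2) * device.ascan_pitch_um
    xx, yy = np.meshgrid(xs, ys)

    bm = eye.bm_elevation(xx, yy)
    elev = np.zeros_like(bm)  # measured elevation above the healthy RPE
    for b in eye.bumps:
        _add_cap_on_grid(
            elev, xs, ys, b.center_x_um, b.center_y_um,
            b.base_radius_um, b.height_um,
        )
    # noise is drawn before the RPD-capture Bernoullis so that with
    # rpd_capture_prob = 0 the surfaces are identical whether or not the
    # eye carries RPD (the capture draws then have no effect at all)
    bm_noise = rpe_noise = 0.0
    if device.surface_noise_sd_um > 0:
        bm_noise = rng.normal(0, device.surface_noise_sd_um, bm.shape)
        rpe_noise = rng.normal(0, device.surface_noise_sd_um, bm.shape)
    if rpd_captured is None:
        rpd_captured = [rng.random() < device.rpd_capture_prob for _ in eye.rpd]
    for lesion, captured in zip(eye.rpd, rpd_captured):
        if captured:
            _add_cap_on_grid(
                elev, xs, ys, lesion.center_x_um, lesion.center_y_um,
                lesion.diameter_um / 2, lesion.height_um,
            )
    biased = np.where(
        elev > 0, device.bias_slope * elev + device.bias_intercept_um, 0.0
    )
    rpe = bm + eye.rpe_offset_um + biased + rpe_noise
    bm = bm + bm_noise
    return LayerSurfaces(
        rpe_um=rpe,
        bm_um=bm,
        bscan_spacing_um=device.bscan_spacing_um,
        ascan_pitch_um=device.ascan_pitch_um,
        axial_pitch_um=device.axial_pitch_um,
        fovea_row=(device.n_bscans - 1) / 2,
        fovea_col=(n_cols - 1) / 2,
        eye_id=eye.eye_id,
        meta={"device": device.name},
    )


def build_cohort(
    config: SimCohortConfig,
) -> list[tuple[GroundTruthEye, dict[str, LayerSurfaces]]]:
    """Generate the full cohort: each eye scanned once per device profile.

    Deterministic given the config (including its seed): two calls with the
    same config produce field-by-field identical cohorts.
    """
    if not config.devices:
        raise ValueError("at least one device profile is required")
    rng = np.random.default_rng(config.rng_seed)
    cohort = []
    idx = 0
    for stage in STAGES:
        n = config.n_per_stage.get(stage, 0)
        for _ in range(n):
            rpd_present = bool(
                stage == "iamd" and rng.random() < config.rpd_fraction_iamd
            )
            eye = build_eye(
                stage,
                rng,
                config,
                eye_id=f"eye{idx:04d}",
                subject_id=f"subj{idx:04d}",
                rpd_present=rpd_present,
            )
            # one capture mask per device family: the same algorithm treats
            # an RPD patch consistently across its scan patterns
            captures: dict[str, list[bool]] = {}
            scans = {}
            for d in config.devices:
                fam = d.family or d.name
                if fam not in captures:
                    captures[fam] = [
                        rng.random() < d.rpd_capture_prob for _ in eye.rpd
                    ]
                scans[d.name] = simulate_scan(eye, d, rng, captures[fam])
            cohort.append((eye, scans))
            idx += 1
    return cohort
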