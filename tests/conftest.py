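import numpy as np
import pytest

from drusenkit.segmentation import LayerSurfaces
from drusenkit.synthetic import (
    DeviceProfile,
    DrusenBump,
    GroundTruthEye,
    SimCohortConfig,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_surfaces():
    """Flat BM at 100 um, RPE at a constant 35 um offset; tiny grid."""
    shape = (20, 30)
    bm = np.full(shape, 100.0)
    return LayerSurfaces(
        rpe_um=bm + 35.0,
        bm_um=bm,
        bscan_spacing_um=30.0,
        ascan_pitch_um=30.0,
        axial_pitch_um=3.9,
        fovea_row=9.5,
        fovea_col=14.5,
    )


def make_eye(bumps=(), rpd=(), offset=35.0, coeffs=None, field=9000.0):
    """Ground-truth eye with explicit drusen and a flat or custom BM."""
    return GroundTruthEye(
        eye_id="test-eye",
        subject_id="test-subj",
        stage="iamd" if bumps else "no_amd",
        rpd_present=bool(rpd),
        fovea_x_um=0.0,
        fovea_y_um=0.0,
        bm_coeffs=np.asarray(coeffs if coeffs is not None else [100, 0, 0, 0, 0], float),
        rpe_offset_um=offset,
        bumps=list(bumps),
        rpd=list(rpd),
        field_x_um=field,
        field_y_um=field,
    )


def clean_device(spacing_um, pitch_um=None, field=5200.0, **kw):
    """Noise-free, bias-free device profile for oracle comparisons."""
    pitch_um = spacing_um if pitch_um is None else pitch_um
    n = int(round(field / spacing_um)) + 1
    kw.setdefault("surface_noise_sd_um", 0.0)
    return DeviceProfile(
        name=f"clean{spacing_um:g}",
        n_bscans=n,
        bscan_spacing_um=spacing_um,
        ascan_pitch_um=pitch_um,
        field_x_um=field,
        **kw,
    )


@pytest.fixture
def single_cap_eye():
    """One 500 um / 60 um spherical cap at the fovea (volume 0.006004 mm^3)."""
    return make_eye([DrusenBump(0.0, 0.0, 500.0, 60.0)])


@pytest.fixture
def small_cohort_config():
    return SimCohortConfig(
        n_per_stage={"no_amd": 3, "eamd": 3, "iamd": 5}, rng_seed=7
    )
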