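import numpy as np
import pytest

import ufd_hemo as u
import ufd_hemo.synthetic_data as sd


@pytest.fixture(scope="session")
def desk_config():
    """Reduced acquisition (64x64 grid, 200-frame blocks, 30 s cadence)."""
    return u.AcquisitionConfig.desk_scale()


@pytest.fixture(scope="session")
def small_config():
    """Tiny acquisition for fast unit tests."""
    return u.AcquisitionConfig.desk_scale(frames_per_block=100,
                                          grid_shape=(32, 32),
                                          block_interval=120.0)


@pytest.fixture(scope="session")
def control_template():
    return u.HemodynamicTemplate.control()


@pytest.fixture(scope="session")
def tlv_template():
    return u.HemodynamicTemplate.tlv()


@pytest.fixture(scope="session")
def sham_template():
    return u.HemodynamicTemplate.sham()


@pytest.fixture(scope="session")
def regions64():
    return u.default_region_set((64, 64))


@pytest.fixture(scope="session")
def layout64(regions64):
    return u.build_vessel_layout(regions64, seed=1)


def bare_field(grid_shape, tissue_amp=0.0, vessel_pixels=(), counts=30.0,
               v=0.0, v_sys=None, v_dia=None, noise_sd=0.0, jitter=0.0,
               motion=None, heart_rate=4.2, blood_amp=1.0):
    """Hand-built scatterer field for closed-form checks."""
    nz, nx = grid_shape
    vessel_pixels = np.asarray(vessel_pixels, dtype=int)
    if v_sys is None:
        v_sys = v
    if v_dia is None:
        v_dia = v
    return sd.ScattererField(
        grid_shape=grid_shape,
        tissue_amp=np.full(grid_shape, float(tissue_amp)),
        tissue_phase=np.zeros(grid_shape),
        motion=motion or sd.TissueMotion(d1_amp=0.0, drift_rate=0.0),
        motion_weight=np.zeros(grid_shape),
        vessel_pixels=vessel_pixels,
        vessel_counts=np.full(vessel_pixels.shape, float(counts)),
        blood_amp=blood_amp, heart_rate=heart_rate,
        v_systolic=float(v_sys), v_diastolic=float(v_dia),
        velocity_jitter_sd=jitter, noise_sd=noise_sd)
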