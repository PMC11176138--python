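import numpy as np
import pytest

from relaxrepro import (
    GeometryConfig,
    TissueParams,
    make_phantom,
    protocol_preset,
    simulate_acquisition,
)

ALL_PRESET_KEYS = [(3, "T2star"), (3, "T2"), (7, "T2star"), (7, "T2")]


@pytest.fixture(scope="session")
def big_geometry():
    """Geometry with a tumor large enough (>1e3 voxels) for sampling checks."""
    return GeometryConfig(
        shape=(96, 96, 4),
        leg_radius=20.0,
        tumor_leg_center=(28.0, 48.0),
        contralateral_center=(68.0, 48.0),
        tumor_center=(24.0, 42.0),
        tumor_radius=12.0,
        muscle_roi_radius=10.0,
    )


@pytest.fixture(scope="session")
def tissue_7t_t2star():
    """7 T pre-contrast T2* operating point (tumor mean 14.2 +/- 2.35 ms)."""
    return {
        "tumor": TissueParams(T_mean=14.2, T_sd=2.35, S0_mean=100.0, A_mean=5.0),
        "muscle": TissueParams(T_mean=14.0, T_sd=1.0, S0_mean=80.0, A_mean=4.0),
        "bone": TissueParams(T_mean=0.8, T_sd=0.05, S0_mean=15.0, A_mean=1.0),
    }


@pytest.fixture(scope="session")
def phantom_7t(big_geometry, tissue_7t_t2star):
    phantom, roi = make_phantom(big_geometry, tissue_7t_t2star, seed=42)
    return phantom, roi


@pytest.fixture(scope="session")
def series_7t_noiseless(phantom_7t):
    phantom, _ = phantom_7t
    protocol = protocol_preset(7, "T2star", matrix=(96, 96), n_slices=4)
    return simulate_acquisition(phantom, protocol, snr=None, seed=0)


@pytest.fixture(scope="session")
def series_7t_snr50(phantom_7t):
    phantom, _ = phantom_7t
    protocol = protocol_preset(7, "T2star", matrix=(96, 96), n_slices=4)
    return simulate_acquisition(phantom, protocol, snr=50.0, seed=7)
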