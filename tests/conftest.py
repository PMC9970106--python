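"""Shared fixtures: expensive white-noise calibration computed once per session."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import audspec as a
from audspec.pipeline import white_noise_calibration

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wn_calib():
    """Full white-noise calibration (3 x 90 s) used by the acceptance checks."""
    return white_noise_calibration(seed=1, duration=90.0, n_noise=3)


@pytest.fixture(scope="session")
def noise_cochleogram():
    """8 s white-noise cochleogram shared by spectrum-profile tests."""
    w = a.gen_white_noise(8.0, 44100.0, seed=11)
    return a.compute_cochleogram(w, a.CochlearFilterbankSpec())


@pytest.fixture(scope="session")
def cf_grid():
    return a.make_cf_grid()


@pytest.fixture(scope="session")
def filterbank():
    return a.make_filterbank()


@pytest.fixture(scope="session")
def smooth_field():
    """Stationary synthetic cochleogram-shaped random field (periodic, mean-free)."""
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(3)
    field = gaussian_filter(rng.standard_normal((8 * 2100, 664)), (3.0, 10.0), mode="wrap")
    field -= field.mean()
    cfs = 100.0 * 2.0 ** (0.01 * np.arange(1, 665))
    return a.Cochleogram(
        values=field.astype(np.float32), env_fs=2100.0, cfs=cfs, octaves=np.log2(cfs / 100.0)
    )
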