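import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tmsemg import RunConfig, SimConfig, simulate_study
from tmsemg.signal import EmgTrace

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_study():
    """Two subjects, isometric only, full outcome set; shared across tests."""
    cfg = SimConfig(n_subjects=2, n_sessions=3, modes=("isometric",), seed=11)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def noiseless_cfg():
    """Degenerate variances and zero background: exact-arithmetic conditions."""
    return SimConfig(
        n_subjects=4, n_sessions=3, modes=("isometric",),
        sigma_session=0.0, sigma_trial=0.0,
        background_target=0.0, background_sd=0.0,
        factor_sigma_subject=0.0, factor_sigma_session=0.0,
        p_lici_missing=0.0, seed=5)


@pytest.fixture(scope="session")
def noiseless_run_cfg():
    return RunConfig(gate_target=0.0, gate_tol=0.02)


def sinusoid_trace(freq_hz: float, n: int = 2000, fs: float = 1000.0,
                   amplitude: float = 1.0, stim: tuple[int, ...] = ()) -> EmgTrace:
    t = np.arange(n) / fs
    return EmgTrace(amplitude * np.sin(2 * np.pi * freq_hz * t), fs, stim)
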