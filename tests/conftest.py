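import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import spikeprc as sp

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow,
                           HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture()
def four_spike_trial() -> sp.Trial:
    """Deterministic 100 ms-period train with a mid-ISI pulse at 150 ms."""
    return sp.Trial("a", np.array([0.0, 100.0, 200.0, 310.0]),
                    sp.PulseEvent(150.0, 50.0, 0.5), 350.0)


@pytest.fixture()
def unit_stats() -> sp.ISIStats:
    return sp.ISIStats(mean_isi=100.0, cv=0.0, n_intervals=2)


@pytest.fixture(scope="session")
def jittered_ensemble() -> sp.TrialEnsemble:
    """2000 jittered-periodic trials (T = 20 ms, spike jitter 1 ms), no pulse effect."""
    cfg = sp.JitteredPeriodicConfig(period=20.0, jitter_sd=1.0)
    proto = sp.ProtocolSpec(baseline=120.0, length=280.0, pulse_amplitude=1.0,
                            pulse_window=(120.0, 160.0), n_trials=2000)
    return sp.simulate_jittered_periodic(cfg, proto, seed=424)


@pytest.fixture(scope="session")
def periodic_ensemble() -> sp.TrialEnsemble:
    """Noiseless periodic trains with a uniformly placed (ineffective) pulse."""
    cfg = sp.JitteredPeriodicConfig(period=20.0, jitter_sd=0.0)
    proto = sp.ProtocolSpec(baseline=120.0, length=280.0, pulse_amplitude=1.0,
                            pulse_window=(120.0, 160.0), n_trials=100)
    return sp.simulate_jittered_periodic(cfg, proto, seed=7)
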