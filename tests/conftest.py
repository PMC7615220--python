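import numpy as np
import pytest

from galpop import synthgen as sg


@pytest.fixture(scope="session")
def small_session():
    """One small virgin-like synthetic session shared by read-only tests."""
    cfg = sg.vir_like_population(seed=7, n_neurons=30, duration=400.0)
    tm, events = sg.generate_population_session(cfg)
    return cfg, tm, events


@pytest.fixture(scope="session")
def patch_with_steps():
    """One patch record with baseline spiking, a step protocol with planted
    depolarization block, and an EPSC-only PSC train."""
    cfg = sg.PatchConfig(duration=60.0, spike_rate_true=5.0, psc_rate_true=2.0,
                         epsc_fraction=1.0,
                         current_steps=[50.0, 100.0, 150.0, 200.0, 250.0],
                         depol_block_current=200.0, seed=3)
    return cfg, sg.generate_patch_record(cfg)


def constant_session(n_neurons=4, n_samples=200, value=1.0, fs=20.0):
    from galpop.datatypes import TraceMatrix
    return TraceMatrix(np.full((n_neurons, n_samples), value), sampling_rate=fs)
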