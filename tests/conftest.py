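import numpy as np
import pytest

from tactile2p.config import SimConfig
from tactile2p.pipeline import analyze_session
from tactile2p.synth import simulate_session, wt_mouse
from tactile2p import traces as tr


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Compact testing-phase session: full task structure, reduced counts."""
    return SimConfig(n_trials=80, go_fraction=0.8, n_neurons_range=(30, 30))


@pytest.fixture(scope="session")
def small_session(small_cfg):
    """One simulated control-like session shared across read-only tests."""
    mouse = wt_mouse(threshold_um=6.0)
    return simulate_session(small_cfg, mouse, np.random.default_rng(0), n_neurons=30)


@pytest.fixture(scope="session")
def small_aligned(small_session):
    """Preprocessed and aligned tensor for the shared session."""
    dff, ok = tr.preprocess(small_session.traces)
    return tr.zscore_align(
        dff, small_session.trial_table, small_session.traces.frame_rate_hz,
        celltype=small_session.traces.celltype, neuron_ok=ok,
    )


@pytest.fixture(scope="session")
def small_dff(small_session):
    dff, _ = tr.preprocess(small_session.traces)
    return dff
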