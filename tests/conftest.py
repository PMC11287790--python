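import numpy as np
import pandas as pd
import pytest

from metarousal.synthetic import (
    ObserverConfig,
    SessionConfig,
    simulate_behavior,
)
from metarousal import sdt


@pytest.fixture(scope="session")
def ideal_counts():
    """Large-sample confusion table from a noiseless-metacognition observer
    (d' = 1.5, c = 0, sigma_meta = 0)."""
    obs = ObserverConfig(d_prime_true=1.5, sigma_meta=0.0, n_trials=100_000)
    tab = simulate_behavior(obs, SessionConfig(p_missed=0.0), seed=10)
    return sdt.tabulate_counts(tab)


@pytest.fixture()
def tiny_trials():
    """Four clean trials covering every stimulus x response combination."""
    return pd.DataFrame({
        "stimulus": ["cw", "cw", "ccw", "ccw"],
        "response": ["cw", "ccw", "ccw", "cw"],
        "confidence": ["high", "high", "high", "high"],
        "rt_ms": [500.0, 600.0, 700.0, 800.0],
        "fixation_lost": [0, 0, 0, 0],
    })


@pytest.fixture()
def rng():
    # function-scoped: every test sees the same fresh stream regardless of
    # execution order
    return np.random.default_rng(1234)
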