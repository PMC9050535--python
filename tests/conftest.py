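import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ieegnorm import PipelineConfig, Recording, SimulationConfig

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def pipeline_cfg():
    return PipelineConfig()


@pytest.fixture
def small_recording(rng):
    """Four channels, 80 s at 200 Hz, distinct band content per channel."""
    fs = 200.0
    t = np.arange(int(80 * fs)) / fs
    samples = np.stack([
        20 * np.sin(2 * np.pi * 10 * t),
        10 * np.sin(2 * np.pi * 2.5 * t),
        5 * np.sin(2 * np.pi * 20 * t),
        np.zeros_like(t),
    ]) + rng.standard_normal((4, t.size))
    return Recording(samples, fs, ["A1", "A2", "B1", "B2"])


@pytest.fixture
def channel_table():
    return pd.DataFrame({
        "channel_id": ["A1", "A2", "B1", "B2"],
        "x": [0.0, 2.0, 10.0, 12.0],
        "y": [0.0, 0.0, 0.0, 0.0],
        "z": [0.0, 0.0, 0.0, 0.0],
        "soz": [False, True, False, False],
        "early_propagation": [False] * 4,
        "lesion": [False] * 4,
        "bad": [False] * 4,
        "white_matter": [False] * 4,
        "spike": [False] * 4,
    })


@pytest.fixture(scope="session")
def fast_map_and_cfg():
    """A normative map from the fast region-level path, shared across tests."""
    from ieegnorm.normative import build_normative_map
    from ieegnorm.simulate import simulate_normative_tables

    cfg = SimulationConfig(seed=7, n_normative=200, coverage=1.0)
    cohort = simulate_normative_tables(cfg)
    nmap = build_normative_map(cohort, min_participants=5)
    return nmap, cfg
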