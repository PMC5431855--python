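import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fibroscore as fs

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cfg():
    return fs.default_config(seed=0)


@pytest.fixture(scope="session")
def lit_table():
    """One full 10x5x5x7 screen with the literature ordering planted at a
    1-log spacing."""
    cfg = fs.literature_scenario(fs.default_config(seed=7), 1.0)
    return fs.generate_dataset(cfg)


@pytest.fixture(scope="session")
def pipeline_result(lit_table):
    return fs.run_pipeline(lit_table)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_pair(x, y, labels=("M1", "M2")):
    x = np.asarray(x, dtype=float)
    donors = [f"D{i}" for i in range(len(x))]
    return fs.PairedSample(labels, x, np.asarray(y, dtype=float), donors)
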