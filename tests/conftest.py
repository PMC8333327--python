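import numpy as np
import pandas as pd
import pytest

import zoomacro as zm


@pytest.fixture(scope="session")
def small_config():
    return zm.TransectConfig(n_stations=40)


@pytest.fixture(scope="session")
def stations(small_config):
    return zm.generate_stations(small_config, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact full dataset: 40 stations, 8 flat groups, all nets."""
    cfg = zm.TransectConfig(n_stations=40, total_abundance=150.0)
    reg = zm.flat_registry([f"G{i}" for i in range(1, 9)])
    return zm.generate_dataset(cfg, seed=5, registry=reg)


@pytest.fixture(scope="session")
def default_dataset():
    """Default 36-group registry at a reduced station count."""
    cfg = zm.TransectConfig(n_stations=60)
    return zm.generate_dataset(cfg, seed=9, nets=["WP2", "Bongo"])


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
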