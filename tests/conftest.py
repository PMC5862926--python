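import numpy as np
import pytest

import defaultbf as d


@pytest.fixture(scope="session")
def presidents():
    """Height-vote correlation summary recovered from printed values."""
    return d.fixture("presidents_stats")


@pytest.fixture(scope="session")
def kitchen_rolls():
    """Rotation-replication t-test summary recovered from printed values."""
    return d.fixture("kitchen_rolls_stats")


@pytest.fixture(scope="session")
def hair_color():
    from defaultbf.datasets import load_hair_color
    return load_hair_color()


@pytest.fixture(scope="session")
def singers():
    from defaultbf.datasets import load_singers
    return load_singers()


@pytest.fixture()
def rng():
    return np.random.default_rng(20170706)


def interleaved_two_group(delta: float, n_per_group: int, seed: int) -> d.DataTable:
    """Two-group stream in alternating collection order (for monitoring)."""
    gen = np.random.default_rng(seed)
    rows_y, rows_g = [], []
    for _ in range(n_per_group):
        rows_y.append(gen.normal(delta / 2.0, 1.0))
        rows_g.append("g1")
        rows_y.append(gen.normal(-delta / 2.0, 1.0))
        rows_g.append("g2")
    return d.DataTable({"y": rows_y, "group": rows_g},
                       {"y": "continuous", "group": "nominal"})
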