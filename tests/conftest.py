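import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from clonodyn import ClonotypeTable

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_table(sizes, sample_id="s", group="other", prefix="CASS"):
    """ClonotypeTable from a list of sizes or a {key: size} dict."""
    if isinstance(sizes, dict):
        counts = pd.Series(sizes, dtype="int64")
    else:
        counts = pd.Series(
            list(sizes),
            index=[f"{prefix}{i:04d}F" for i in range(len(sizes))],
            dtype="int64",
        )
    return ClonotypeTable(sample_id=sample_id, counts=counts, group=group)


@pytest.fixture
def table_factory():
    return make_table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_table(rng, max_clones=30, max_size=50, sample_id="r"):
    n = int(rng.integers(1, max_clones + 1))
    sizes = rng.integers(1, max_size + 1, size=n)
    return make_table(list(sizes), sample_id=sample_id, prefix=f"C{sample_id.upper()}")
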