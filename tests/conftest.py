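import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import chromstate as cs
from chromstate import synthetic as syn

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tiny_world():
    """A 2 x 1.5 Mbp simulated study shared across tests."""
    return cs.simulate(cs.Scenario.tiny(), seed=1)


@pytest.fixture(scope="session")
def tiny_grid(tiny_world):
    return tiny_world.truth.grid


@pytest.fixture()
def toy_layout():
    return cs.GenomeLayout([("chr1", 100_000), ("chr2", 60_000)])


def peakset(mark, rep, rows):
    """rows: (chrom, start, end, score) tuples."""
    df = pd.DataFrame(
        [(c, s, e, "", sc, ".") for c, s, e, sc in rows],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
    return cs.PeakSet(mark, rep, df)
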