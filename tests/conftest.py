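"""Shared fixtures. Expensive assets (the full lattice, the sorted
partition on it) are session-scoped so the acceptance tests and unit
tests reuse one copy."""

import numpy as np
import pytest

from hetsort.experiment import make_fixtures
from hetsort.graphs import make_bc_lattice, make_ws_graph
from hetsort.sortedness import random_partition, sort_network


@pytest.fixture(scope="session")
def ws1000():
    return make_ws_graph(1000, 12, 0.2, seed=0)


@pytest.fixture(scope="session")
def bc1018():
    return make_bc_lattice()


@pytest.fixture(scope="session")
def ring6():
    return make_fixtures("ring6")


@pytest.fixture(scope="session")
def labelled30():
    return make_fixtures("labelled30", seed=0)


@pytest.fixture(scope="session")
def bc_sorted(bc1018):
    """Random 10% partition on the full lattice plus its forward sorting
    trace (shared by the synchrony and sortedness acceptance tests)."""
    rng = np.random.default_rng(np.random.SeedSequence([7, 1]))
    part0 = random_partition(bc1018.N, 0.1, rng)
    trace = sort_network(
        bc1018, part0, rng=np.random.default_rng(np.random.SeedSequence([7, 2]))
    )
    return {"partition0": part0, "trace": trace}
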