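from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from netdose import (
    AffinityRecord,
    AffinityTable,
    PathwayNetwork,
    lps_pge2_fixture,
)


@pytest.fixture
def chain_net() -> PathwayNetwork:
    """Minimal A -> B -> C chain with exit C."""
    return PathwayNetwork.from_edges([("A", "B"), ("B", "C")], exit_node="C")


@pytest.fixture(scope="session")
def fixture_net() -> PathwayNetwork:
    return lps_pge2_fixture()


@pytest.fixture
def chain_affinity() -> AffinityTable:
    """One compound inhibiting node A of the chain with Ki = 10 uM (pKi 5)."""
    return AffinityTable([AffinityRecord("drug", "A", 5.0)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240516)
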