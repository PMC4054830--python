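import numpy as np
import pytest

from methylsite.curation import ProteinRecord
from methylsite.profiles import NormalizedProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20240501)


@pytest.fixture
def toy_records():
    """Three hand-built records: 2 annotated and 5 unannotated R sites, no
    window collisions (sequences differ everywhere outside the centres)."""
    return [
        ProteinRecord("P1", "ACDEFRGHIKLMN", {"R": {6}}),  # 1 pos
        ProteinRecord("P2", "WYVTSRQPNMRKI", {"R": set()}),  # 2 neg
        ProteinRecord("P3", "RHKDERCCWWRYYFARED", {"R": {11}}),  # 1 pos, 3 neg
    ]


@pytest.fixture
def uniform_profile():
    """All-0.5 normalized profile (every column constant)."""
    return NormalizedProfile(np.full((11, 20), 0.5))


def random_normalized_profile(rng):
    return NormalizedProfile(rng.uniform(0.05, 0.95, size=(11, 20)))
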