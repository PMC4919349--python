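import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from sterolscan import load_fixtures
from sterolscan.align import SubstitutionMatrix
from sterolscan.simulate import make_reference_annotation


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def blosum62():
    return SubstitutionMatrix.load("BLOSUM62")


@pytest.fixture(scope="session")
def synthetic_reference():
    """A synthetic LAS-annotated reference cyclase (650 aa) and its annotation."""
    return make_reference_annotation(seed=101)
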