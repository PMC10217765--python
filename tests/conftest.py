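from pathlib import Path

import numpy as np
import pytest

from midecomp import crosstab, read_uci_german
from midecomp.validation import random_table

REPO_ROOT = Path(__file__).resolve().parents[1]
GERMAN_PATHS = sorted((REPO_ROOT / "data" / "german").glob("german-*.data"))


@pytest.fixture(scope="session")
def german_records():
    """The UCI Statlog German credit data (1000 customers, 21 attributes)."""
    return read_uci_german(GERMAN_PATHS)


@pytest.fixture(scope="session")
def german_table(german_records):
    """Joint table of the benchmark attributes and the creditability target."""
    return crosstab(german_records, ["A1", "A3", "A12", "A14", "A21"])


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture
def make_table():
    """Factory for seeded random multinomial tables."""

    def _make(seed=0, **kw):
        return random_table(np.random.default_rng(seed), **kw)

    return _make
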