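import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `util` helpers

from phyloga import Alignment, SubstitutionModel
from util import quick_alignment, random_binary_tree


@pytest.fixture
def rng():
    return np.random.default_rng(20_26)


@pytest.fixture(scope="session")
def tiny_alignment():
    """Handwritten 4-taxon, 8-site alignment."""
    return Alignment(
        ["alpha", "beta", "gamma", "delta"],
        {
            "alpha": "ACGTACGT",
            "beta":  "ACGTACGA",
            "gamma": "ACGTTCGA",
            "delta": "ACGGTCGA",
        },
    )


@pytest.fixture(scope="session")
def jc_tree8():
    return random_binary_tree([f"t{i}" for i in range(8)], seed=81)


@pytest.fixture(scope="session")
def jc_alignment8(jc_tree8):
    """8 taxa x 600 sites simulated under JC."""
    return quick_alignment(jc_tree8, SubstitutionModel(family="JC"), 600, seed=82)
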