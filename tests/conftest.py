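import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from dekernet import Dataset, GoldStandard


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_dataset(rng):
    X = rng.normal(size=(12, 4))
    return Dataset(X=X, feature_names=("G1", "G2", "G3", "G4"))


@pytest.fixture
def triplet_gold():
    """Gold standard a -- b -- c plus an isolated node d."""
    return GoldStandard(
        true_edges=frozenset({("a", "b"), ("b", "c")}),
        feature_names=("a", "b", "c", "d"),
    )


@pytest.fixture
def separating_fixture():
    from dekernet.fixtures import separating_feature

    return separating_feature()
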