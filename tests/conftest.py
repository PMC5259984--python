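import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from pretata.ctd import DEFAULT_GROUPINGS, HYDROPHOBICITY_GROUPS, PropertyGrouping
from pretata.seqio import AMINO_ALPHABET, FeatureTable


@pytest.fixture(scope="session")
def hydrophobicity():
    return PropertyGrouping.from_strings("hydrophobicity", *HYDROPHOBICITY_GROUPS)


@pytest.fixture(scope="session")
def grouping_strings():
    """The 8 default partitions as plain letter strings for the oracles."""
    return [
        tuple("".join(sorted(g)) for g in gp.groups)
        for gp in DEFAULT_GROUPINGS.groupings
    ]


def random_amino(rng, length):
    return "".join(rng.choice(list(AMINO_ALPHABET), size=length))


def random_ss(rng, length):
    return "".join(rng.choice(list("HEC"), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_labeled_table():
    rng = np.random.default_rng(11)
    values = rng.normal(size=(30, 5))
    values[:, 0] += np.repeat([0.0, 3.0], 15)  # informative column
    return FeatureTable(
        row_ids=[f"r{i}" for i in range(30)],
        feature_names=[f"f{j}" for j in range(5)],
        values=values,
        labels=["negative"] * 15 + ["positive"] * 15,
    )
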