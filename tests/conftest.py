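import numpy as np
import pandas as pd
import pytest

from metacompare.ecology import AbundanceMatrix
from metacompare.synthetic_data import (
    make_reference_set,
    table1_preset,
)
from metacompare.taxonomy import KmerClassifier


@pytest.fixture
def rng():
    return np.random.default_rng(1)


@pytest.fixture
def two_group_matrix():
    """Small raw-count matrix: 3 features x 4 samples in two groups."""
    data = pd.DataFrame(
        {
            "a1": [30, 10, 60],
            "a2": [25, 15, 60],
            "b1": [5, 40, 55],
            "b2": [8, 35, 57],
        },
        index=["f1", "f2", "f3"],
    )
    groups = pd.Series({"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    return AbundanceMatrix(data, groups, raw=True)


@pytest.fixture(scope="session")
def preset_power():
    """Reduced-dispersion study spec + shared references and classifier.

    Session-scoped because the reference genomes and the k-mer index are
    the fixed database side of the study; only community/read seeds vary
    between runs.
    """
    spec = table1_preset(n_human=20, reads_per_library=1000, sigma=0.3)
    refs = make_reference_set(spec, np.random.default_rng(2**20 + 11))
    classifier = KmerClassifier(refs.references())
    return spec, refs, classifier
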