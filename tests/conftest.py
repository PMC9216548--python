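"""Shared fixtures: small matrices plus the session-scoped benchmark corpus."""

import warnings

import numpy as np
import pandas as pd
import pytest

from mplkit.io import BetaMatrix
from mplkit.split import detect_split_sites
from mplkit.synthetic import preset_corpus

#: Seed of the benchmark bundle used across the suite.
CORPUS_SEED = 42


@pytest.fixture(scope="session")
def corpus():
    return preset_corpus(CORPUS_SEED)


@pytest.fixture(scope="session")
def corpus_split_calls(corpus):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return detect_split_sites(corpus.matrix)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix():
    """3 sites x 4 samples, clean values."""
    data = pd.DataFrame(
        [[0.10, 0.12, 0.11, 0.09],
         [0.90, 0.88, 0.91, 0.92],
         [0.50, 0.49, 0.51, 0.50]],
        index=["cgA", "cgB", "cgC"],
        columns=["S1", "S2", "S3", "S4"],
    )
    return BetaMatrix(data, dataset_id="demo")


def make_matrix(values, sites=None, samples=None, dataset_id=None):
    values = np.asarray(values, dtype=float)
    sites = sites or [f"cg{i:03d}" for i in range(values.shape[0])]
    samples = samples or [f"S{j + 1}" for j in range(values.shape[1])]
    return BetaMatrix(pd.DataFrame(values, index=sites, columns=samples),
                      dataset_id=dataset_id)
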