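"""Shared fixtures: a small seeded synthetic corpus and its features.

Session scope keeps corpus generation and featurization out of individual
test timings; every consumer treats the objects as read-only.
"""

import numpy as np
import pytest

from lncclass import (CorpusSpec, enumerate_patterns, featurize_records,
                      generate_corpus)


@pytest.fixture(scope="session")
def table5():
    return enumerate_patterns(1, 5)


@pytest.fixture(scope="session")
def small_corpus():
    """120 transcripts per class at the default class separation."""
    return generate_corpus(CorpusSpec(n_per_class=120, seed=11,
                                      length_range=(300, 1200)))


@pytest.fixture(scope="session")
def small_features(small_corpus, table5):
    """(pos_X, neg_X) feature matrices for the small corpus."""
    pos_X, _ = featurize_records(small_corpus.coding, table5)
    neg_X, _ = featurize_records(small_corpus.noncoding, table5)
    return pos_X, neg_X


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write `(id, seq)` pairs to a temporary FASTA file and return the path."""
    def _write(records, name="input.fa"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path
    return _write


@pytest.fixture(scope="session")
def separable_problem():
    """Two well-separated Gaussian clusters in 8 dimensions."""
    rng = np.random.default_rng(42)
    n = 60
    pos = rng.normal(loc=2.0, scale=0.4, size=(n, 8))
    neg = rng.normal(loc=-2.0, scale=0.4, size=(n, 8))
    X = np.vstack([pos, neg])
    y = np.concatenate([np.ones(n, dtype=int), -np.ones(n, dtype=int)])
    return X, y
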