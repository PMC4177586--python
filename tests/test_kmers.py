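"""k-mer pattern enumeration, sliding-window counting and calibrated features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncclass import (InputError, TranscriptRecord, default_calibration,
                      enumerate_patterns, featurize, featurize_batch,
                      featurize_records, sliding_window_counts,
                      uniform_calibration)
from lncclass.io import write_feature_tsv, write_svmlight


def naive_counts(seq: str, k: int):
    """Independent oracle: substring extraction over every window."""
    counts: dict[str, int] = {}
    valid = 0
    for i in range(len(seq) - k + 1):
        window = seq[i:i + k]
        if set(window) <= set("ACGT"):
            counts[window] = counts.get(window, 0) + 1
            valid += 1
    return counts, valid


# --- pattern enumeration ---------------------------------------------------

@pytest.mark.parametrize("k_min,k_max,size", [
    (1, 5, 1364),  # 4 + 16 + 64 + 256 + 1024
    (1, 4, 340),
    (1, 1, 4),
    (2, 3, 80),
])
def test_pattern_table_size(k_min, k_max, size):
    assert len(enumerate_patterns(k_min, k_max)) == size


def test_pattern_table_ordering_and_uniqueness():
    table = enumerate_patterns(1, 2)
    assert table.patterns[:4] == ("A", "C", "G", "T")
    assert table.patterns[4:8] == ("AA", "AC", "AG", "AT")
    assert table.patterns[-1] == "TT"
    assert len(set(table.patterns)) == len(table.patterns)
    # grouped by ascending k, lexicographic within each k
    lengths = [len(p) for p in table.patterns]
    assert lengths == sorted(lengths)
    assert table.index_of("AC") == 5
    assert table.offset(2) == 4


@pytest.mark.parametrize("k_min,k_max", [(0, 5), (3, 2), (1, 9)])
def test_pattern_table_invalid_range(k_min, k_max):
    with pytest.raises(InputError):
        enumerate_patterns(k_min, k_max)


# --- sliding-window counts -------------------------------------------------

def test_counts_homopolymer():
    kc = sliding_window_counts(TranscriptRecord("r", "AAAAA"), k=1)
    assert kc.count_of("A") == 5 and kc.valid_windows == 5


def test_counts_hand_enumerated():
    kc = sliding_window_counts(TranscriptRecord("r", "ACGTACGT"), k=2)
    assert kc.valid_windows == 7
    expected = {"AC": 2, "CG": 2, "GT": 2, "TA": 1}
    for pattern, count in expected.items():
        assert kc.count_of(pattern) == count
    assert kc.counts.sum() == 7


def test_counts_skip_ambiguous_windows():
    # windows AC, CN, NG, GT: only the two clean ones count
    kc = sliding_window_counts(TranscriptRecord("r", "ACNGT"), k=2)
    assert kc.valid_windows == 2
    assert kc.count_of("AC") == 1 and kc.count_of("GT") == 1


def test_counts_sequence_shorter_than_k():
    kc = sliding_window_counts(TranscriptRecord("r", "ACG"), k=5)
    assert kc.valid_windows == 0 and kc.counts.sum() == 0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seq=st.text(alphabet="ACGTN", min_size=0, max_size=120),
       k=st.integers(min_value=1, max_value=5))
def test_counts_match_naive_oracle(seq, k):
    kc = sliding_window_counts(TranscriptRecord("r", seq), k)
    expected, valid = naive_counts(seq, k)
    assert kc.valid_windows == valid
    assert kc.counts.sum() == valid  # conservation
    for pattern, count in expected.items():
        assert kc.count_of(pattern) == count


# --- calibration -----------------------------------------------------------

def test_default_calibration_weights():
    cal = default_calibration(1, 5)
    assert cal.weights == {1: 1 / 256, 2: 1 / 64, 3: 1 / 16, 4: 1 / 4, 5: 1.0}
    assert default_calibration(1, 1).weights == {1: 1.0}


@pytest.mark.parametrize("factory", [default_calibration, uniform_calibration])
def test_calibration_weights_increase_with_k(factory):
    weights = factory(1, 5).weights
    values = [weights[k] for k in sorted(weights)]
    assert all(a < b for a, b in zip(values, values[1:]))
    assert all(v > 0 for v in values)


def test_calibration_equalises_natural_scales():
    # under a uniform base model a mononucleotide has frequency ~0.25 and a
    # specific 5-mer ~0.001; after calibration both land near 1e-3
    cal = default_calibration(1, 5)
    assert 0.25 * cal.weights[1] == pytest.approx(0.25 / 256)
    assert abs(0.25 * cal.weights[1] - 0.25 ** 5 * cal.weights[5]) < 1e-3


# --- featurize -------------------------------------------------------------

def test_featurize_homopolymer_closed_form(table5):
    fv = featurize(TranscriptRecord("a", "A" * 5), table5)
    assert fv.values[table5.index_of("A")] == pytest.approx(1 / 256)
    assert fv.values[table5.index_of("AA")] == pytest.approx(1 / 64)
    assert fv.values[table5.index_of("AAAAA")] == pytest.approx(1.0)
    nonzero = np.nonzero(fv.values)[0]
    assert set(nonzero) == {table5.index_of("A" * k) for k in range(1, 6)}


def test_per_k_normalization(table5):
    rng = np.random.default_rng(5)
    cal = default_calibration(1, 5)
    for _ in range(5):
        seq = "".join(rng.choice(list("ACGT"), size=rng.integers(5, 400)))
        fv = featurize(TranscriptRecord("r", seq), table5)
        for k in range(1, 6):
            block = fv.values[table5.block(k)]
            if len(seq) >= k:
                assert block.sum() == pytest.approx(cal.weights[k])
            else:
                assert block.sum() == 0


def test_featurize_empty_sequence_is_zero(table5, caplog):
    with caplog.at_level("WARNING"):
        fv = featurize(TranscriptRecord("e", ""), table5)
    assert not fv.values.any()
    assert any("empty" in rec.message for rec in caplog.records)


def test_uniform_random_composition(table5):
    """On a 10 kb uniform sequence, de-calibrated frequencies match the
    theoretical 0.25 (per base) and 0.25^5 (per specific 5-mer)."""
    rng = np.random.default_rng(123)
    seq = "".join(rng.choice(list("ACGT"), size=10_000))
    fv = featurize(TranscriptRecord("u", seq), table5)
    cal = default_calibration(1, 5)
    g = fv.values[table5.index_of("G")] / cal.weights[1]
    sigma1 = np.sqrt(0.25 * 0.75 / 10_000)
    assert abs(g - 0.25) < 3 * sigma1
    ggggg = fv.values[table5.index_of("GGGGG")] / cal.weights[5]
    p5 = 0.25 ** 5
    sigma5 = np.sqrt(p5 * (1 - p5) / 9_996)
    assert abs(ggggg - p5) < 3 * sigma5


def test_features_are_strand_specific(table5):
    """Reverse complement yields a different vector by design."""
    fwd = featurize(TranscriptRecord("f", "AAACCCGGG" * 30), table5)
    rev = featurize(TranscriptRecord("r", "CCCGGGTTT" * 30), table5)
    assert not np.allclose(fwd.values, rev.values)


def test_calibration_range_mismatch(table5):
    with pytest.raises(InputError):
        featurize(TranscriptRecord("r", "ACGT" * 60), table5,
                  calibration=default_calibration(1, 3))


# --- batch + export --------------------------------------------------------

def test_featurize_batch_shape_and_determinism(write_fasta_file, table5):
    path = write_fasta_file([("a", "ACGT" * 80), ("b", "GGCC" * 70),
                             ("c", "ATAT" * 90)])
    X1, ids1 = featurize_batch(path, table5)
    X2, _ = featurize_batch(path, table5)
    assert X1.shape == (3, 1364)
    assert ids1 == ["a", "b", "c"]
    assert np.array_equal(X1, X2)


def test_featurize_batch_empty_record_row(write_fasta_file, table5, caplog):
    path = write_fasta_file([("a", "ACGT" * 80), ("empty", "")])
    with caplog.at_level("WARNING"):
        X, ids = featurize_batch(path, table5)
    assert ids == ["a", "empty"]
    assert not X[1].any()


def test_featurize_batch_no_records(tmp_path, table5):
    path = tmp_path / "empty.fa"
    path.write_text("")
    with pytest.raises(InputError):
        featurize_batch(path, table5)


def test_featurize_thread_invariance(small_corpus, table5):
    records = list(small_corpus.coding[:12])
    X1, ids1 = featurize_records(records, table5, threads=1)
    X4, ids4 = featurize_records(records, table5, threads=4)
    assert ids1 == ids4
    assert np.array_equal(X1, X4)


def test_feature_exports(tmp_path, table5, small_features):
    import pandas as pd
    from sklearn.datasets import load_svmlight_file

    pos_X, _ = small_features
    X = pos_X[:5]
    tsv = tmp_path / "features.tsv"
    write_feature_tsv(tsv, [f"t{i}" for i in range(5)], X, table5.patterns)
    frame = pd.read_csv(tsv, sep="\t")
    assert frame.shape == (5, 1365)
    assert list(frame["id"]) == [f"t{i}" for i in range(5)]

    sparse = tmp_path / "features.svmlight"
    write_svmlight(sparse, X, [1, 1, 1, -1, -1])
    X_back, y_back = load_svmlight_file(str(sparse), n_features=1364)
    assert np.allclose(X_back.toarray(), X, atol=1e-12)
    assert list(y_back) == [1, 1, 1, -1, -1]
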