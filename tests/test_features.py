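"""PPM construction, log-odds scores, featurization, k-mers and F-scores."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qirnaforest.features import (
    FeatureMatrix,
    FeatureSpec,
    build_ppm,
    build_score_matrix,
    combine_features,
    featurize,
    fscore_rank,
    kmer_featurize,
    labeled_feature_matrix,
    position_index_set,
    ppm_feature_names,
    ppm_featurize,
    score_matrix,
)
from qirnaforest.seqio import from_strings
from qirnaforest.synthetic import GeneratorSpec, generate

seq_strategy = st.text(alphabet="ACGU", min_size=4, max_size=25)


class TestBuildPpm:
    def test_hand_counted_two_sequences(self):
        ppm = build_ppm(from_strings(["UA", "UG"]), window=2)
        assert ppm["U", 1] == 1.0
        assert ppm["A", 2] == 0.5
        assert ppm["G", 2] == 0.5
        assert ppm["A", -1] == 0.5
        assert ppm["G", -1] == 0.5
        # length-2 sequences overlap: position 2 is also position -1, 1 is -2
        assert ppm["U", -2] == 1.0

    @settings(max_examples=30, deadline=None)
    @given(st.lists(seq_strategy, min_size=1, max_size=20))
    def test_columns_sum_to_one(self, seqs):
        ppm = build_ppm(from_strings(seqs), window=4)
        sums = ppm.probs.sum(axis=0)
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_recovers_generator_first_position_probability(self):
        pos, _ = generate(GeneratorSpec(n_pos=1000, n_neg=0, pos_first_U=0.8, seed=12))
        ppm = build_ppm(pos, window=10)
        se = math.sqrt(0.8 * 0.2 / 1000)
        assert abs(ppm["U", 1] - 0.8) <= 3 * se

    def test_short_sequences_skipped_and_error_when_none_fit(self):
        mixed = from_strings(["ACGUACGUACGUACGU", "ACG"])
        ppm = build_ppm(mixed, window=10)
        assert ppm.n_sequences == 1 and ppm.n_skipped == 1
        with pytest.raises(ValueError, match="window 10"):
            build_ppm(from_strings(["ACG"]), window=10)


class TestScoreMatrix:
    def test_log2_ratio(self):
        # PPMs with controlled probabilities via sequence choice
        pos = build_ppm(from_strings(["AA", "AA", "CC", "GG"]), window=1)
        neg = build_ppm(from_strings(["AA", "CC", "GG", "UU"]), window=1)
        m = score_matrix(pos, neg)
        assert m["A", 1] == pytest.approx(math.log2(0.5 / 0.25))  # = 1.0

    def test_equal_ppms_give_zero_matrix(self):
        p = build_ppm(from_strings(["ACGUA", "GUACG", "CAGUA"]), window=2)
        m = score_matrix(p, p)
        assert (m.scores.to_numpy() == 0).all()

    def test_zero_probability_guard(self):
        pos = build_ppm(from_strings(["AA", "AA", "AC"]), window=1)  # P(U,1)=0? no U
        neg = build_ppm(from_strings(["UA", "CA", "GA"]), window=1)
        m = score_matrix(pos, neg)
        # P(A,1)=1 vs N(A,1)=0 -> guard gives 0; P(U,1)=0 vs N(U,1)=1/3 -> 0
        assert m["A", 1] == 0.0
        assert m["U", 1] == 0.0

    def test_window_mismatch_rejected(self):
        p2 = build_ppm(from_strings(["ACGU"]), window=2)
        p3 = build_ppm(from_strings(["ACGU"]), window=3)
        with pytest.raises(ValueError, match="mismatch"):
            score_matrix(p2, p3)

    def test_tsv_roundtrip(self, tmp_path):
        pos, neg = generate(GeneratorSpec(n_pos=40, n_neg=40, seed=2))
        m = build_score_matrix(pos, neg, window=10)
        path = tmp_path / "sm.tsv"
        m.to_tsv(path)
        from qirnaforest.features import ScoreMatrix

        back = ScoreMatrix.from_tsv(path)
        assert back.window == 10
        assert np.allclose(back.scores.to_numpy(), m.scores.to_numpy())


class TestPpmFeaturize:
    def test_one_hot_masking_hand_example(self):
        pos, neg = generate(GeneratorSpec(n_pos=60, n_neg=60, seed=3))
        m = build_score_matrix(pos, neg, window=10)
        seq = "U" + "G" * 18 + "A"
        fm = ppm_featurize(from_strings([seq]), m)
        names = dict(zip(fm.feature_names, fm.X[0]))
        assert names["1U"] == pytest.approx(m["U", 1])
        assert names["-1A"] == pytest.approx(m["A", -1])
        assert names["1A"] == names["1C"] == names["1G"] == 0.0

    def test_eighty_features_at_default_window(self, default_data):
        pos, neg = default_data
        m = build_score_matrix(pos, neg, window=10)
        fm = ppm_featurize(pos, m)
        assert fm.n_features == 80
        assert len(ppm_feature_names(10)) == 80

    def test_all_zero_matrix_gives_all_zero_features(self):
        p = build_ppm(from_strings(["ACGUACGUAC"] * 3), window=5)
        m = score_matrix(p, p)
        fm = ppm_featurize(from_strings(["ACGUACGUAC"]), m)
        assert (fm.X == 0).all()

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.text(alphabet="ACGU", min_size=6, max_size=25), min_size=2, max_size=8))
    def test_matches_per_character_lookup_oracle(self, seqs):
        w = 3
        half = max(1, len(seqs) // 2)
        pos = from_strings(seqs[:half])
        neg = from_strings(seqs[half:] or ["ACGUAC"])
        m = build_score_matrix(pos, neg, window=w)
        s = from_strings(seqs)
        fm = ppm_featurize(s, m)
        for row, rec in zip(fm.X, s):
            expected = {}
            for j in position_index_set(w):
                base = rec.seq[j - 1] if j > 0 else rec.seq[len(rec.seq) + j]
                for nuc in "ACGU":
                    expected[f"{j}{nuc}"] = m[nuc, j] if nuc == base else 0.0
            got = dict(zip(fm.feature_names, row))
            assert got == pytest.approx(expected)
            nonzero_slots = sum(
                any(got[f"{j}{n}"] != 0 for n in "ACGU") for j in position_index_set(w)
            )
            assert nonzero_slots <= 2 * w

    def test_binary_mode_is_indicator(self):
        pos, neg = generate(GeneratorSpec(n_pos=30, n_neg=30, seed=4))
        m = build_score_matrix(pos, neg, window=10)
        fm = ppm_featurize(pos, m, binary=True)
        assert set(np.unique(fm.X)) <= {0.0, 1.0}
        assert (fm.X.sum(axis=1) == 20).all()  # one hot per position


class TestKmerFeaturize:
    def test_mononucleotide_frequencies(self):
        fm = kmer_featurize(from_strings(["ACGU"]), kmax=1)
        assert fm.n_features == 4
        assert np.allclose(fm.X[0], 0.25)

    def test_dimension_1364_at_kmax_5(self):
        fm = kmer_featurize(from_strings(["ACGUACGUACGUACGUACGU"]), kmax=5)
        assert fm.n_features == sum(4 ** m for m in range(1, 6)) == 1364

    @settings(max_examples=30, deadline=None)
    @given(st.text(alphabet="ACGU", min_size=5, max_size=25))
    def test_matches_sliding_window_oracle_and_normalization(self, seq):
        kmax = 3
        fm = kmer_featurize(from_strings([seq]), kmax=kmax)
        values = dict(zip(fm.feature_names, fm.X[0]))
        for m in range(1, kmax + 1):
            denom = len(seq) - m + 1
            total = 0.0
            for kmer in ("".join(t) for t in itertools.product("ACGU", repeat=m)):
                count = sum(seq[i:i + m] == kmer for i in range(denom))
                assert values[kmer] == pytest.approx(count / denom)
                total += values[kmer]
            assert total == pytest.approx(1.0)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="shorter than kmax"):
            kmer_featurize(from_strings(["ACG"]), kmax=5)


def naive_fscore(X, y):
    """Two-pass textbook evaluation of the F-score formula."""
    out = []
    for i in range(X.shape[1]):
        xp = X[y == 1, i]
        xn = X[y == -1, i]
        xa = X[:, i]
        num = (xp.mean() - xa.mean()) ** 2 + (xn.mean() - xa.mean()) ** 2
        den = sum((v - xp.mean()) ** 2 for v in xp) / (len(xp) - 1) + sum(
            (v - xn.mean()) ** 2 for v in xn
        ) / (len(xn) - 1)
        if den == 0:
            out.append(np.inf if num > 0 else 0.0)
        else:
            out.append(num / den)
    return np.array(out)


class TestFscoreRank:
    def test_worked_example(self):
        fm = FeatureMatrix(
            ids=["a", "b", "c", "d"],
            X=np.array([[1.0], [0.0], [0.0], [0.0]]),
            feature_names=["f"],
            labels=np.array([1, 1, -1, -1]),
        )
        table = fscore_rank(fm)
        # means: pos 0.5, neg 0, all 0.25 -> numerator 0.125, denominator 0.5
        assert table.table.loc[0, "fscore"] == pytest.approx(0.25)

    def test_constant_feature_scores_zero(self):
        fm = FeatureMatrix(
            ids=list("abcd"), X=np.full((4, 1), 3.0), feature_names=["f"],
            labels=np.array([1, 1, -1, -1]),
        )
        assert fscore_rank(fm).table.loc[0, "fscore"] == 0.0

    def test_perfect_separation_flagged_infinite_and_ranked_first(self):
        fm = FeatureMatrix(
            ids=list("abcd"),
            X=np.array([[1.0, 0.3], [1.0, 0.1], [0.0, 0.2], [0.0, 0.4]]),
            feature_names=["sep", "noise"],
            labels=np.array([1, 1, -1, -1]),
        )
        table = fscore_rank(fm)
        assert table.table.loc[0, "feature"] == "sep"
        assert table.table.loc[0, "infinite"]
        assert np.isinf(table.table.loc[0, "fscore"])

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_agrees_with_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n, d = rng.integers(4, 50), rng.integers(1, 20)
        n_pos = int(rng.integers(2, n - 1))
        X = rng.normal(size=(int(n), int(d)))
        y = np.array([1] * n_pos + [-1] * (int(n) - n_pos))
        fm = FeatureMatrix(ids=[str(i) for i in range(int(n))], X=X,
                           feature_names=[f"f{i}" for i in range(int(d))], labels=y)
        got = fscore_rank(fm)
        expected = naive_fscore(X, y)
        lookup = dict(zip(fm.feature_names, expected))
        for _, row in got.table.iterrows():
            assert row["fscore"] == pytest.approx(lookup[row["feature"]], abs=1e-9)

    def test_enriched_positional_features_rank_top(self, default_data):
        pos, neg = default_data
        m = build_score_matrix(pos, neg, window=10)
        fm = labeled_feature_matrix(pos, neg, FeatureSpec(), m)
        table = fscore_rank(fm)
        top5 = table.top(5)
        assert "1U" in top5
        assert "-1A" in top5

    def test_requires_two_per_class(self):
        fm = FeatureMatrix(ids=list("abc"), X=np.zeros((3, 1)), feature_names=["f"],
                           labels=np.array([1, -1, -1]))
        with pytest.raises(ValueError, match="at least 2"):
            fscore_rank(fm)


class TestCombineFeatures:
    def test_column_counts_add(self, default_data):
        pos, neg = default_data
        m = build_score_matrix(pos, neg, window=10)
        a = ppm_featurize(pos, m)
        b = kmer_featurize(pos, kmax=5)
        c = combine_features(a, b)
        assert c.n_features == 80 + 1364 == 1444
        assert len(set(c.feature_names)) == 1444

    def test_identity_with_empty(self):
        a = kmer_featurize(from_strings(["ACGUA"]), kmax=1)
        empty = FeatureMatrix(ids=a.ids, X=np.empty((1, 0)), feature_names=[])
        assert combine_features(a, empty) is a

    def test_row_mismatch_rejected(self):
        a = kmer_featurize(from_strings(["ACGUA"]), kmax=1)
        b = kmer_featurize(from_strings(["ACGUA", "GGGGG"]), kmax=1)
        with pytest.raises(ValueError):
            combine_features(a, b)


def test_feature_matrix_tsv_roundtrip(tmp_path, default_data):
    pos, neg = default_data
    m = build_score_matrix(pos, neg, window=10)
    fm = labeled_feature_matrix(pos, neg, FeatureSpec(), m)
    path = tmp_path / "fm.tsv"
    fm.to_tsv(path)
    back = FeatureMatrix.from_tsv(path)
    assert back.feature_names == fm.feature_names
    assert np.allclose(back.X, fm.X)
    assert np.array_equal(back.labels, fm.labels)
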