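"""Feature encoding, linear kernel, SVM training and evaluation."""

import numpy as np
import pytest

from helixvar.assembly import HelixSegment
from helixvar.classifier import (
    FEATURE_NAMES,
    N_FEATURES,
    EvalMetrics,
    TrainingSet,
    build_training_set,
    encode,
    evaluate,
    feature_weights,
    holdout_evaluate,
    kernel,
    partition_sequence,
    train,
)


def _segment(seq, fb="GGGG", fa="PPPP", label="regular"):
    n = len(seq)
    return HelixSegment(
        "t", 5, 4 + n, seq, subclass_labels=(label,) * (n - 7),
        flank_before=fb, flank_after=fa,
        flank_before_mask=tuple(c != "-" for c in fb),
        flank_after_mask=tuple(c != "-" for c in fa),
    )


class TestPartition:
    def test_length8_middle_positions_4_to_6(self):
        seq = "ACCDEFGH"
        parts = partition_sequence(_segment(seq))
        assert parts["nterm"] == seq[:4]
        assert parts["cterm"] == seq[4:]
        assert parts["middle"] == seq[3:6]  # positions 4,5,6

    def test_length12_middle_positions_4_to_8(self):
        seq = "ACDEFGHIKLMN"
        parts = partition_sequence(_segment(seq))
        assert parts["middle"] == seq[3:8]  # position 4 .. length-4

    def test_position4_shared_between_nterm_and_middle(self):
        seq = "ACDEFGHI"
        parts = partition_sequence(_segment(seq))
        assert parts["nterm"][-1] == parts["middle"][0] == seq[3]

    def test_length_limits_enforced(self):
        with pytest.raises(ValueError):
            partition_sequence(_segment("A" * 16), max_length=15)


class TestEncode:
    def test_exactly_440_unit_norm(self):
        x = encode(_segment("ACDEFGHIKLM"))
        assert x.shape == (N_FEATURES,) == (440,)
        assert np.linalg.norm(x) == pytest.approx(1.0, abs=1e-12)

    def test_hand_constructed_sparse_layout(self):
        # homopolymer helix with G/P flanks: known sparse pattern
        x = encode(_segment("AAAAAAAA", fb="GGGG", fa="PPPP"))
        v = dict(zip(FEATURE_NAMES, x))
        scale = x[FEATURE_NAMES.index("helix_comp_A")]  # = 1/norm
        assert v["helix_comp_A"] == pytest.approx(scale)
        assert v["nterm_comp_A"] == pytest.approx(scale)
        assert v["mid_comp_A"] == pytest.approx(scale)
        assert v["prior_comp_G"] == pytest.approx(scale)
        assert v["after_comp_P"] == pytest.approx(scale)
        # positional indicators: 4 ones in nterm A columns, 4 in prior G
        for p in ("N1", "N2", "N3", "N4"):
            assert v[f"nterm_{p}_A"] > 0
        for p in ("C4", "C3", "C2", "C1"):
            assert v[f"cterm_{p}_A"] > 0
        for p in ("P1", "P2", "P3", "P4"):
            assert v[f"prior_{p}_G"] > 0
        # everything else zero
        nonzero = {k for k, val in v.items() if val > 0}
        assert all(("_A" in k) or ("_G" in k) or ("_P" in k and "comp" not in k)
                   or k in ("prior_comp_G", "after_comp_P") for k in nonzero)
        assert sum(val > 0 for val in v.values()) == 5 + 16 + 1

    def test_masked_flank_contributes_nothing(self):
        x_masked = encode(_segment("ACDEFGHI", fb="----",
                                   fa="KKKK"))
        v = dict(zip(FEATURE_NAMES, x_masked))
        assert all(v[f"prior_comp_{a}"] == 0 for a in "ACDEFGHIKLMNPQRSTVWY")
        assert all(v[k] == 0 for k in FEATURE_NAMES if k.startswith("prior_P"))

    def test_deterministic(self):
        a = encode(_segment("ACDEFGHIKL"))
        b = encode(_segment("ACDEFGHIKL"))
        np.testing.assert_array_equal(a, b)

    def test_nonstandard_residue_warns(self):
        with pytest.warns(UserWarning, match="non-standard"):
            encode(_segment("ACDEFGHX"))

    def test_c_positional_block_order_is_c4_to_c1(self):
        x = encode(_segment("AAAAAAAG"))
        v = dict(zip(FEATURE_NAMES, x))
        assert v["cterm_C1_G"] > 0
        assert v["cterm_C4_A"] > 0
        assert v["cterm_C1_A"] == 0


class TestKernel:
    def test_self_similarity_is_one(self):
        x = encode(_segment("ACDEFGHIKL"))
        assert kernel(x, x) == pytest.approx(1.0)

    def test_symmetry_and_range(self):
        x = encode(_segment("ACDEFGHIKL"))
        y = encode(_segment("MNPQRSTVWY"))
        assert kernel(x, y) == pytest.approx(kernel(y, x))
        assert 0 <= kernel(x, y) <= 1

    def test_disjoint_vectors_orthogonal(self):
        a = np.zeros(440)
        b = np.zeros(440)
        a[0] = 1.0
        b[1] = 1.0
        assert kernel(a, b) == 0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kernel(np.ones(440), np.ones(10))


class TestTrain:
    def test_two_point_problem_closed_form(self):
        X = np.zeros((2, 440))
        X[0, 0] = 1.0
        X[1, 1] = 1.0
        D = TrainingSet(X, np.array([1, -1]))
        model = train(D, C=10.0)
        # both points are support vectors; boundary passes through midpoint
        assert len(model.support_vectors) == 2
        mid = (X[0] + X[1]) / 2
        assert model.decision_function(mid[None, :])[0] == pytest.approx(0, abs=1e-6)
        assert model.decision_function(X[0][None, :])[0] > 0
        assert model.decision_function(X[1][None, :])[0] < 0

    def test_separable_data_trains_to_zero_error(self, rng):
        X = np.zeros((40, 440))
        y = np.array([1] * 20 + [-1] * 20)
        X[:20, 0] = 1 + rng.random(20)
        X[20:, 1] = 1 + rng.random(20)
        D = TrainingSet(X, y)
        model = train(D)
        assert np.array_equal(model.predict(X), y)

    def test_support_expansion_equals_primal_decision(self, rng):
        X = rng.random((60, 440))
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        y = np.where(X[:, 0] > X[:, 1], 1, -1)
        model = train(TrainingSet(X, y))
        Q = rng.random((10, 440))
        np.testing.assert_allclose(model.decision_from_support(Q),
                                   model.decision_function(Q), atol=1e-8)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train(TrainingSet(np.random.rand(5, 440), np.ones(5, dtype=int)))


class TestFeatureWeights:
    def test_informative_dimension_dominates(self, rng):
        X = np.zeros((100, 440))
        X[:, 0] = np.r_[rng.normal(2, 0.1, 50), rng.normal(-2, 0.1, 50)]
        X[:, 1] = rng.normal(0, 0.1, 100)
        y = np.array([1] * 50 + [-1] * 50)
        w = feature_weights(train(TrainingSet(X, y)))
        assert abs(w.iloc[0]) > 10 * abs(w.iloc[1])
        assert w.index[0] == FEATURE_NAMES[0]

    def test_weights_reproduce_decision_values(self, rng):
        X = rng.random((50, 440))
        y = np.where(X.sum(axis=1) > X.sum(axis=1).mean(), 1, -1)
        model = train(TrainingSet(X, y))
        w = feature_weights(model).to_numpy()
        Q = rng.random((5, 440))
        np.testing.assert_allclose(Q @ w + model.bias,
                                   model.decision_function(Q), atol=1e-8)


class TestEvaluate:
    def _easy_set(self, rng, n=200):
        X = np.zeros((n, 440))
        y = np.where(rng.random(n) < 0.5, 1, -1)
        X[y == 1, 0] = 1
        X[y == -1, 1] = 1
        return TrainingSet(X, y)

    def test_perfect_classifier_perfect_metrics(self, rng):
        m = evaluate(self._easy_set(rng), folds=5, seed=0)
        assert m.precision == m.recall == m.f1 == 1.0

    def test_f1_identity_on_every_fold(self, default_training_set):
        D, _, _ = default_training_set
        m = evaluate(D, folds=4, seed=0)
        for fold in [m] + m.per_fold:
            if fold.precision + fold.recall > 0:
                expected = (2 * fold.precision * fold.recall
                            / (fold.precision + fold.recall))
                assert fold.f1 == pytest.approx(expected, abs=1e-12)

    def test_harmonic_mean_arithmetic(self):
        m = EvalMetrics.from_confusion(tp=8805, fp=2069, fn=1195, tn=0)
        # P = 0.8097, R = 0.8805 -> F1 = 0.8436 by the harmonic mean
        assert m.precision == pytest.approx(0.8097, abs=2e-4)
        assert m.recall == pytest.approx(0.8805, abs=1e-4)
        assert m.f1 == pytest.approx(0.8436, abs=1e-4)

    def test_matches_sklearn_metrics(self, rng):
        from sklearn.metrics import precision_recall_fscore_support

        y_true = np.where(rng.random(200) < 0.6, 1, -1)
        y_pred = np.where(rng.random(200) < 0.5, 1, -1)
        tp = int(np.sum((y_true == 1) & (y_pred == 1)))
        fp = int(np.sum((y_true == -1) & (y_pred == 1)))
        fn = int(np.sum((y_true == 1) & (y_pred == -1)))
        tn = int(np.sum((y_true == -1) & (y_pred == -1)))
        m = EvalMetrics.from_confusion(tp, fp, fn, tn)
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, pos_label=1, average="binary", zero_division=0)
        assert m.precision == pytest.approx(p)
        assert m.recall == pytest.approx(r)
        assert m.f1 == pytest.approx(f)

    def test_holdout_split_fraction(self, rng):
        D = self._easy_set(rng, n=100)
        m = holdout_evaluate(D, train_fraction=0.7, seed=0)
        assert sum(m.confusion.values()) == 30

    def test_more_folds_than_examples_rejected(self, rng):
        with pytest.raises(ValueError):
            evaluate(self._easy_set(rng, n=8), folds=10)


def test_build_training_set_labels_and_rows(default_corpus):
    from helixvar.assembly import select_training_segments

    pos, neg = select_training_segments(default_corpus.segments)
    D = build_training_set(pos[:10], neg[:10])
    assert np.array_equal(np.unique(D.y), [-1, 1])
    np.testing.assert_allclose(np.linalg.norm(D.X, axis=1), 1.0, atol=1e-12)
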