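"""Splits, tabular models, Shapley attribution, sequence models, CV."""

import math

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

from undulate.classifiers import (SplitSpec, cross_validate, evaluate,
                                  evaluate_predictions, feature_importance,
                                  shapley_values, split_dataset,
                                  split_indices, train_gru, train_tabular)
from undulate.nn import (CNNGRUClassifier, ConvEncoder, GRUClassifier,
                         GRUCore, MaskCNNClassifier, _sigmoid)


def gaussian_toy(n=100, sep=6.0, d=4, seed=0):
    rng = np.random.default_rng(seed)
    x0 = rng.normal(0, 1, (n // 2, d))
    x1 = rng.normal(sep, 1, (n - n // 2, d))
    x = np.vstack([x0, x1])
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    perm = rng.permutation(n)
    return x[perm], y[perm]


class TestSplits:
    def test_exact_70_15_15_counts(self):
        _, y = gaussian_toy(100)
        tr, va, te = split_indices(y, SplitSpec(seed=1))
        assert (len(tr), len(va), len(te)) == (70, 15, 15)
        assert not (set(tr) & set(va) or set(tr) & set(te)
                    or set(va) & set(te))
        assert len(set(tr) | set(va) | set(te)) == 100

    def test_same_seed_identical_partition(self):
        _, y = gaussian_toy(60)
        a = split_indices(y, SplitSpec(seed=9))
        b = split_indices(y, SplitSpec(seed=9))
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa, pb)

    def test_standardization_fit_on_train_only(self):
        x, y = gaussian_toy(100)
        split = split_dataset(x, y, SplitSpec(seed=2))
        x_tr, _ = split["train"]
        np.testing.assert_allclose(x_tr.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(x_tr.std(axis=0), 1.0, atol=1e-9)
        # val/test use train statistics, so they are not exactly centered
        x_va, _ = split["val"]
        assert not np.allclose(x_va.mean(axis=0), 0.0, atol=1e-6)

    def test_stratified_preserves_class_balance(self):
        y = np.array([0] * 80 + [1] * 20)
        tr, va, te = split_indices(y, SplitSpec(seed=3))
        for part in (tr, va, te):
            frac = (y[part] == 1).mean()
            assert frac == pytest.approx(0.2, abs=0.05)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            split_indices(np.array([0, 1] * 5), SplitSpec())


class TestEvaluate:
    def test_perfect_predictions(self):
        rep = evaluate_predictions([0, 0, 1, 1], [0, 0, 1, 1])
        np.testing.assert_array_equal(rep.confusion, np.eye(2))
        assert rep.accuracy == 1.0

    def test_constant_predictor_scores_half_on_balanced_data(self):
        rep = evaluate_predictions([0, 1] * 10, [1] * 20)
        assert rep.accuracy == 0.5

    def test_confusion_arithmetic(self):
        y_true = [0] * 50 + [1] * 50
        y_pred = ([0] * 45 + [1] * 5) + ([1] * 40 + [0] * 10)
        rep = evaluate_predictions(y_true, y_pred)
        # TP=40, FN=10, FP=5, TN=45 → (0.90 + 0.80)/2 = 0.85
        assert rep.accuracy == pytest.approx(0.85)
        assert rep.tpr == pytest.approx(0.80)
        assert rep.fpr == pytest.approx(0.10)
        np.testing.assert_allclose(rep.confusion.sum(axis=1), 1.0,
                                   atol=1e-9)

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate_predictions([], [])


class TestTrainTabular:
    def test_separable_classes_reach_perfect_accuracy(self):
        x, y = gaussian_toy(120, sep=8.0)
        for kind in ("random_forest", "svm"):
            result = train_tabular(x, y, model_kind=kind, seed=0)
            assert result.report.accuracy == 1.0

    def test_permuted_labels_score_near_chance(self):
        x, y = gaussian_toy(200, sep=6.0, seed=1)
        rng = np.random.default_rng(5)
        y_perm = rng.permutation(y)
        result = train_tabular(x, y_perm, seed=0)
        n_test = result.report.n_test
        half_width = 1.96 * 0.5 / math.sqrt(n_test)
        assert abs(result.report.accuracy - 0.5) <= half_width + 0.05

    def test_single_class_rejected(self):
        x = np.random.default_rng(0).normal(size=(40, 3))
        with pytest.raises(ValueError):
            train_tabular(x, np.zeros(40, dtype=int))

    def test_reports_bit_reproducible(self):
        x, y = gaussian_toy(120, sep=2.0, seed=2)
        r1 = train_tabular(x, y, seed=4)
        r2 = train_tabular(x, y, seed=4)
        np.testing.assert_array_equal(r1.report.counts, r2.report.counts)
        assert r1.report.accuracy == r2.report.accuracy


class TestShapley:
    def _informative_model(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, 5))
        y = (x[:, 2] > 0).astype(int)   # only feature 2 informative
        model = LogisticRegression().fit(x, y)
        return model, x, y

    def test_informative_feature_ranked_first(self):
        model, x, _ = self._informative_model()
        report = feature_importance(model, x[:60], x[60:100],
                                    feature_names=list("abcde"))
        assert report.names[0] == "c"
        assert np.all(np.diff(report.mean_abs) <= 1e-12)

    def test_efficiency_identity(self):
        model, x, _ = self._informative_model()
        phi, base = shapley_values(model, x[:50], x[50:70])
        preds = model.predict_proba(x[50:70])[:, 1]
        np.testing.assert_allclose(phi.sum(axis=1), preds - base,
                                   atol=1e-6)

    def test_duplicated_feature_splits_attribution(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(300, 2))
        y = (x[:, 0] > 0).astype(int)
        single = LogisticRegression().fit(x, y)
        x_dup = np.column_stack([x[:, 0], x[:, 0], x[:, 1]])
        dup = LogisticRegression().fit(x_dup, y)
        phi_s, _ = shapley_values(single, x[:80], x[80:160])
        phi_d, _ = shapley_values(dup, x_dup[:80], x_dup[80:160])
        total_single = np.abs(phi_s[:, 0]).mean()
        total_dup = np.abs(phi_d[:, 0] + phi_d[:, 1]).mean()
        assert total_dup == pytest.approx(total_single, rel=0.10)

    def test_unfitted_model_rejected(self):
        with pytest.raises(ValueError):
            shapley_values(object(), np.zeros((3, 2)), np.zeros((2, 2)))


def toy_sequences(n=120, t_len=20, channels=3, seed=0):
    """Label encoded entirely in the first timestep of channel 0."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1, (n, t_len, channels))
    y = rng.integers(0, 2, n)
    x[:, 0, 0] = y * 4.0 - 2.0
    valid = np.ones((n, t_len), dtype=bool)
    valid[:, 15:] = False
    return x, valid, y


class TestGRU:
    def test_learns_first_step_signal(self):
        x, valid, y = toy_sequences(n=200, seed=1)
        result = train_gru(x, valid, y, units=12, epochs=120, seed=0)
        assert result.report.accuracy >= 0.98

    def test_permuted_labels_near_chance(self):
        x, valid, y = toy_sequences(seed=2)
        y_perm = np.random.default_rng(7).permutation(y)
        result = train_gru(x, valid, y_perm, units=12, epochs=25, seed=0)
        n_test = result.report.n_test
        half_width = 1.96 * 0.5 / math.sqrt(n_test)
        assert abs(result.report.accuracy - 0.5) <= half_width + 0.1

    def test_padded_steps_cannot_leak_signal(self):
        # bury the label in the padded tail: the masked recurrence must
        # not see it
        x, valid, y = toy_sequences(seed=3)
        x[:, 0, 0] = np.random.default_rng(0).normal(size=len(y))
        x[:, 16, 1] = y * 10.0
        result = train_gru(x, valid, y, units=12, epochs=25, seed=0)
        n_test = result.report.n_test
        half_width = 1.96 * 0.5 / math.sqrt(n_test)
        assert abs(result.report.accuracy - 0.5) <= half_width + 0.1

    def test_gradients_match_numerics(self):
        rng = np.random.default_rng(0)
        core = GRUCore(3, 4, rng)
        x = rng.normal(size=(5, 7, 3))
        valid = np.ones((5, 7), bool)
        valid[2, 4:] = False
        y = np.array([0, 1, 1, 0, 1])
        prob, cache = core.forward(x, valid, cache=True)
        grads, _ = core.backward(x, valid, y, prob, cache)

        def loss():
            p = core.forward(x, valid)
            return -np.mean(y * np.log(p + 1e-12)
                            + (1 - y) * np.log(1 - p + 1e-12))

        eps = 1e-6
        for key in ("Wz", "Uh", "br", "w_out"):
            flat_g = np.asarray(grads[key], float).ravel()
            flat_p = core.p[key].reshape(-1)
            for i in rng.choice(flat_p.size, 4, replace=False):
                orig = flat_p[i]
                flat_p[i] = orig + eps
                up = loss()
                flat_p[i] = orig - eps
                down = loss()
                flat_p[i] = orig
                numeric = (up - down) / (2 * eps)
                assert flat_g[i] == pytest.approx(numeric, rel=1e-4,
                                                  abs=1e-9)


def shape_family_sequences(n=80, t_len=6, size=48, seed=0):
    """Discs (class 0) vs 2:1 ellipses (class 1), static in time."""
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    x = np.zeros((n, t_len, size, size, 2), dtype=np.uint8)
    yy, xx = np.mgrid[:size, :size]
    c = size // 2
    for i, label in enumerate(y):
        r = rng.uniform(8, 11)
        a, b = (r, r) if label == 0 else (r * math.sqrt(2),
                                          r / math.sqrt(2))
        mask = ((xx - c) / a) ** 2 + ((yy - c) / b) ** 2 <= 1.0
        x[i, :, :, :, 0] = mask
        x[i, :, :, :, 1] = mask
    valid = np.ones((n, t_len), dtype=bool)
    valid[:, 4:] = False
    return x, valid, y


class TestCNNGRU:
    def test_separates_disc_from_ellipse(self):
        x, valid, y = shape_family_sequences(n=120, seed=4)
        from undulate.classifiers import train_cnn_gru
        result = train_cnn_gru(x, valid, y, units=8, epochs=40, lr=1e-2,
                               seed=0, filters1=4, filters2=8,
                               input_pool=2)
        assert result.report.accuracy >= 0.95

    def test_all_zero_input_scores_majority_rate(self):
        x, valid, y = shape_family_sequences(n=60, seed=5)
        x[:] = 0
        from undulate.classifiers import train_cnn_gru
        result = train_cnn_gru(x, valid, y, units=8, epochs=5, seed=0,
                               filters1=4, filters2=8, input_pool=2)
        majority = max(np.mean(y == 0), np.mean(y == 1))
        assert result.report.accuracy <= majority + 0.15

    def test_encoder_gradients_match_numerics(self):
        rng = np.random.default_rng(1)
        enc = ConvEncoder(3, 5, rng, in_channels=2, input_pool=2)
        # float64 weights for the finite-difference check; the encoder
        # trains in float32, too coarse for 1e-6 perturbations
        enc.p = {k: v.astype(np.float64) for k, v in enc.p.items()}
        x = rng.normal(size=(3, 20, 20, 2))
        w = rng.normal(size=5)
        y = np.array([1, 0, 1])

        def loss():
            emb = enc.forward(x)
            p = _sigmoid(emb @ w)
            return -np.mean(y * np.log(p + 1e-12)
                            + (1 - y) * np.log(1 - p + 1e-12))

        emb, cache = enc.forward(x, cache=True)
        p = _sigmoid(emb @ w)
        demb = np.outer((p - y) / 3, w)
        grads = enc.backward(demb, cache)
        eps = 1e-6
        for key in ("C1", "C2", "c1b", "c2b"):
            flat_g = grads[key].ravel()
            flat_p = enc.p[key].reshape(-1)
            for i in rng.choice(flat_p.size, min(4, flat_p.size),
                                replace=False):
                orig = flat_p[i]
                flat_p[i] = orig + eps
                up = loss()
                flat_p[i] = orig - eps
                down = loss()
                flat_p[i] = orig
                assert flat_g[i] == pytest.approx((up - down) / (2 * eps),
                                                  rel=1e-4, abs=1e-8)


class TestCrossValidate:
    def test_deterministic_classifier_has_zero_sem(self):
        class Constant:
            def fit(self, x, y):
                return self

            def predict(self, x):
                return np.zeros(len(x), dtype=int)

        y = np.array([0, 1] * 50)
        x = np.zeros((100, 2))
        out = cross_validate(Constant, x, y, k=5, seed=0)
        assert out["sem"] == 0.0
        assert out["fold_sizes"] == [20] * 5

    def test_mean_is_arithmetic_mean_of_folds(self):
        from sklearn.ensemble import RandomForestClassifier
        x, y = gaussian_toy(100, sep=2.0, seed=6)
        out = cross_validate(
            lambda: RandomForestClassifier(n_estimators=20,
                                           random_state=0),
            x, y, k=5, seed=1)
        assert out["mean"] == pytest.approx(
            np.mean(out["fold_accuracies"]), abs=1e-12)

    def test_k_less_than_two_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(lambda: None, np.zeros((10, 2)),
                           np.array([0, 1] * 5), k=1)
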