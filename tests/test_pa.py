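"""Passive-aggressive classifier: update rule, invariants, training, tuning."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from somnorisk.errors import ValidationError
from somnorisk.pa import (PAModel, Standardizer, decision_score, fine_tune,
                          fit_generic, hinge_loss, load_model, pa_update,
                          predict, save_model, _run_stream)


def reference_pa_stream(X, y, C=1.0, variant="PA-I"):
    """Independent brute-force PA reference in plain Python floats."""
    d = len(X[0])
    w = [0.0] * d
    b = 0.0
    for xi, yi in zip(X, y):
        score = sum(wj * xj for wj, xj in zip(w, xi)) + b
        loss = max(0.0, 1.0 - yi * score)
        if loss > 0.0:
            denom = sum(xj * xj for xj in xi) + 1.0
            if variant == "PA-I":
                tau = min(C, loss / denom)
            else:
                tau = loss / (denom + 1.0 / (2.0 * C))
            w = [wj + tau * yi * xj for wj, xj in zip(w, xi)]
            b += tau * yi
    return np.array(w), b


class TestHingeLoss:
    @pytest.mark.parametrize("margin,loss", [(1.2, 0.0), (0.0, 1.0),
                                             (-1.0, 2.0), (1.0, 0.0)])
    def test_values(self, margin, loss):
        assert hinge_loss(margin) == loss


class TestPAUpdate:
    def test_unit_vector_from_zero_model(self):
        m = PAModel.zeros(3, aggressiveness_c=1.0)
        x = np.array([1.0, 0.0, 0.0])
        pa_update(m, x, 1)
        # loss 1, ||x||^2+1 = 2 -> tau = 0.5
        assert np.allclose(m.weights, [0.5, 0.0, 0.0])
        assert m.bias == 0.5 and m.n_updates == 1

    def test_confident_correct_sample_is_passive(self):
        m = PAModel(weights=np.array([1.0, 0.0]), bias=0.5)
        before = m.copy()
        pa_update(m, np.array([1.0, 0.0]), 1)  # margin 1.5
        assert np.array_equal(m.weights, before.weights)
        assert m.bias == before.bias and m.n_updates == 0

    def test_tau_clipped_by_aggressiveness(self):
        # loss 2 with ||x||^2+1 = 2 would give tau 1; C = 0.5 clips it
        m = PAModel(weights=np.array([-1.0]), bias=0.0,
                    aggressiveness_c=0.5)
        pa_update(m, np.array([1.0]), 1)  # margin -1, loss 2
        assert np.allclose(m.weights, [-0.5])  # moved by tau=0.5
        assert m.bias == 0.5

    def test_bad_label_rejected(self):
        with pytest.raises(ValidationError):
            pa_update(PAModel.zeros(2), np.zeros(2), 0)

    @given(st.integers(0, 2 ** 32 - 1))
    def test_passive_aggressive_invariants(self, seed):
        rng = np.random.default_rng(seed)
        m = PAModel(weights=rng.normal(size=4), bias=float(rng.normal()),
                    aggressiveness_c=float(rng.uniform(0.1, 2.0)))
        x = rng.normal(size=4)
        y = int(rng.choice([-1, 1]))
        margin = y * decision_score(m, x)
        loss = hinge_loss(margin)
        before = m.copy()
        pa_update(m, x, y)
        if loss == 0.0:
            assert np.array_equal(m.weights, before.weights)
            assert m.bias == before.bias
        else:
            tau = loss / (x @ x + 1.0)
            dw = m.weights - before.weights
            # weights move only along y*x; bias along y
            assert np.allclose(dw, min(m.aggressiveness_c, tau) * y * x)
            if tau < m.aggressiveness_c:  # unclipped: new margin exactly 1
                assert y * decision_score(m, x) == pytest.approx(1.0)

    @given(st.integers(0, 2 ** 32 - 1))
    def test_stream_matches_bruteforce_reference(self, seed):
        rng = np.random.default_rng(seed)
        n, d = int(rng.integers(1, 50)), int(rng.integers(1, 6))
        X = rng.normal(size=(n, d))
        y = rng.choice([-1.0, 1.0], size=n)
        C = float(rng.uniform(0.05, 2.0))
        m = PAModel.zeros(d, aggressiveness_c=C)
        _run_stream(m, X, y)
        w_ref, b_ref = reference_pa_stream(X.tolist(), y.tolist(), C)
        assert np.allclose(m.weights, w_ref, atol=1e-12)
        assert m.bias == pytest.approx(b_ref, abs=1e-12)


class TestDecision:
    def test_zero_model_predicts_positive(self):
        m = PAModel.zeros(2)
        assert decision_score(m, np.zeros(2)) == 0.0
        assert predict(m, np.zeros(2)) == 1

    def test_dot_product_score(self):
        m = PAModel(weights=np.array([1.0, 0.0]), bias=0.0)
        assert decision_score(m, np.array([2.0, 5.0])) == 2.0

    def test_sign_flips_under_negation(self):
        m = PAModel(weights=np.array([0.7, -0.2]), bias=0.3)
        x = np.array([1.0, 2.0])
        neg = PAModel(weights=-m.weights, bias=-m.bias)
        assert decision_score(neg, x) == -decision_score(m, x)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            decision_score(PAModel.zeros(3), np.zeros(2))


class TestFitGeneric:
    def _separable(self):
        X = np.array([[2.0, 0.0], [3.0, 1.0], [2.5, -1.0], [4.0, 0.5],
                      [-2.0, 0.0], [-3.0, 1.0], [-2.5, -1.0], [-4.0, 0.5]])
        y = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        return X, y

    def test_separable_toy_reaches_zero_training_error(self):
        X, y = self._separable()
        model, std = fit_generic(X, y, epochs=10, seed=0)
        preds = predict(model, std.transform(X))
        assert np.array_equal(preds, np.where(y > 0, 1, -1))

    def test_empty_stream_rejected(self):
        with pytest.raises(ValidationError):
            fit_generic(np.empty((0, 3)), np.empty(0))

    def test_single_class_stream_rejected(self):
        with pytest.raises(ValidationError):
            fit_generic(np.ones((5, 2)), np.ones(5))

    def test_same_seed_gives_identical_weights(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 4))
        y = (X[:, 0] > 0).astype(int)
        m1, _ = fit_generic(X, y, seed=9)
        m2, _ = fit_generic(X, y, seed=9)
        assert np.array_equal(m1.weights, m2.weights) and m1.bias == m2.bias

    def test_final_epoch_average_equals_stepwise_mean_of_states(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 3))
        y = (X[:, 0] + 0.3 * rng.normal(size=30) > 0).astype(int)
        model, std = fit_generic(X, y, epochs=1, seed=4)
        # replay the same shuffled stream with single-step updates
        Xs = std.transform(X)
        idx = np.random.default_rng(4).permutation(len(Xs))
        m = PAModel.zeros(3)
        states_w, states_b = [], []
        for i in idx:
            pa_update(m, Xs[i], 1 if y[i] > 0 else -1)
            states_w.append(m.weights.copy())
            states_b.append(m.bias)
        assert np.allclose(model.weights, np.mean(states_w, axis=0))
        assert model.bias == pytest.approx(np.mean(states_b))

    def test_endpoint_mode_matches_sequential_updates(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 3))
        y = (X[:, 1] > 0).astype(int)
        model, std = fit_generic(X, y, epochs=2, seed=7,
                                 average_final_epoch=False)
        Xs = std.transform(X)
        m = PAModel.zeros(3)
        rng2 = np.random.default_rng(7)
        for _ in range(2):
            for i in rng2.permutation(len(Xs)):
                pa_update(m, Xs[i], 1 if y[i] > 0 else -1)
        assert np.allclose(model.weights, m.weights, atol=1e-12)
        assert model.bias == pytest.approx(m.bias, abs=1e-12)


class TestFineTune:
    def _generic(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] > 0).astype(int)
        return fit_generic(X, y, seed=1), X

    def test_zero_samples_is_a_noop_copy(self):
        (model, std), X = self._generic()
        tuned = fine_tune(model, X[:0], np.empty(0), std)
        assert tuned is not model
        assert np.array_equal(tuned.weights, model.weights)

    def test_already_confident_samples_leave_model_unchanged(self):
        (model, std), _ = self._generic()
        # craft samples the model classifies with margin >= 1
        x_raw = std.loc + 5.0 * model.weights / np.linalg.norm(
            model.weights) ** 2 * std.scale
        tuned = fine_tune(model, x_raw[None, :], np.array([1]), std)
        assert np.array_equal(tuned.weights, model.weights)
        assert tuned.n_updates == model.n_updates

    def test_one_misclassified_sample_applies_exactly_one_update(self):
        (model, std), _ = self._generic()
        x_raw = std.loc - 5.0 * model.weights * std.scale
        tuned = fine_tune(model, x_raw[None, :], np.array([1]), std)
        assert tuned.n_updates == model.n_updates + 1
        assert not np.array_equal(tuned.weights, model.weights)
        # the generic model itself is untouched
        assert tuned is not model

    def test_single_class_personal_data_is_allowed(self):
        (model, std), X = self._generic()
        tuned = fine_tune(model, X[:5], np.ones(5), std)
        assert tuned.weights.shape == model.weights.shape


def test_standardizer_zero_variance_guard():
    X = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
    std = Standardizer.fit(X)
    assert std.scale[0] == 1.0
    assert np.allclose(std.transform(X)[:, 0], 0.0)


def test_model_serialization_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    X = rng.normal(size=(30, 4))
    y = (X[:, 2] > 0).astype(int)
    model, std = fit_generic(X, y, seed=2)
    path = tmp_path / "model.txt"
    save_model(model, std, path)
    model2, std2 = load_model(path)
    assert np.array_equal(model2.weights, model.weights)
    assert model2.bias == model.bias
    assert model2.variant == model.variant
    assert np.array_equal(std2.loc, std.loc)
    assert np.array_equal(std2.scale, std.scale)
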