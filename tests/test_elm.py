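"""Extreme learning machine: closed-form solve vs oracle, interpolation,
regularization algebra, CV sizing."""

import numpy as np
import pytest

from myodecode import (ElmModel, cv_select_hidden, elm_accuracy, fit_elm,
                       hidden_map, one_hot, predict)
from myodecode.elm import _solve_output_weights


def _random_problem(n=60, Z=5, m=3, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, Z))
    y = np.array([f"c{i % m}" for i in range(n)])
    return X, y


def test_tribas_peak_and_support():
    X0, y0 = _random_problem()
    model = fit_elm(X0, n_hidden=10, labels=y0, seed=1)
    # pre-activation 0 -> 1 (peak); |pre| >= 1 -> 0 (bounded support)
    tri = lambda v: np.maximum(1 - np.abs(v), 0)
    assert tri(0.0) == 1.0
    assert tri(1.0) == 0.0 and tri(-3.0) == 0.0
    # hidden_map actually implements it
    X = np.zeros((1, 5))
    H = hidden_map(model, X)
    z = (X - model.input_mean) / model.input_scale
    pre = z @ model.hidden_weights.T + model.hidden_biases
    np.testing.assert_allclose(H, tri(pre), atol=1e-12)


def test_rbf_unit_activation_at_center():
    X, y = _random_problem(seed=2)
    model = fit_elm(X, n_hidden=8, labels=y, activation="rbf", seed=3)
    z = (X[0] - model.input_mean) / model.input_scale
    model.hidden_weights[0] = z  # move one center onto the first sample
    H = hidden_map(model, X[:1])
    assert H[0, 0] == pytest.approx(1.0)


def test_output_weights_match_normal_equations_oracle():
    """Solved weights equal (H^T H + lam I)^{-1} H^T O computed densely."""
    X, y = _random_problem(n=200, seed=4)
    lam = 1e-3
    model = fit_elm(X, n_hidden=50, labels=y, lam=lam, seed=5)
    H = hidden_map(model, X)
    O = one_hot(y, model.class_order)
    oracle = np.linalg.inv(H.T @ H + lam * np.eye(50)) @ H.T @ O
    np.testing.assert_allclose(model.output_weights, oracle, rtol=1e-8,
                               atol=1e-10)


def test_interpolation_with_many_neurons():
    """lam ~ 0 and N >= n on distinct points -> 100% training accuracy."""
    X, y = _random_problem(n=50, Z=4, m=5, seed=6)
    model = fit_elm(X, n_hidden=80, labels=y, lam=1e-12, seed=7)
    assert elm_accuracy(model, X, y) == 1.0
    # and an interpolating model labels a training point with its own label
    pred, _ = predict(model, X[:1])
    assert pred[0] == y[0]


def test_duplicating_samples_doubles_lambda():
    """Duplicated data with lam doubled gives the same output weights."""
    X, y = _random_problem(n=40, seed=8)
    lam = 1e-2
    m1 = fit_elm(X, n_hidden=20, labels=y, lam=lam, seed=9)
    H = hidden_map(m1, X)
    O = one_hot(y, m1.class_order)
    w1 = _solve_output_weights(H, O, lam)
    w2 = _solve_output_weights(np.vstack([H, H]), np.vstack([O, O]), 2 * lam)
    np.testing.assert_allclose(w1, w2, rtol=1e-8)


def test_scores_compose_hidden_map_and_weights():
    X, y = _random_problem(seed=10)
    model = fit_elm(X, n_hidden=15, labels=y, seed=11)
    pts = np.random.default_rng(0).standard_normal((5, 5))
    _, scores = predict(model, pts)
    np.testing.assert_allclose(scores, hidden_map(model, pts) @ model.output_weights,
                               atol=1e-12)


def test_prediction_invariant_to_row_order():
    X, y = _random_problem(seed=12)
    model = fit_elm(X, n_hidden=25, labels=y, seed=13)
    perm = np.random.default_rng(1).permutation(len(X))
    p1, _ = predict(model, X)
    p2, _ = predict(model, X[perm])
    assert (p1[perm] == p2).all()


def test_zero_scores_tie_break_to_first_class():
    X, y = _random_problem(seed=14)
    model = fit_elm(X, n_hidden=10, labels=y, seed=15)
    model.output_weights = np.zeros_like(model.output_weights)
    pred, _ = predict(model, X[:3])
    assert (pred == model.class_order[0]).all()


def test_training_error_monotone_in_lambda():
    X, y = _random_problem(n=80, seed=16)
    model = fit_elm(X, n_hidden=30, labels=y, seed=17)
    H = hidden_map(model, X)
    O = one_hot(y, model.class_order)
    errs = []
    for lam in (1e-8, 1e-4, 1e-1, 1.0, 10.0):
        w = _solve_output_weights(H, O, lam)
        errs.append(np.linalg.norm(H @ w - O) ** 2)
    assert all(a <= b + 1e-10 for a, b in zip(errs, errs[1:]))


def test_inputs_standardized_by_training_stats():
    X, y = _random_problem(n=100, seed=18)
    model = fit_elm(X, n_hidden=5, labels=y, seed=19)
    Z = (X - model.input_mean) / model.input_scale
    np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-12)
    np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-12)


def test_cv_grid_of_one_returns_it():
    X, y = _random_problem(seed=20)
    best, acc = cv_select_hidden(X, grid=(17,), labels=y, seed=21)
    assert best == 17 and set(acc) == {17}


def test_cv_separable_problem_high_accuracy():
    """Two linearly separable classes: both grid points >= 95% CV accuracy."""
    rng = np.random.default_rng(22)
    X = np.vstack([rng.normal(-2, 0.3, (60, 3)), rng.normal(2, 0.3, (60, 3))])
    y = np.array(["neg"] * 60 + ["pos"] * 60)
    best, acc = cv_select_hidden(X, grid=(10, 100), labels=y, seed=23)
    assert all(a >= 0.95 for a in acc.values())


def test_cv_seeded_determinism():
    X, y = _random_problem(n=100, seed=24)
    r1 = cv_select_hidden(X, grid=(10, 30), labels=y, seed=25)
    r2 = cv_select_hidden(X, grid=(10, 30), labels=y, seed=25)
    assert r1 == r2


def test_cv_rejects_class_starvation():
    X = np.random.default_rng(2).standard_normal((5, 3))
    y = np.array(["a", "a", "a", "a", "b"])
    with pytest.raises(ValueError):
        cv_select_hidden(X, grid=(5,), labels=y, folds=2)


def test_model_round_trip_bit_identical_predictions(tmp_path):
    X, y = _random_problem(seed=26)
    model = fit_elm(X, n_hidden=12, labels=y, seed=27)
    model.save(tmp_path / "elm.npz")
    back = ElmModel.load(tmp_path / "elm.npz")
    p1, s1 = predict(model, X)
    p2, s2 = predict(back, X)
    assert (p1 == p2).all()
    assert s1.tobytes() == s2.tobytes()
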