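"""Boosting bookkeeping, weighted-median combination, recursion contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ebrm.boosting import (
    BETA_FLOOR,
    combine_predictions,
    fit_ebrm,
    predict_ebrm,
    weighted_median,
)
from ebrm.cohort import CohortConfig, simulate_cohort, to_matrices

from conftest import LinearLearner, linear_factory


def brute_force_weighted_median(preds, betas):
    """Independent evaluation of the infimum definition: smallest candidate t
    with sum of log(1/beta) over predictions <= t reaching half the total."""
    preds = np.asarray(preds, float)
    w = np.maximum(np.log(1.0 / np.asarray(betas, float)), 0.0)
    total = w.sum()
    if total == 0:
        return float(np.median(preds))
    for t in sorted(preds):
        if w[preds <= t].sum() >= total / 2:
            return float(t)
    raise AssertionError("unreachable")


def test_equal_betas_give_ordinary_median():
    assert weighted_median([100, 110, 120], [0.5, 0.5, 0.5]) == 110


def test_single_learner_returns_own_prediction():
    assert weighted_median([104.2], [0.3]) == 104.2


def test_weighted_median_agrees_with_brute_force():
    rng = np.random.default_rng(0)
    for _ in range(300):
        k = rng.integers(1, 7)
        preds = rng.normal(110, 15, size=k)
        betas = rng.uniform(0.01, 1.5, size=k)
        assert weighted_median(preds, betas) == brute_force_weighted_median(
            preds, betas
        )


@given(st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=1, max_size=9))
@settings(max_examples=60, deadline=None)
def test_equal_beta_reduction_property(preds):
    betas = [0.4] * len(preds)
    med = np.median(preds)
    wm = weighted_median(preds, betas)
    # with even counts the infimum rule picks an order statistic, not the
    # midpoint; it must still lie on a sample point bracketing the median
    if len(preds) % 2:
        assert wm == med
    else:
        assert min(preds) <= wm <= max(preds)
        assert wm in preds


def test_weighted_median_rejects_bad_betas():
    with pytest.raises(ValueError):
        weighted_median([1.0, 2.0], [0.5, -0.1])


def test_beta_above_one_gets_zero_weight():
    # the beta >= 1 learner contributes nothing: result is the trusted one
    assert weighted_median([200.0, 100.0], [5.0, 0.2]) == 100.0


def test_combined_prediction_within_learner_range():
    rng = np.random.default_rng(1)
    per_learner = rng.normal(110, 10, size=(4, 20, 2))
    betas = rng.uniform(0.05, 0.9, size=4)
    out = combine_predictions(per_learner, betas)
    assert np.all(out >= per_learner.min(axis=0))
    assert np.all(out <= per_learner.max(axis=0))


def _toy_matrices(n=60, seed=2):
    rng = np.random.default_rng(seed)
    V = rng.uniform(-1, 1, size=(n, 3))
    T = np.column_stack([110 + 20 * V[:, 0] + rng.normal(0, 2, n),
                         70 + 10 * V[:, 1] + rng.normal(0, 2, n)])
    return V, T


def test_round_bookkeeping_invariants():
    """Weights stay a distribution; eps in range; beta recomputable."""
    V, T = _toy_matrices()
    model = fit_ebrm(V, T, K=4, learner_factory=linear_factory, seed=3)
    w = np.full(len(V), 1.0 / len(V))
    for trace in model.traces:
        assert np.all(trace.eps_m >= 0) and np.all(trace.eps_m <= 1)
        assert 0 <= trace.eps_bar < 0.5
        assert trace.beta == pytest.approx(trace.eps_bar / (1 - trace.eps_bar))
        assert trace.eps_bar == pytest.approx(float(trace.eps_m @ w))
        w = w * trace.beta ** (1.0 - trace.eps_m)
        w = w / w.sum()
        assert abs(w.sum() - 1.0) < 1e-12
    assert np.allclose(model.instance_weights, w, atol=1e-12)


def test_perfect_learner_triggers_degenerate_round():
    V, T = _toy_matrices(n=30)

    def perfect_factory(U, Ttr, seed):
        # memorises the full target table via nearest-feature lookup
        class Perfect:
            def predict(self, Uq):
                Uq = np.atleast_2d(Uq)
                idx = [np.argmin(np.abs(V[:, 0] - u[0])) for u in Uq]
                return T[idx]

        return Perfect()

    model = fit_ebrm(V, T, K=5, learner_factory=perfect_factory, seed=4)
    assert len(model.learners) == 1
    assert model.betas[0] == BETA_FLOOR
    assert np.allclose(predict_ebrm(model, V), T)


def test_equal_relative_errors_leave_weights_unchanged():
    """lines 17-18 algebra: w * beta^(1-eps) renormalised is w when eps_m is
    constant across instances."""
    rng = np.random.default_rng(5)
    w = rng.dirichlet(np.ones(20))
    for eps in (0.0, 0.3, 0.9):
        beta = 0.25
        w_new = w * beta ** (1.0 - eps)
        w_new /= w_new.sum()
        assert np.allclose(w_new, w, atol=1e-14)


def test_high_error_instances_gain_weight():
    V, T = _toy_matrices(n=40, seed=6)

    def biased_factory(U, Ttr, seed):
        # constant predictor: per-instance error is driven by the target value
        class Const:
            def predict(self, Uq):
                return np.tile(Ttr.mean(axis=0), (len(np.atleast_2d(Uq)), 1))

        return Const()

    model = fit_ebrm(V, T, K=1, learner_factory=biased_factory, seed=7)
    trace = model.traces[0]
    hard = np.argmax(trace.eps_m)
    easy = np.argmin(trace.eps_m)
    assert model.instance_weights[hard] > model.instance_weights[easy]


def test_single_round_prediction_equals_learner_output():
    V, T = _toy_matrices(n=35, seed=8)
    model = fit_ebrm(V, T, K=1, learner_factory=linear_factory, seed=9)
    X = V[:7]
    feedback = model.baseline.predict(X)
    direct = model.learners[0].predict(np.hstack([X, feedback]))
    assert np.allclose(predict_ebrm(model, X), direct)


def test_recovery_on_noise_free_cohort():
    """Held-out AAMI-style recovery on an exactly affine cohort."""
    cfg = CohortConfig(n_subjects=20, within_subject_sd=0.0, observer_sd=0.0,
                       feature_noise_sd=0.0, n_features=6, seed=10)
    cohort = simulate_cohort(cfg)
    V, T = to_matrices(cohort[:15])
    Vh, Th = to_matrices(cohort[15:])
    model = fit_ebrm(V, T, K=3, learner_factory=linear_factory, seed=11)
    err = predict_ebrm(model, Vh) - Th
    assert np.all(np.abs(err.mean(axis=0)) < 5.0)
    assert np.all(err.std(axis=0, ddof=1) < 8.0)


def test_fit_input_validation():
    V, T = _toy_matrices(n=20)
    with pytest.raises(ValueError):
        fit_ebrm(V, T, K=0, learner_factory=linear_factory)
    with pytest.raises(ValueError):
        fit_ebrm(V, T, K=1, M=21, learner_factory=linear_factory)


def test_predict_rejects_wrong_dimension():
    V, T = _toy_matrices(n=20)
    model = fit_ebrm(V, T, K=1, learner_factory=linear_factory, seed=12)
    with pytest.raises(ValueError, match="features"):
        predict_ebrm(model, np.zeros((2, 5)))


def test_fit_is_deterministic_for_fixed_seed():
    V, T = _toy_matrices(n=30, seed=13)
    a = fit_ebrm(V, T, K=3, learner_factory=linear_factory, seed=14)
    b = fit_ebrm(V, T, K=3, learner_factory=linear_factory, seed=14)
    assert np.array_equal(a.betas, b.betas)
    assert np.array_equal(a.instance_weights, b.instance_weights)
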