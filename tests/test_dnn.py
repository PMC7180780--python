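"""Weak learner: gradients, pre-training, determinism, learnability."""

import numpy as np
import pytest

from ebrm.cohort import CohortConfig, simulate_cohort, to_matrices
from ebrm.dnn import (
    DNNParams,
    TrainingDivergedError,
    _init_stack,
    bagged_init,
    gbrbm_pretrain,
    mlp_gradients,
    mlp_loss,
    rbm_reconstruction_error,
    train_dnn,
)
from ebrm._rng import seedseq


def test_analytic_gradients_match_finite_differences():
    """Backprop gradient of the squared-error cost vs central differences."""
    rng = np.random.default_rng(0)
    weights, biases = _init_stack([3, 4, 2], 0.5, rng)
    X = rng.standard_normal((7, 3))
    Y = rng.standard_normal((7, 2))
    gw, gb = mlp_gradients(weights, biases, X, Y)
    eps = 1e-6
    for params, grads in ((weights, gw), (biases, gb)):
        for p, g in zip(params, grads):
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                p[i] += eps
                up = mlp_loss(weights, biases, X, Y)
                p[i] -= 2 * eps
                dn = mlp_loss(weights, biases, X, Y)
                p[i] += eps
                fd = (up - dn) / (2 * eps)
                assert abs(fd - g[i]) / max(abs(g[i]), 1e-8) < 1e-4


def _standardized_blob(n=60, d=5, seed=1):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d)) @ rng.standard_normal((d, d))
    return (X - X.mean(axis=0)) / X.std(axis=0)


def test_pretrain_zero_epochs_returns_random_init():
    V = _standardized_blob()
    params = DNNParams(hidden_sizes=(6, 4), epochs_pretrain=0)
    w, b = gbrbm_pretrain(V, params, seed=5)
    exp_w, exp_b = _init_stack([V.shape[1], 6, 4], params.init_scale,
                               np.random.default_rng(5))
    for wi, ei in zip(w, exp_w):
        assert np.array_equal(wi, ei)
    for bi, ei in zip(b, exp_b):
        assert np.array_equal(bi, ei)


def test_pretrain_is_deterministic():
    V = _standardized_blob()
    params = DNNParams(hidden_sizes=(8,), epochs_pretrain=5)
    w1, b1 = gbrbm_pretrain(V, params, seed=6)
    w2, b2 = gbrbm_pretrain(V, params, seed=6)
    assert all(np.array_equal(a, b) for a, b in zip(w1, w2))
    assert all(np.array_equal(a, b) for a, b in zip(b1, b2))


def test_pretraining_reduces_reconstruction_error():
    V = _standardized_blob(n=120, seed=2)
    params = DNNParams(hidden_sizes=(8,), epochs_pretrain=25, init_scale=0.5)
    w0, b0 = _init_stack([V.shape[1], 8], params.init_scale,
                         np.random.default_rng(7))
    w, b = gbrbm_pretrain(V, params, seed=7)
    assert rbm_reconstruction_error(V, w[0], b[0]) <= rbm_reconstruction_error(
        V, w0[0], b0[0]
    )


def test_pretrain_rejects_nonfinite():
    V = _standardized_blob()
    V[0, 0] = np.inf
    with pytest.raises(ValueError):
        gbrbm_pretrain(V, DNNParams())


def test_bagged_init_single_member_equals_plain_pretrain():
    V = _standardized_blob()
    params = DNNParams(hidden_sizes=(6,), epochs_pretrain=3)
    bag = bagged_init(V, 1, params, seed=8)
    child = seedseq(8).spawn(1)[0]
    w, b = gbrbm_pretrain(V, params, seed=child.spawn(1)[0])
    assert all(np.array_equal(a, c) for a, c in zip(bag.weights, w))
    assert all(np.array_equal(a, c) for a, c in zip(bag.hidden_biases, b))


def test_bagging_shrinks_init_variance():
    """Averaging more pre-trained stacks reduces spread across master seeds."""
    V = _standardized_blob(n=50, d=4, seed=3)
    params = DNNParams(hidden_sizes=(6,), epochs_pretrain=3)

    def spread(k_pre):
        mats = [bagged_init(V, k_pre, params, seed=s).weights[0] for s in range(6)]
        return np.std(np.stack(mats), axis=0).mean()

    assert spread(5) < spread(1)


def test_bagged_init_requires_positive_k():
    with pytest.raises(ValueError):
        bagged_init(_standardized_blob(), 0, DNNParams())


def test_zero_learning_rate_freezes_training():
    rng = np.random.default_rng(4)
    U = rng.standard_normal((40, 3))
    T = rng.standard_normal((40, 2))
    params = DNNParams(hidden_sizes=(5,), epochs_finetune=8,
                       lr_weights=0.0, lr_hidden_bias=0.0, epochs_pretrain=0)
    model = train_dnn(U, T, params, seed=9)
    assert np.allclose(model.cost_history, model.cost_history[0])


def test_training_is_deterministic():
    rng = np.random.default_rng(5)
    U = rng.standard_normal((50, 4))
    T = rng.standard_normal((50, 2))
    params = DNNParams(hidden_sizes=(8,), epochs_finetune=10)
    a = train_dnn(U, T, params, seed=10)
    b = train_dnn(U, T, params, seed=10)
    assert all(np.array_equal(x, y) for x, y in zip(a.weights, b.weights))
    X = rng.standard_normal((5, 4))
    assert np.array_equal(a.predict(X), b.predict(X))


def test_divergence_is_reported_with_epoch():
    rng = np.random.default_rng(6)
    U = rng.standard_normal((30, 3))
    T = 100 * rng.standard_normal((30, 2))
    params = DNNParams(hidden_sizes=(5,), epochs_finetune=40, lr_weights=1e8,
                       lr_hidden_bias=1e8)
    with pytest.raises(TrainingDivergedError), np.errstate(all="ignore"):
        train_dnn(U, T, params, seed=11)


def test_learns_noise_free_linear_cohort():
    """Training RMSE < 2 mmHg on a noise-free affine cohort, held-out RMSE
    within 2x of training RMSE."""
    cfg = CohortConfig(n_subjects=125, within_subject_sd=0.0, observer_sd=0.0,
                       feature_noise_sd=0.0, seed=3)
    cohort = simulate_cohort(cfg)
    V, T = to_matrices(cohort[:100])
    Vh, Th = to_matrices(cohort[100:])
    model = train_dnn(V, T, DNNParams(epochs_finetune=300), seed=0)
    train_rmse = np.sqrt(np.mean((model.predict(V) - T) ** 2))
    test_rmse = np.sqrt(np.mean((model.predict(Vh) - Th) ** 2))
    assert train_rmse < 2.0
    assert test_rmse < 2 * train_rmse


def test_prediction_contract():
    rng = np.random.default_rng(7)
    U = rng.standard_normal((30, 4))
    T = rng.standard_normal((30, 2))
    model = train_dnn(U, T, DNNParams(hidden_sizes=(6,), epochs_finetune=5),
                      seed=12)
    X = np.tile(rng.standard_normal(4), (3, 1))
    out = model.predict(X)
    assert np.array_equal(out[0], out[1]) and np.array_equal(out[1], out[2])
    assert np.all(np.isfinite(model.predict(rng.standard_normal((10, 4)) * 50)))
    with pytest.raises(ValueError, match="input features"):
        model.predict(np.zeros((2, 5)))


def test_conjugate_gradient_optimizer_reduces_cost():
    """The optional CG fine-tuner lowers the cost and is deterministic."""
    rng = np.random.default_rng(8)
    U = rng.uniform(-1, 1, size=(60, 3))
    T = np.column_stack([110 + 10 * U[:, 0], 70 + 5 * U[:, 1]])
    params = DNNParams(hidden_sizes=(6,), epochs_finetune=40, epochs_pretrain=0,
                       optimizer="cg")
    a = train_dnn(U, T, params, seed=13)
    b = train_dnn(U, T, params, seed=13)
    assert a.cost_history[-1] < a.cost_history[0]
    assert np.array_equal(a.predict(U), b.predict(U))
    with pytest.raises(ValueError, match="optimizer"):
        train_dnn(U, T, DNNParams(optimizer="adam"), seed=0)
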