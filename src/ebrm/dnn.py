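"""Feed-forward regression weak learner with RBM pre-training.

The weak learner is a small multilayer perceptron: logistic hidden layers, a
linear two-unit output (SBP, DBP — a logistic output could not represent
unbounded mmHg values), squared-error cost

    L = (1/C) * sum_batch sum_d (That_d - T_d)^2

minimised by mini-batch gradient descent with momentum,

    velocity <- eta * velocity - zeta * grad,   param <- param + velocity,

with separate learning rates for weights and biases.  Inputs and targets are
standardized internally on training statistics, which are frozen for
prediction.

Pre-training initialises the hidden stack generatively: a Gaussian-Bernoulli
restricted Boltzmann machine (GBRBM) connects the real-valued standardized
input layer to the first binary hidden layer, and Bernoulli-Bernoulli RBMs
stack above it, each trained with one-step contrastive divergence (CD-1).
Because random initialisation is itself a source of uncertainty, ``bagged_init``
pre-trains K_pre RBM stacks on bootstrap resamples of the rows and combines
them element-wise into one ensemble initialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit
from ._rng import seedseq


@dataclass
class DNNParams:
    """Hyperparameters; defaults follow the reference configuration
    (3 hidden layers of 32 logistic units, weight rate 0.001, bias rates 0.01,
    momentum 0.9, weights initialised uniformly in (-1, 1))."""

    hidden_sizes: tuple[int, ...] = (32, 32, 32)
    lr_weights: float = 0.001
    lr_visible_bias: float = 0.01
    lr_hidden_bias: float = 0.01
    momentum: float = 0.9
    epochs_pretrain: int = 10
    epochs_finetune: int = 50
    batch_size: int = 32
    init_scale: float = 1.0  # weights ~ Uniform(-init_scale, init_scale)
    optimizer: str = "momentum"  # or "cg" (full-batch conjugate gradients)

    def __post_init__(self) -> None:
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")


@dataclass
class BaggedInit:
    """Element-wise combination of K_pre pre-trained RBM stacks."""

    weights: list[np.ndarray]  # per hidden layer, shape (n_in, n_out)
    hidden_biases: list[np.ndarray]
    k_pre: int
    input_dim: int


def _init_stack(sizes: list[int], scale: float, rng) -> tuple[list, list]:
    weights = [
        rng.uniform(-scale, scale, size=(sizes[i], sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]
    biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    return weights, biases


def gbrbm_pretrain(
    V: np.ndarray, params: DNNParams, seed=None
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Layerwise CD-1 pre-training of the hidden stack on standardized inputs.

    Returns (weights, hidden_biases) for the hidden layers only; the linear
    output layer is never pre-trained.  With ``epochs_pretrain == 0`` the
    random initialisation is returned unchanged.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("pre-training inputs must be finite")
    rng = np.random.default_rng(seed)
    sizes = [V.shape[1], *params.hidden_sizes]
    weights, hbiases = _init_stack(sizes, params.init_scale, rng)
    data = V
    for layer in range(len(params.hidden_sizes)):
        W = weights[layer]
        hb = hbiases[layer]
        vb = np.zeros(sizes[layer])
        gaussian = layer == 0  # GBRBM at the bottom, Bernoulli RBMs above
        for _ in range(params.epochs_pretrain):
            order = rng.permutation(data.shape[0])
            for start in range(0, data.shape[0], params.batch_size):
                v0 = data[order[start : start + params.batch_size]]
                h0p = expit(v0 @ W + hb)
                h0s = (rng.random(h0p.shape) < h0p).astype(float)
                v1 = h0s @ W.T + vb
                if not gaussian:
                    v1 = expit(v1)
                h1p = expit(v1 @ W + hb)
                m = v0.shape[0]
                W += params.lr_weights * (v0.T @ h0p - v1.T @ h1p) / m
                vb += params.lr_visible_bias * (v0 - v1).mean(axis=0)
                hb += params.lr_hidden_bias * (h0p - h1p).mean(axis=0)
        data = expit(data @ W + hb)
    return weights, hbiases


def rbm_reconstruction_error(V: np.ndarray, W: np.ndarray, hb: np.ndarray,
                             vb: np.ndarray | None = None) -> float:
    """Mean squared one-step reconstruction error of a GBRBM on V."""
    V = np.asarray(V, dtype=float)
    if vb is None:
        vb = np.zeros(V.shape[1])
    h = expit(V @ W + hb)
    recon = h @ W.T + vb
    return float(np.mean((V - recon) ** 2))


def bagged_init(
    V: np.ndarray, k_pre: int, params: DNNParams, seed=None
) -> BaggedInit:
    """Pre-train ``k_pre`` stacks on bootstrap resamples of rows; combine
    element-wise by averaging.  (Summation would scale activations by k_pre;
    the mean keeps them on the single-learner scale.)"""
    if k_pre < 1:
        raise ValueError("k_pre must be at least 1")
    V = np.asarray(V, dtype=float)
    master = seedseq(seed)
    children = master.spawn(k_pre)
    acc_w: list[np.ndarray] | None = None
    acc_b: list[np.ndarray] | None = None
    for child in children:
        rng = np.random.default_rng(child)
        rows = rng.integers(0, V.shape[0], size=V.shape[0]) if k_pre > 1 else np.arange(V.shape[0])
        w, b = gbrbm_pretrain(V[rows], params, seed=child.spawn(1)[0])
        if acc_w is None:
            acc_w = [wi.copy() for wi in w]
            acc_b = [bi.copy() for bi in b]
        else:
            for i in range(len(w)):
                acc_w[i] += w[i]
                acc_b[i] += b[i]
    assert acc_w is not None and acc_b is not None
    return BaggedInit(
        weights=[wi / k_pre for wi in acc_w],
        hidden_biases=[bi / k_pre for bi in acc_b],
        k_pre=k_pre,
        input_dim=V.shape[1],
    )


# ---------------------------------------------------------------------------
# MLP forward / backward on explicit parameter lists (testable in isolation)

def mlp_forward(weights, biases, X):
    """Forward pass; returns (activations per layer, output)."""
    acts = [X]
    a = X
    for i in range(len(weights) - 1):
        a = expit(a @ weights[i] + biases[i])
        acts.append(a)
    out = a @ weights[-1] + biases[-1]
    return acts, out


def mlp_loss(weights, biases, X, Y) -> float:
    """Squared-error cost: mean over rows of the summed per-target error."""
    _, out = mlp_forward(weights, biases, X)
    return float(np.mean(np.sum((out - Y) ** 2, axis=1)))


def mlp_gradients(weights, biases, X, Y):
    """Analytic gradients of :func:`mlp_loss` w.r.t. every weight and bias."""
    acts, out = mlp_forward(weights, biases, X)
    m = X.shape[0]
    delta = 2.0 * (out - Y) / m
    gw = [None] * len(weights)
    gb = [None] * len(biases)
    gw[-1] = acts[-1].T @ delta
    gb[-1] = delta.sum(axis=0)
    for i in range(len(weights) - 2, -1, -1):
        delta = (delta @ weights[i + 1].T) * acts[i + 1] * (1 - acts[i + 1])
        gw[i] = acts[i].T @ delta
        gb[i] = delta.sum(axis=0)
    return gw, gb


class _Standardizer:
    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.sd = np.where(sd > 0, sd, 1.0)

    def transform(self, X):
        return (X - self.mean) / self.sd

    def inverse(self, Z):
        return Z * self.sd + self.mean


class DNNRegressor:
    """Trained weak learner: standardizers + MLP parameters."""

    def __init__(self, weights, biases, x_scaler, y_scaler, params: DNNParams,
                 cost_history: list[float]):
        self.weights = weights
        self.biases = biases
        self._x = x_scaler
        self._y = y_scaler
        self.params = params
        self.cost_history = cost_history

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    def predict(self, U: np.ndarray) -> np.ndarray:
        U = np.atleast_2d(np.asarray(U, dtype=float))
        if U.shape[1] != self.input_dim:
            raise ValueError(
                f"expected {self.input_dim} input features, got {U.shape[1]}"
            )
        _, out = mlp_forward(self.weights, self.biases, self._x.transform(U))
        return self._y.inverse(out)


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int):
        super().__init__(f"training cost became non-finite at epoch {epoch}")
        self.epoch = epoch


def train_dnn(
    U: np.ndarray,
    T: np.ndarray,
    params: DNNParams | None = None,
    init: BaggedInit | None = None,
    seed=None,
) -> DNNRegressor:
    """Fit the weak learner.

    ``params.optimizer`` selects mini-batch momentum gradient descent
    (default) or full-batch nonlinear conjugate gradients ("cg", with
    ``epochs_finetune`` as the iteration budget).  ``init`` supplies
    pre-trained hidden-layer parameters (from :func:`gbrbm_pretrain` via
    :func:`bagged_init`); the output layer is always freshly initialised.
    Raises :class:`TrainingDivergedError` if the cost leaves the finite range.
    """
    params = params or DNNParams()
    U = np.asarray(U, dtype=float)
    T = np.asarray(T, dtype=float)
    if U.shape[0] != T.shape[0]:
        raise ValueError("row counts of inputs and targets differ")
    rng = np.random.default_rng(seed)
    xs = _Standardizer(U)
    ys = _Standardizer(T)
    X = xs.transform(U)
    Y = ys.transform(T)
    sizes = [X.shape[1], *params.hidden_sizes, T.shape[1]]
    weights, biases = _init_stack(sizes, params.init_scale, rng)
    if init is not None:
        if init.input_dim != X.shape[1]:
            raise ValueError("bagged init dimension does not match inputs")
        for i in range(len(init.weights)):
            weights[i] = init.weights[i].copy()
            biases[i] = init.hidden_biases[i].copy()
    if params.optimizer == "cg":
        weights, biases, cost_history = _fit_cg(weights, biases, X, Y, params)
        return DNNRegressor(weights, biases, xs, ys, params, cost_history)
    if params.optimizer != "momentum":
        raise ValueError(f"unknown optimizer {params.optimizer!r}")
    vel_w = [np.zeros_like(w) for w in weights]
    vel_b = [np.zeros_like(b) for b in biases]
    cost_history: list[float] = []
    for epoch in range(params.epochs_finetune):
        order = rng.permutation(X.shape[0])
        for start in range(0, X.shape[0], params.batch_size):
            sel = order[start : start + params.batch_size]
            gw, gb = mlp_gradients(weights, biases, X[sel], Y[sel])
            for i in range(len(weights)):
                vel_w[i] = params.momentum * vel_w[i] - params.lr_weights * gw[i]
                weights[i] += vel_w[i]
                vel_b[i] = params.momentum * vel_b[i] - params.lr_hidden_bias * gb[i]
                biases[i] += vel_b[i]
        cost = mlp_loss(weights, biases, X, Y)
        if not np.isfinite(cost):
            raise TrainingDivergedError(epoch)
        cost_history.append(cost)
    return DNNRegressor(weights, biases, xs, ys, params, cost_history)


def _fit_cg(weights, biases, X, Y, params: DNNParams):
    """Full-batch conjugate-gradient fine-tuning with analytic gradients."""
    from scipy.optimize import minimize

    shapes_w = [w.shape for w in weights]
    shapes_b = [b.shape for b in biases]

    def unpack(theta):
        ws, bs, pos = [], [], 0
        for s in shapes_w:
            ws.append(theta[pos : pos + s[0] * s[1]].reshape(s))
            pos += s[0] * s[1]
        for s in shapes_b:
            bs.append(theta[pos : pos + s[0]])
            pos += s[0]
        return ws, bs

    def fun(theta):
        ws, bs = unpack(theta)
        return mlp_loss(ws, bs, X, Y)

    def jac(theta):
        ws, bs = unpack(theta)
        gw, gb = mlp_gradients(ws, bs, X, Y)
        return np.concatenate([g.ravel() for g in gw + gb])

    theta0 = np.concatenate([w.ravel() for w in weights]
                            + [b.ravel() for b in biases])
    history: list[float] = []
    res = minimize(fun, theta0, jac=jac, method="CG",
                   callback=lambda th: history.append(fun(th)),
                   options={"maxiter": params.epochs_finetune})
    if not np.isfinite(res.fun):
        raise TrainingDivergedError(len(history))
    ws, bs = unpack(res.x)
    return [w.copy() for w in ws], [b.copy() for b in bs], history or [float(res.fun)]
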