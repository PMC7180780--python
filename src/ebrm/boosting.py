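"""Ensemble-based recursive methodology: AdaBoost-style boosting for BP
regression with previous-estimate feedback.

The ensemble maintains a weight distribution w over the L artificial training
rows.  Each round draws M rows with replacement according to w, trains a weak
learner on the block input [features | current BP estimate] — the two running
estimate columns are what makes the recursion different from plain
AdaBoost.R2 — and then scores all L rows:

    loss_m   = ||prediction_m - target_m||^2
    eps_max  = max_m loss_m
    eps_m    = loss_m / eps_max               (relative error in [0, 1])
    eps_bar  = sum_m eps_m * w_m              (weighted mean error)
    beta_k   = eps_bar / (1 - eps_bar)        (confidence; small = trusted)
    w_m     <- w_m * beta_k^(1 - eps_m), renormalised.

With eps_bar < 1/2, beta_k < 1 and the exponent 1 - eps_m shrinks low-error
instances the most, concentrating the next round on hard rows.  The running
BP estimate fed to round k+1 is the weighted median of rounds 1..k, the same
rule used at prediction time.

The combination rule is the weighted median with weights log(1/beta_k): the
smallest prediction t such that the cumulative weight of learners predicting
at most t reaches half the total.  Equal betas reduce it to the ordinary
median.

Degenerate rounds: eps_max = 0 or eps_bar = 0 means the learner is essentially
perfect on the weighted sample — it receives a floor beta of 1e-10 (maximal
confidence) and boosting stops early.  A round with eps_bar >= 1/2 is worse
than the combination can absorb; it is discarded and resampled up to a retry
cap (the AdaBoost.R2 convention).  Learners with beta_k >= 1 would carry a
non-positive log-weight and get zero weight in the median.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np

from ._rng import seedseq
from .dnn import BaggedInit, DNNParams, bagged_init, train_dnn

BETA_FLOOR = 1e-10


class WeakLearner(Protocol):
    def predict(self, U: np.ndarray) -> np.ndarray: ...


# factory signature: (U, T, seed) -> fitted WeakLearner
LearnerFactory = Callable[[np.ndarray, np.ndarray, object], WeakLearner]


@dataclass
class BoostRoundTrace:
    round_index: int
    eps_max: float
    eps_m: np.ndarray
    eps_bar: float
    beta: float
    retries: int


@dataclass
class EnsembleModel:
    baseline: WeakLearner
    learners: list[WeakLearner]
    betas: np.ndarray
    traces: list[BoostRoundTrace]
    instance_weights: np.ndarray
    M: int
    feature_dim: int

    def __post_init__(self) -> None:
        if np.any(self.betas <= 0):
            raise ValueError("all betas must be positive")


def _median_weights(betas) -> np.ndarray:
    """log(1/beta) clamped below at zero (beta >= 1 contributes nothing)."""
    betas = np.asarray(betas, dtype=float)
    if np.any(betas <= 0):
        raise ValueError("betas must be positive")
    return np.maximum(np.log(1.0 / betas), 0.0)


def weighted_median(predictions, betas) -> float:
    """Weighted median of K scalar predictions with confidences beta_k.

    Returns the smallest prediction t such that the summed log(1/beta) weight
    of learners predicting <= t reaches half the total weight.  If every beta
    is >= 1 (total weight zero) the ordinary median is returned.
    """
    preds = np.asarray(predictions, dtype=float)
    if preds.size < 1:
        raise ValueError("need at least one prediction")
    w = _median_weights(betas)
    if w.shape != preds.shape:
        raise ValueError("predictions and betas must have equal length")
    total = w.sum()
    if total == 0:
        return float(np.median(preds))
    order = np.argsort(preds, kind="stable")
    cum = np.cumsum(w[order])
    idx = int(np.searchsorted(cum, total / 2.0))
    return float(preds[order[idx]])


def _weighted_median_cols(preds: np.ndarray, betas) -> np.ndarray:
    """Column-wise weighted median: preds shape (K, R) -> length-R vector."""
    w = _median_weights(betas)
    total = w.sum()
    if total == 0:
        return np.median(preds, axis=0)
    order = np.argsort(preds, axis=0, kind="stable")
    sorted_preds = np.take_along_axis(preds, order, axis=0)
    cum = np.cumsum(w[order], axis=0)
    idx = (cum >= total / 2.0).argmax(axis=0)
    return sorted_preds[idx, np.arange(preds.shape[1])]


def combine_predictions(per_learner: np.ndarray, betas) -> np.ndarray:
    """Weighted median across learners: (K, n, 2) -> (n, 2), per target."""
    K, n, d = per_learner.shape
    flat = per_learner.reshape(K, n * d)
    return _weighted_median_cols(flat, betas).reshape(n, d)


def dnn_learner_factory(
    params: DNNParams | None = None, init: BaggedInit | None = None
) -> LearnerFactory:
    """Factory producing momentum-trained MLP weak learners."""
    params = params or DNNParams()

    def factory(U, T, seed):
        return train_dnn(U, T, params=params, init=init, seed=seed)

    return factory


def fit_ebrm(
    V: np.ndarray,
    T: np.ndarray,
    K: int,
    M: int | None = None,
    learner_factory: LearnerFactory | None = None,
    dnn_params: DNNParams | None = None,
    k_pre: int = 3,
    seed=None,
    retry_cap: int = 3,
) -> EnsembleModel:
    """Boost K weak learners over the artificial rows (V, T).

    M is the per-round weighted-sample size (default: all L rows, M <= L
    required).  Without an explicit ``learner_factory`` the MLP weak learner
    is used: RBM stacks are bagged over ``k_pre`` bootstrap resamples to build
    the shared initialisation, once for the feedback baseline (features only)
    and once for the boosted learners (features + 2 feedback columns).

    The feedback matrix for round 1 is the prediction of a baseline learner
    trained on the features alone; thereafter it is the weighted median of
    the rounds fitted so far, evaluated on all L rows.
    """
    V = np.asarray(V, dtype=float)
    T = np.asarray(T, dtype=float)
    L = V.shape[0]
    if K < 1:
        raise ValueError("K must be at least 1")
    M = L if M is None else int(M)
    if not (1 <= M <= L):
        raise ValueError("require 1 <= M <= L")
    master = seedseq(seed)
    ss_baseline, ss_init_v, ss_init_u, ss_rounds = master.spawn(4)

    def zscore(X):
        sd = X.std(axis=0)
        return (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)

    if learner_factory is None:
        params = dnn_params or DNNParams()
        base_init = bagged_init(zscore(V), k_pre, params, seed=ss_init_v)
        baseline_factory = dnn_learner_factory(params, base_init)
    else:
        baseline_factory = learner_factory
    baseline = baseline_factory(V, T, ss_baseline)
    feedback = np.asarray(baseline.predict(V), dtype=float)

    if learner_factory is None:
        round_init = bagged_init(
            zscore(np.hstack([V, feedback])), k_pre, params, seed=ss_init_u
        )
        round_factory = dnn_learner_factory(params, round_init)
    else:
        round_factory = learner_factory

    w = np.full(L, 1.0 / L)
    learners: list[WeakLearner] = []
    betas: list[float] = []
    traces: list[BoostRoundTrace] = []
    all_preds: list[np.ndarray] = []
    rng_pool = ss_rounds.spawn(K * (retry_cap + 1))
    pool_pos = 0
    stop = False
    for k in range(1, K + 1):
        if stop:
            break
        for attempt in range(retry_cap + 1):
            child = rng_pool[pool_pos]
            pool_pos += 1
            rng = np.random.default_rng(child)
            idx = rng.choice(L, size=M, replace=True, p=w)
            U_train = np.hstack([V[idx], feedback[idx]])
            learner = round_factory(U_train, T[idx], child.spawn(1)[0])
            preds = np.asarray(learner.predict(np.hstack([V, feedback])), dtype=float)
            loss = np.sum((preds - T) ** 2, axis=1)
            eps_max = float(loss.max())
            if eps_max == 0.0:
                beta, eps_m, eps_bar, stop = BETA_FLOOR, np.zeros(L), 0.0, True
                break
            eps_m = loss / eps_max
            eps_bar = float(np.dot(eps_m, w))
            if eps_bar == 0.0:
                beta, stop = BETA_FLOOR, True
                break
            if eps_bar < 0.5:
                beta = eps_bar / (1.0 - eps_bar)
                break
        else:
            # every retry had eps_bar >= 1/2: no usable round, stop boosting
            break
        learners.append(learner)
        betas.append(beta)
        all_preds.append(preds)
        traces.append(
            BoostRoundTrace(
                round_index=k,
                eps_max=eps_max,
                eps_m=eps_m,
                eps_bar=eps_bar,
                beta=beta,
                retries=attempt,
            )
        )
        if not stop:
            w = w * beta ** (1.0 - eps_m)
            w = w / w.sum()
            feedback = combine_predictions(np.stack(all_preds), np.array(betas))
    if not learners:
        raise RuntimeError(
            "no boosting round achieved weighted mean error below 1/2; "
            "the weak learner is not better than chance on this data"
        )
    return EnsembleModel(
        baseline=baseline,
        learners=learners,
        betas=np.array(betas),
        traces=traces,
        instance_weights=w,
        M=M,
        feature_dim=V.shape[1],
    )


def predict_ebrm(model: EnsembleModel, features: np.ndarray) -> np.ndarray:
    """Predict (SBP, DBP) per row.

    Mirrors training: the baseline learner seeds the feedback columns from the
    features alone, each boosted learner sees [features | feedback], and after
    learner k the feedback becomes the weighted median of learners 1..k.  The
    final output is the weighted median of all K learners, per target.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.feature_dim:
        raise ValueError(
            f"expected {model.feature_dim} features, got {X.shape[1]}"
        )
    feedback = np.asarray(model.baseline.predict(X), dtype=float)
    preds = []
    for k, learner in enumerate(model.learners):
        preds.append(
            np.asarray(learner.predict(np.hstack([X, feedback])), dtype=float)
        )
        feedback = combine_predictions(np.stack(preds), model.betas[: k + 1])
    return feedback
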