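"""Serialization: model bundles and run configuration.

A model bundle is a single JSON document holding the baseline learner, each
boosted learner, the betas, per-round trace summaries, and the seed/config
echo.  Only the MLP weak learner is serializable; test doubles are not.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .boosting import BoostRoundTrace, EnsembleModel
from .cohort import CohortConfig
from .dnn import DNNParams, DNNRegressor, _Standardizer

FORMAT_VERSION = 1


def _learner_to_dict(learner: DNNRegressor) -> dict:
    return {
        "weights": [w.tolist() for w in learner.weights],
        "biases": [b.tolist() for b in learner.biases],
        "x_mean": learner._x.mean.tolist(),
        "x_sd": learner._x.sd.tolist(),
        "y_mean": learner._y.mean.tolist(),
        "y_sd": learner._y.sd.tolist(),
        "params": dataclasses.asdict(learner.params),
        "cost_history": learner.cost_history,
    }


def _learner_from_dict(d: dict) -> DNNRegressor:
    xs = _Standardizer.__new__(_Standardizer)
    xs.mean = np.asarray(d["x_mean"], dtype=float)
    xs.sd = np.asarray(d["x_sd"], dtype=float)
    ys = _Standardizer.__new__(_Standardizer)
    ys.mean = np.asarray(d["y_mean"], dtype=float)
    ys.sd = np.asarray(d["y_sd"], dtype=float)
    p = dict(d["params"])
    p["hidden_sizes"] = tuple(p["hidden_sizes"])
    return DNNRegressor(
        [np.asarray(w, dtype=float) for w in d["weights"]],
        [np.asarray(b, dtype=float) for b in d["biases"]],
        xs,
        ys,
        DNNParams(**p),
        list(d["cost_history"]),
    )


def save_model(model: EnsembleModel, path, config_echo: dict | None = None) -> None:
    if not isinstance(model.baseline, DNNRegressor):
        raise TypeError("only MLP-based ensembles are serializable")
    doc = {
        "format_version": FORMAT_VERSION,
        "betas": model.betas.tolist(),
        "M": model.M,
        "feature_dim": model.feature_dim,
        "instance_weights": model.instance_weights.tolist(),
        "baseline": _learner_to_dict(model.baseline),
        "learners": [_learner_to_dict(l) for l in model.learners],
        "traces": [
            {
                "round_index": t.round_index,
                "eps_max": t.eps_max,
                "eps_bar": t.eps_bar,
                "beta": t.beta,
                "retries": t.retries,
            }
            for t in model.traces
        ],
        "config_echo": config_echo or {},
    }
    Path(path).write_text(json.dumps(doc))


def load_model(path) -> EnsembleModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format_version") != FORMAT_VERSION:
        raise ValueError("unrecognised model bundle format")
    traces = [
        BoostRoundTrace(
            round_index=t["round_index"],
            eps_max=t["eps_max"],
            eps_m=np.array([]),
            eps_bar=t["eps_bar"],
            beta=t["beta"],
            retries=t["retries"],
        )
        for t in doc["traces"]
    ]
    return EnsembleModel(
        baseline=_learner_from_dict(doc["baseline"]),
        learners=[_learner_from_dict(d) for d in doc["learners"]],
        betas=np.asarray(doc["betas"], dtype=float),
        traces=traces,
        instance_weights=np.asarray(doc["instance_weights"], dtype=float),
        M=int(doc["M"]),
        feature_dim=int(doc["feature_dim"]),
    )


def cohort_config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    for key in ("feature_loadings", "feature_intercepts"):
        if d[key] is not None:
            d[key] = np.asarray(d[key]).tolist()
    return d


def cohort_config_from_dict(d: dict) -> CohortConfig:
    return CohortConfig(**d)


def load_cohort_config(path) -> CohortConfig:
    text = Path(path).read_text()
    d = yaml.safe_load(text)
    return cohort_config_from_dict(d)


def save_cohort_config(config: CohortConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cohort_config_to_dict(config)))


def config_hash(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def write_manifest(path, config: dict, seed) -> None:
    """Seed/config echo written next to every pipeline output."""
    doc = {"seed": seed, "config": config, "config_hash": config_hash(config)}
    Path(path).write_text(json.dumps(doc, indent=1))
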