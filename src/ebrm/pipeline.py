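"""End-to-end helpers: cohort -> artificial rows -> ensemble -> reports.

These are the functions the examples and the command-line interface call; each
one wraps the lower-level modules without adding behaviour of its own.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import seedseq
from .boosting import EnsembleModel, fit_ebrm, predict_ebrm
from .bootstrap import augment_cohort
from .cohort import SubjectSession, to_matrices
from .confint import bootstrap_ci, monte_carlo_ci
from .dnn import DNNParams
from .normality import lilliefors
from .protocols import GradeReport, error_stats, grade_report, n_folds, rotating_split
from .uncertainty import bp_uncertainty_report

TARGETS = ("sbp", "dbp")


def fit_from_cohort(
    cohort: Sequence[SubjectSession],
    B: int = 100,
    K: int = 5,
    M: int | None = None,
    dnn_params: DNNParams | None = None,
    k_pre: int = 3,
    learner_factory=None,
    seed=None,
) -> EnsembleModel:
    """Augment a cohort with B bootstrap replicates per subject and boost K
    weak learners on the artificial rows."""
    V, T = to_matrices(cohort)
    ss = seedseq(seed)
    ss_aug, ss_fit = ss.spawn(2)
    V_art, T_art = augment_cohort(V, T, B=B, seed=ss_aug)
    return fit_ebrm(
        V_art,
        T_art,
        K=K,
        M=M,
        learner_factory=learner_factory,
        dnn_params=dnn_params,
        k_pre=k_pre,
        seed=ss_fit,
    )


def predict_cohort(model: EnsembleModel, cohort: Sequence[SubjectSession]) -> pd.DataFrame:
    """Per-sequence predictions next to the references."""
    V, T = to_matrices(cohort)
    est = predict_ebrm(model, V)
    rows = []
    r = 0
    for subj in cohort:
        for seq in subj.sequences:
            rows.append(
                {
                    "subject_id": subj.subject_id,
                    "seq": seq.seq_index,
                    "est_sbp": est[r, 0],
                    "est_dbp": est[r, 1],
                    "ref_sbp": seq.ref_sbp,
                    "ref_dbp": seq.ref_dbp,
                }
            )
            r += 1
    return pd.DataFrame(rows)


def subject_interval_table(
    predictions: pd.DataFrame, B: int = 100, alpha: float = 0.025, seed=None
) -> pd.DataFrame:
    """Per-subject 95 % intervals and GUM uncertainty from the five estimates.

    One row per (subject, target) with the bootstrap-percentile interval, the
    closed-form CLT ("Monte-Carlo") interval, and the expanded-uncertainty
    interval mean ± U.
    """
    master = seedseq(seed)
    rows = []
    groups = list(predictions.groupby("subject_id", sort=False))
    children = master.spawn(len(groups) * len(TARGETS))
    c = 0
    for sid, grp in groups:
        for target in TARGETS:
            est = grp[f"est_{target}"].to_numpy()
            ref = float(grp[f"ref_{target}"].mean())
            boot = bootstrap_ci(est, B=B, alpha=alpha, seed=children[c], target=target)
            mc = monte_carlo_ci(est, alpha=alpha, target=target)
            unc = bp_uncertainty_report(est, ref, quantity=target)
            lo_u, hi_u = unc.interval
            rows.append(
                {
                    "subject_id": sid,
                    "target": target,
                    "n": len(est),
                    "mean_est": float(est.mean()),
                    "mean_ref": ref,
                    "boot_lower": boot.lower,
                    "boot_upper": boot.upper,
                    "boot_width": boot.width,
                    "mc_lower": mc.lower,
                    "mc_upper": mc.upper,
                    "mc_width": mc.width,
                    "bias": unc.u_beta,
                    "u": unc.u_alpha,
                    "uc": unc.uc,
                    "U": unc.U,
                    "u_lower": lo_u,
                    "u_upper": hi_u,
                }
            )
            c += 1
    return pd.DataFrame(rows)


def normality_summary(
    predictions: pd.DataFrame, B: int = 100, alpha: float = 0.05, seed=None
) -> pd.DataFrame:
    """Lilliefors + moment summary of the artificial per-subject BP estimates.

    For each subject and target, the five estimates are expanded into B
    parametric-bootstrap replicate means (columns of Gaussian draws around the
    fitted mean/sd, the same construction as the bootstrap confidence
    interval) and tested for normality; the table reports the mean and
    standard deviation of each test quantity across subjects, one row per
    target.  The nonparametric replicate means are unsuitable here: with only
    five repeats they live on a small lattice, and the resulting ties fail the
    test for discreteness rather than non-normality.
    """
    master = seedseq(seed)
    groups = list(predictions.groupby("subject_id", sort=False))
    children = master.spawn(len(groups) * len(TARGETS))
    acc: dict[str, dict[str, list[float]]] = {
        t: {k: [] for k in ("h", "p", "k", "cv", "kurtosis", "skewness")}
        for t in TARGETS
    }
    c = 0
    for _, grp in groups:
        for target in TARGETS:
            est = grp[f"est_{target}"].to_numpy()
            s_boot, s_test = children[c].spawn(2)
            c += 1
            rng = np.random.default_rng(s_boot)
            draws = est.mean() + est.std(ddof=1) * rng.standard_normal(
                (est.size, B)
            )
            art = draws.mean(axis=0)
            res = lilliefors(art, alpha=alpha, seed=s_test)
            acc[target]["h"].append(res.h)
            acc[target]["p"].append(res.p)
            acc[target]["k"].append(res.k)
            acc[target]["cv"].append(res.cv)
            acc[target]["kurtosis"].append(res.kurtosis)
            acc[target]["skewness"].append(res.skewness)
    rows = []
    for target in TARGETS:
        row: dict[str, float | str] = {"target": target, "alpha": alpha}
        for key, vals in acc[target].items():
            arr = np.asarray(vals, dtype=float)
            row[key] = float(arr.mean())
            row[f"{key}_std"] = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_rotating(
    cohort: Sequence[SubjectSession],
    train_subjects: int,
    test_subjects: int,
    B: int = 100,
    K: int = 5,
    M: int | None = None,
    dnn_params: DNNParams | None = None,
    k_pre: int = 3,
    learner_factory=None,
    seed=None,
) -> tuple[dict[str, GradeReport], pd.DataFrame]:
    """Rotating subject-wise evaluation.

    Each fold trains on ``train_subjects`` and tests the next block of
    ``test_subjects``; every subject is tested exactly once.  Returns grade
    reports per target over the pooled held-out predictions, plus the pooled
    prediction table.
    """
    folds = n_folds(len(cohort), test_subjects)
    master = seedseq(seed)
    children = master.spawn(folds)
    parts = []
    for fold in range(folds):
        train, test = rotating_split(cohort, train_subjects, test_subjects, fold)
        model = fit_from_cohort(
            train,
            B=B,
            K=K,
            M=M,
            dnn_params=dnn_params,
            k_pre=k_pre,
            learner_factory=learner_factory,
            seed=children[fold],
        )
        part = predict_cohort(model, test)
        part["fold"] = fold
        parts.append(part)
    pooled = pd.concat(parts, ignore_index=True)
    reports = {
        t: grade_report(
            pooled[f"est_{t}"].to_numpy(), pooled[f"ref_{t}"].to_numpy(), target=t
        )
        for t in TARGETS
    }
    return reports, pooled
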