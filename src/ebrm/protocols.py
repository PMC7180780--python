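"""AAMI / BHS device-grading metrics and the rotating subject-wise split.

AAMI criterion: a device passes if the mean error against the auscultatory
reference is within ±5 mmHg and the standard deviation of error is below
8 mmHg.  BHS grading classifies by the cumulative fractions of absolute
errors within 5, 10 and 15 mmHg: A requires (60, 85, 95) %, B (50, 75, 90) %,
C (40, 65, 85) %, all three thresholds simultaneously (inclusive), else D.

Evaluation splits are always by subject — all five sequences of a subject go
to the same side — rotating a test block through the cohort so that every
subject is tested exactly once across folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

MAE_THRESHOLDS = (5.0, 10.0, 15.0)
# cumulative-percentage floors per grade at |err| <= 5 / 10 / 15 mmHg
BHS_GRADE_THRESHOLDS = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}

AAMI_ME_LIMIT = 5.0
AAMI_SDE_LIMIT = 8.0


@dataclass
class ErrorStats:
    target: str
    mean_error: float
    sde: float
    mae_pcts: tuple[float, float, float]
    n: int

    def __post_init__(self) -> None:
        p5, p10, p15 = self.mae_pcts
        if not (0 <= p5 <= p10 <= p15 <= 100):
            raise ValueError("mae percentages must be non-decreasing within [0, 100]")


@dataclass
class GradeReport:
    target: str
    aami_pass: bool
    bhs_grade: str
    stats: ErrorStats


def error_stats(estimates, references, target: str = "BP") -> ErrorStats:
    """ME, SDE (n-1 divisor) and cumulative absolute-error percentages."""
    est = np.asarray(estimates, dtype=float)
    ref = np.asarray(references, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("estimates and references must have equal length")
    if est.size < 2:
        raise ValueError("need at least 2 paired measurements")
    err = est - ref
    pcts = tuple(
        float(100.0 * np.mean(np.abs(err) <= t)) for t in MAE_THRESHOLDS
    )
    return ErrorStats(
        target=target,
        mean_error=float(err.mean()),
        sde=float(err.std(ddof=1)),
        mae_pcts=pcts,
        n=int(est.size),
    )


def bhs_grade(mae_pcts: Sequence[float]) -> str:
    """Grade A-D from the (<=5, <=10, <=15 mmHg) percentage triple."""
    p = tuple(float(v) for v in mae_pcts)
    if len(p) != 3:
        raise ValueError("expected three percentages")
    for grade, floors in BHS_GRADE_THRESHOLDS.items():
        if all(v >= f for v, f in zip(p, floors)):
            return grade
    return "D"


def aami_pass(stats: ErrorStats) -> bool:
    return abs(stats.mean_error) < AAMI_ME_LIMIT and stats.sde < AAMI_SDE_LIMIT


def grade_report(estimates, references, target: str = "BP") -> GradeReport:
    stats = error_stats(estimates, references, target=target)
    return GradeReport(
        target=target,
        aami_pass=aami_pass(stats),
        bhs_grade=bhs_grade(stats.mae_pcts),
        stats=stats,
    )


def rotating_split(
    cohort: Sequence, train_subjects: int = 60, test_subjects: int = 25, fold: int = 0
) -> tuple[list, list]:
    """Subject-wise rotating split.

    Fold f tests the f-th consecutive block of ``test_subjects`` subjects (the
    last fold may be smaller when the cohort size is not a multiple); the
    training set is the next ``train_subjects`` subjects cyclically after the
    test block.  Across folds 0 .. n_folds(...)-1 the test blocks partition
    the cohort, so each subject is tested exactly once.
    """
    S = len(cohort)
    if train_subjects + test_subjects > S:
        raise ValueError("train_subjects + test_subjects exceeds cohort size")
    if test_subjects < 1 or train_subjects < 1:
        raise ValueError("split sizes must be positive")
    folds = n_folds(S, test_subjects)
    if not (0 <= fold < folds):
        raise ValueError(f"fold must be in [0, {folds - 1}]")
    start = fold * test_subjects
    stop = min(start + test_subjects, S)
    test = list(cohort[start:stop])
    rest = [cohort[(stop + i) % S] for i in range(S - (stop - start))]
    train = rest[:train_subjects]
    return train, test


def n_folds(n_subjects: int, test_subjects: int) -> int:
    return math.ceil(n_subjects / test_subjects)
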