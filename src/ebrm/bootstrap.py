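"""Artificial features by bootstrap resampling of the five repeats.

Five repeats per subject are too few to train on directly, so each subject's
sample is enlarged by the bootstrap: B replicate means of the n=5 original
values become "artificial" features.  The replicate-mean distribution tends to
Gaussian as B grows, and two uncertainty summaries come with it:

* bias  = (mean of the B replicate means) - (original sample mean)
* bootstrap standard error = sd of the replicate means (1/(B-1) divisor)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import seedseq
from .cohort import SEQUENCES_PER_SUBJECT


@dataclass
class ArtificialFeatureSet:
    """B bootstrap replicate means of one feature with bias / SE estimates."""

    source_name: str
    replicate_means: np.ndarray
    original_mean: float
    overall_mean: float
    bias: float
    boot_se: float
    B: int

    def __post_init__(self) -> None:
        self.replicate_means = np.asarray(self.replicate_means, dtype=float)
        if len(self.replicate_means) != self.B:
            raise ValueError("replicate_means length must equal B")
        if self.boot_se < 0:
            raise ValueError("boot_se must be non-negative")


def bootstrap_replicates(
    x, B: int, seed=None, source_name: str = "feature"
) -> ArtificialFeatureSet:
    """Resample ``x`` with replacement B times and collect the replicate means."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 observations to bootstrap")
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    means = x[idx].mean(axis=1)
    overall = float(means.mean())
    original = float(x.mean())
    se = float(means.std(ddof=1))
    return ArtificialFeatureSet(
        source_name=source_name,
        replicate_means=means,
        original_mean=original,
        overall_mean=overall,
        bias=overall - original,
        boot_se=se,
        B=B,
    )


def augment_cohort(
    V: np.ndarray,
    T: np.ndarray,
    B: int,
    seed=None,
    synchronous: bool = True,
    resample: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap-augment a cohort matrix pair into B artificial rows per subject.

    V has 5 rows per subject (grouped, in subject order); T the matching
    (SBP, DBP) references.  For each subject, replicate b resamples the five
    rows with replacement and records the column means, giving B x S rows.

    With ``synchronous=True`` (default) one index set per replicate is shared
    by every feature column *and* the targets, so artificial features stay
    paired with artificial targets.  ``synchronous=False`` draws an
    independent index set per column, which preserves only the marginals.

    Per-subject random streams are spawned from the master seed, so adding a
    subject does not perturb the replicates of the others.  With
    ``resample=False`` every replicate is the identity draw (no resampling),
    so each artificial row equals the subject's plain per-sequence mean —
    useful as a degenerate reference.
    """
    V = np.asarray(V, dtype=float)
    T = np.asarray(T, dtype=float)
    n = SEQUENCES_PER_SUBJECT
    if V.ndim != 2 or T.ndim != 2 or V.shape[0] != T.shape[0]:
        raise ValueError("V and T must be 2-D with matching row counts")
    if V.shape[0] % n:
        raise ValueError(f"row count must be a multiple of {n} (rows per subject)")
    if B < 1:
        raise ValueError("B must be at least 1")
    S = V.shape[0] // n
    master = seedseq(seed)
    children = master.spawn(S)
    V_parts, T_parts = [], []
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        Vs = V[s * n : (s + 1) * n]
        Ts = T[s * n : (s + 1) * n]
        if not resample:
            idx = np.tile(np.arange(n), (B, 1))
            V_parts.append(Vs[idx].mean(axis=1))
            T_parts.append(Ts[idx].mean(axis=1))
            continue
        if synchronous:
            idx = rng.integers(0, n, size=(B, n))
            V_parts.append(Vs[idx].mean(axis=1))
            T_parts.append(Ts[idx].mean(axis=1))
        else:
            cols_v = [
                Vs[rng.integers(0, n, size=(B, n)), j].mean(axis=1)
                for j in range(V.shape[1])
            ]
            cols_t = [
                Ts[rng.integers(0, n, size=(B, n)), j].mean(axis=1)
                for j in range(T.shape[1])
            ]
            V_parts.append(np.column_stack(cols_v))
            T_parts.append(np.column_stack(cols_t))
    return np.vstack(V_parts), np.vstack(T_parts)


def feature_summary_table(
    sets: list[ArtificialFeatureSet], original: dict[str, np.ndarray] | None = None
) -> pd.DataFrame:
    """Summary table per artificial feature: means, sds, bias, bootstrap SE.

    ``original`` optionally maps source names to the raw samples so the raw
    standard deviation column can be filled in.
    """
    rows = []
    for fs in sets:
        raw_sd = np.nan
        if original is not None and fs.source_name in original:
            raw_sd = float(np.std(original[fs.source_name], ddof=1))
        rows.append(
            {
                "feature": fs.source_name,
                "mean": fs.original_mean,
                "boot_mean": fs.overall_mean,
                "sd": raw_sd,
                "boot_se": fs.boot_se,
                "bias": fs.bias,
                "B": fs.B,
            }
        )
    return pd.DataFrame(rows)
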