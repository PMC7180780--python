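"""Synthetic measurement cohorts emulating a repeated oscillometric BP protocol.

Each subject contributes five repeated measurement sequences.  For every
sequence two trained observers ("nurses") read the auscultatory pressure off a
mmHg manometer; the average of the two readings is the reference SBP/DBP for
that sequence.  Alongside the references, every sequence carries a feature
vector standing in for quantities extracted from the oscillometric waveform.

The generator draws a per-subject true pressure pair from a population
distribution, perturbs it per sequence with within-subject physiological
variation, rounds noisy observer readings to integer mmHg, and emits features
as a configured affine map of the sequence's true pressures plus Gaussian
noise.  The affine construction keeps the feature/pressure relationship exactly
invertible in the noise-free limit, which makes recovery checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence as TypingSequence

import numpy as np
import pandas as pd

SEQUENCES_PER_SUBJECT = 5


def nurse_average(reading1: float, reading2: float) -> float:
    """Reference pressure: arithmetic mean of the two observers' readings."""
    if not (np.isfinite(reading1) and np.isfinite(reading2)):
        raise ValueError("nurse readings must be finite")
    return (reading1 + reading2) / 2.0


@dataclass
class MeasurementSequence:
    """One repeat: two observers' readings, their average, and a feature vector."""

    seq_index: int
    nurse1_sbp: float
    nurse2_sbp: float
    nurse1_dbp: float
    nurse2_dbp: float
    ref_sbp: float
    ref_dbp: float
    features: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 1:
            raise ValueError("features must be a 1-D vector")
        expect_sbp = nurse_average(self.nurse1_sbp, self.nurse2_sbp)
        expect_dbp = nurse_average(self.nurse1_dbp, self.nurse2_dbp)
        if not np.isclose(self.ref_sbp, expect_sbp) or not np.isclose(
            self.ref_dbp, expect_dbp
        ):
            raise ValueError("reference BP must equal the mean of the nurse readings")


@dataclass
class SubjectSession:
    """A subject's five repeated sequences plus (optionally) the latent true BPs.

    ``true_sbp``/``true_dbp`` are known for simulated subjects and ``None`` for
    sessions reconstructed from a cohort CSV, which stores observed columns only.
    """

    subject_id: str
    true_sbp: float | None
    true_dbp: float | None
    sequences: list[MeasurementSequence]

    def __post_init__(self) -> None:
        if len(self.sequences) != SEQUENCES_PER_SUBJECT:
            raise ValueError(
                f"expected {SEQUENCES_PER_SUBJECT} sequences per subject, "
                f"got {len(self.sequences)}"
            )
        if self.true_sbp is not None and self.true_dbp is not None:
            if not (self.true_sbp > self.true_dbp > 0):
                raise ValueError("require true_sbp > true_dbp > 0")


@dataclass
class CohortConfig:
    """Population and noise model for a simulated cohort.

    Pressures in mmHg.  ``feature_noise_sd`` is in the same units as the
    features, which the default affine map keeps on a mmHg-like scale.
    """

    n_subjects: int = 85
    n_features: int = 12
    sbp_mean: float = 115.0
    sbp_sd: float = 12.0
    dbp_mean: float = 67.0
    dbp_sd: float = 9.0
    within_subject_sd: float = 2.5
    observer_sd: float = 1.0
    feature_noise_sd: float = 3.0
    feature_loadings: np.ndarray | None = None  # shape (n_features, 2)
    feature_intercepts: np.ndarray | None = None  # shape (n_features,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if self.n_features < 2:
            raise ValueError("n_features must be at least 2 (affine map rank)")
        for name in ("sbp_sd", "dbp_sd", "within_subject_sd", "observer_sd",
                     "feature_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.feature_loadings is not None:
            self.feature_loadings = np.asarray(self.feature_loadings, dtype=float)
            if self.feature_loadings.shape != (self.n_features, 2):
                raise ValueError("feature_loadings must have shape (n_features, 2)")
        if self.feature_intercepts is not None:
            self.feature_intercepts = np.asarray(self.feature_intercepts, dtype=float)
            if self.feature_intercepts.shape != (self.n_features,):
                raise ValueError("feature_intercepts must have shape (n_features,)")

    def resolved_feature_map(self) -> tuple[np.ndarray, np.ndarray]:
        """Affine map (A, b): features = A @ (sbp, dbp) + b + noise.

        When not supplied, A and b are drawn once from a stream derived from
        the config seed, so the map is a deterministic function of the config.
        """
        if self.feature_loadings is not None:
            loadings = self.feature_loadings
        else:
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xFEA7]))
            loadings = rng.uniform(-1.0, 1.0, size=(self.n_features, 2))
        if self.feature_intercepts is not None:
            intercepts = self.feature_intercepts
        else:
            rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x1CEB]))
            intercepts = rng.uniform(-20.0, 20.0, size=self.n_features)
        return loadings, intercepts


def simulate_cohort(config: CohortConfig) -> list[SubjectSession]:
    """Draw a cohort of subjects under the repeated-measurement protocol.

    Deterministic for a fixed config (including seed).  Per-subject random
    streams are spawned from one master seed, so enlarging the cohort leaves
    previously generated subjects untouched.
    """
    loadings, intercepts = config.resolved_feature_map()
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(config.n_subjects)
    subjects: list[SubjectSession] = []
    for s, child in enumerate(children):
        rng = np.random.default_rng(child)
        # Latent true BPs are whole mmHg (auscultatory references resolve to
        # integer manometer ticks); rejection keeps the ordering SBP > DBP > 0.
        for _ in range(1000):
            true_sbp = round(rng.normal(config.sbp_mean, config.sbp_sd))
            true_dbp = round(rng.normal(config.dbp_mean, config.dbp_sd))
            if true_sbp > true_dbp > 0:
                break
        else:  # pragma: no cover - unreachable for sane configs
            raise RuntimeError("could not draw true_sbp > true_dbp > 0")
        sequences = []
        for j in range(SEQUENCES_PER_SUBJECT):
            seq_sbp = true_sbp + rng.normal(0.0, config.within_subject_sd)
            seq_dbp = true_dbp + rng.normal(0.0, config.within_subject_sd)
            n1_sbp = round(seq_sbp + rng.normal(0.0, config.observer_sd))
            n2_sbp = round(seq_sbp + rng.normal(0.0, config.observer_sd))
            n1_dbp = round(seq_dbp + rng.normal(0.0, config.observer_sd))
            n2_dbp = round(seq_dbp + rng.normal(0.0, config.observer_sd))
            feats = (
                loadings @ np.array([seq_sbp, seq_dbp])
                + intercepts
                + rng.normal(0.0, config.feature_noise_sd, size=config.n_features)
            )
            sequences.append(
                MeasurementSequence(
                    seq_index=j + 1,
                    nurse1_sbp=float(n1_sbp),
                    nurse2_sbp=float(n2_sbp),
                    nurse1_dbp=float(n1_dbp),
                    nurse2_dbp=float(n2_dbp),
                    ref_sbp=nurse_average(n1_sbp, n2_sbp),
                    ref_dbp=nurse_average(n1_dbp, n2_dbp),
                    features=feats,
                )
            )
        subjects.append(
            SubjectSession(
                subject_id=f"S{s + 1:03d}",
                true_sbp=float(true_sbp),
                true_dbp=float(true_dbp),
                sequences=sequences,
            )
        )
    return subjects


def to_matrices(cohort: TypingSequence[SubjectSession]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a cohort into a feature matrix V (L x I) and target matrix T (L x 2).

    Rows are ordered (subject, sequence) lexicographically; T columns are
    (reference SBP, reference DBP) in mmHg.  L = 5 x n_subjects.
    """
    dims = {len(seq.features) for subj in cohort for seq in subj.sequences}
    if len(dims) > 1:
        raise ValueError(f"ragged feature vectors across cohort: lengths {sorted(dims)}")
    V = np.array([seq.features for subj in cohort for seq in subj.sequences])
    T = np.array(
        [[seq.ref_sbp, seq.ref_dbp] for subj in cohort for seq in subj.sequences]
    )
    return V, T


def cohort_to_frame(cohort: TypingSequence[SubjectSession]) -> pd.DataFrame:
    """One row per sequence: ids, nurse readings, references, f1..fI."""
    rows = []
    for subj in cohort:
        for seq in subj.sequences:
            row = {
                "subject_id": subj.subject_id,
                "seq": seq.seq_index,
                "nurse1_sbp": seq.nurse1_sbp,
                "nurse2_sbp": seq.nurse2_sbp,
                "nurse1_dbp": seq.nurse1_dbp,
                "nurse2_dbp": seq.nurse2_dbp,
                "ref_sbp": seq.ref_sbp,
                "ref_dbp": seq.ref_dbp,
            }
            for i, v in enumerate(seq.features):
                row[f"f{i + 1}"] = v
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_cohort(frame: pd.DataFrame) -> list[SubjectSession]:
    """Rebuild sessions from a cohort table; latent true BPs are not stored."""
    feat_cols = sorted(
        (c for c in frame.columns if c.startswith("f") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    if not feat_cols:
        raise ValueError("cohort table has no feature columns f1..fI")
    subjects = []
    for sid, grp in frame.groupby("subject_id", sort=False):
        grp = grp.sort_values("seq")
        sequences = [
            MeasurementSequence(
                seq_index=int(r["seq"]),
                nurse1_sbp=float(r["nurse1_sbp"]),
                nurse2_sbp=float(r["nurse2_sbp"]),
                nurse1_dbp=float(r["nurse1_dbp"]),
                nurse2_dbp=float(r["nurse2_dbp"]),
                ref_sbp=float(r["ref_sbp"]),
                ref_dbp=float(r["ref_dbp"]),
                features=r[feat_cols].to_numpy(dtype=float),
            )
            for _, r in grp.iterrows()
        ]
        subjects.append(
            SubjectSession(subject_id=str(sid), true_sbp=None, true_dbp=None,
                           sequences=sequences)
        )
    return subjects


def write_cohort_csv(cohort: TypingSequence[SubjectSession], path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def read_cohort_csv(path) -> list[SubjectSession]:
    return frame_to_cohort(pd.read_csv(path))
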