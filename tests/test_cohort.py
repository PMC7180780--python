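"""Cohort generator: protocol arithmetic, reproducibility, feature recovery."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ebrm.cohort import (
    CohortConfig,
    MeasurementSequence,
    SubjectSession,
    nurse_average,
    read_cohort_csv,
    simulate_cohort,
    to_matrices,
    write_cohort_csv,
)


@pytest.mark.parametrize(
    "r1, r2, expected",
    [(90, 90, 90), (96, 94, 95), (100, 98, 99), (96, 96, 96), (98, 96, 97),
     (60, 60, 60), (64, 64, 64), (70, 70, 70), (66, 66, 66)],
)
def test_nurse_average_protocol_rows(r1, r2, expected):
    """The reference column is the arithmetic mean of the two observers."""
    assert nurse_average(r1, r2) == expected


@given(st.floats(min_value=30, max_value=250, allow_nan=False))
def test_nurse_average_identical_readings(x):
    assert nurse_average(x, x) == x


def test_nurse_average_rejects_nonfinite():
    with pytest.raises(ValueError):
        nurse_average(np.nan, 90)


def test_references_equal_nurse_means(small_cohort):
    for subj in small_cohort:
        for seq in subj.sequences:
            assert seq.ref_sbp == (seq.nurse1_sbp + seq.nurse2_sbp) / 2
            assert seq.ref_dbp == (seq.nurse1_dbp + seq.nurse2_dbp) / 2


def test_noise_free_references_equal_true_bp(noisefree_config):
    """With all noise terms at zero every reference equals the latent true BP."""
    for subj in simulate_cohort(noisefree_config):
        for seq in subj.sequences:
            assert seq.ref_sbp == subj.true_sbp
            assert seq.ref_dbp == subj.true_dbp


def test_feature_map_inversion_recovers_true_bp():
    """Zero feature noise: solving the configured affine system for (SBP, DBP)
    from any sequence's feature vector recovers the latent pressures."""
    rng = np.random.default_rng(0)
    A = rng.uniform(-1, 1, size=(6, 2))
    b = rng.uniform(-5, 5, size=6)
    cfg = CohortConfig(
        n_subjects=4,
        n_features=6,
        within_subject_sd=0.0,
        observer_sd=0.0,
        feature_noise_sd=0.0,
        feature_loadings=A,
        feature_intercepts=b,
        seed=9,
    )
    for subj in simulate_cohort(cfg):
        for seq in subj.sequences:
            sol, *_ = np.linalg.lstsq(A, seq.features - b, rcond=None)
            assert np.allclose(sol, [subj.true_sbp, subj.true_dbp], atol=1e-8)


@pytest.mark.parametrize("n_subjects, rows", [(2, 10), (25, 125), (60, 300)])
def test_to_matrices_row_counts(n_subjects, rows):
    cohort = simulate_cohort(CohortConfig(n_subjects=n_subjects, seed=1))
    V, T = to_matrices(cohort)
    assert V.shape == (rows, 12)
    assert T.shape == (rows, 2)


def test_to_matrices_row_order_and_targets(small_cohort):
    V, T = to_matrices(small_cohort)
    r = 0
    for subj in small_cohort:
        for seq in subj.sequences:
            assert np.array_equal(V[r], seq.features)
            assert T[r, 0] == seq.ref_sbp and T[r, 1] == seq.ref_dbp
            r += 1


def test_to_matrices_rejects_ragged_features(small_cohort):
    bad_seq = [
        MeasurementSequence(i + 1, 100, 100, 70, 70, 100, 70, np.zeros(3))
        for i in range(5)
    ]
    ragged = list(small_cohort) + [SubjectSession("bad", 100.0, 70.0, bad_seq)]
    with pytest.raises(ValueError, match="ragged"):
        to_matrices(ragged)


def test_simulation_is_bit_reproducible():
    cfg = CohortConfig(n_subjects=6, seed=123)
    a = to_matrices(simulate_cohort(cfg))
    b = to_matrices(simulate_cohort(cfg))
    assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


def test_population_mean_matches_config():
    cfg = CohortConfig(n_subjects=1200, seed=77)
    cohort = simulate_cohort(cfg)
    sbp = np.array([s.true_sbp for s in cohort])
    dbp = np.array([s.true_dbp for s in cohort])
    assert abs(sbp.mean() - cfg.sbp_mean) < 3 * cfg.sbp_sd / np.sqrt(len(sbp))
    assert abs(dbp.mean() - cfg.dbp_mean) < 3 * cfg.dbp_sd / np.sqrt(len(dbp))


def test_csv_round_trip(tmp_path, small_cohort):
    path = tmp_path / "cohort.csv"
    write_cohort_csv(small_cohort, path)
    back = read_cohort_csv(path)
    V0, T0 = to_matrices(small_cohort)
    V1, T1 = to_matrices(back)
    assert np.allclose(V0, V1) and np.allclose(T0, T1)
    assert [s.subject_id for s in back] == [s.subject_id for s in small_cohort]


@pytest.mark.parametrize(
    "kwargs",
    [dict(n_subjects=1), dict(within_subject_sd=-1.0), dict(observer_sd=-0.1),
     dict(feature_noise_sd=-2.0)],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ValueError):
        CohortConfig(**kwargs)


def test_subject_session_requires_five_sequences():
    seqs = [
        MeasurementSequence(i + 1, 100, 100, 70, 70, 100, 70, np.zeros(3))
        for i in range(4)
    ]
    with pytest.raises(ValueError, match="5 sequences"):
        SubjectSession("x", 100.0, 70.0, seqs)
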