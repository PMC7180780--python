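"""Lilliefors normality test and moment summaries.

The Lilliefors test is a Kolmogorov-Smirnov-type test of composite normality:
the test statistic k is the sup-distance between the empirical CDF and the
normal CDF with mean and standard deviation estimated from the same sample.
Because the parameters are estimated, the plain KS critical values do not
apply; critical values here come from a Monte-Carlo table frozen into the
package (1e5 null replicates per sample size, fixed seed, interpolated in
1/sqrt(n)), which agrees with the large-sample approximation 0.886/sqrt(n) at
alpha = 0.05.  The null is rejected (h = 1) iff k exceeds the critical value.

P-values are simulated from the null on demand; following the usual reporting
convention for this test, p is capped at 0.5 — beyond that the statistic is so
deep inside the null that the exact tail probability carries no information.

Moment summaries report Pearson (non-excess) kurtosis, reference value 3 for a
Gaussian, and ordinary skewness, reference value 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import stats as sps
from scipy.stats import norm

_TABLE = None


def _cv_table() -> dict:
    global _TABLE
    if _TABLE is None:
        with resources.files("ebrm.data").joinpath("lilliefors_cv.json").open() as f:
            _TABLE = json.load(f)
    return _TABLE


@dataclass
class NormalityResult:
    h: int
    p: float
    k: float
    cv: float
    kurtosis: float
    skewness: float
    n: int
    alpha: float


def lilliefors_statistic(x) -> float:
    """Sup |ECDF - Phi((x - xbar)/s)| with mean and sd (ddof=1) from the sample."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    s = x.std(ddof=1)
    if s == 0:
        raise ValueError("zero-variance sample")
    z = np.sort((x - x.mean()) / s)
    u = norm.cdf(z)
    i = np.arange(1, n + 1)
    dplus = np.max(i / n - u)
    dminus = np.max(u - (i - 1) / n)
    return float(max(dplus, dminus))


def lilliefors_critical_value(n: int, alpha: float = 0.05) -> float:
    """Critical value from the frozen Monte-Carlo table.

    Interpolation is linear in cv*sqrt(n) against 1/sqrt(n) between tabulated
    sample sizes, and linear across the tabulated alpha levels; beyond the
    table the asymptotic cv*sqrt(n) of the largest tabulated n is carried over
    (for alpha = 0.05 this tracks 0.886/sqrt(n)).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    tab = _cv_table()
    alphas = np.array(tab["alphas"], dtype=float)  # descending: 0.20 .. 0.01
    if not (alphas.min() <= alpha <= alphas.max()):
        raise ValueError(f"alpha must lie within the tabulated range {alphas.min()}-{alphas.max()}")
    ngrid = np.array(tab["n_grid"], dtype=int)

    def cv_at(alpha_col: float, n_val: int) -> float:
        col = np.array([tab["cv"][str(m)][f"{alpha_col:g}"] for m in ngrid])
        scaled = col * np.sqrt(ngrid)  # nearly constant in n
        inv = 1.0 / np.sqrt(ngrid)
        x = 1.0 / np.sqrt(n_val)
        if n_val >= ngrid[-1]:
            return scaled[-1] / np.sqrt(n_val)
        # ngrid ascending -> inv descending; interpolate on reversed axis
        val = np.interp(x, inv[::-1], scaled[::-1])
        return float(val / np.sqrt(n_val))

    order = np.argsort(alphas)
    lo, hi = alphas[order[0]], alphas[order[-1]]
    if alpha in alphas:
        return cv_at(float(alpha), n)
    a_sorted = alphas[order]
    vals = np.array([cv_at(float(a), n) for a in a_sorted])
    return float(np.interp(alpha, a_sorted, vals))


def _null_statistics(n: int, n_sim: int, rng: np.random.Generator) -> np.ndarray:
    z = rng.standard_normal((n_sim, n))
    z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, ddof=1, keepdims=True)
    u = norm.cdf(np.sort(z, axis=1))
    i = np.arange(1, n + 1)
    return np.maximum((i / n - u).max(axis=1), (u - (i - 1) / n).max(axis=1))


def lilliefors(
    x,
    alpha: float = 0.05,
    n_sim: int = 10_000,
    seed=None,
) -> NormalityResult:
    """Run the Lilliefors test at level ``alpha``.

    ``n_sim`` null replicates (simulated at the sample's n) give the p-value,
    capped at 0.5.  The h decision uses the frozen critical-value table, not
    the simulated p, so it is deterministic regardless of ``seed``.
    """
    x = np.asarray(x, dtype=float)
    k = lilliefors_statistic(x)
    n = x.size
    cv = lilliefors_critical_value(n, alpha)
    rng = np.random.default_rng(seed)
    null = _null_statistics(n, n_sim, rng)
    p = float(np.mean(null >= k))
    p = min(p, 0.5)
    kurt, skew = excess_moments(x)
    return NormalityResult(
        h=int(k > cv), p=p, k=k, cv=cv, kurtosis=kurt, skewness=skew, n=n, alpha=alpha
    )


def excess_moments(x) -> tuple[float, float]:
    """(Pearson kurtosis, skewness): 4th and 3rd standardized moments.

    Kurtosis is reported non-excess (Gaussian reference 3).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if x.std() == 0:
        raise ValueError("zero-variance sample")
    return float(sps.kurtosis(x, fisher=False)), float(sps.skew(x))
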