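"""Per-subject confidence intervals from a handful of repeated BP estimates.

Two routes to a 95 % interval for the subject's mean pressure:

* Parametric bootstrap: fit (mean, sd) to the n estimates, fill an n x B
  matrix with Gaussian draws mean + sd*Z, average each column into B replicate
  means, sort them ascending and read off the alpha and 1-alpha percentiles.
  A nonparametric variant (resampling the estimates themselves) is available
  behind a flag.
* Closed-form CLT interval ("Monte-Carlo" method): mean ± z_{1-alpha} * s /
  sqrt(n) with s the sample standard deviation (n-1 divisor) and z the
  standard-normal quantile (1.96 at the 0.975 level).

With n = 5 repeats both are optimistic relative to a t-interval; that is a
property of the methods as defined, not corrected for here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm


@dataclass
class ConfidenceInterval:
    target: str
    level: float
    lower: float
    upper: float
    method: str

    def __post_init__(self) -> None:
        if not (0 < self.level < 1):
            raise ValueError("level must be in (0, 1)")
        if self.lower > self.upper:
            raise ValueError("lower must not exceed upper")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def percentile(sorted_values, q: float) -> float:
    """Order-statistic percentile on pre-sorted values.

    Index rule: linear interpolation between the closest order statistics,
    i.e. index q*(n-1) on the 0-based sorted array (numpy's "linear" rule).
    Fixed so that interval endpoints are bit-stable across platforms.
    """
    v = np.asarray(sorted_values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    if not (0 <= q <= 1):
        raise ValueError("q must be in [0, 1]")
    pos = q * (v.size - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


def bootstrap_ci(
    estimates,
    B: int = 100,
    alpha: float = 0.025,
    seed=None,
    target: str = "BP",
    parametric: bool = True,
) -> ConfidenceInterval:
    """Bootstrap percentile interval at level 1 - 2*alpha for the subject mean.

    Parametric (default): B columns of n Gaussian draws around the fitted
    (mean, sd); the column means are the bootstrap replicates.  Nonparametric:
    column b resamples the n estimates with replacement instead.

    Zero-variance input yields the degenerate interval [mean, mean].
    """
    est = np.asarray(estimates, dtype=float)
    n = est.size
    if n < 2:
        raise ValueError("need at least 2 estimates")
    if B < 20:
        raise ValueError("need at least 20 bootstrap replicates")
    if not (0 < alpha < 0.5):
        raise ValueError("alpha must be in (0, 0.5)")
    mu = float(est.mean())
    sigma = float(est.std(ddof=1))
    rng = np.random.default_rng(seed)
    if parametric:
        draws = mu + sigma * rng.standard_normal((n, B))
    else:
        draws = est[rng.integers(0, n, size=(n, B))]
    means = np.sort(draws.mean(axis=0))
    return ConfidenceInterval(
        target=target,
        level=1 - 2 * alpha,
        lower=percentile(means, alpha),
        upper=percentile(means, 1 - alpha),
        method="bootstrap" if parametric else "bootstrap_nonparametric",
    )


def monte_carlo_ci(
    estimates, alpha: float = 0.025, target: str = "BP"
) -> ConfidenceInterval:
    """CLT interval mean ± z_{1-alpha} * s/sqrt(n), s with the n-1 divisor."""
    est = np.asarray(estimates, dtype=float)
    n = est.size
    if n < 2:
        raise ValueError("need at least 2 estimates")
    if not (0 < alpha < 0.5):
        raise ValueError("alpha must be in (0, 0.5)")
    mu = float(est.mean())
    s = float(est.std(ddof=1))
    half = norm.ppf(1 - alpha) * s / np.sqrt(n)
    return ConfidenceInterval(
        target=target,
        level=1 - 2 * alpha,
        lower=mu - half,
        upper=mu + half,
        method="monte_carlo",
    )
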