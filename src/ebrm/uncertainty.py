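"""GUM-style measurement uncertainty: standard, combined, expanded.

Following the Guide to the Expression of Uncertainty in Measurement, the
standard uncertainty of a mean of n repeats is u = sd/sqrt(n) (Type A); the
combined uncertainty adds the random component, the bias (systematic) and —
for device-level pressure reports — the maximum permissible error of the
reference sphygmomanometer (±1 mmHg) in quadrature; the expanded uncertainty
U = K_cov * uc, with coverage factor K_cov = 2 for a ~95 % interval
x̄ ± U.

Two report flavours exist:

* feature-level (two components, bias + bootstrap SE of the mean) for the
  artificial features, and
* device-level (three components, including the permissible error) for
  repeated blood-pressure estimates of one subject against the reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .bootstrap import ArtificialFeatureSet

DEFAULT_COVERAGE_FACTOR = 2.0
DEFAULT_MAX_PERMISSIBLE_ERROR = 1.0  # mmHg, mercury-sphygmomanometer reference


@dataclass
class UncertaintyReport:
    quantity: str
    n: int
    mean: float
    sd: float
    u_alpha: float  # standard uncertainty (random, Type A)
    u_beta: float  # bias (systematic)
    u_gamma: float  # maximum permissible error (0 when excluded)
    uc: float  # combined
    coverage_factor: float
    U: float  # expanded

    @property
    def interval(self) -> tuple[float, float]:
        return (self.mean - self.U, self.mean + self.U)


def standard_uncertainty(sd: float, n: int) -> float:
    """Type A standard uncertainty of a mean: sd / sqrt(n)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    return sd / math.sqrt(n)


def combined_uncertainty(
    u_alpha: float, u_beta: float, u_gamma: float | None = None
) -> float:
    """Root-sum-of-squares of the components; u_gamma=None drops the MPE term."""
    comps = [u_alpha, u_beta] + ([] if u_gamma is None else [u_gamma])
    if not all(np.isfinite(comps)):
        raise ValueError("uncertainty components must be finite")
    return float(math.sqrt(sum(c * c for c in comps)))


def expanded_uncertainty(uc: float, coverage_factor: float = DEFAULT_COVERAGE_FACTOR) -> float:
    """U = K_cov * uc; K_cov = 2 corresponds to ~95 % coverage for a Gaussian."""
    if uc < 0:
        raise ValueError("uc must be non-negative")
    if coverage_factor <= 0:
        raise ValueError("coverage_factor must be positive")
    return coverage_factor * uc


def feature_uncertainty_report(
    fs: ArtificialFeatureSet, coverage_factor: float = DEFAULT_COVERAGE_FACTOR
) -> UncertaintyReport:
    """Two-component report for an artificial feature.

    The random component is the standard uncertainty of the overall bootstrap
    mean, boot_se / sqrt(B); the systematic component is the bootstrap bias.
    The maximum-permissible-error term does not apply at feature level.
    """
    u_a = standard_uncertainty(fs.boot_se, fs.B)
    uc = combined_uncertainty(u_a, fs.bias)
    return UncertaintyReport(
        quantity=fs.source_name,
        n=fs.B,
        mean=fs.overall_mean,
        sd=fs.boot_se,
        u_alpha=u_a,
        u_beta=fs.bias,
        u_gamma=0.0,
        uc=uc,
        coverage_factor=coverage_factor,
        U=expanded_uncertainty(uc, coverage_factor),
    )


def bp_uncertainty_report(
    estimates,
    reference: float,
    mpe: float = DEFAULT_MAX_PERMISSIBLE_ERROR,
    coverage_factor: float = DEFAULT_COVERAGE_FACTOR,
    quantity: str = "BP",
) -> UncertaintyReport:
    """Three-component report for repeated BP estimates of one subject.

    u_alpha from the spread of the repeats, u_beta = mean(estimates) -
    reference, u_gamma = mpe (the reference device's maximum permissible
    error, ±1 mmHg by default).
    """
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("need at least 2 repeated estimates")
    sd = float(est.std(ddof=1))
    u_a = standard_uncertainty(sd, est.size)
    u_b = float(est.mean() - reference)
    uc = combined_uncertainty(u_a, u_b, mpe)
    return UncertaintyReport(
        quantity=quantity,
        n=int(est.size),
        mean=float(est.mean()),
        sd=sd,
        u_alpha=u_a,
        u_beta=u_b,
        u_gamma=mpe,
        uc=uc,
        coverage_factor=coverage_factor,
        U=expanded_uncertainty(uc, coverage_factor),
    )
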