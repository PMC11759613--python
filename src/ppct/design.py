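"""Trial design: power, required sample size and arm allocation.

All calculators work on the sqrt(N)-scaled asymptotic variance V of an
ATE estimator (see :func:`ppct.estimators.variance_asymptotic`): the
finite-sample variance of the estimate is approximately V / N, so a
variance reduction translates one-for-one into a sample-size reduction
at equal power.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignResult",
    "required_sample_size",
    "power",
    "optimal_allocation_reference",
    "optimal_allocation_ppi",
    "control_arm_reduction",
    "control_arm_ratio_table",
    "variance_ratio_rule",
]


@dataclass(frozen=True)
class DesignResult:
    """Bundle of design outputs for one estimator/scenario."""

    alpha: float
    power_target: float
    delta_h: float
    v_asym: float
    n_total: int
    n_control: int | None = None
    n_treated: int | None = None
    notes: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "power_target": self.power_target,
            "delta_h": self.delta_h,
            "v_asym": self.v_asym,
            "n_total": self.n_total,
            "n_control": self.n_control,
            "n_treated": self.n_treated,
            "notes": list(self.notes),
        }


def required_sample_size(
    v_asym: float,
    delta_h: float,
    alpha: float = 0.05,
    power: float = 0.8,
) -> int:
    """Minimum N for a two-sided level-alpha test to reach the target power.

    N = ceil( V * (z_{1-alpha/2} + z_{power})^2 / delta_h^2 )

    under the normal approximation, for a hypothesized effect ``delta_h``.
    Rounded up: the returned N always meets or exceeds the target.
    """
    if v_asym <= 0:
        raise ValueError("v_asym must be positive")
    if delta_h == 0:
        raise ValueError("delta_h = 0: no sample size is large enough")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    q = stats.norm.ppf(1.0 - alpha / 2.0) + stats.norm.ppf(power)
    return int(math.ceil(v_asym * q**2 / delta_h**2))


def power(
    v_asym: float,
    n_total: int,
    delta_h: float,
    alpha: float = 0.05,
) -> float:
    """Exact two-sided normal power at total sample size ``n_total``.

    Phi(-z_{alpha/2} + |delta_h| sqrt(N/V)) + Phi(-z_{alpha/2} - |delta_h| sqrt(N/V));
    the second term (rejection on the wrong side) is negligible except at
    tiny effects, where it makes the power tend to alpha as delta_h -> 0.
    """
    if v_asym <= 0 or n_total <= 0:
        raise ValueError("v_asym and n_total must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    shift = abs(delta_h) * math.sqrt(n_total / v_asym)
    return float(stats.norm.cdf(-z + shift) + stats.norm.cdf(-z - shift))


def _best_integer_split(n_total: int, a_c: float, a_t: float) -> int:
    """Integer control count minimizing a_c/n + a_t/(N-n).

    The objective is convex in n, so the integer optimum brackets the
    continuous one; both neighbors are evaluated and ties go to the
    larger control group.
    """
    x = n_total / (1.0 + math.sqrt(a_t / a_c))
    lo = max(1, min(n_total - 1, math.floor(x)))
    hi = max(1, min(n_total - 1, math.ceil(x)))

    def v(n: int) -> float:
        return a_c / n + a_t / (n_total - n)

    if v(hi) < v(lo):
        return hi
    return max(lo, hi) if v(lo) == v(hi) else lo


def optimal_allocation_reference(
    sigma_c: float, sigma_t: float, n_total: int
) -> tuple[int, int]:
    """Variance-minimizing split for the difference-of-means estimator.

    Continuous optimum n_control = N * sigma_c / (sigma_c + sigma_t)
    (allocate proportionally to the arm SDs), achieving variance
    (sigma_c + sigma_t)^2 / N.  Returns (n_control, n_treated) as the
    best integer split.
    """
    if sigma_c <= 0 or sigma_t <= 0:
        raise ValueError("arm SDs must be positive")
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    n_c = _best_integer_split(n_total, sigma_c**2, sigma_t**2)
    return n_c, n_total - n_c


def optimal_allocation_ppi(
    sigma_c: float,
    sigma_t: float,
    sigma_f: float,
    rho_c: float,
    rho_t: float,
    lam: float,
    n_total: int,
) -> tuple[int, int]:
    """Variance-minimizing split for the lambda-weighted estimator.

    With per-arm variance contributions
    A_a = sigma_a^2 + lam^2 sigma_f^2 - 2 lam sigma_f sigma_a rho_a,
    the continuous optimum is n_control = N / (1 + sqrt(A_t / A_c)).
    A better-correlated control arm (rho_c > rho_t) shrinks A_c and hence
    the control group.  At lam = 0 this reduces to
    :func:`optimal_allocation_reference`.  A non-positive A (perfect
    prediction in one arm) returns the boundary split with a warning.
    """
    if sigma_c <= 0 or sigma_t <= 0 or sigma_f < 0:
        raise ValueError("SDs must be positive")
    if n_total < 2:
        raise ValueError("n_total must be >= 2")
    a_c = sigma_c**2 + lam**2 * sigma_f**2 - 2 * lam * sigma_f * sigma_c * rho_c
    a_t = sigma_t**2 + lam**2 * sigma_f**2 - 2 * lam * sigma_f * sigma_t * rho_t
    if a_c <= 0 or a_t <= 0:
        warnings.warn(
            "perfect prediction in one arm: returning boundary allocation",
            UserWarning,
            stacklevel=2,
        )
        return (1, n_total - 1) if a_c <= 0 else (n_total - 1, 1)
    n_c = _best_integer_split(n_total, a_c, a_t)
    return n_c, n_total - n_c


def control_arm_reduction(rho_c: float, m: int) -> int:
    """Reduced control-arm size with the same power as a balanced design.

    Keeping m treated subjects, n* = ceil(m * sqrt(1 - rho_c^2)) controls
    analyzed with the variance-minimizing weighted estimator give at
    least the power of the balanced m/m design analyzed with the
    difference of means.  A negative correlation is equivalent to a
    positive one after flipping the sign of the prognostic score, so
    |rho_c| is used (with a warning).
    """
    if abs(rho_c) > 1:
        raise ValueError("rho_c must lie in [-1, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    if rho_c < 0:
        warnings.warn(
            "negative rho_c: using |rho_c| (equivalent to predictor sign flip)",
            UserWarning,
            stacklevel=2,
        )
        rho_c = -rho_c
    return int(math.ceil(m * math.sqrt(1.0 - rho_c**2)))


def control_arm_ratio_table(rho_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Ratio n*/m = sqrt(1 - rho_c^2) on a grid of correlations.

    Defaults to rho_c in {0.0, 0.1, ..., 1.0}; ratios rounded to 2
    decimals, the usual design-table view.
    """
    if rho_grid is None:
        rho_grid = np.round(np.arange(0.0, 1.05, 0.1), 1)
    rho_grid = np.asarray(rho_grid, dtype=float)
    ratio = np.sqrt(1.0 - rho_grid**2)
    return pd.DataFrame(
        {"rho_c": rho_grid, "ratio": np.round(ratio, 2)}
    )


def variance_ratio_rule(rho: float) -> float:
    """Relative variance (and sample size) of the weight-optimized estimator.

    Under sigma_c = sigma_t, rho_c = rho_t = rho and balanced arms, the
    optimally weighted estimator has variance (1 - rho^2) times the
    reference variance — rho^2 is the out-of-sample R^2 of the prognostic
    score, and the required sample size shrinks by the same factor.
    """
    if abs(rho) > 1:
        raise ValueError("rho must lie in [-1, 1]")
    return 1.0 - rho**2
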