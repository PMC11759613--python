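"""Hypothesis tests and confidence intervals for an ATE estimate.

Two routes to a p-value: the normal approximation (the estimators are
asymptotically normal, so the standardized estimate is compared with
normal quantiles) and a randomization test that permutes the arm labels,
which is valid for every estimator without distributional assumptions —
useful when arm sizes are too small to trust the CLT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .estimators import (
    AteEstimate,
    TrialData,
    estimate,
)

__all__ = ["TestResult", "z_test", "permutation_test"]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a significance test on the ATE."""

    method: str
    statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    alpha: float
    reject: bool
    sides: str = "two"
    n_permutations: int | None = None
    warnings: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "alpha": self.alpha,
            "reject": self.reject,
            "sides": self.sides,
            "n_permutations": self.n_permutations,
            "warnings": list(self.warnings),
        }


def z_test(est: AteEstimate, alpha: float = 0.05, sides: str = "two") -> TestResult:
    """Normal-approximation test of H0: ATE = 0.

    Two-sided: reject when |ate| exceeds the (1 - alpha/2) normal
    quantile times the standard error; the confidence interval is
    ``ate +/- z_{1-alpha/2} * se`` so rejection and the CI excluding 0
    agree exactly.  One-sided tests H0: ATE <= 0 against ATE > 0.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if sides not in ("two", "one"):
        raise ValueError("sides must be 'two' or 'one'")
    if est.variance == 0.0:
        # degenerate: the estimator claims to know the ATE exactly
        p = 0.0 if est.ate != 0.0 else 1.0
        return TestResult(
            method=est.method,
            statistic=np.inf if est.ate > 0 else (-np.inf if est.ate < 0 else 0.0),
            p_value=p,
            ci_low=est.ate,
            ci_high=est.ate,
            alpha=alpha,
            reject=p < alpha,
            sides=sides,
            warnings=est.warnings + ("zero_variance",),
        )
    z = est.ate / est.se
    if sides == "two":
        p = 2.0 * stats.norm.sf(abs(z))
        q = stats.norm.ppf(1.0 - alpha / 2.0)
        ci_low, ci_high = est.ate - q * est.se, est.ate + q * est.se
    else:
        p = float(stats.norm.sf(z))
        q = stats.norm.ppf(1.0 - alpha)
        ci_low, ci_high = est.ate - q * est.se, np.inf
    return TestResult(
        method=est.method,
        statistic=float(z),
        p_value=float(p),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        alpha=alpha,
        reject=bool(p < alpha),
        sides=sides,
        warnings=est.warnings,
    )


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


def _fast_point(y: np.ndarray, f: np.ndarray, tr: np.ndarray, method: str,
                lam: float | None) -> float:
    """Point estimate on raw arrays, re-estimating lambda when data-driven.

    Used inside the permutation loop, where constructing a full
    :class:`TrialData` per draw would dominate the runtime.  The ANCOVA
    point estimate uses its two-arm closed form (per-arm OLS slopes),
    which is algebraically identical to the regression coefficient.
    """
    co = ~tr
    yt, yc = y[tr], y[co]
    if method == "reference":
        return float(yt.mean() - yc.mean())
    ft, fc = f[tr], f[co]
    if method == "ppi":
        lam = 1.0
    elif method == "ppi_lambda":
        if lam is None:
            raise ValueError("ppi_lambda requires lam")
    elif lam is None:
        m, n = len(yt), len(yc)
        sd_t, sd_c = yt.std(ddof=1), yc.std(ddof=1)
        sd_ft, sd_fc = ft.std(ddof=1), fc.std(ddof=1)
        cov_t = float(np.cov(yt, ft, ddof=1)[0, 1]) if m > 1 else 0.0
        cov_c = float(np.cov(yc, fc, ddof=1)[0, 1]) if n > 1 else 0.0
        if method == "ancova":
            lam_t = cov_t / sd_ft**2 if sd_ft > 0 else 0.0
            lam_c = cov_c / sd_fc**2 if sd_fc > 0 else 0.0
            return float(
                (yt.mean() - lam_t * ft.mean()) - (yc.mean() - lam_c * fc.mean())
            )
        sd_all = f.std(ddof=1)
        if sd_all == 0.0:
            lam = 0.0
        elif method == "ppct":
            rho_t = cov_t / (sd_t * sd_ft) if sd_t > 0 and sd_ft > 0 else 0.0
            rho_c = cov_c / (sd_c * sd_fc) if sd_c > 0 and sd_fc > 0 else 0.0
            lam = (n * sd_t * rho_t + m * sd_c * rho_c) / ((m + n) * sd_all)
        elif method == "ppct2":
            cov_pooled = ((m - 1) * cov_t + (n - 1) * cov_c) / (m + n - 2)
            lam = cov_pooled / sd_all**2
        else:
            raise ValueError(f"unknown method {method!r}")
    z = y - lam * f
    return float(z[tr].mean() - z[co].mean())


def permutation_test(
    data: TrialData,
    method: str = "reference",
    B: int = 10000,
    seed: int | None = None,
    sides: str = "two",
    alpha: float = 0.05,
    lam: float | None = None,
    freeze_lambda: bool = False,
) -> TestResult:
    """Randomization test: re-estimate the ATE on permuted arm labels.

    The null distribution is the chosen estimator recomputed on ``B``
    uniformly random permutations of the arm labels; by default any
    data-driven weight (ppct / ppct2 / the ANCOVA slopes) is re-estimated
    inside each permutation so the whole analysis procedure is permuted.
    ``freeze_lambda=True`` estimates the weight once on the observed
    labels and holds it fixed, a faster approximation.

    p = (1 + #{|ATE_b| >= |ATE_obs|}) / (B + 1), so p >= 1/(B+1) and the
    test is valid at any finite B.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    if sides not in ("two", "one"):
        raise ValueError("sides must be 'two' or 'one'")
    rng = np.random.default_rng(seed)
    y, f = data.y, data.f
    tr_obs = data.treated

    frozen: float | None = lam
    if freeze_lambda and method in ("ppct", "ppct2") and frozen is None:
        frozen = estimate(data, method).lam
        method_inner = "ppi_lambda"
    else:
        method_inner = method

    obs = _fast_point(y, f, tr_obs, method_inner, frozen)

    null = np.empty(B)
    failures = 0
    max_failures = max(1, B // 10)
    b = 0
    while b < B:
        perm_tr = np.zeros(data.N, dtype=bool)
        perm_tr[rng.permutation(data.N)[: data.m]] = True
        try:
            null[b] = _fast_point(y, f, perm_tr, method_inner, frozen)
        except (ValueError, np.linalg.LinAlgError, ZeroDivisionError):
            failures += 1
            if failures > max_failures:
                raise RuntimeError(
                    f"more than 10% of permutations failed ({failures}); "
                    "the estimator is unstable on this dataset"
                )
            continue
        b += 1

    if sides == "two":
        p = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (B + 1.0)
    else:
        p = (1.0 + np.sum(null >= obs)) / (B + 1.0)

    flags: tuple[str, ...] = ()
    if failures:
        flags = (f"permutation_failures:{failures}",)
    return TestResult(
        method=method,
        statistic=float(obs),
        p_value=float(p),
        ci_low=float("nan"),
        ci_high=float("nan"),
        alpha=alpha,
        reject=bool(p < alpha),
        sides=sides,
        n_permutations=B,
        warnings=flags,
    )
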