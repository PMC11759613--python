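"""Point estimators of the average treatment effect (ATE) and their variances.

A two-arm randomized trial is summarized per subject by an outcome ``y``,
a binary arm indicator ``t`` (1 = treated, 0 = control) and a scalar
prognostic score ``f`` — a baseline-only prediction of the untreated
outcome produced by any external black-box model.  The estimand is

    ATE = E[Y | T=1] - E[Y | T=0].

Five estimators are provided:

``reference``
    Difference of arm means.
``ppi``
    Prediction-powered estimator: difference of arm means of the
    prediction residual ``y - f``; the control-arm term is the
    *rectifier* that debiases the predictions.
``ppi_lambda``
    Weighted interpolation ``(1 - lam) * reference + lam * ppi`` for a
    user-chosen weight ``lam``.
``ppct`` / ``ppct2``
    ``ppi_lambda`` evaluated at a variance-minimizing weight estimated
    from the trial itself — either the per-arm plug-in ``lambda_star``
    (ppct) or the pooled-covariance ratio assuming a constant treatment
    effect (ppct2).
``ancova``
    OLS of ``y`` on ``(1, t, f, t*f)`` with a heteroskedasticity-robust
    (sandwich) variance; the coefficient of ``t`` estimates the ATE.

All empirical standard deviations and covariances use ``ddof=1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "TrialData",
    "ArmMoments",
    "AteEstimate",
    "RegressionFit",
    "TrialDataError",
    "DegeneratePredictorError",
    "SingularDesignError",
    "METHODS",
    "compute_moments",
    "ate_reference",
    "ate_ppi",
    "ate_ppi_lambda",
    "lambda_star_plugin",
    "lambda_pooled",
    "ate_ppct",
    "ate_ancova",
    "variance_asymptotic",
    "estimate",
]

METHODS = ("reference", "ppi", "ppi_lambda", "ppct", "ppct2", "ancova")

# warning tags carried on AteEstimate.warnings
WARN_DEGENERATE_PREDICTOR = "degenerate_predictor"
WARN_DEGENERATE_CORRELATION = "degenerate_correlation"
WARN_VARIANCE_CLIPPED = "variance_clipped"
WARN_SMALL_ARM_SANDWICH = "small_arm_sandwich"


class TrialDataError(ValueError):
    """Invalid trial data (sizes, arm indicator, missing values)."""


class DegeneratePredictorError(ValueError):
    """The prognostic score has zero variance; a data-driven lambda is undefined."""


class SingularDesignError(ValueError):
    """The ANCOVA design matrix (1, T, f, T*f) is rank deficient."""


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialData:
    """Per-subject outcome, arm indicator and prognostic score.

    Parameters
    ----------
    y : array-like of float
        Trial outcome, one value per subject.
    t : array-like of {0, 1}
        Arm indicator (1 = treated, 0 = control).
    f : array-like of float
        Scalar prognostic score, same units as ``y``.

    Missing values are rejected: imputation is an analysis decision the
    estimators refuse to make silently.
    """

    y: np.ndarray
    t: np.ndarray
    f: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        t = np.asarray(self.t)
        f = np.asarray(self.f, dtype=float)
        if not (y.ndim == t.ndim == f.ndim == 1):
            raise TrialDataError("y, t, f must be one-dimensional")
        if not (len(y) == len(t) == len(f)):
            raise TrialDataError(
                f"length mismatch: y={len(y)}, t={len(t)}, f={len(f)}"
            )
        if len(y) < 4:
            raise TrialDataError(f"need at least 4 subjects, got {len(y)}")
        if np.isnan(y).any() or np.isnan(f).any():
            raise TrialDataError("missing values in y or f are not supported")
        bad = ~np.isin(t, (0, 1))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            val = t[i].item() if hasattr(t[i], "item") else t[i]
            raise TrialDataError(
                f"t must contain only 0/1; found {val} at row {i}"
            )
        t = t.astype(np.int8)
        m = int(t.sum())
        n = len(t) - m
        if m < 2 or n < 2:
            raise TrialDataError(
                f"each arm needs >= 2 subjects, got m={m} treated, n={n} controls"
            )
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "f", f)

    @property
    def m(self) -> int:
        """Number of treated subjects."""
        return int(self.t.sum())

    @property
    def n(self) -> int:
        """Number of controls."""
        return len(self.t) - self.m

    @property
    def N(self) -> int:
        return len(self.t)

    @property
    def treated(self) -> np.ndarray:
        return self.t == 1

    @property
    def controls(self) -> np.ndarray:
        return self.t == 0


@dataclass(frozen=True)
class ArmMoments:
    """Empirical per-arm moments; every plug-in symbol lives here.

    Suffix ``_t`` / ``_c`` denote treated / control arm; ``sd_f`` is the
    standard deviation of the prognostic score over *all* N subjects
    pooled, while ``sd_ft`` / ``sd_fc`` are its per-arm versions (used by
    the closed-form ANCOVA slopes).  ``pi_t = m/N`` and ``pi_c = n/N``
    are the empirical arm fractions.
    """

    m: int
    n: int
    mean_t: float
    mean_c: float
    mean_ft: float
    mean_fc: float
    sd_t: float
    sd_c: float
    sd_f: float
    sd_ft: float
    sd_fc: float
    rho_t: float
    rho_c: float
    cov_pooled: float
    warnings: tuple[str, ...] = ()

    @property
    def N(self) -> int:
        return self.m + self.n

    @property
    def pi_t(self) -> float:
        return self.m / self.N

    @property
    def pi_c(self) -> float:
        return self.n / self.N


@dataclass(frozen=True)
class AteEstimate:
    """A point estimate of the ATE with its finite-sample variance.

    ``lam`` is the prediction weight actually used; it is ``None`` for
    methods without a free weight (reference, ppi, ancova — ppi is the
    fixed weight 1 by convention).  ``variance`` is the plug-in estimate
    of the variance of the *estimator* (squared outcome units); negative
    plug-in values are clipped to zero and flagged.
    """

    method: str
    ate: float
    variance: float
    m: int
    n: int
    lam: float | None = None
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def se(self) -> float:
        return float(np.sqrt(self.variance))

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "ate": self.ate,
            "lambda": self.lam,
            "variance": self.variance,
            "se": self.se,
            "m": self.m,
            "n": self.n,
            "warnings": list(self.warnings),
        }


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of y on the columns (1, T, f, T*f)."""

    coefficients: np.ndarray
    cov: np.ndarray
    residuals: np.ndarray = field(repr=False)
    centered: bool = False


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------


def _corr(x: np.ndarray, y: np.ndarray, ddof: int) -> tuple[float, bool]:
    """Pearson correlation; (0, degenerate-flag) if either SD is zero."""
    sx = x.std(ddof=ddof)
    sy = y.std(ddof=ddof)
    if sx == 0.0 or sy == 0.0:
        return 0.0, True
    cov = float(np.cov(x, y, ddof=ddof)[0, 1])
    return cov / (sx * sy), False


def compute_moments(data: TrialData, ddof: int = 1) -> ArmMoments:
    """Empirical means, SDs and outcome-score correlations per arm.

    ``cov_pooled`` is the within-arm covariance of ``y`` and ``f`` pooled
    over both arms with an N-2 denominator (two arm means estimated),
    the numerator of the constant-treatment-effect weight of
    :func:`lambda_pooled`.
    """
    tr, co = data.treated, data.controls
    y_t, y_c = data.y[tr], data.y[co]
    f_t, f_c = data.f[tr], data.f[co]
    m, n = data.m, data.n

    rho_t, deg_t = _corr(y_t, f_t, ddof)
    rho_c, deg_c = _corr(y_c, f_c, ddof)
    cov_t = float(np.cov(y_t, f_t, ddof=1)[0, 1])
    cov_c = float(np.cov(y_c, f_c, ddof=1)[0, 1])
    cov_pooled = ((m - 1) * cov_t + (n - 1) * cov_c) / (m + n - 2)

    flags: tuple[str, ...] = ()
    if deg_t or deg_c or data.f.std(ddof=ddof) == 0.0:
        flags = (WARN_DEGENERATE_CORRELATION,)

    return ArmMoments(
        m=m,
        n=n,
        mean_t=float(y_t.mean()),
        mean_c=float(y_c.mean()),
        mean_ft=float(f_t.mean()),
        mean_fc=float(f_c.mean()),
        sd_t=float(y_t.std(ddof=ddof)),
        sd_c=float(y_c.std(ddof=ddof)),
        sd_f=float(data.f.std(ddof=ddof)),
        sd_ft=float(f_t.std(ddof=ddof)),
        sd_fc=float(f_c.std(ddof=ddof)),
        rho_t=rho_t,
        rho_c=rho_c,
        cov_pooled=cov_pooled,
        warnings=flags,
    )


# ---------------------------------------------------------------------------
# the lambda family: reference (lam=0), ppi (lam=1), ppi_lambda, ppct, ppct2
# ---------------------------------------------------------------------------


def _lambda_family_variance(mom: ArmMoments, lam: float) -> tuple[float, bool]:
    """Finite-sample plug-in variance of the lam-weighted estimator.

    (sd_t^2 + lam^2 sd_f^2 - 2 lam sd_f sd_t rho_t)/m
      + (sd_c^2 + lam^2 sd_f^2 - 2 lam sd_f sd_c rho_c)/n

    with sd_f pooled over all N.  Because rho uses the per-arm SD of f in
    its denominator while the cross term uses the pooled sd_f, the value
    can be negative on pathological data; it is then clipped to 0 and the
    second return value is True.
    """
    a_t = mom.sd_t**2 + lam**2 * mom.sd_f**2 - 2 * lam * mom.sd_f * mom.sd_t * mom.rho_t
    a_c = mom.sd_c**2 + lam**2 * mom.sd_f**2 - 2 * lam * mom.sd_f * mom.sd_c * mom.rho_c
    v = a_t / mom.m + a_c / mom.n
    if v < 0.0:
        return 0.0, True
    return float(v), False


def _lambda_family_point(data: TrialData, lam: float) -> float:
    z = data.y - lam * data.f
    return float(z[data.treated].mean() - z[data.controls].mean())


def ate_ppi_lambda(
    data: TrialData,
    lam: float,
    *,
    method: str = "ppi_lambda",
    mom: ArmMoments | None = None,
    extra_warnings: tuple[str, ...] = (),
) -> AteEstimate:
    """Weighted prediction-powered estimator at a fixed weight ``lam``.

    Identically ``(1 - lam) * reference + lam * ppi``.
    """
    if not np.isfinite(lam):
        raise ValueError(f"lam must be finite, got {lam!r}")
    if mom is None:
        mom = compute_moments(data)
    ate = _lambda_family_point(data, lam)
    variance, clipped = _lambda_family_variance(mom, lam)
    flags = mom.warnings + extra_warnings
    if clipped:
        flags = flags + (WARN_VARIANCE_CLIPPED,)
    return AteEstimate(
        method=method,
        ate=ate,
        variance=variance,
        m=data.m,
        n=data.n,
        lam=lam,
        warnings=flags,
    )


def ate_reference(data: TrialData) -> AteEstimate:
    """Difference of arm means; variance sd_c^2/n + sd_t^2/m."""
    est = ate_ppi_lambda(data, 0.0, method="reference")
    return AteEstimate(
        method="reference",
        ate=est.ate,
        variance=est.variance,
        m=est.m,
        n=est.n,
        lam=None,
        warnings=est.warnings,
    )


def ate_ppi(data: TrialData) -> AteEstimate:
    """Prediction-powered estimator: arm-mean difference of ``y - f``.

    The control-arm mean of ``y - f`` is the rectifier correcting any
    systematic bias of the prognostic score.
    """
    est = ate_ppi_lambda(data, 1.0, method="ppi")
    return AteEstimate(
        method="ppi",
        ate=est.ate,
        variance=est.variance,
        m=est.m,
        n=est.n,
        lam=None,
        warnings=est.warnings,
    )


def lambda_star_plugin(mom: ArmMoments) -> float:
    """Variance-minimizing weight, per-arm plug-in.

    lambda_star = (n sd_t rho_t + m sd_c rho_c) / (N sd_f)

    which is exactly the minimizer of the finite-sample plug-in variance
    of the lambda family at the observed moments.
    """
    if mom.sd_f == 0.0:
        raise DegeneratePredictorError("prognostic score has zero variance")
    return (mom.n * mom.sd_t * mom.rho_t + mom.m * mom.sd_c * mom.rho_c) / (
        mom.N * mom.sd_f
    )


def lambda_pooled(data: TrialData, mom: ArmMoments | None = None) -> float:
    """Constant-treatment-effect weight: pooled covariance over variance of f.

    Numerator: within-arm covariance of y and f pooled with an N-2
    denominator; denominator: unbiased (ddof=1) variance of f over all N.
    Assumes rho_c = rho_t, which holds under a constant treatment effect;
    more stable than the per-arm plug-in when one arm is very small.
    """
    if mom is None:
        mom = compute_moments(data)
    var_f = mom.sd_f**2
    if var_f == 0.0:
        raise DegeneratePredictorError("prognostic score has zero variance")
    return mom.cov_pooled / var_f


def ate_ppct(
    data: TrialData,
    lambda_method: Literal["plugin", "pooled", "fixed"] = "plugin",
    lam_fixed: float | None = None,
) -> AteEstimate:
    """Prediction-powered clinical-trial estimator at a data-driven weight.

    ``plugin`` uses :func:`lambda_star_plugin` (method tag ``ppct``),
    ``pooled`` uses :func:`lambda_pooled` (tag ``ppct2``), ``fixed`` uses
    ``lam_fixed`` (tag ``ppi_lambda``).  A zero-variance prognostic score
    falls back to the reference estimator (weight 0) with a warning: the
    trial analysis must still return an answer.
    """
    mom = compute_moments(data)
    extra: tuple[str, ...] = ()
    if lambda_method == "fixed":
        if lam_fixed is None:
            raise ValueError("lam_fixed is required when lambda_method='fixed'")
        return ate_ppi_lambda(data, lam_fixed, method="ppi_lambda", mom=mom)
    if lambda_method == "plugin":
        tag = "ppct"
        try:
            lam = lambda_star_plugin(mom)
        except DegeneratePredictorError:
            lam, extra = 0.0, (WARN_DEGENERATE_PREDICTOR,)
    elif lambda_method == "pooled":
        tag = "ppct2"
        try:
            lam = lambda_pooled(data, mom)
        except DegeneratePredictorError:
            lam, extra = 0.0, (WARN_DEGENERATE_PREDICTOR,)
    else:
        raise ValueError(f"unknown lambda_method {lambda_method!r}")
    if extra:
        warnings.warn(
            "prognostic score is constant; falling back to the reference "
            "estimator (lambda = 0)",
            UserWarning,
            stacklevel=2,
        )
    return ate_ppi_lambda(data, lam, method=tag, mom=mom, extra_warnings=extra)


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------


def ancova_closed_form(mom: ArmMoments) -> float:
    """Two-arm closed form of the uncentered ANCOVA treatment coefficient.

    mean(y_t - lam_t f_t) - mean(y_c - lam_c f_c) with the per-arm OLS
    slopes lam_a = rho_a sd_a / sd_f^a.  Equals the coefficient of T in
    the OLS fit of y on (1, T, f, T*f) because the interaction term makes
    the two arms fit independently.
    """
    lam_t = mom.rho_t * mom.sd_t / mom.sd_ft if mom.sd_ft > 0 else 0.0
    lam_c = mom.rho_c * mom.sd_c / mom.sd_fc if mom.sd_fc > 0 else 0.0
    return (mom.mean_t - lam_t * mom.mean_ft) - (mom.mean_c - lam_c * mom.mean_fc)


def ate_ancova(
    data: TrialData,
    center_f: bool = False,
    sandwich: Literal["HC0", "HC1", "HC3"] = "HC1",
) -> tuple[AteEstimate, RegressionFit]:
    """ANCOVA estimator: OLS of y on (1, T, f, T*f), sandwich variance.

    With ``center_f=False`` (the literal definition) the coefficient of T
    is the arm contrast extrapolated to f = 0; it equals
    :func:`ancova_closed_form` exactly.  ``center_f=True`` mean-centers f
    first, so the coefficient targets the ATE even when the two arms have
    different slopes — recommended in practice, off by default for
    fidelity to the uncentered definition.
    """
    import statsmodels.api as sm

    if sandwich not in ("HC0", "HC1", "HC3"):
        raise ValueError(f"unknown sandwich flavor {sandwich!r}")
    f = data.f - data.f.mean() if center_f else data.f
    t = data.t.astype(float)
    Z = np.column_stack([np.ones(data.N), t, f, t * f])
    if np.linalg.matrix_rank(Z) < 4:
        raise SingularDesignError(
            "design matrix (1, T, f, T*f) is rank deficient; "
            "is the prognostic score constant?"
        )
    flags: tuple[str, ...] = ()
    if min(data.m, data.n) < 3:
        flags = (WARN_SMALL_ARM_SANDWICH,)
    with warnings.catch_warnings():
        # a saturated fit (df_resid = 0) makes the HC scale divide by zero
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sm.OLS(data.y, Z).fit(cov_type=sandwich)
        cov = np.asarray(res.cov_params())
    fit = RegressionFit(
        coefficients=np.asarray(res.params),
        cov=cov,
        residuals=np.asarray(res.resid),
        centered=center_f,
    )
    variance = float(fit.cov[1, 1])
    clipped = not (np.isfinite(variance) and variance >= 0.0)
    est = AteEstimate(
        method="ancova",
        ate=float(fit.coefficients[1]),
        variance=variance if not clipped else 0.0,
        m=data.m,
        n=data.n,
        lam=None,
        warnings=flags + ((WARN_VARIANCE_CLIPPED,) if clipped else ()),
    )
    return est, fit


# ---------------------------------------------------------------------------
# asymptotic variance (sqrt(N)-scale), shared with the design module
# ---------------------------------------------------------------------------


def variance_asymptotic(mom: ArmMoments, method: str, lam: float | None = None) -> float:
    """Asymptotic variance V with finite-sample variance ~ V/N.

    For the lambda family,

        V(lam) = (sd_t^2 + lam^2 sd_f^2 - 2 lam sd_f sd_t rho_t)/pi_t
               + (sd_c^2 + lam^2 sd_f^2 - 2 lam sd_f sd_c rho_c)/pi_c

    with ``reference`` at lam=0, ``ppi`` at lam=1, ``ppct``/``ppct2``/
    ``ancova`` at the variance-minimizing lam (the three share one
    asymptotic variance).  Evaluating V/N with pi_t = m/N, pi_c = n/N
    reproduces the finite-sample plug-in formulas exactly.
    """
    if not (0.0 < mom.pi_t < 1.0 and 0.0 < mom.pi_c < 1.0):
        raise ValueError("arm fractions must lie strictly in (0, 1)")

    def v_at(lam: float) -> float:
        a_t = (
            mom.sd_t**2
            + lam**2 * mom.sd_f**2
            - 2 * lam * mom.sd_f * mom.sd_t * mom.rho_t
        )
        a_c = (
            mom.sd_c**2
            + lam**2 * mom.sd_f**2
            - 2 * lam * mom.sd_f * mom.sd_c * mom.rho_c
        )
        return a_t / mom.pi_t + a_c / mom.pi_c

    if method == "reference":
        return v_at(0.0)
    if method == "ppi":
        return v_at(1.0)
    if method == "ppi_lambda":
        if lam is None:
            raise ValueError("ppi_lambda requires lam")
        return v_at(lam)
    if method in ("ppct", "ppct2", "ancova"):
        if mom.sd_f == 0.0:
            return v_at(0.0)
        return max(v_at(lambda_star_plugin(mom)), 0.0)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------


def estimate(
    data: TrialData,
    method: str,
    lam: float | None = None,
    ancova_center: bool = False,
) -> AteEstimate:
    """Compute one named estimator on a trial dataset."""
    if method == "reference":
        return ate_reference(data)
    if method == "ppi":
        return ate_ppi(data)
    if method == "ppi_lambda":
        if lam is None:
            raise ValueError("ppi_lambda requires lam")
        return ate_ppi_lambda(data, lam)
    if method == "ppct":
        return ate_ppct(data, "plugin")
    if method == "ppct2":
        return ate_ppct(data, "pooled")
    if method == "ancova":
        return ate_ancova(data, center_f=ancova_center)[0]
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
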