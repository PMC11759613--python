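"""Unit and property tests for the ATE estimators and their variances."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ppct
from ppct import (
    AdditiveSimConfig,
    ArmMoments,
    TrialData,
    TrialDataError,
    ancova_closed_form,
    ate_ancova,
    ate_ppct,
    ate_ppi,
    ate_ppi_lambda,
    ate_reference,
    compute_moments,
    estimate,
    gen_additive_trial,
    lambda_pooled,
    lambda_star_plugin,
    variance_asymptotic,
)
from ppct.estimators import SingularDesignError, _lambda_family_variance

from conftest import random_trial


def moments(sd_t=1.0, sd_c=1.0, sd_f=1.0, rho_t=0.0, rho_c=0.0, m=50, n=50):
    return ArmMoments(
        m=m, n=n, mean_t=0.0, mean_c=0.0, mean_ft=0.0, mean_fc=0.0,
        sd_t=sd_t, sd_c=sd_c, sd_f=sd_f, sd_ft=sd_f, sd_fc=sd_f,
        rho_t=rho_t, rho_c=rho_c, cov_pooled=0.0,
    )


# ---------------------------------------------------------------------------
# trial data validation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "y, t, f, match",
    [
        ([1, 2, 3], [1, 1, 0], [0, 0, 0], "at least 4"),
        ([1, 2, 3, 4], [1, 1, 0], [0, 0, 0, 0], "length mismatch"),
        ([1, 2, 3, 4], [1, 1, 0, 2], [0, 0, 0, 0], "only 0/1"),
        ([1, 2, 3, 4], [1, 1, 1, 0], [0, 0, 0, 0], ">= 2 subjects"),
        ([1, np.nan, 3, 4], [1, 1, 0, 0], [0, 0, 0, 0], "missing"),
    ],
)
def test_trial_data_rejects_invalid_input(y, t, f, match):
    with pytest.raises(TrialDataError, match=match):
        TrialData(y=y, t=t, f=f)


# ---------------------------------------------------------------------------
# moments
# ---------------------------------------------------------------------------


def test_moments_hand_example(toy):
    mom = compute_moments(toy)
    assert mom.sd_t == pytest.approx(np.sqrt(2))
    assert mom.sd_c == pytest.approx(np.sqrt(2))
    assert mom.rho_t == pytest.approx(1.0)
    assert mom.rho_c == pytest.approx(1.0)
    assert mom.sd_f == pytest.approx(np.std([2, 4, 1, 3], ddof=1))
    assert mom.pi_t + mom.pi_c == pytest.approx(1.0)


def test_moments_pooled_covariance_definition():
    d = random_trial(3)
    mom = compute_moments(d)
    tr, co = d.treated, d.controls
    cov_t = np.cov(d.y[tr], d.f[tr], ddof=1)[0, 1]
    cov_c = np.cov(d.y[co], d.f[co], ddof=1)[0, 1]
    expected = ((d.m - 1) * cov_t + (d.n - 1) * cov_c) / (d.N - 2)
    assert mom.cov_pooled == pytest.approx(expected, rel=1e-12)


def test_moments_constant_predictor_flags_degenerate():
    d = TrialData(y=[1, 2, 3, 4], t=[1, 1, 0, 0], f=[5, 5, 5, 5])
    mom = compute_moments(d)
    assert mom.sd_f == 0.0
    assert mom.rho_t == 0.0 and mom.rho_c == 0.0
    assert "degenerate_correlation" in mom.warnings


def test_moments_independent_predictor_correlation_vanishes():
    # law of large numbers: with y and f independent, rho -> 0
    rng = np.random.default_rng(0)
    N = 10**5
    t = (np.arange(N) < N // 2).astype(int)
    d = TrialData(y=rng.normal(0, 1, N), t=t, f=rng.normal(0, 1, N))
    mom = compute_moments(d)
    assert abs(mom.rho_t) < 0.02
    assert abs(mom.rho_c) < 0.02


# ---------------------------------------------------------------------------
# the lambda family
# ---------------------------------------------------------------------------


def test_reference_constant_arms():
    d = TrialData(y=[2, 2, 1, 1], t=[1, 1, 0, 0], f=[0, 1, 0, 1])
    assert ate_reference(d).ate == pytest.approx(1.0)


def test_reference_hand_example(toy):
    est = ate_reference(toy)
    assert est.ate == pytest.approx(2.0)
    assert est.variance == pytest.approx(2.0)  # 2/2 + 2/2
    assert est.lam is None


def test_ppi_zero_predictor_equals_reference(toy):
    d = TrialData(y=toy.y, t=toy.t, f=np.zeros(4))
    assert ate_ppi(d).ate == ate_reference(d).ate


def test_ppi_hand_example(toy):
    assert ate_ppi(toy).ate == pytest.approx(1.0)


def test_ppi_lambda_endpoints_match_reference_and_ppi(toy):
    ref, ppi = ate_reference(toy), ate_ppi(toy)
    at0 = ate_ppi_lambda(toy, 0.0)
    at1 = ate_ppi_lambda(toy, 1.0)
    assert at0.ate == ref.ate and at0.variance == ref.variance
    assert at1.ate == ppi.ate and at1.variance == ppi.variance


def test_ppi_lambda_halfway_hand_example(toy):
    assert ate_ppi_lambda(toy, 0.5).ate == pytest.approx(1.5)


def test_ppi_lambda_rejects_nonfinite(toy):
    with pytest.raises(ValueError):
        ate_ppi_lambda(toy, np.nan)


@given(st.integers(0, 10**6), st.floats(-3, 3, allow_nan=False))
def test_interpolation_identity(seed, lam):
    """ppi_lambda(lam) == (1 - lam) * reference + lam * ppi exactly."""
    d = random_trial(seed)
    lhs = ate_ppi_lambda(d, lam).ate
    rhs = (1 - lam) * ate_reference(d).ate + lam * ate_ppi(d).ate
    assert lhs == pytest.approx(rhs, abs=1e-10)


@pytest.mark.parametrize(
    "mom, expected",
    [
        (moments(rho_t=0.0, rho_c=0.0), 0.0),       # useless predictor
        (moments(rho_t=1.0, rho_c=1.0), 1.0),       # perfect predictor
        (moments(sd_f=2.0, rho_t=0.5, rho_c=0.5), 0.25),
    ],
)
def test_lambda_star_closed_form(mom, expected):
    assert lambda_star_plugin(mom) == pytest.approx(expected)


@given(st.integers(0, 10**6))
def test_lambda_star_is_the_variance_minimizer(seed):
    """The plug-in weight sits at the grid minimum of the plug-in variance."""
    d = random_trial(seed)
    mom = compute_moments(d)
    lam_star = lambda_star_plugin(mom)
    grid = np.arange(-5.0, 5.0, 1e-3)
    vals = np.array([_lambda_family_variance(mom, l)[0] for l in grid])
    assert abs(grid[vals.argmin()] - lam_star) <= 1e-3 + 1e-9


@given(st.integers(0, 10**6))
def test_ppct_never_less_efficient_than_reference(seed):
    """Plug-in variance at the optimized weight <= reference plug-in variance."""
    d = random_trial(seed)
    assert ate_ppct(d, "plugin").variance <= ate_reference(d).variance + 1e-12


def test_lambda_pooled_hand_example():
    d = TrialData(y=[1, 3, 0, 2], t=[1, 1, 0, 0], f=[0, 2, 0, 2])
    assert lambda_pooled(d) == pytest.approx(1.5)


def test_lambda_pooled_consistency_perfect_predictor():
    # f == y in both arms: the pooled weight converges to 1
    rng = np.random.default_rng(7)
    N = 10**4
    y = rng.normal(0, 1, N)
    t = (np.arange(N) < N // 2).astype(int)
    d = TrialData(y=y, t=t, f=y.copy())
    assert lambda_pooled(d) == pytest.approx(1.0, abs=0.02)


def test_lambda_pooled_no_signal():
    rng = np.random.default_rng(8)
    N = 10**4
    t = (np.arange(N) < N // 2).astype(int)
    d = TrialData(y=rng.normal(0, 1, N), t=t, f=rng.normal(0, 1, N))
    assert abs(lambda_pooled(d)) < 0.05


@given(st.integers(0, 10**6))
def test_cancellation_when_arm_means_of_f_coincide(seed):
    """Equal per-arm predictor means: every weighted estimate == reference."""
    rng = np.random.default_rng(seed)
    m = n = 6
    f_arm = rng.normal(0, 1, m)
    f = np.concatenate([f_arm, f_arm])  # identical f in both arms
    y = rng.normal(0, 1, m + n)
    d = TrialData(y=y, t=[1] * m + [0] * n, f=f)
    ref = ate_reference(d).ate
    for lam in (-1.3, 0.4, 1.0, 2.7):
        assert ate_ppi_lambda(d, lam).ate == pytest.approx(ref, abs=1e-12)
    assert ate_ppct(d, "plugin").ate == pytest.approx(ref, abs=1e-12)
    assert ate_ppct(d, "pooled").ate == pytest.approx(ref, abs=1e-12)


def test_ppct_degenerate_predictor_falls_back_to_reference():
    d = TrialData(y=[1.0, 2, 3, 4, 5, 6], t=[1, 1, 1, 0, 0, 0], f=[2.0] * 6)
    with pytest.warns(UserWarning, match="constant"):
        est = ate_ppct(d, "plugin")
    assert est.lam == 0.0
    assert est.ate == ate_reference(d).ate
    assert "degenerate_predictor" in est.warnings


def test_ppct_fixed_requires_lam(toy):
    with pytest.raises(ValueError, match="lam_fixed"):
        ate_ppct(toy, "fixed")
    est = ate_ppct(toy, "fixed", lam_fixed=0.5)
    assert est.method == "ppi_lambda"
    assert est.ate == pytest.approx(1.5)


def test_method_tags():
    d = random_trial(11)
    assert ate_ppct(d, "plugin").method == "ppct"
    assert ate_ppct(d, "pooled").method == "ppct2"
    assert estimate(d, "ancova").method == "ancova"


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------


def test_ancova_saturated_hand_example():
    d = TrialData(y=[2, 4, 0, 2], t=[1, 1, 0, 0], f=[0, 2, 0, 2])
    est, fit = ate_ancova(d)
    np.testing.assert_allclose(fit.coefficients, [0, 2, 1, 0], atol=1e-10)
    assert est.ate == pytest.approx(2.0)
    # saturated fit: sandwich variance is undefined, clipped and flagged
    assert est.variance == 0.0
    assert "variance_clipped" in est.warnings


def test_ancova_constant_predictor_is_singular():
    d = TrialData(y=[1.0, 2, 3, 4, 5, 6], t=[1, 1, 1, 0, 0, 0], f=[1.0] * 6)
    with pytest.raises(SingularDesignError):
        ate_ancova(d)


@given(st.integers(0, 10**6))
def test_ancova_equals_two_arm_closed_form(seed):
    """Uncentered treatment coefficient == per-arm-slope closed form."""
    d = random_trial(seed)
    est, _ = ate_ancova(d, center_f=False)
    assert est.ate == pytest.approx(ancova_closed_form(compute_moments(d)), abs=1e-10)


def test_ancova_sandwich_flavors_and_centering():
    d = random_trial(5, m=40, n=40)
    for flavor in ("HC0", "HC1", "HC3"):
        est, fit = ate_ancova(d, sandwich=flavor)
        assert est.variance > 0
        assert np.allclose(fit.cov, fit.cov.T)
    centered, fit_c = ate_ancova(d, center_f=True)
    assert fit_c.centered
    # centering shifts the contrast to the mean predictor value
    assert centered.ate != pytest.approx(ate_ancova(d)[0].ate, abs=1e-15)


def test_ancova_and_ppct_asymptotically_equivalent():
    cfg = AdditiveSimConfig(rho_target=0.5, m=5000, n=5000, reps=1)
    d = gen_additive_trial(cfg, 42)
    diff = ate_ancova(d)[0].ate - ate_ppct(d, "plugin").ate
    assert abs(diff) < 0.01


# ---------------------------------------------------------------------------
# asymptotic variance
# ---------------------------------------------------------------------------


def test_variance_asymptotic_reference_balanced_unit():
    assert variance_asymptotic(moments(), "reference") == pytest.approx(4.0)


def test_variance_asymptotic_perfect_predictor_zero():
    mom = moments(rho_t=1.0, rho_c=1.0)
    assert variance_asymptotic(mom, "ppi_lambda", lam=1.0) == pytest.approx(0.0)


def test_variance_asymptotic_ppct_grid_crosscheck():
    mom = moments(sd_f=2.0, rho_t=0.5, rho_c=0.5)
    v = variance_asymptotic(mom, "ppct")
    assert v == pytest.approx(3.0)  # 0.75 * V_ref
    grid = np.arange(-2, 2, 1e-4)
    v_grid = min(variance_asymptotic(mom, "ppi_lambda", lam=l) for l in grid)
    assert v == pytest.approx(v_grid, abs=1e-6)


@given(st.integers(0, 10**6))
def test_asymptotic_matches_finite_sample_at_empirical_fractions(seed):
    """V / N reproduces the finite-sample plug-in variance exactly."""
    d = random_trial(seed)
    mom = compute_moments(d)
    for meth, lam in [("reference", None), ("ppi", None), ("ppi_lambda", 0.7)]:
        v = variance_asymptotic(mom, meth, lam=lam)
        est = estimate(d, meth, lam=lam)
        assert v / d.N == pytest.approx(est.variance, rel=1e-10)


def test_variance_asymptotic_invalid_fractions():
    mom = moments(m=0, n=50)
    with pytest.raises(ValueError):
        variance_asymptotic(mom, "reference")


def test_estimate_dispatch_unknown_method(toy):
    with pytest.raises(ValueError, match="unknown method"):
        estimate(toy, "bogus")
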