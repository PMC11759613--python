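# Methods

## Setting and estimand

A two-arm randomized trial with $N$ participants: outcome $Y_i$, arm
indicator $T_i$ ($1$ = treated, $m$ subjects; $0$ = control, $n$
subjects), and a scalar prognostic score $f(X_i)$ computed from baseline
covariates only. The estimand is the average treatment effect
$\mathrm{ATE} = \mathbb{E}[Y \mid T=1] - \mathbb{E}[Y \mid T=0]$.
Randomization guarantees $X \perp T$, so the score has the same
distribution in both arms; everything below relies on that and on i.i.d.
sampling. Covariate-adaptive randomization schemes (stratified blocks,
minimization) are out of scope. The score is treated as a black box; it
must be trained on data disjoint from the trial, but it need not be
unbiased or calibrated — any systematic error is absorbed by the
rectifier / regression intercepts.

## Estimators and their variances

Write $\sigma_t, \sigma_c$ for the arm SDs of $Y$, $\sigma_f$ for the SD
of $f$, $\rho_t, \rho_c$ for the within-arm correlations of $Y$ with
$f$, and $\pi_t = m/N$, $\pi_c = n/N$. All empirical moments use
`ddof=1`; correlations are the plug-in ratio of those.

The weighted family
$\widehat{\mathrm{ATE}}(\lambda) = \overline{(Y - \lambda f)}^{\,t} - \overline{(Y - \lambda f)}^{\,c}$
interpolates between the difference of means ($\lambda = 0$) and full
prediction substitution with rectifier ($\lambda = 1$); it is unbiased
for every fixed $\lambda$ because the arm means of $f$ have equal
expectation. Its finite-sample variance estimate is

$$\widehat V(\lambda) = \frac{\hat\sigma_t^2 + \lambda^2\hat\sigma_f^2 - 2\lambda\hat\sigma_f\hat\sigma_t\hat\rho_t}{m} + \frac{\hat\sigma_c^2 + \lambda^2\hat\sigma_f^2 - 2\lambda\hat\sigma_f\hat\sigma_c\hat\rho_c}{n},$$

a quadratic in $\lambda$ minimized exactly at
$\hat\lambda^* = (n\hat\sigma_t\hat\rho_t + m\hat\sigma_c\hat\rho_c)/(N\hat\sigma_f)$
— the `ppct` plug-in weight. Because $\hat\lambda^*$ is the argmin,
$\widehat V(\hat\lambda^*) \le \widehat V(0)$ on every dataset: the
optimized estimator can only match or beat the reference. In fact
$\widehat V(\hat\lambda^*) \ge 0$ always (Cauchy–Schwarz on the
within-arm covariances), so the "clip negative plug-in variance to 0"
guard in the code is unreachable for this family and exists only
defensively; the one reachable clipping path is a saturated ANCOVA fit
whose sandwich variance is undefined.

`ppct2` replaces the per-arm weight with the pooled ratio
$\hat\lambda = \widehat{\mathrm{Cov}}_{\mathrm{pooled}}(Y, f)/\hat\sigma_f^2$
(within-arm covariances pooled with an $N-2$ denominator over the
all-$N$, `ddof=1` variance of $f$). It is consistent for the same
$\lambda^*$ under a constant treatment effect ($\rho_c = \rho_t$) and is
much more stable when one arm is very small, because the dominant
per-arm correlation in $\hat\lambda^*$ is otherwise estimated from a
handful of subjects — the simulation grid shows `ppct` underestimating
its variance at $n \in \{2, 5\}$ while `ppct2` stays calibrated.

**Choice of $\sigma_f$.** The plug-in weight and variance use the SD of
$f$ over all $N$ subjects pooled (legitimate since $f \perp T$); the
per-arm SDs appear only in the ANCOVA closed form. A per-arm convention
would be asymptotically identical; the pooled one uses twice the data.

**ANCOVA.** OLS of $Y$ on $(1, T, f, Tf)$; the interaction makes the two
arms fit independently, so the $T$ coefficient equals
$\overline{(Y - \hat\lambda_t f)}^{\,t} - \overline{(Y - \hat\lambda_c f)}^{\,c}$
with the per-arm regression slopes
$\hat\lambda_a = \hat\rho_a\hat\sigma_a/\hat\sigma_f^a$ — the same shape
as the weighted family but with two arm-specific weights. The fit and
its heteroskedasticity-consistent covariance come from statsmodels;
HC1 is the default flavor (HC0/HC3 selectable). With both weights
consistent for the same limit, ANCOVA and `ppct` are asymptotically
equivalent in point estimate and variance.

*Centering.* The raw $T$ coefficient is the arm contrast extrapolated to
$f = 0$. When the arm slopes differ and $f$ is far from zero (e.g. a
0–70 clinical scale), that extrapolation inflates the variance of the
coefficient by roughly $\mathrm{Var}(\hat\lambda_t - \hat\lambda_c)\bar f^2$
and it no longer targets the ATE. `ate_ancova(center_f=True)` mean-centers
$f$ first, which fixes both; it is off by default so the literal
uncentered definition (and its documented small-$n$ instability) remains
reproducible, but the power-curve harness uses the centered form, and we
recommend it for any real analysis. This is the one place the package's
two ANCOVA behaviours genuinely diverge; the difference vanishes when
the slopes are equal or $\mathbb{E}[f] = 0$.

## Testing

The estimators are asymptotically normal, so the default test rejects
$H_0: \mathrm{ATE} = 0$ when $|\widehat{\mathrm{ATE}}|$ exceeds
$\Phi^{-1}(1-\alpha/2)\sqrt{\widehat V}$; the confidence interval is the
matching Wald interval, so CI exclusion of zero and rejection agree
exactly. Normality is conventionally trusted for arm sizes around 20+;
below that, the permutation test permutes the arm *labels* uniformly
(preserving $m$ and $n$) and recomputes the full estimator — including
re-estimation of any data-driven weight — inside each permutation, so
the randomization distribution reflects the whole procedure. The
p-value uses the add-one rule $p = (1 + \#\{|\widehat{\mathrm{ATE}}_b| \ge |\widehat{\mathrm{ATE}}_{\mathrm{obs}}|\})/(B+1)$,
valid at any finite $B$. A `freeze_lambda` fast mode holds the weight
fixed; it is off by default because re-estimation preserves
exchangeability of the entire analysis. Label permutation (rather than
residual permutation) is the standard randomization test under the
sharp null. The permutation minimum of 100 draws is enforced; a
permutation in which the estimator fails is redrawn, aborting past a
10% failure rate.

## Design formulas

With asymptotic variance $V$ (finite-sample variance $\approx V/N$),
hypothesized effect $\Delta_H$, level $\alpha$ and target power
$1-\beta$:

- required size: $N = \lceil V(\Phi^{-1}(1-\alpha/2) + \Phi^{-1}(1-\beta))^2/\Delta_H^2 \rceil$,
  rounded up so the target is always met. Variance reduction scales the
  requirement proportionally.
- power: the exact two-sided expression
  $\Phi(-z_{\alpha/2} + |\Delta_H|\sqrt{N/V}) + \Phi(-z_{\alpha/2} - |\Delta_H|\sqrt{N/V})$;
  the second (wrong-side) term is what makes power tend to $\alpha$, not
  0, as $\Delta_H \to 0$. The sample-size formula is the standard
  one-term approximation; the difference is negligible whenever
  $|\Delta_H|/\mathrm{se} > 1$.
- allocation: the variance $A_c/n + A_t/(N-n)$ (with
  $A_a = \sigma_a^2 + \lambda^2\sigma_f^2 - 2\lambda\sigma_f\sigma_a\rho_a$;
  $A_a = \sigma_a^2$ for the reference) is convex in $n$, so the integer
  optimum is one of the two integers bracketing the continuous optimum
  $N/(1+\sqrt{A_t/A_c})$. The code evaluates both and keeps the better,
  with ties going to the larger control group — plain nearest-rounding
  can return the wrong neighbor, and the exhaustive-enumeration tests
  require true optimality. If $A_a \le 0$ (perfect prediction in an
  arm) the boundary split is returned with a warning.
- control-arm reduction: keeping $m$ treated,
  $n^* = \lceil m\sqrt{1-\rho_c^2} \rceil$ controls analyzed with the
  optimized estimator preserve the power of the balanced $m/m$
  reference design. This uses only $\rho_c$ (a sufficient condition
  also requiring $\sigma_t = \sigma_c$ and $\rho_t \ge 0$); a sharper
  bound using a known $\rho_t$ would solve
  $(n\rho_t + m\rho_c)^2 \ge m^2 - n^{*2}$ and is deliberately not
  tabulated — the conservative rule needs one quantity a pilot study can
  actually estimate. Negative $\rho_c$ is folded to $|\rho_c|$ (flip the
  score's sign) with a warning.

## Synthetic-trial generators

**Additive model** (`AdditiveSimConfig`): counterfactual control outcome
$Y^c \sim \mathcal N(0, \sigma_c^2)$ or $\chi^2_5$ (a skewed
alternative, variance 10); treated observe $Y^c + \Delta$ with constant
$\Delta$ (default 1); every subject's predictor is its *own*
counterfactual, $f = Y^c + \varepsilon$,
$\varepsilon \sim \mathcal N(0, \sigma_\varepsilon^2)$. The noise can be
set directly or calibrated to a target correlation via
$\sigma_\varepsilon^2 = \sigma_c^2(1-\rho^2)/\rho^2$ (using the family's
intrinsic variance, i.e. 10 for $\chi^2_5$). That formula diverges at
$\rho = 0$, where the generator instead draws an independent standard
normal score — the uninformative-predictor scenario it emulates.
Defaults ($\sigma_c = 1$, $\Delta = 1$, $m = 100$, $n$ varying, 1000
replicates) are the study conditions of the estimator-comparison grid.
Note the calibration applied to the $\chi^2$ family yields
$\sigma_\varepsilon^2 = 10(1-\rho^2)/\rho^2$; published $\chi^2$
comparisons at $\rho > 0$ appear instead consistent with unit-variance
scaling, so the direct `sigma_eps` override exists to reproduce either
convention, and we treat only the $\rho = 0$ $\chi^2$ cells as
theory-anchored. Likewise the normal $\rho = 0.95$ cells of the printed
grid are inconsistent with the calibration formula under every
convention we tried (the formula implies PPI SDs around 0.046, not
0.13) and are excluded from quantitative checks.

**Bounded-outcome model** (`BetaTrialConfig`): a one-year trial on a
0–70 cognitive scale (higher = worse). Subject $i$ has random effects
$\eta_i \sim \mathcal N(\mu_\eta, \sigma_\eta^2)$ (baseline logit
severity) and $\alpha_i \sim \mathcal N(\mu_\alpha, \sigma_\alpha^2)$
(annual logit progression); the latent end-of-trial severity is
$\psi_i = \mathrm{logit}^{-1}(\eta_i + \alpha_i t + \delta T_i)$ and the
observed outcome $Y_i = 70 B_i$ with
$B_i \sim \mathrm{Beta}(\psi_i\tau, (1-\psi_i)\tau)$, so
$\mathbb{E}[Y\mid\psi] = 70\psi$ and the precision $\tau$ sets the
observation noise, $\mathrm{Var}(Y/70 \mid \psi) = \psi(1-\psi)/(\tau+1)$.
$\psi$ is clamped to $[10^{-9}, 1-10^{-9}]$. The prognostic score is the
noiseless *untreated* trajectory $70\,\mathrm{logit}^{-1}(\eta_i + \alpha_i t)$
plus $\mathcal N(0, \sigma_\varepsilon^2)$ noise, so $\sigma_\varepsilon$
dials predictor quality directly on the outcome scale — exactly what a
disease progression model would supply and how it would degrade. The
outcome is the end-of-trial score; a change-score mode subtracts a
simulated baseline. The defaults ($\mu_\eta = -0.85$, $\sigma_\eta = 0.6$,
$\mu_\alpha = 0.35$, $\sigma_\alpha = 0.2$, $\tau = 20$,
$\delta = -0.25$, $t = 1$ year) are synthetic placeholders describing a
moderately impaired population (mean score ≈ 21/70 at baseline,
worsening ≈ 4 points/year, between-subject SD ≈ 10 points) with a
clinically plausible treatment effect of ≈ −3.7 points; they are not
calibrated to any cohort and every field is configurable. The true ATE
under this model,
$70\,\mathbb{E}[\mathrm{logit}^{-1}(\eta+\alpha t+\delta) - \mathrm{logit}^{-1}(\eta+\alpha t)]$,
has no closed form and is computed by seeded Monte-Carlo integration
($10^6$ draws).

**What the generators do and do not emulate.** They reproduce the
mechanisms the estimators are sensitive to: predictor quality (through
$\rho$ or $\sigma_\varepsilon$), arm imbalance, skewed and bounded
outcome laws, and subject-level heterogeneity. They do not emulate
dropout, measurement-occasion structure, covariate-dependent treatment
effects, site effects, or a predictor whose *error* correlates with
treatment status. Passing simulation checks therefore demonstrates the
estimators' statistical properties under clean randomization, not
robustness to those real-data complications.

## Monte-Carlo harness and reproducibility

`monte_carlo` runs `reps` independent trials; replicate $k$ uses
`numpy.random.default_rng([seed, k])`, a counter-based derivation that
makes streams independent, order-insensitive and bit-reproducible.
Reported per method: mean and SD of the point estimates, mean and SD of
the variance estimates (calibration: the mean plug-in variance matches
the empirical estimator variance within ~10% at $m = n = 100$), and the
rejection rate of the normal test. `power_curve` sweeps
$\sigma_\varepsilon$ and reports, per noise level, empirical power and
the relative sample size of an equally powered trial,
$100\,\bar{\widehat V}_{\mathrm{method}}/\bar{\widehat V}_{\mathrm{ref}}$.
Replicate counts in the test suite (300–5000 depending on the
granularity of the quantity checked) were chosen so Monte-Carlo error is
small against each assertion's tolerance while the whole suite stays
fast; the headline comparison cells use the full 1000 replicates of the
original study conditions.

## Numerical and degenerate-input choices

- Zero-variance prognostic score: data-driven weights are undefined;
  estimators fall back to $\lambda = 0$ (the reference) with an explicit
  warning rather than failing, because a trial analysis must return an
  answer. A constant score makes the ANCOVA design matrix singular,
  which *is* an error (there is no sensible fallback coefficient).
- Zero within-arm SD of $Y$ or $f$: the correlation is reported as 0
  with a degenerate-data flag.
- Arms of size 2 are the minimum (ddof-1 moments need it); ANCOVA with
  an arm below 3 carries a sandwich-unreliable warning, and a fully
  saturated 4-point fit reports variance 0 with a clipped flag.
- Missing values are rejected at construction, never imputed.
- PPI is represented internally as the weighted family at $\lambda = 1$
  and the reference at $\lambda = 0$: one code path, five method tags.

## Known limitations

- Scalar scores only; a multivariate prognostic vector would need the
  matrix generalization of the optimal weight, which reduces to
  $\xi^* = \lambda^*\sigma_f^2$ in the scalar case implemented here.
- The data-driven weight makes `ppct`/`ppct2` consistent but not exactly
  unbiased at finite $n$; simulations across $N \in [10, 1000]$ bound
  the bias below Monte-Carlo resolution, but a pre-specified fixed
  $\lambda$ (supported via `lambda_method="fixed"`) is the conservative
  regulatory choice.
- The normal test at very small arms relies on the permutation fallback;
  exact enumeration of permutations for tiny $N$ is not implemented.
- No multiplicity adjustment across endpoints; one endpoint per call.
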