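# Methods

## The problem

Two measurements of a positive continuous outcome are taken on each of n
subjects (before/after a treatment period, two follow-up days, ...), and the
question is whether an exposure — typically a baseline covariate interacted
with time, or a time-varying covariate — shifts the *change* in the outcome.
The classical tools are a random-intercept model (REM) on the long data or a
linear regression on the within-subject differences.  Both lean on normality
assumptions; the REM additionally assumes a distribution for the
subject-specific intercepts.  When the outcome lives on the "wrong" scale
(e.g. it is log-normal), a Box-Cox transformation is the usual remedy, but a
transformation chosen to normalize the REM's *total* error is corrupted by a
skewed intercept distribution even when the measurement error is perfectly
well behaved on some scale.

The conditional-probit (cprobit) workflow implemented here sidesteps both
assumptions in its first step by using only the within-subject *ordering* of
the two measurements.

## Model

Data-generating model (per subject i, time j = 1, 2):

    y_ij = alpha_i + beta' x_ij + eps_ij,      eps_ij ~ N(0, sigma^2)

with arbitrary subject intercepts alpha_i.  Differencing eliminates them:

    dy_i = beta' dx_i + deps_i,                deps_i ~ N(0, sigma_d^2),
    sigma_d^2 = 2 sigma^2.

Dividing by sigma_d and observing only the sign I_i = 1{y_i2 > y_i1} gives a
probit regression with no intercept:

    Pr(I_i = 1) = Phi(beta_c' dx_i),           beta_c = beta / sigma_d.

### The three steps

1. **Probit.**  Fit beta_c by maximum likelihood (Fisher scoring with
   step-halving from beta_c = 0; convergence when the score norm falls below
   1e-8; at most 100 iterations).  Because I_i depends on the outcomes only
   through their ordering, beta_c_hat is *identical* under any strictly
   increasing transformation of the outcome, and needs no assumption on the
   intercepts.  Covariance is the inverse Fisher information.  A heuristic
   flags (quasi-)complete separation (all fitted linear predictors of one
   response class beyond ±8, or any SE above 100); a Jeffreys-penalized
   (Firth-type) fit is available behind a flag for separated data.
2. **Scale.**  With beta_c fixed at beta_c_hat, estimate the difference-error
   SD by maximizing l(sigma) = −n log sigma − Σ(dy_i − sigma·eta_i)²/(2sigma²),
   eta_i = beta_c_hat' dx_i (bounded Brent on log sigma plus Newton polish of
   the score; the stationarity condition is the positive root of
   n·sigma² + (Σ dy·eta)·sigma − Σ dy² = 0, used as an independent
   cross-check in the tests).  Report the plug-in effect
   beta_hat = sigma_hat·beta_c_hat with SE(beta_hat) = sigma_hat·SE(beta_c_hat)
   and Wald 95% CIs (z = 1.959964).  Test the residuals
   dy_i − sigma_hat·eta_i for normality (Lilliefors).
3. **Box-Cox (gated).**  If Step-2 residuals reject normality at alpha_diag
   (default 0.05), assume the model holds for y^(lambda) instead and maximize
   the profile log-likelihood over lambda in [−3, 3] (61-point scan plus
   bounded Brent; boundary maxima are flagged).  Report
   beta_lambda_hat = sigma_lambda_hat·beta_c_hat on the transformed scale,
   with the same plug-in SE construction, a lambda CI, and a second
   Lilliefors test.  If that test also rejects, the report's recommendation
   is "none_adequate": extend the mean model rather than trust the estimate.

### The profile likelihood for lambda, and its Jacobian

At fixed lambda the inner problem is exactly Step 2 applied to the
transformed differences, so

    l_p(lambda) = max_sigma [ −n log sigma − Σ_i (dy_i^(lambda) − sigma·eta_i)² / (2 sigma²) ]
                  + (lambda − 1) Σ_i log sqrt(y_i1 · y_i2).

The Jacobian term deserves a note, because the likelihood is built from n
*difference* observations while 2n raw measurements are transformed.  A
Jacobian factor per raw measurement, (lambda−1)Σ(log y_i1 + log y_i2), would
add ≈ n(lambda−1)·mean(log y) net of the Gaussian part's opposite drift and
push lambda_hat to the search boundary for any data (we verified this
numerically: with it, mean lambda_hat ≈ 3.0 for true lambda in {0, 1/3, 1}).
The package therefore attaches exactly one factor per difference, evaluated
at the within-pair geometric mean — the symmetric linearization of
d(dy^(lambda))/d(dy).  With this choice lambda_hat is an essentially
unbiased estimate of the generating value (simulation at n = 1200, 200
replicates: mean lambda_hat 0.000 / 0.334 / 1.000 for true 0 / 1/3 / 1), and
the Wald CI from the numerical profile curvature covers at ≈ 95–96%.  The
conditional-on-baseline alternative (one factor at y_i2) was evaluated and
shows a small positive bias (+0.04 to +0.08); it is not used.

### What is deliberately *not* propagated

SE(beta_hat) ignores the sampling variability of sigma_hat, and
SE(beta_lambda_hat) additionally ignores that of lambda_hat.  This mirrors
the estimator's definition; the practical consequence, visible in the
simulations, is mild SE underestimation and (at small n with strong effects)
a small upward bias in |beta_lambda_hat| driven by the multiplicative
relationship between lambda error and the fitted scale.  Users who need
calibrated uncertainty for lambda itself should read the reported lambda CI,
which does use the profile curvature.

## Random-effects comparator

`fit_rem` is exact ML for the balanced two-observation random-intercept
model, computed by an orthogonal within/between split: d_i = (y_i2−y_i1)/√2
~ N(Xd γ, σ²) and m_i = (y_i1+y_i2)/√2 ~ N(Xm γ, σ²·r), r = 1 + 2σ_α²/σ²
profiled by 1-D Brent with closed-form GLS inside.  ML (not REML) so that
log-likelihoods are comparable across Box-Cox lambda.  `fit_rem_boxcox`
profiles lambda against the full marginal Gaussian likelihood of the 2n
transformed measurements plus the standard 2n-term Jacobian (here the
Gaussian part also has 2n terms, so the usual convention is the consistent
one).  A variance-ratio maximum at r = 1 (σ_α² = 0) is returned with a
boundary flag.  Fixed-effect SEs are plug-in ML (variance parameters treated
as known), matching standard mixed-model practice.

The REM Box-Cox lambda targets normality of the *total* error alpha + eps;
this is exactly why it breaks under skewed intercepts while the cprobit
Step 3 — which never sees the intercepts — does not.  The simulation suite
reproduces this contrast directionally.

## Synthetic data

No real data ship with the package; the generator emulates the structure of
the motivating applications (a baseline predictor against the change in the
outcome, entering the long-format model as a baseline-by-time interaction):

    y*_ij = alpha_i + b1·t_ij + beta·t_ij·x_i + eps_ij,   t_i1 = 0, t_i2 = 1,

so each observation carries covariates (t, t·x) which difference to
(1, x_i): a period indicator and the baseline predictor.  Defaults, chosen
once as realistic for the motivating EMR settings and fixed:
x_i ~ N(0,1); mu_alpha = 5, sigma_alpha = 1 (normal intercepts, or a shifted
gamma(shape 2) matched to the same mean and SD, skewness √2, for the skewed
family); sigma_eps = 1; time effect b1 = 0.1; effect sizes beta in
{0, −0.06}; n in {300, 1200}; 2000 replicates.  Study 2 maps y* through the
inverse Box-Cox transform with lambda in {1, 1/3, 0}; mu_alpha = 5 keeps
lambda·y* + 1 > 0 with overwhelming margin, and the rare violating subject
is redrawn rather than truncated (truncation would distort the error law);
generation fails loudly after 100 redraw rounds.  Replicate r of a run uses
seed (master + r), so any replicate is re-runnable in isolation.

What the generator does **not** emulate: measurement rounding, missing or
unpaired visits, heteroscedastic errors, more than two time points, or
informative tie structure.  Passing simulations therefore certify the
estimator's operating characteristics under the stated model, not robustness
to those real-data features.

## Numerical choices and degenerate inputs

- Ties (dy = 0) carry no ordering information and make the conditional
  likelihood undefined; they are excluded with a logged count by default,
  or raise an error in strict mode.
- Covariate columns that difference to exactly zero (time-invariant
  covariates) are rejected with a message explaining that they are
  implicitly controlled for.
- Lilliefors p-values use the Dallal–Wilkinson approximation (table-based
  in the large-p regime); the statistic and p match R's
  `nortest::lillie.test` to 1e-10 / 1e-4 in the tests.
- lambda CI: Wald from a central-difference second derivative (step 1e-4)
  of the profile; a profile-likelihood-ratio interval (drop of 1.9207) is
  available via `ci_method="profile"`.  At a boundary maximum the CI is
  reported as NaN with a flag.
- The sigma optimizer's Brent bracket spans e^±15 around the eta = 0 closed
  form sqrt(mean(dy²)); the returned value satisfies |dl/dsigma| ≤ 1e-8.

## Problem sizes used by the test and acceptance runs

Nominal-level checks (type I error, coverage, Lilliefors rejection,
relative bias) use the full 2000 replicates at the documented n.  Recovery
checks at n = 1200 use 200 replicates and a 3-Monte-Carlo-SE criterion;
directional comparisons with the REM use 500 replicates.  A 2000-replicate
mean of beta_lambda_hat at n = 300 carries ≈ 4% (of the true effect)
Monte-Carlo standard error — single-window estimates of the relative bias
can read several points above or below the long-run value of ≈ 1–2%.

## Known limitations

- Exactly two time points per subject; no unbalanced designs or imputation.
- Probit link only: the scaling identity beta = sigma_d·beta_c is specific
  to the normal error model.
- Plug-in SEs understate uncertainty as described above; no bootstrap is
  provided.
- The Box-Cox family itself: outcomes must be strictly positive, and no
  shifted-power or Yeo-Johnson variants are offered.
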