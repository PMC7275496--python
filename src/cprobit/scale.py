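"""Step 2: scale estimation on the observed outcome and the plug-in effect.

With beta_c fixed at the Step-1 estimate, the difference model reads

    delta_y_i = sigma_delta * beta_c' . delta_x_i + delta_eps_i,
    delta_eps_i ~ N(0, sigma_delta^2),

and sigma_delta is estimated by maximizing this estimated likelihood in the
single unknown sigma.  The effect on the observed outcome is the plug-in

    beta_hat = sigma_delta_hat * beta_c_hat,
    SE(beta_hat) = sigma_delta_hat * SE(beta_c_hat),

deliberately ignoring the sampling variability of sigma_delta_hat (this
mirrors the estimator as defined; the resulting mild SE underestimation is a
documented property, see docs/methods.md).  Residuals
delta_y_i - sigma_hat * eta_hat_i feed a Lilliefors normality test that
gates whether a Box-Cox step is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors

from .data import PairedDataset
from .exceptions import DegenerateSampleError, InsufficientDataError
from .probit import Step1Result

__all__ = ["Step2Result", "estimate_sigma_delta", "lilliefors_test", "fit_step2", "Z_95"]

Z_95 = 1.959964  # standard normal 97.5% quantile, as conventionally rounded


@dataclass
class Step2Result:
    """Untransformed-scale fit: scale, plug-in effect, residual diagnostics."""

    sigma_delta_hat: float
    beta_hat: np.ndarray
    se_beta_hat: np.ndarray
    ci_beta: np.ndarray  # (p, 2) Wald 95% limits
    residuals: np.ndarray
    lilliefors_stat: float
    lilliefors_p: float
    normality_ok: bool
    loglik: float
    covariate_names: tuple = ()


def _sigma_loglik_terms(delta_y, eta_hat):
    dy = np.asarray(delta_y, dtype=float)
    eta = np.asarray(eta_hat, dtype=float)
    if dy.shape != eta.shape or dy.ndim != 1:
        raise ValueError("delta_y and eta_hat must be 1-D arrays of equal length")
    n = dy.size
    A = float(dy @ dy)
    B = float(dy @ eta)
    C = float(eta @ eta)
    return n, A, B, C


def estimate_sigma_delta(delta_y, eta_hat) -> float:
    """Maximize l(sigma) = -n log(sigma) - sum_i (dy_i - sigma*eta_i)^2 / (2 sigma^2).

    Brent's method on log(sigma) over a wide bracket centred at the eta = 0
    closed form sqrt(mean(dy^2)), followed by Newton polishing of the score
    so that |dl/dsigma| <= 1e-8 at the returned value.
    """
    n, A, B, C = _sigma_loglik_terms(delta_y, eta_hat)
    if n < 2:
        raise InsufficientDataError("need at least 2 subjects to estimate sigma_delta")
    if A == 0.0:
        raise DegenerateSampleError("all outcome differences are zero")

    # l(sigma) = -n log s - A/(2 s^2) + B/s - C/2
    def negll(t):
        s = np.exp(t)
        return n * t + A / (2.0 * s * s) - B / s

    t0 = 0.5 * np.log(A / n)
    res = minimize_scalar(negll, bounds=(t0 - 15.0, t0 + 15.0), method="bounded",
                          options={"xatol": 1e-12})
    if not res.success:  # pragma: no cover - bounded Brent essentially always succeeds
        raise ArithmeticError(f"sigma_delta bracket search failed: {res.message}")
    s = float(np.exp(res.x))

    def score(s):
        return -n / s + A / s**3 - B / s**2

    def dscore(s):
        return n / s**2 - 3.0 * A / s**4 + 2.0 * B / s**3

    for _ in range(50):
        g = score(s)
        if abs(g) <= 1e-8:
            break
        step = g / dscore(s)
        if not np.isfinite(step) or abs(step) > 0.5 * s:
            break
        s -= step
    return s


def sigma_profile_loglik(sigma: float, delta_y, eta_hat) -> float:
    """The estimated log-likelihood l(sigma) used by Steps 2 and 3."""
    n, A, B, C = _sigma_loglik_terms(delta_y, eta_hat)
    return -n * np.log(sigma) - A / (2.0 * sigma**2) + B / sigma - C / 2.0


def lilliefors_test(sample) -> tuple[float, float]:
    """Lilliefors (KS with estimated mean/SD) test of normality.

    Returns (statistic, p).  The statistic is sup_x |F_hat(x) - Phi((x - xbar)/s)|;
    the p-value uses the Dallal-Wilkinson approximation (table-based for large p).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise InsufficientDataError(f"Lilliefors test needs n >= 5, got {x.size}")
    if np.ptp(x) == 0.0:
        raise DegenerateSampleError("constant sample: normality test undefined")
    stat, p = _sm_lilliefors(x, dist="norm", pvalmethod="approx")
    return float(stat), float(p)


def fit_step2(data: PairedDataset, step1: Step1Result, alpha_diag: float = 0.05) -> Step2Result:
    """Scale Step-1's beta_c_hat to the observed outcome.

    ``normality_ok`` is True when the Lilliefors p-value on the residuals is
    at least ``alpha_diag`` (default 5%); it gates Step 3 in the workflow.
    """
    if not step1.converged:
        raise ValueError("Step-1 fit did not converge; cannot scale its estimate")
    eta = data.delta_x @ step1.beta_c_hat
    sigma = estimate_sigma_delta(data.delta_y, eta)
    beta = sigma * step1.beta_c_hat
    se = sigma * step1.se_beta_c
    ci = np.column_stack([beta - Z_95 * se, beta + Z_95 * se])
    resid = data.delta_y - sigma * eta
    stat, p = lilliefors_test(resid)
    return Step2Result(
        sigma_delta_hat=sigma,
        beta_hat=beta,
        se_beta_hat=se,
        ci_beta=ci,
        residuals=resid,
        lilliefors_stat=stat,
        lilliefors_p=p,
        normality_ok=bool(p >= alpha_diag),
        loglik=sigma_profile_loglik(sigma, data.delta_y, eta),
        covariate_names=step1.covariate_names,
    )
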