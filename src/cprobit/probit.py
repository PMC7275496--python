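"""Step 1: conditional probit model on the increase indicator.

For paired outcomes generated by a random-intercept model, the probability
that subject i's outcome increases is

    Pr(I_i = 1) = Phi(beta_c' . delta_x_i),        beta_c = beta / sigma_delta,

where Phi is the standard normal CDF and sigma_delta is the SD of the
within-subject error difference.  Because I_i depends on the outcomes only
through their within-subject ordering, beta_c_hat is invariant to any
strictly increasing transformation of the outcome — this is what makes the
three-step workflow robust to the (unknown) outcome scale.

The linear predictor is exactly beta_c' . delta_x: no intercept is added.
A constant column can only arise from differencing a time indicator, in
which case it is a legitimate design column supplied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, ndtr
from scipy.stats import norm

from .data import PairedDataset
from .exceptions import DesignError
from .exceptions import CprobitError

__all__ = ["Step1Result", "fit_step1", "predict_increase_prob"]

# fitted probabilities this close to 0/1 are treated as numerically degenerate
_ETA_SEPARATION = 8.0
_SE_CAP = 100.0


@dataclass
class Step1Result:
    """Maximum-likelihood probit fit on the increase indicator.

    ``beta_c_hat`` estimates the scaled effect beta / sigma_delta; its
    covariance is the inverse Fisher information at the maximum.
    """

    beta_c_hat: np.ndarray
    cov_beta_c: np.ndarray
    converged: bool
    separation_flag: bool
    loglik: float
    n_iter: int
    covariate_names: tuple = ()

    @property
    def se_beta_c(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta_c))


def _loglik(beta: np.ndarray, X: np.ndarray, I: np.ndarray) -> float:
    eta = X @ beta
    # log Phi(eta) for I=1, log Phi(-eta) for I=0, evaluated stably
    return float(np.sum(np.where(I == 1, log_ndtr(eta), log_ndtr(-eta))))


def _score_and_information(beta, X, I):
    eta = X @ beta
    phi = norm.pdf(eta)
    Phi = np.clip(ndtr(eta), 1e-14, 1.0 - 1e-14)
    resid = (I - Phi) * phi / (Phi * (1.0 - Phi))
    w = phi * phi / (Phi * (1.0 - Phi))
    score = X.T @ resid
    info = (X * w[:, None]).T @ X
    return score, info


def fit_step1(
    data: PairedDataset,
    max_iter: int = 100,
    tol: float = 1e-8,
    firth: bool = False,
) -> Step1Result:
    """Fit Pr(I_i = 1) = Phi(beta_c' . delta_x_i) by Fisher scoring.

    Fisher scoring with step-halving, started at beta_c = 0; convergence is
    declared when the Euclidean norm of the score drops below ``tol``.
    (Quasi-)complete separation is detected heuristically — all fitted
    linear predictors of one response class beyond +/-8, or a standard error
    above 100 — and flagged, with estimates still returned.

    Parameters
    ----------
    data : PairedDataset
    max_iter, tol : Fisher-scoring controls.
    firth : if set, maximize the Jeffreys-penalized likelihood
        l(b) + 0.5 log det I(b) instead (bias reduction under separation;
        off by default as it is outside the core workflow).
    """
    X = data.delta_x
    I = data.increase_indicator
    n, p = X.shape
    if p == 0:
        raise DesignError("no covariates: the conditional probit has no parameters to fit")
    if n < p + 1:
        raise DesignError(f"need at least p+1 = {p + 1} subjects for p = {p} covariates, got {n}")
    if np.linalg.matrix_rank(X) < p:
        raise DesignError("delta_x is rank deficient; drop collinear covariate columns")

    if firth:
        return _fit_firth(data, max_iter, tol)

    beta = np.zeros(p)
    ll = _loglik(beta, X, I)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        score, info = _score_and_information(beta, X, I)
        if np.linalg.norm(score) <= tol:
            converged = True
            it -= 1
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # step-halving: accept the first step that does not decrease the loglik
        new_ll = -np.inf
        for _ in range(30):
            cand = beta + step
            new_ll = _loglik(cand, X, I)
            if new_ll >= ll - 1e-12:
                break
            step *= 0.5
        if new_ll < ll - 1e-12:
            break
        beta, ll = beta + step, new_ll
    else:
        it = max_iter

    score, info = _score_and_information(beta, X, I)
    if not converged and np.linalg.norm(score) <= tol:
        converged = True
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)

    eta = X @ beta
    sep = False
    if (I == 1).any() and np.all(eta[I == 1] > _ETA_SEPARATION):
        sep = True
    if (I == 0).any() and np.all(eta[I == 0] < -_ETA_SEPARATION):
        sep = True
    with np.errstate(invalid="ignore"):
        if np.any(np.sqrt(np.diag(cov)) > _SE_CAP):
            sep = True

    return Step1Result(
        beta_c_hat=beta,
        cov_beta_c=cov,
        converged=converged,
        separation_flag=sep,
        loglik=ll,
        n_iter=it,
        covariate_names=data.covariate_names,
    )


def _fit_firth(data: PairedDataset, max_iter: int, tol: float) -> Step1Result:
    """Jeffreys-penalized probit via quasi-Newton on the penalized likelihood."""
    from scipy.optimize import minimize

    X, I = data.delta_x, data.increase_indicator
    p = X.shape[1]

    def neg_pen_ll(beta):
        _, info = _score_and_information(beta, X, I)
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return np.inf
        return -(_loglik(beta, X, I) + 0.5 * logdet)

    res = minimize(neg_pen_ll, np.zeros(p), method="BFGS", options={"maxiter": max_iter, "gtol": tol})
    _, info = _score_and_information(res.x, X, I)
    cov = np.linalg.inv(info)
    return Step1Result(
        beta_c_hat=res.x,
        cov_beta_c=cov,
        converged=bool(res.success),
        separation_flag=False,
        loglik=_loglik(res.x, X, I),
        n_iter=int(res.nit),
        covariate_names=data.covariate_names,
    )


def predict_increase_prob(result: Step1Result, delta_x_row) -> float:
    """Probability of an outcome increase for a covariate-difference row."""
    if not result.converged:
        raise CprobitError("cannot predict from a non-converged Step-1 fit")
    row = np.asarray(delta_x_row, dtype=float)
    if row.shape != result.beta_c_hat.shape:
        raise ValueError(f"expected a length-{result.beta_c_hat.size} row, got shape {row.shape}")
    return float(ndtr(row @ result.beta_c_hat))
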