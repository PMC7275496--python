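"""Synthetic paired data and replicate-level performance evaluation.

Study 1 draws two-time-point data from the random-intercept model

    y_ij = alpha_i + b1 * t_ij + beta * t_ij * x_i + eps_ij,
    t_i1 = 0, t_i2 = 1,  x_i ~ N(0, 1),  eps_ij ~ N(0, sigma_eps^2),

so the within-subject difference follows delta_y_i = b1 + beta * x_i +
delta_eps_i — the "baseline predictor vs change in outcome" design.  The
intercepts alpha_i are either normal N(mu_alpha, sigma_alpha^2) or a shifted
gamma(shape 2) matched to the same mean and SD (skewness sqrt(2)), which
stresses the intercept-distribution assumption of the random-effects model
while leaving the conditional-probit workflow untouched.

Study 2 pushes the Study-1 (latent, transformed-scale) outcome through the
inverse Box-Cox map with lambda in {1, 1/3, 0}, so the observed outcome
requires no / cube-root / log transformation to restore a Gaussian linear
model.  Positivity of the observed outcome is guaranteed by per-subject
resampling of the rare draws with lambda*y + 1 <= 0 (silent truncation would
distort the error distribution); generation fails loudly if a subject cannot
be redrawn within 100 rounds.

`run_simulation` evaluates an estimator ("cprobit" or "rem", with or without
Box-Cox) over replicates and aggregates bias, empirical SE, mean model SE,
95%-CI coverage, rejection rate (type I error under beta = 0, power
otherwise) and the Lilliefors rejection rate.  The monitored coefficient is
always the LAST design column — the baseline-predictor-by-time interaction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .boxcox import fit_step3, inverse_box_cox
from .data import ObservationRecord, build_paired_dataset
from .exceptions import CprobitError, SimulationError
from .probit import fit_step1
from .rem import fit_rem, fit_rem_boxcox
from .scale import Z_95, fit_step2, lilliefors_test

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulationMetrics",
    "generate_study1",
    "generate_study2",
    "run_simulation",
    "summarize_replicates",
    "metrics_to_frame",
]


@dataclass
class SimulationConfig:
    """Generator settings; defaults are the documented study conditions."""

    n_subjects: int = 300
    beta: float = 0.0                 # effect of the baseline predictor on the change
    true_lambda: float | None = None  # None => Study 1; {1, 1/3, 0} => Study 2
    intercept_family: str = "normal"  # "normal" or "skewed"
    mu_alpha: float = 5.0
    sigma_alpha: float = 1.0
    sigma_eps: float = 1.0
    time_effect: float = 0.1          # b1, the period effect
    n_replicates: int = 2000
    seed: int = 0
    alpha_test: float = 0.05

    def __post_init__(self):
        if self.n_subjects < 2:
            raise SimulationError("n_subjects must be at least 2")
        if self.sigma_alpha <= 0 or self.sigma_eps <= 0:
            raise SimulationError("sigma_alpha and sigma_eps must be positive")
        if self.n_replicates < 1:
            raise SimulationError("n_replicates must be at least 1")
        if self.intercept_family not in ("normal", "skewed"):
            raise SimulationError(f"unknown intercept_family {self.intercept_family!r}")


@dataclass
class SimulationMetrics:
    """Replicate-level performance summary for one (config, estimator, transform) cell."""

    bias: float
    relative_bias_pct: float
    empirical_se: float
    mean_model_se: float
    coverage_95: float
    rejection_rate: float
    lilliefors_rejection_rate: float
    mean_lambda_hat: float | None = None
    lambda_coverage: float | None = None
    n_replicates_used: int = 0
    n_failed_replicates: int = 0
    warning: str | None = None


def _draw_intercepts(rng: np.random.Generator, config: SimulationConfig, size: int) -> np.ndarray:
    if config.intercept_family == "normal":
        return config.mu_alpha + config.sigma_alpha * rng.standard_normal(size)
    # gamma(shape 2, scale sa/sqrt(2)) has SD = sa; shift to mean mu_alpha
    scale = config.sigma_alpha / np.sqrt(2.0)
    return rng.gamma(2.0, scale, size) + config.mu_alpha - 2.0 * scale


def _draw_latent(rng: np.random.Generator, config: SimulationConfig, size: int):
    """Draw (x, y1, y2) on the latent (transformed/linear) scale for `size` subjects."""
    x = rng.standard_normal(size)
    alpha = _draw_intercepts(rng, config, size)
    eps = config.sigma_eps * rng.standard_normal((size, 2))
    y1 = alpha + eps[:, 0]
    y2 = alpha + config.time_effect + config.beta * x + eps[:, 1]
    return x, y1, y2


def _records_from_arrays(x, y1, y2) -> list[ObservationRecord]:
    recs = []
    for i in range(x.size):
        recs.append(ObservationRecord(i + 1, 1, float(y1[i]), (0.0, 0.0)))
        recs.append(ObservationRecord(i + 1, 2, float(y2[i]), (1.0, float(x[i]))))
    return recs


def generate_study1(config: SimulationConfig, replicate_seed: int) -> list[ObservationRecord]:
    """One Study-1 replicate: untransformed random-intercept data.

    Each observation carries the covariates (t_ij, t_ij * x_i), which
    difference to (1, x_i) — a period indicator and the baseline predictor.
    Deterministic given ``replicate_seed``.
    """
    rng = np.random.default_rng(replicate_seed)
    x, y1, y2 = _draw_latent(rng, config, config.n_subjects)
    return _records_from_arrays(x, y1, y2)


def generate_study2(config: SimulationConfig, replicate_seed: int) -> list[ObservationRecord]:
    """One Study-2 replicate: Study-1 latent outcomes mapped through the
    inverse Box-Cox transform with ``config.true_lambda``.

    Subjects whose latent draw falls outside the image of the Box-Cox map
    (lambda*y + 1 <= 0, vanishingly rare under the default mu_alpha = 5) are
    redrawn, up to 100 rounds.
    """
    lam = config.true_lambda
    if lam is None:
        raise SimulationError("generate_study2 requires true_lambda (e.g. 1, 1/3 or 0)")
    rng = np.random.default_rng(replicate_seed)
    x, y1, y2 = _draw_latent(rng, config, config.n_subjects)
    if lam != 0.0:
        for attempt in range(100):
            bad = (lam * y1 + 1.0 <= 0.0) | (lam * y2 + 1.0 <= 0.0)
            if not bad.any():
                break
            idx = np.nonzero(bad)[0]
            xb, y1b, y2b = _draw_latent(rng, config, idx.size)
            x[idx], y1[idx], y2[idx] = xb, y1b, y2b
        else:
            raise SimulationError(
                "could not draw latent outcomes inside the Box-Cox image after 100 rounds; "
                "increase mu_alpha so that lambda*y + 1 stays positive"
            )
    return _records_from_arrays(x, inverse_box_cox(y1, lam), inverse_box_cox(y2, lam))


def _fit_one(records, estimator: str, transform: str, effect_index: int,
             alpha_diag: float):
    """Fit one replicate; returns (est, se, ci_lo, ci_hi, lil_p, lam_hat, lam_ci)."""
    if estimator == "cprobit":
        data = build_paired_dataset(records, drop_ties=True)
        s1 = fit_step1(data)
        if not s1.converged or s1.separation_flag:
            raise CprobitError("step-1 fit unusable")
        if transform == "none":
            s2 = fit_step2(data, s1, alpha_diag=alpha_diag)
            j = effect_index % s2.beta_hat.size
            return (s2.beta_hat[j], s2.se_beta_hat[j], s2.ci_beta[j, 0], s2.ci_beta[j, 1],
                    s2.lilliefors_p, None, None)
        s3 = fit_step3(data, s1, alpha_diag=alpha_diag)
        j = effect_index % s3.beta_lambda_hat.size
        return (s3.beta_lambda_hat[j], s3.se_beta_lambda[j],
                s3.ci_beta_lambda[j, 0], s3.ci_beta_lambda[j, 1],
                s3.lilliefors_p, s3.lambda_hat, s3.ci_lambda)
    if estimator == "rem":
        fit = fit_rem(records) if transform == "none" else fit_rem_boxcox(records)
        j = effect_index % fit.beta_hat.size
        est, se = fit.beta_hat[j], fit.se_beta[j]
        # marginal ("total") residuals retain the intercept deviation and are
        # what a residual-normality check on the REM actually sees
        from .data import _validate_pairing
        from .boxcox import box_cox
        pairs = _validate_pairing(records)
        y = np.array([[r1.outcome, r2.outcome] for r1, r2 in
                      (pairs[s] for s in sorted(pairs, key=str))])
        X1 = np.array([[1.0, *pairs[s][0].covariates] for s in sorted(pairs, key=str)])
        X2 = np.array([[1.0, *pairs[s][1].covariates] for s in sorted(pairs, key=str)])
        yt = y if fit.lambda_hat is None else box_cox(y, fit.lambda_hat)
        resid = np.concatenate([yt[:, 0] - X1 @ fit.beta_hat, yt[:, 1] - X2 @ fit.beta_hat])
        _, lil_p = lilliefors_test(resid)
        return (est, se, est - Z_95 * se, est + Z_95 * se, lil_p,
                fit.lambda_hat, fit.ci_lambda)
    raise ValueError(f"unknown estimator {estimator!r}")


def summarize_replicates(
    estimates, ses, ci_low, ci_high, truth: float,
    lilliefors_p=None, alpha: float = 0.05,
    lambda_hats=None, lambda_cis=None, true_lambda: float | None = None,
    n_failed: int = 0,
) -> SimulationMetrics:
    """Aggregate per-replicate results into a :class:`SimulationMetrics`."""
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    lo = np.asarray(ci_low, dtype=float)
    hi = np.asarray(ci_high, dtype=float)
    n = est.size
    bias = float(est.mean() - truth)
    metrics = SimulationMetrics(
        bias=bias,
        relative_bias_pct=float(100.0 * bias / truth) if truth != 0 else float("nan"),
        empirical_se=float(est.std(ddof=1)) if n > 1 else 0.0,
        mean_model_se=float(se.mean()),
        coverage_95=float(np.mean((lo <= truth) & (truth <= hi))),
        rejection_rate=float(np.mean((lo > 0.0) | (hi < 0.0))),
        lilliefors_rejection_rate=(
            float(np.mean(np.asarray(lilliefors_p, dtype=float) < alpha))
            if lilliefors_p is not None else float("nan")
        ),
        n_replicates_used=n,
        n_failed_replicates=n_failed,
    )
    if lambda_hats is not None and len(lambda_hats):
        lh = np.asarray(lambda_hats, dtype=float)
        metrics.mean_lambda_hat = float(lh.mean())
        if lambda_cis is not None and true_lambda is not None:
            lc = np.asarray(lambda_cis, dtype=float)
            ok = np.isfinite(lc).all(axis=1)
            if ok.any():
                metrics.lambda_coverage = float(
                    np.mean((lc[ok, 0] <= true_lambda) & (true_lambda <= lc[ok, 1]))
                )
    if n_failed > 0.05 * max(n + n_failed, 1):
        metrics.warning = f"{n_failed} of {n + n_failed} replicates failed (> 5%)"
        logger.warning(metrics.warning)
    return metrics


def run_simulation(
    config: SimulationConfig,
    estimator: str = "cprobit",
    transform: str = "none",
    effect_index: int = -1,
    collect=None,
) -> SimulationMetrics:
    """Monte-Carlo evaluation of one estimator on one configuration.

    Replicate r uses seed ``config.seed + r`` so any replicate can be re-run
    in isolation.  ``collect``, if given, is a list that receives the
    per-replicate (estimate, se, ci_lo, ci_hi, lilliefors_p, lambda_hat)
    tuples for audit.  Raises if every replicate fails.
    """
    gen = generate_study1 if config.true_lambda is None else generate_study2
    ests, ses, los, his, lils, lams, lamcis = [], [], [], [], [], [], []
    n_failed = 0
    for r in range(config.n_replicates):
        records = gen(config, config.seed + r)
        try:
            est, se, lo, hi, lil_p, lam, lam_ci = _fit_one(
                records, estimator, transform, effect_index, config.alpha_test
            )
        except CprobitError:
            n_failed += 1
            continue
        ests.append(est); ses.append(se); los.append(lo); his.append(hi); lils.append(lil_p)
        if lam is not None:
            lams.append(lam)
            lamcis.append(lam_ci if lam_ci is not None else (np.nan, np.nan))
        if collect is not None:
            collect.append((est, se, lo, hi, lil_p, lam))
    if not ests:
        raise SimulationError("all replicates failed")
    return summarize_replicates(
        ests, ses, los, his, truth=config.beta,
        lilliefors_p=lils, alpha=config.alpha_test,
        lambda_hats=lams or None, lambda_cis=lamcis or None,
        true_lambda=config.true_lambda, n_failed=n_failed,
    )


def metrics_to_frame(rows: Sequence[tuple]):
    """Tidy DataFrame from (config, estimator, transform, metrics) tuples."""
    import pandas as pd

    out = []
    for config, estimator, transform, m in rows:
        out.append({
            "n_subjects": config.n_subjects,
            "beta": config.beta,
            "true_lambda": config.true_lambda,
            "intercept_family": config.intercept_family,
            "n_replicates": config.n_replicates,
            "seed": config.seed,
            "estimator": estimator,
            "transform": transform,
            "bias": m.bias,
            "relative_bias_pct": m.relative_bias_pct,
            "empirical_se": m.empirical_se,
            "mean_model_se": m.mean_model_se,
            "coverage_95": m.coverage_95,
            "rejection_rate": m.rejection_rate,
            "lilliefors_rejection_rate": m.lilliefors_rejection_rate,
            "mean_lambda_hat": m.mean_lambda_hat,
            "lambda_coverage": m.lambda_coverage,
            "n_failed_replicates": m.n_failed_replicates,
        })
    return pd.DataFrame(out)
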