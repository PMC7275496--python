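"""The three-step workflow: probit, scale, and (gated) Box-Cox.

Step 1 (always): conditional probit on the increase indicator; gives the
transformation-invariant beta_c_hat.
Step 2 (always): estimate sigma_delta on the observed scale and report
beta_hat = sigma_hat * beta_c_hat; test residual normality (Lilliefors).
Step 3 (gated): if Step-2 residuals reject normality and the outcomes are
positive, profile a Box-Cox lambda jointly with the transformed-scale SD and
report beta_lambda_hat = sigma_lambda_hat * beta_c_hat.

The same beta_c_hat flows through all three steps without refitting: the
probit never sees the outcome values, only their within-subject ordering.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import __version__
from .boxcox import Step3Result, fit_step3
from .data import ObservationRecord, build_paired_dataset
from .exceptions import ConvergenceError, DomainError
from .probit import Step1Result, fit_step1
from .scale import Step2Result, fit_step2

__all__ = ["WorkflowReport", "run_workflow"]


@dataclass
class WorkflowReport:
    """Assembled result of the three-step workflow.

    ``recommended_scale`` is "observed" when the untransformed residuals look
    normal, "box_cox" when the transformation restored normality, and
    "none_adequate" when even the Box-Cox residuals reject — in which case a
    richer mean model (interactions, splines) should be considered rather
    than reporting beta_lambda_hat uncritically.
    """

    step1: Step1Result
    step2: Step2Result
    step3: Step3Result | None
    recommended_scale: str
    messages: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    tie_count: int = 0

    # ------------------------------------------------------------------ export
    def to_dict(self) -> dict:
        d = {
            "schema_version": 1,
            "metadata": self.metadata,
            "recommended_scale": self.recommended_scale,
            "tie_count": self.tie_count,
            "messages": list(self.messages),
            "step1": {
                "beta_c_hat": self.step1.beta_c_hat.tolist(),
                "se_beta_c": self.step1.se_beta_c.tolist(),
                "cov_beta_c": self.step1.cov_beta_c.tolist(),
                "converged": self.step1.converged,
                "separation_flag": self.step1.separation_flag,
                "loglik": self.step1.loglik,
                "covariates": list(self.step1.covariate_names),
            },
            "step2": {
                "sigma_delta_hat": self.step2.sigma_delta_hat,
                "beta_hat": self.step2.beta_hat.tolist(),
                "se_beta_hat": self.step2.se_beta_hat.tolist(),
                "ci_beta": self.step2.ci_beta.tolist(),
                "lilliefors_stat": self.step2.lilliefors_stat,
                "lilliefors_p": self.step2.lilliefors_p,
                "normality_ok": self.step2.normality_ok,
            },
            "step3": None,
        }
        if self.step3 is not None:
            s3 = self.step3
            d["step3"] = {
                "lambda_hat": s3.lambda_hat,
                "ci_lambda": [s3.ci_lambda[0], s3.ci_lambda[1]],
                "sigma_lambda_delta_hat": s3.sigma_lambda_delta_hat,
                "beta_lambda_hat": s3.beta_lambda_hat.tolist(),
                "se_beta_lambda": s3.se_beta_lambda.tolist(),
                "ci_beta_lambda": s3.ci_beta_lambda.tolist(),
                "lilliefors_stat": s3.lilliefors_stat,
                "lilliefors_p": s3.lilliefors_p,
                "normality_ok": s3.normality_ok,
                "at_boundary": s3.at_boundary,
            }
        return d

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, default=float)

    def to_text(self) -> str:
        """Human-readable summary table (6 significant digits)."""
        g = "{:.6g}".format
        names = self.step1.covariate_names or tuple(
            f"x{j}" for j in range(self.step1.beta_c_hat.size)
        )
        lines = ["Three-step conditional-probit workflow", "=" * 40]
        lines.append(f"Subjects analysed: {len(self.step2.residuals)}   ties dropped: {self.tie_count}")
        lines.append("")
        lines.append("Step 1: conditional probit (scale-free effect beta_c)")
        for j, nm in enumerate(names):
            lines.append(f"  {nm:<16} beta_c = {g(self.step1.beta_c_hat[j]):>10}  "
                         f"SE = {g(self.step1.se_beta_c[j])}")
        if self.step1.separation_flag:
            lines.append("  WARNING: separation detected; estimates unreliable")
        lines.append("")
        s2 = self.step2
        lines.append(f"Step 2: observed scale (sigma_delta_hat = {g(s2.sigma_delta_hat)})")
        for j, nm in enumerate(names):
            lines.append(f"  {nm:<16} beta = {g(s2.beta_hat[j]):>10}  SE = {g(s2.se_beta_hat[j])}  "
                         f"95% CI [{g(s2.ci_beta[j, 0])}, {g(s2.ci_beta[j, 1])}]")
        lines.append(f"  Lilliefors D = {g(s2.lilliefors_stat)}, p = {g(s2.lilliefors_p)} "
                     f"-> normality {'adequate' if s2.normality_ok else 'REJECTED'}")
        if self.step3 is not None:
            s3 = self.step3
            lines.append("")
            lines.append(f"Step 3: Box-Cox scale (lambda_hat = {g(s3.lambda_hat)}, "
                         f"95% CI [{g(s3.ci_lambda[0])}, {g(s3.ci_lambda[1])}]; "
                         f"sigma_lambda_delta_hat = {g(s3.sigma_lambda_delta_hat)})")
            for j, nm in enumerate(names):
                lines.append(f"  {nm:<16} beta_lambda = {g(s3.beta_lambda_hat[j]):>10}  "
                             f"SE = {g(s3.se_beta_lambda[j])}  "
                             f"95% CI [{g(s3.ci_beta_lambda[j, 0])}, {g(s3.ci_beta_lambda[j, 1])}]")
            lines.append(f"  Lilliefors D = {g(s3.lilliefors_stat)}, p = {g(s3.lilliefors_p)} "
                         f"-> normality {'adequate' if s3.normality_ok else 'REJECTED'}")
        lines.append("")
        lines.append(f"Recommended reporting scale: {self.recommended_scale}")
        for m in self.messages:
            lines.append(f"note: {m}")
        return "\n".join(lines)


def run_workflow(
    records: Sequence[ObservationRecord],
    covariate_names: Sequence[str] | None = None,
    *,
    drop_ties: bool = True,
    alpha_diag: float = 0.05,
    lambda_bounds: tuple = (-3.0, 3.0),
    force_step3: bool = False,
    enable_step3: bool = True,
    max_iter: int = 100,
    tol: float = 1e-8,
    seed=None,
) -> WorkflowReport:
    """Run the full three-step workflow on long-format records.

    Step 3 runs when Step-2 residuals reject normality at ``alpha_diag``
    (or always, with ``force_step3``), provided ``enable_step3`` and all raw
    outcomes are positive.  ``seed`` is recorded in the metadata only — the
    workflow itself is deterministic.
    """
    messages: list[str] = []
    data = build_paired_dataset(records, drop_ties=drop_ties, covariate_names=covariate_names)
    if data.tie_count:
        messages.append(f"dropped {data.tie_count} tied subject(s) with delta_y = 0")

    step1 = fit_step1(data, max_iter=max_iter, tol=tol)
    if not step1.converged:
        raise ConvergenceError(
            "Step-1 probit did not converge"
            + (" (separation detected: the increase indicator is perfectly predicted "
               "by the covariate differences)" if step1.separation_flag else "")
        )
    if step1.separation_flag:
        messages.append("separation heuristic triggered in Step 1; interpret SEs with caution")

    step2 = fit_step2(data, step1, alpha_diag=alpha_diag)
    messages.append(
        f"Step-2 Lilliefors p = {step2.lilliefors_p:.4g}: normality "
        f"{'adequate' if step2.normality_ok else 'rejected'} at alpha = {alpha_diag:g}"
    )

    step3 = None
    want_step3 = force_step3 or not step2.normality_ok
    if want_step3 and enable_step3:
        if np.any(data.raw_outcomes <= 0.0):
            bad = [data.subject_ids[i]
                   for i in np.nonzero((data.raw_outcomes <= 0).any(axis=1))[0][:10]]
            raise DomainError(
                "Step 3 (Box-Cox) requires strictly positive outcomes; "
                f"offending subject(s): {bad}"
            )
        step3 = fit_step3(data, step1, lambda_bounds=lambda_bounds, alpha_diag=alpha_diag)
        messages.append(
            f"Step 3 run ({'forced' if force_step3 and step2.normality_ok else 'gated'}): "
            f"lambda_hat = {step3.lambda_hat:.4g}, Lilliefors p = {step3.lilliefors_p:.4g}"
        )
    elif want_step3 and not enable_step3:
        messages.append(
            "WARNING: Step-2 residuals reject normality but Step 3 is disabled; "
            "the observed-scale estimate may be unreliable"
        )

    if step2.normality_ok:
        scale = "observed"
    elif step3 is not None:
        scale = "box_cox" if step3.normality_ok else "none_adequate"
        if scale == "none_adequate":
            messages.append(
                "Box-Cox did not restore residual normality; consider extending the mean "
                "model (interaction terms, splines) before reporting an effect estimate"
            )
    else:
        scale = "observed"

    metadata = {
        "software": f"cprobit {__version__}",
        "alpha_diag": alpha_diag,
        "lambda_bounds": [float(lambda_bounds[0]), float(lambda_bounds[1])],
        "jacobian_in_profile": True,
        "drop_ties": drop_ties,
        "force_step3": force_step3,
        "enable_step3": enable_step3,
        "seed": seed,
    }
    return WorkflowReport(
        step1=step1,
        step2=step2,
        step3=step3,
        recommended_scale=scale,
        messages=messages,
        metadata=metadata,
        tie_count=data.tie_count,
    )
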