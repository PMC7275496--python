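"""Box-Cox transform, profile likelihood and the Step-3 fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cprobit import (
    SimulationConfig,
    box_cox,
    build_paired_dataset,
    fit_step1,
    fit_step2,
    fit_step3,
    generate_study2,
    inverse_box_cox,
    profile_loglik_lambda,
)
from cprobit.boxcox import _jacobian_term
from cprobit.exceptions import DomainError
from cprobit.scale import estimate_sigma_delta


class TestTransform:
    def test_basic_values(self):
        assert box_cox(1.0, 2.0) == 0.0
        assert box_cox(4.0, 1.0) == 3.0
        assert box_cox(np.e, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_continuity_at_lambda_zero(self):
        assert abs(box_cox(np.e, 1e-8) - 1.0) < 1e-6

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            box_cox(-1.0, 0.5)
        with pytest.raises(DomainError):
            box_cox(0.0, 1.0)
        with pytest.raises(DomainError):
            inverse_box_cox(-3.0, 0.5)  # 0.5*(-3)+1 < 0

    def test_inverse_fixed_points(self):
        assert inverse_box_cox(0.0, 0.7) == pytest.approx(1.0)
        assert inverse_box_cox(0.0, 0.0) == pytest.approx(1.0)
        assert inverse_box_cox(1.0, 0.0) == pytest.approx(np.e)

    @settings(max_examples=1000, derandomize=True)
    @given(st.floats(-5, 5), st.one_of(st.just(0.0), st.floats(-2, -1e-3), st.floats(1e-3, 2)))
    def test_round_trip(self, z, lam):
        if lam != 0.0 and lam * z + 1.0 <= 1e-3:
            return  # ill-conditioned edge of the domain
        y = inverse_box_cox(z, lam)
        assert y > 0
        assert abs(box_cox(y, lam) - z) < 1e-10


@pytest.fixture
def boxcox_dataset():
    """n = 30 positive-outcome dataset generated at true lambda = 1/3."""
    cfg = SimulationConfig(n_subjects=30, beta=-0.4, true_lambda=1 / 3,
                           seed=42, n_replicates=1)
    return build_paired_dataset(generate_study2(cfg, 42))


class TestProfile:
    def test_reduces_to_step2_at_lambda_one(self, boxcox_dataset):
        d = boxcox_dataset
        s1 = fit_step1(d)
        s2 = fit_step2(d, s1)
        assert profile_loglik_lambda(1.0, d, s1) == pytest.approx(s2.loglik, rel=1e-12)

    def test_joint_grid_oracle(self, boxcox_dataset):
        """Profile maximum matches a brute-force (lambda, sigma) grid to 1e-4."""
        d = boxcox_dataset
        s1 = fit_step1(d)
        s3 = fit_step3(d, s1)
        eta = d.delta_x @ s1.beta_c_hat
        C = eta @ eta

        def grid_best(lams, sigmas):
            best = -np.inf
            for lam in lams:
                yt = box_cox(d.raw_outcomes, lam)
                dy = yt[:, 1] - yt[:, 0]
                A, B = dy @ dy, dy @ eta
                ll = (-d.n_subjects * np.log(sigmas) - A / (2 * sigmas**2)
                      + B / sigmas - C / 2 + _jacobian_term(d, lam))
                best = max(best, ll.max())
            return best

        coarse = grid_best(np.arange(-3, 3.001, 0.01), np.logspace(-3, 3, 3000))
        lh = s3.lambda_hat
        fine = grid_best(np.arange(lh - 0.05, lh + 0.05, 1e-3),
                         np.logspace(np.log10(s3.sigma_lambda_delta_hat) - 0.5,
                                     np.log10(s3.sigma_lambda_delta_hat) + 0.5, 100_000))
        assert s3.profile_loglik_at_max >= coarse - 1e-4
        assert s3.profile_loglik_at_max == pytest.approx(fine, abs=1e-4)

    def test_maximum_dominates_601_point_grid(self, boxcox_dataset):
        d = boxcox_dataset
        s1 = fit_step1(d)
        s3 = fit_step3(d, s1)
        grid = np.linspace(-3, 3, 601)
        vals = [profile_loglik_lambda(l, d, s1) for l in grid]
        assert s3.profile_loglik_at_max >= max(vals) - 1e-9


class TestFitStep3:
    def test_degenerate_bounds_reduce_to_step2(self, boxcox_dataset):
        d = boxcox_dataset
        s1 = fit_step1(d)
        s2 = fit_step2(d, s1)
        s3 = fit_step3(d, s1, lambda_bounds=(1.0, 1.0))
        np.testing.assert_allclose(s3.beta_lambda_hat, s2.beta_hat, rtol=1e-12)
        np.testing.assert_allclose(s3.sigma_lambda_delta_hat, s2.sigma_delta_hat, rtol=1e-12)
        assert s3.ci_lambda == (1.0, 1.0)

    def test_ordering_invariance_across_lambda(self, boxcox_dataset):
        d = boxcox_dataset
        raw_I = d.increase_indicator
        for lam in np.linspace(-3, 3, 13):
            yt = box_cox(d.raw_outcomes, lam)
            np.testing.assert_array_equal((yt[:, 1] > yt[:, 0]).astype(int), raw_I)

    def test_plugin_identities(self, boxcox_dataset):
        d = boxcox_dataset
        s1 = fit_step1(d)
        s3 = fit_step3(d, s1)
        np.testing.assert_array_equal(
            s3.beta_lambda_hat, s3.sigma_lambda_delta_hat * s1.beta_c_hat)
        assert -3.0 <= s3.lambda_hat <= 3.0
        lo, hi = s3.ci_lambda
        assert lo <= s3.lambda_hat <= hi

    def test_profile_ci_contains_wald_point(self, boxcox_dataset):
        d = boxcox_dataset
        s1 = fit_step1(d)
        s3 = fit_step3(d, s1, ci_method="profile")
        lo, hi = s3.ci_lambda
        assert lo < s3.lambda_hat < hi

    def test_nonpositive_outcome_raises(self, boxcox_dataset):
        d = boxcox_dataset
        bad = d.raw_outcomes.copy()
        bad[3, 0] = -0.5
        from dataclasses import replace

        d_bad = replace(d, raw_outcomes=bad)
        s1 = fit_step1(d)
        with pytest.raises(DomainError, match="positive"):
            fit_step3(d_bad, s1)

    @pytest.mark.parametrize("true_lambda, tol", [(0.0, 0.05), (1.0, 0.12)])
    def test_lambda_recovery(self, true_lambda, tol):
        """Mean lambda_hat over replicates lands near the generating value."""
        lams = []
        for rep in range(40):
            cfg = SimulationConfig(n_subjects=600, beta=-0.06, true_lambda=true_lambda,
                                   seed=7_000 + rep, n_replicates=1)
            d = build_paired_dataset(generate_study2(cfg, 7_000 + rep))
            s1 = fit_step1(d)
            lams.append(fit_step3(d, s1).lambda_hat)
        assert abs(np.mean(lams) - true_lambda) < tol

    def test_sigma_inner_maximizer_consistency(self, boxcox_dataset):
        d = boxcox_dataset
        s1 = fit_step1(d)
        s3 = fit_step3(d, s1)
        eta = d.delta_x @ s1.beta_c_hat
        yt = box_cox(d.raw_outcomes, s3.lambda_hat)
        dy = yt[:, 1] - yt[:, 0]
        assert s3.sigma_lambda_delta_hat == pytest.approx(
            estimate_sigma_delta(dy, eta), rel=1e-10)
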