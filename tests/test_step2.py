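"""Scale estimation, plug-in effect, and the Lilliefors diagnostic."""

import subprocess

import numpy as np
import pytest
from scipy.special import ndtr

from cprobit import (
    build_paired_dataset,
    estimate_sigma_delta,
    fit_step1,
    fit_step2,
    lilliefors_test,
)
from cprobit.exceptions import DegenerateSampleError, InsufficientDataError
from cprobit.scale import sigma_profile_loglik
from conftest import make_records


class TestEstimateSigmaDelta:
    def test_closed_form_when_eta_zero(self, rng):
        dy = rng.normal(size=25)
        s = estimate_sigma_delta(dy, np.zeros(25))
        assert s == pytest.approx(np.sqrt(np.mean(dy**2)), rel=1e-9)

    def test_grid_search_oracle(self, rng):
        """Agrees with a 1e6-point log-spaced grid to relative 1e-5."""
        n = 20
        eta = rng.normal(size=n)
        dy = 2.5 * eta + rng.normal(size=n)
        s = estimate_sigma_delta(dy, eta)
        grid = np.logspace(-3, 3, 1_000_000)
        A, B = dy @ dy, dy @ eta
        ll = -n * np.log(grid) - A / (2 * grid**2) + B / grid
        best = grid[np.argmax(ll)]
        assert s == pytest.approx(best, rel=1e-5)
        # the returned value dominates the whole grid
        assert sigma_profile_loglik(s, dy, eta) >= ll.max() - eta @ eta / 2 - 1e-10

    def test_stationarity_and_analytic_root(self, rng):
        n = 40
        eta = rng.normal(size=n)
        dy = 1.3 * eta + rng.normal(size=n)
        s = estimate_sigma_delta(dy, eta)
        A, B = dy @ dy, dy @ eta
        score = -n / s + A / s**3 - B / s**2
        assert abs(score) <= 1e-8
        root = (-B + np.sqrt(B**2 + 4 * n * A)) / (2 * n)  # positive root of n s^2 + B s - A
        assert s == pytest.approx(root, rel=1e-9)

    def test_positive_scaling_equivariance(self, rng):
        dy = rng.normal(size=30)
        eta = rng.normal(size=30)
        s1 = estimate_sigma_delta(dy, eta)
        s3 = estimate_sigma_delta(3.0 * dy, eta)
        assert s3 == pytest.approx(3.0 * s1, rel=1e-9)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            estimate_sigma_delta([1.0], [0.0])
        with pytest.raises(DegenerateSampleError):
            estimate_sigma_delta([0.0, 0.0], [1.0, 1.0])


class TestLilliefors:
    def test_near_perfect_normal_sample(self):
        from scipy.stats import norm

        q = norm.ppf((np.arange(1, 101) - 0.5) / 100)
        stat, p = lilliefors_test(q)
        assert p > 0.5

    def test_gross_non_normality(self, rng):
        x = rng.exponential(1.0, size=500)
        _, p = lilliefors_test(x)
        assert p < 0.001

    def test_statistic_matches_direct_formula(self, rng):
        x = np.array([0.31, -1.2, 0.05, 2.4, -0.7, 1.1, 0.0, -0.4, 0.9, -2.2])
        stat, _ = lilliefors_test(x)
        z = np.sort((x - x.mean()) / x.std(ddof=1))
        F = ndtr(z)
        n = x.size
        d_plus = np.max(np.arange(1, n + 1) / n - F)
        d_minus = np.max(F - np.arange(0, n) / n)
        assert stat == pytest.approx(max(d_plus, d_minus), abs=1e-10)

    def test_matches_r_nortest(self, rng):
        """Same statistic and p-value as nortest::lillie.test (the reference tool)."""
        x = rng.exponential(1.0, size=60)  # clearly non-normal: p in the DW regime
        stat, p = lilliefors_test(x)
        rcode = (
            "x <- c(%s); r <- nortest::lillie.test(x); "
            'cat(sprintf("%%.15g %%.15g", r$statistic, r$p.value))'
            % ",".join(repr(float(v)) for v in x))
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True, check=True)
        r_stat, r_p = map(float, out.stdout.split())
        assert stat == pytest.approx(r_stat, abs=1e-10)
        assert p == pytest.approx(r_p, rel=1e-4, abs=1e-6)

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            lilliefors_test([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateSampleError):
            lilliefors_test([2.0] * 10)


def _simulate_fit(rng, n=200, beta=0.5):
    x = rng.standard_normal(n)
    y1 = 5.0 + rng.standard_normal(n)
    y2 = y1 + beta * x + rng.standard_normal(n)
    d = build_paired_dataset(make_records(y1, y2, covs1=np.zeros((n, 1)), covs2=x[:, None]))
    s1 = fit_step1(d)
    return d, s1, fit_step2(d, s1)


class TestFitStep2:
    def test_plugin_identities_and_ci(self, rng):
        d, s1, s2 = _simulate_fit(rng)
        np.testing.assert_array_equal(s2.beta_hat, s2.sigma_delta_hat * s1.beta_c_hat)
        np.testing.assert_array_equal(s2.se_beta_hat, s2.sigma_delta_hat * s1.se_beta_c)
        assert np.all(s2.ci_beta[:, 0] < s2.beta_hat) and np.all(s2.beta_hat < s2.ci_beta[:, 1])
        assert s2.residuals.shape == (d.n_subjects,)
        np.testing.assert_allclose(
            s2.residuals, d.delta_y - s2.sigma_delta_hat * (d.delta_x @ s1.beta_c_hat))

    def test_zero_coefficient_scales_to_zero(self, rng):
        d, s1, _ = _simulate_fit(rng)
        s1.beta_c_hat = np.zeros_like(s1.beta_c_hat)
        s2 = fit_step2(d, s1)
        np.testing.assert_array_equal(s2.beta_hat, np.zeros_like(s2.beta_hat))

    def test_outcome_scaling_equivariance(self, rng):
        n = 120
        x = rng.standard_normal(n)
        y1 = 5.0 + rng.standard_normal(n)
        y2 = y1 + 0.5 * x + rng.standard_normal(n)
        c = 7.0
        r1 = None
        for scale in (1.0, c):
            recs = make_records(scale * y1, scale * y2,
                                covs1=np.zeros((n, 1)), covs2=x[:, None])
            d = build_paired_dataset(recs)
            s1 = fit_step1(d)
            s2 = fit_step2(d, s1)
            if r1 is None:
                r1 = (s1, s2)
            else:
                np.testing.assert_array_equal(s1.beta_c_hat, r1[0].beta_c_hat)
                assert s2.sigma_delta_hat == pytest.approx(c * r1[1].sigma_delta_hat, rel=1e-9)
                np.testing.assert_allclose(s2.beta_hat, c * r1[1].beta_hat, rtol=1e-9)
                assert s2.lilliefors_p == pytest.approx(r1[1].lilliefors_p, abs=1e-10)

    def test_effect_recovery_over_replicates(self):
        """Mean of beta_hat across replicates stays within 3 MC SEs of truth."""
        beta = -0.06
        ests = []
        for rep in range(300):
            rng = np.random.default_rng(900 + rep)
            _, _, s2 = _simulate_fit(rng, n=300, beta=beta)
            ests.append(s2.beta_hat[0])
        ests = np.asarray(ests)
        mc_se = ests.std(ddof=1) / np.sqrt(ests.size)
        assert abs(ests.mean() - beta) < 3 * mc_se

    def test_null_lilliefors_rejection_rate(self):
        """On exactly-normal differences the 5%-level gate fires ~5% of the time."""
        rejections = 0
        reps = 1000
        for rep in range(reps):
            rng = np.random.default_rng(5_000 + rep)
            _, _, s2 = _simulate_fit(rng, n=100, beta=0.3)
            rejections += not s2.normality_ok
        rate = rejections / reps
        assert 0.03 <= rate <= 0.07
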