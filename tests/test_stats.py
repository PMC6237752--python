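"""Poisson fitting, zero-class deficit, Welch tests and summaries."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from halofoci import (
    fit_poisson,
    summarize_diameters,
    welch_ttest,
    zero_class_deficit,
)
from halofoci.stats import poisson_gof, p_to_stars, replicate_summary


class TestFitPoisson:
    def test_constant_counts_mle_is_value(self):
        fit = fit_poisson([3] * 20, method="mle_full", n_bootstrap=10)
        assert fit.lambda_hat == 3.0

    def test_small_sample_mle_is_mean(self):
        fit = fit_poisson([1, 2, 3, 4], method="mle_full", n_bootstrap=10)
        assert fit.lambda_hat == 2.5

    def test_sampled_lambda_recovered_within_clt_bound(self):
        rng = np.random.default_rng(123)
        counts = rng.poisson(2.76, size=391)
        fit = fit_poisson(counts, method="mle_full", n_bootstrap=50, seed=1)
        assert abs(fit.lambda_hat - 2.76) <= 3 * math.sqrt(2.76 / 391)

    def test_histogram_ls_close_to_mle_on_large_sample(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(3.0, size=20000)
        full = fit_poisson(counts, method="mle_full", n_bootstrap=10, seed=1)
        ls = fit_poisson(
            counts, support=(0, 12), method="histogram_ls", n_bootstrap=10, seed=1
        )
        assert ls.lambda_hat == pytest.approx(full.lambda_hat, rel=0.02)

    def test_truncated_mle_close_to_full_for_moderate_lambda(self):
        rng = np.random.default_rng(6)
        counts = rng.poisson(2.76, size=5000)
        full = fit_poisson(counts, method="mle_full", n_bootstrap=10, seed=1)
        trunc = fit_poisson(counts, method="mle_truncated", n_bootstrap=10, seed=1)
        assert trunc.lambda_hat == pytest.approx(full.lambda_hat, rel=0.05)

    def test_truncated_mle_exact_inversion(self):
        # mean of positives determines lambda through m = lam/(1-exp(-lam))
        lam = 1.7
        m = lam / (1 - math.exp(-lam))
        rng = np.random.default_rng(0)
        counts = rng.poisson(lam, size=200000)
        fit = fit_poisson(counts, method="mle_truncated", n_bootstrap=2, seed=0)
        assert fit.lambda_hat == pytest.approx(lam, abs=0.05)
        assert m > 1.0

    def test_all_zero_truncated_rejected(self):
        with pytest.raises(ValueError):
            fit_poisson([0, 0, 0], method="mle_truncated", n_bootstrap=5)

    def test_bootstrap_stderr_matches_asymptotics(self):
        rng = np.random.default_rng(11)
        counts = rng.poisson(2.5, size=1000)
        fit = fit_poisson(counts, method="mle_full", n_bootstrap=500, seed=3)
        assert fit.stderr == pytest.approx(math.sqrt(2.5 / 1000), rel=0.15)

    def test_zero_fraction_fields(self):
        counts = [0] * 10 + [2] * 90
        fit = fit_poisson(counts, method="mle_full", n_bootstrap=5)
        assert fit.observed_zero_fraction == 0.10
        assert fit.expected_zero_fraction == pytest.approx(math.exp(-1.8))


class TestZeroClassDeficit:
    def test_expected_zero_fraction_closed_form(self):
        counts = [1, 2, 3]
        fit = fit_poisson(counts, method="mle_full", n_bootstrap=5)
        fit.lambda_hat = math.log(2)
        _, expected, _ = zero_class_deficit(counts, fit)
        assert expected == pytest.approx(0.5)

    def test_no_zeros_highly_significant(self):
        counts = [2] * 100
        fit = fit_poisson(counts, method="mle_full", n_bootstrap=5)
        obs, exp, p = zero_class_deficit(counts, fit)
        assert obs == 0.0
        assert exp == pytest.approx(math.exp(-2), abs=1e-12)
        # exact binomial: P(0 zeros | n=100, p=exp(-2)) = (1-exp(-2))^100
        assert p == pytest.approx((1 - math.exp(-2)) ** 100, rel=1e-9)
        assert p < 0.001

    def test_calibration_under_the_null(self):
        """On Poisson data the one-sided test rejects at most ~alpha."""
        rng = np.random.default_rng(2718)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            counts = rng.poisson(2.0, size=200)
            fit = fit_poisson(counts, method="mle_full", n_bootstrap=0)
            _, _, p = zero_class_deficit(counts, fit)
            rejections += p < 0.05
        assert rejections / n_rep < 0.09


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == 1.0

    def test_textbook_hand_computation(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 3, 4, 5, 6])
        t, df, p = welch_ttest(x, y)
        sx2, sy2 = x.var(ddof=1), y.var(ddof=1)
        se = math.sqrt(sx2 / 5 + sy2 / 5)
        t_hand = (x.mean() - y.mean()) / se
        df_hand = (sx2 / 5 + sy2 / 5) ** 2 / (
            (sx2 / 5) ** 2 / 4 + (sy2 / 5) ** 2 / 4
        )
        p_hand = 2 * sps.t.sf(abs(t_hand), df_hand)
        assert t == pytest.approx(t_hand, abs=1e-6)
        assert df == pytest.approx(df_hand, abs=1e-6)
        assert p == pytest.approx(p_hand, abs=1e-6)

    def test_swap_negates_t_preserves_p(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 2, 25)
        t1, _, p1 = welch_ttest(x, y)
        t2, _, p2 = welch_ttest(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            welch_ttest([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_ttest([1.0, 1.0], [2.0, 2.0])

    def test_stars(self):
        assert p_to_stars(0.3) == "ns"
        assert p_to_stars(0.03) == "*"
        assert p_to_stars(0.003) == "**"
        assert p_to_stars(3e-4) == "***"
        assert p_to_stars(3e-5) == "****"


class TestSummaries:
    def test_single_value_degenerate(self):
        s = summarize_diameters([150.0])
        assert s.mean == 150.0
        assert s.ci95 == (150.0, 150.0)
        assert list(s.cdf) == [1.0]

    def test_truncated_normal_mean_recovered(self):
        a, b = (50 - 150) / 40, (300 - 150) / 40
        dist = sps.truncnorm(a, b, loc=150, scale=40)
        rng = np.random.default_rng(4)
        draws = dist.rvs(size=1000, random_state=rng)
        s = summarize_diameters(draws)
        se = dist.std() / math.sqrt(1000)
        assert abs(s.mean - dist.mean()) < 3 * se
        assert s.ci95[0] < dist.mean() < s.ci95[1]

    def test_cdf_non_decreasing_ends_at_one(self):
        rng = np.random.default_rng(5)
        s = summarize_diameters(rng.uniform(50, 300, 77))
        assert np.all(np.diff(s.cdf) >= 0)
        assert s.cdf[-1] == 1.0
        assert np.all(np.diff(s.sorted_values) >= 0)

    def test_ci_formula(self):
        vals = np.array([100.0, 120, 140, 160, 180])
        s = summarize_diameters(vals)
        half = sps.t.ppf(0.975, 4) * vals.std(ddof=1) / math.sqrt(5)
        assert s.ci95 == pytest.approx((vals.mean() - half, vals.mean() + half))

    def test_replicate_summary(self):
        out = replicate_summary([[1.0, 2.0], [3.0, 5.0], [2.0, 2.0]])
        assert out["replicate_means"] == [1.5, 4.0, 2.0]
        assert out["grand_mean"] == pytest.approx(2.5)


class TestPoissonGof:
    def test_accepts_true_poisson(self):
        rng = np.random.default_rng(6)
        chi2, df, p = poisson_gof(rng.poisson(2.76, 1000))
        assert p > 0.01

    def test_rejects_clearly_non_poisson(self):
        counts = np.array([0] * 500 + [6] * 500)
        _, _, p = poisson_gof(counts)
        assert p < 1e-6
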