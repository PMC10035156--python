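"""Priors, MCMC fitting contract, posterior summaries, and prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agbgrowth import (DataError, FitResult, GrowthParams, MCMCConfig, PFT,
                       PosteriorSample, PriorSpec, TruthSpec, fit,
                       is_significant, log_prior, normalize_climate,
                       posterior_predict, simulate_records, summarize)
from conftest import make_sample


class TestLogPrior:
    def scipy_oracle(self, params, prior=PriorSpec()):
        lp = stats.norm.logpdf(params.beta_mu[0], 200.0, 1e3)
        lp += stats.norm.logpdf(params.beta_r[0], 2.0, 1e3)
        for s in (*params.beta_mu[1:], *params.beta_r[1:]):
            lp += stats.norm.logpdf(s, 0.0, 1e3)
        lp += stats.invgamma.logpdf(params.sigma ** 2, 1.0, scale=1.0)
        return lp

    def test_matches_density_oracle_on_random_params(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            p = GrowthParams(tuple(rng.normal(300, 200, 3)),
                             tuple(rng.normal(5, 3, 3)),
                             float(rng.uniform(0.05, 3.0)))
            assert log_prior(p) == pytest.approx(self.scipy_oracle(p), abs=1e-10)

    def test_prior_mode_at_normal_means(self):
        # each Normal term is maximized at its mean; inv-Gamma(1,1) at
        # sigma^2 = 1 contributes density e^-1
        at_mode = GrowthParams((200.0, 0, 0), (2.0, 0, 0), 1.0)
        shifted = GrowthParams((210.0, 0, 0), (2.0, 0, 0), 1.0)
        assert log_prior(at_mode) > log_prior(shifted)
        assert self.scipy_oracle(at_mode) - 6 * stats.norm.logpdf(0, 0, 1e3) \
            == pytest.approx(-1.0, abs=1e-12)

    def test_gaussian_quadratic_shift(self):
        base = GrowthParams((200.0, 0, 0), (2.0, 0, 0), 1.0)
        moved = GrowthParams((1200.0, 0, 0), (2.0, 0, 0), 1.0)
        assert log_prior(moved) - log_prior(base) == pytest.approx(-0.5, abs=1e-12)

    def test_invalid_sigma_unrepresentable(self):
        with pytest.raises(ValueError):
            GrowthParams((200.0, 0, 0), (2.0, 0, 0), 0.0)


class TestFitContract:
    def test_same_seed_bit_identical_draws(self, bd_data, fast_config):
        a = fit(bd_data, config=fast_config, check_convergence=False)
        b = fit(bd_data, config=fast_config, check_convergence=False)
        assert np.array_equal(a.draws, b.draws)

    def test_tiny_dataset_rejected(self, bd_data):
        with pytest.raises(DataError):
            fit(bd_data.subset(range(5)))

    def test_mixed_pft_rejected(self):
        data = simulate_records(TruthSpec(
            n={PFT.BROADLEAF_DECIDUOUS: 20, PFT.BROADLEAF_EVERGREEN: 20}, seed=1))
        with pytest.raises(DataError):
            fit(data)

    def test_converged_fit_covers_truth(self, bd_data):
        """A full-length fit on known-truth data meets the R-hat/ESS
        contract and its 95% intervals cover most generating parameters."""
        spec = TruthSpec.single("bd", 1000, seed=21)
        data = simulate_records(spec)
        sample = fit(data, config=MCMCConfig(chains=4, iterations=3000, seed=2))
        assert sample.converged
        assert sample.max_rhat < 1.01 and sample.min_ess > 400
        table = summarize(sample).table
        truth = spec.params[PFT.BROADLEAF_DECIDUOUS].as_vector()
        covered = sum(
            bool(table.iloc[j]["q2_5"] <= truth[j] <= table.iloc[j]["q97_5"])
            for j in range(7))
        assert covered >= 6

    def test_posterior_interval_width_shrinks_with_n(self):
        """95% CI of the saturation intercept narrows as n grows (averaged
        over seeds)."""
        widths = []
        for n in (200, 1000, 5000):
            acc = []
            for seed in range(5):
                data = simulate_records(TruthSpec.single("bd", n, seed=100 + seed))
                sample = fit(data, config=MCMCConfig(chains=2, iterations=800,
                                                     seed=seed),
                             check_convergence=False)
                t = summarize(sample).table.loc["beta_mu_0"]
                acc.append(t["q97_5"] - t["q2_5"])
            widths.append(np.mean(acc))
        assert widths[0] > widths[1] > widths[2]

    def test_prior_only_sampling_recovers_prior(self, bd_data):
        """With the likelihood switched off the sampler reproduces the prior:
        Normal component means within 3 Monte-Carlo SE, and the sigma^2
        median near the inv-Gamma(1,1) median 1/ln 2."""
        sample = fit(bd_data.subset(range(10)), prior_only=True,
                     config=MCMCConfig(chains=4, iterations=4000, seed=3),
                     check_convergence=False)
        res = summarize(sample)
        flat = sample.flat()
        for j, (name, mean) in enumerate([("beta_mu_0", 200.0), ("beta_r_0", 2.0),
                                          ("beta_mu_1", 0.0), ("beta_r_2", 0.0)]):
            idx = list(sample.param_names).index(name)
            x = flat[:, idx]
            ess = max(float(res.table.loc[name, "ess"]), 10.0)
            se = x.std() / np.sqrt(ess)
            assert abs(x.mean() - mean) < 3 * se
            assert x.std() == pytest.approx(1e3, rel=0.15)
        sigma2 = flat[:, 6] ** 2
        assert np.median(sigma2) == pytest.approx(1 / np.log(2), rel=0.2)


class TestSummarize:
    def test_degenerate_sample_collapses(self, degenerate_sample):
        t = summarize(degenerate_sample).table
        row = t.loc["beta_mu_0"]
        assert row["mean"] == row["median"] == row["q2_5"] == row["q97_5"] == 400.0

    def test_quantiles_match_sorted_array_oracle(self):
        rng = np.random.default_rng(17)
        draws = rng.normal(5.0, 2.0, size=(50_000, 2, 7))
        draws[..., 6] = np.abs(draws[..., 6]) + 0.01
        t = summarize(PosteriorSample(draws)).table
        flat = draws.reshape(-1, 7)
        for j, name in enumerate(t.index):
            x = np.sort(flat[:, j])
            for q, col in ((0.025, "q2_5"), (0.5, "median"), (0.975, "q97_5")):
                # linear-interpolation order statistic
                h = (x.size - 1) * q
                lo = int(np.floor(h))
                ref = x[lo] + (h - lo) * (x[min(lo + 1, x.size - 1)] - x[lo])
                assert t.loc[name, col] == pytest.approx(ref, abs=1e-10)

    def test_original_scale_columns_rescale_slopes(self, truths):
        p = truths[PFT.BROADLEAF_DECIDUOUS].as_vector()
        t = summarize(make_sample(p)).table
        assert t.loc["beta_mu_1", "mean_orig"] == pytest.approx(-0.2122)
        assert t.loc["beta_mu_2", "mean_orig"] == pytest.approx(19.0471)
        assert t.loc["beta_mu_0", "mean_orig"] == pytest.approx(393.55)


class TestSignificance:
    def result_with_ci(self, lo, hi):
        table = pd.DataFrame({"q2_5": [lo], "q97_5": [hi]},
                             index=pd.Index(["beta_r_1"], name="parameter"))
        return FitResult(table=table, n=100)

    @pytest.mark.parametrize("lo,hi,expected", [
        (-0.0005, 0.0001, False),   # interval straddles zero
        (0.0062, 0.0079, True),     # wholly positive
        (-1.0, 1.0, False),
        (-0.0729, -0.0043, True),   # wholly negative
    ])
    def test_interval_rule(self, lo, hi, expected):
        assert is_significant(self.result_with_ci(lo, hi), "beta_r_1") is expected

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValueError):
            is_significant(self.result_with_ci(0, 1), "beta_x")


class TestPosteriorPredict:
    def test_degenerate_sample_is_point_prediction(self, degenerate_sample, z0):
        pred = posterior_predict(degenerate_sample, 50.0, z0, interval=0.8)
        assert pred.agb_median == pytest.approx(400.0 * 50 / 150)
        assert pred.agb_lower == pred.agb_upper == pred.agb_median
        assert pred.rate_median == pytest.approx(4.0 / 1.5 ** 2)

    def test_negative_draws_truncated_to_zero(self, z0):
        # half the draws have r < 0 -> they contribute y = 0, not negative
        draws = np.tile([400.0, 0, 0, 4.0, 0, 0, 0.5], (100, 2, 1))
        draws[:50, :, 3] = -2.0
        pred = posterior_predict(PosteriorSample(draws), 50.0, z0)
        values = sorted([0.0, 400.0 * 50 / 150])
        assert pred.agb_lower == 0.0
        assert pred.agb_upper == pytest.approx(values[1])

    def test_median_matches_per_draw_oracle(self, z0):
        from agbgrowth import monod_agb
        rng = np.random.default_rng(3)
        draws = rng.normal([400, -20, 30, 5, 1, -0.5, 0],
                           [50, 10, 10, 1, 0.5, 0.2, 0], size=(1000, 1, 7))
        draws[..., 6] = 0.5
        sample = PosteriorSample(draws)
        pred = posterior_predict(sample, 40.0, z0)
        flat = sample.flat()
        ys = [monod_agb(max(d[0], 0.0), max(d[3], 0.0), 40.0) for d in flat]
        assert pred.agb_median == np.median(ys)

    def test_median_curve_monotone_in_age(self, z0):
        sample = make_sample([400.0, -20.0, 30.0, 4.0, 0.5, -0.2, 0.5],
                             n_draws=200, jitter=1.0, seed=8)
        meds = [posterior_predict(sample, a, z0).agb_median
                for a in np.linspace(0, 200, 30)]
        assert all(b >= a - 1e-9 for a, b in zip(meds, meds[1:]))

    def test_invalid_inputs_rejected(self, degenerate_sample, z0):
        with pytest.raises(ValueError):
            posterior_predict(degenerate_sample, -1.0, z0)
        with pytest.raises(ValueError):
            posterior_predict(degenerate_sample, 10.0, z0, interval=1.5)
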