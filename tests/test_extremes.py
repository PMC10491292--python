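"""GEV primitives, MLE fits, model selection and return periods."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from heatlimits.extremes import (
    NonstationaryGEV,
    StationaryGEV,
    classify_return_periods,
    compute_return_period_table,
    gev_cdf,
    gev_pdf,
    gev_ppf,
    ks_test,
    llr_test,
    return_period,
)


def gev_sample(rng, loc, sigma, xi, n=None):
    size = n if n is not None else np.shape(loc)
    return gev_ppf(rng.uniform(size=size), loc, sigma, xi)


class TestGEVPrimitives:
    def test_gumbel_closed_form_at_location(self):
        assert gev_cdf(5.0, 5.0, 2.0, 0.0) == pytest.approx(np.exp(-1.0))

    def test_bounded_tail_saturates_at_one(self):
        # xi < 0: finite upper endpoint mu - sigma/xi
        endpoint = 10.0 - 2.0 / (-0.2)
        assert gev_cdf(endpoint + 1.0, 10.0, 2.0, -0.2) == 1.0
        assert gev_pdf(endpoint + 1.0, 10.0, 2.0, -0.2) == 0.0

    def test_cdf_matches_scipy_genextreme(self):
        # scipy's shape c is the negative of the convention used here
        x = np.linspace(-5, 25, 50)
        for xi in (-0.3, -0.1, 0.15):
            np.testing.assert_allclose(
                gev_cdf(x, 8.0, 2.0, xi),
                stats.genextreme.cdf(x, -xi, loc=8.0, scale=2.0),
                atol=1e-12,
            )

    def test_cdf_increments_match_density_quadrature(self):
        mu, sigma, xi = 5.0, 1.5, -0.1
        grid = np.linspace(2.0, 12.0, 11)
        for a, b in zip(grid[:-1], grid[1:]):
            quad, _ = integrate.quad(lambda x: gev_pdf(x, mu, sigma, xi), a, b,
                                     epsabs=1e-12)
            inc = gev_cdf(b, mu, sigma, xi) - gev_cdf(a, mu, sigma, xi)
            assert inc == pytest.approx(quad, abs=1e-8)

    def test_gumbel_continuity_at_tiny_shape(self):
        x = np.linspace(-5, 25, 200)
        gumbel = np.exp(-np.exp(-(x - 8.0) / 2.0))
        np.testing.assert_allclose(gev_cdf(x, 8.0, 2.0, 1e-8), gumbel, atol=1e-6)

    def test_ppf_round_trips_through_cdf(self):
        for xi in (-0.2, 0.0, 0.2):
            q = np.linspace(0.01, 0.99, 25)
            x = gev_ppf(q, 3.0, 1.2, xi)
            np.testing.assert_allclose(gev_cdf(x, 3.0, 1.2, xi), q, atol=1e-12)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            gev_cdf(0.0, 0.0, -1.0, 0.1)


class TestStationaryFit:
    def test_gumbel_parameters_recovered_at_n_1000(self, rng):
        y = gev_sample(rng, 10.0, 2.0, 0.0, n=1000)
        m = StationaryGEV().fit(y)
        assert abs(m.loc_ - 10.0) < 0.3
        assert abs(m.scale_ - 2.0) < 0.3
        assert abs(m.shape_) < 0.1

    def test_likelihood_at_optimum_dominates_truth(self, rng):
        from heatlimits.extremes import _gev_negloglik

        y = gev_sample(rng, 5.0, 1.0, -0.1, n=200)
        m = StationaryGEV().fit(y)
        ll_truth = -_gev_negloglik(np.array([5.0, 1.0, -0.1]), y, None)
        assert m.log_likelihood_ >= ll_truth - 1e-6

    def test_small_sample_refused(self):
        with pytest.raises(ValueError, match="n_min"):
            StationaryGEV(n_min=20).fit(np.arange(5.0))

    def test_return_level_round_trips(self, rng):
        y = gev_sample(rng, 5.0, 1.0, -0.1, n=100)
        m = StationaryGEV().fit(y)
        x50 = m.return_level(50.0)
        assert m.cdf(x50) == pytest.approx(1.0 - 1.0 / 50.0, abs=1e-12)


class TestKS:
    def test_self_consistent_samples_pass_at_high_rate(self):
        # parametric-fit KS is conservative: pass rate well above 1 - alpha
        rng = np.random.default_rng(3)
        passed = 0
        for _ in range(500):
            y = gev_sample(rng, 5.0, 1.0, -0.1, n=200)
            m = StationaryGEV().fit(y)
            passed += ks_test(y, m).passed
        assert passed / 500 >= 0.90

    def test_gross_misfit_detected(self, rng):
        y = gev_sample(rng, 5.0, 1.0, -0.1, n=200)
        m = StationaryGEV().fit(y)
        far = rng.normal(50.0, 0.5, size=200)
        assert not ks_test(far, m).passed

    def test_quantile_matched_sample_has_tiny_statistic(self):
        m = StationaryGEV.__new__(StationaryGEV)
        m.loc_, m.scale_, m.shape_ = 5.0, 1.0, -0.1
        n = 100
        y = m.ppf((np.arange(1, n + 1) - 0.5) / n)
        assert ks_test(y, m).statistic < 1.0 / n


class TestNonstationaryFit:
    def test_trendless_data_gives_near_zero_slope(self, rng):
        cov = np.linspace(0, 1, 300)
        y = gev_sample(rng, 5.0, 1.0, -0.1, n=300)
        m = NonstationaryGEV().fit(cov, y)
        assert abs(m.a2_) < 0.5
        assert m.log_likelihood_ == pytest.approx(
            m.stationary_.log_likelihood_, abs=2.0
        )

    def test_parameter_recovery_on_500_year_ramp(self, rng):
        # tolerances ~4x the replicate spread of this experiment
        cov = np.linspace(0.0, 1.5, 500)
        y = gev_sample(rng, 5.0 + 3.0 * cov, 1.0, -0.1)
        m = NonstationaryGEV().fit(cov, y)
        assert abs(m.a1_ - 5.0) < 0.35
        assert abs(m.a2_ - 3.0) < 0.45
        assert abs(m.scale_ - 1.0) < 0.14
        assert abs(m.shape_ + 0.1) < 0.13

    def test_nested_likelihood_ordering(self, rng):
        for _ in range(10):
            cov = np.linspace(0, 1, 60)
            y = gev_sample(rng, 5.0 + rng.uniform(0, 2) * cov, 1.0, -0.1)
            m = NonstationaryGEV().fit(cov, y)
            assert m.log_likelihood_ >= m.stationary_.log_likelihood_ - 1e-9

    def test_constant_covariate_rejected(self, rng):
        y = gev_sample(rng, 5.0, 1.0, -0.1, n=50)
        with pytest.raises(ValueError, match="constant"):
            NonstationaryGEV().fit(np.ones(50), y)


class TestLLR:
    def test_identical_likelihoods_select_stationary(self, rng):
        y = gev_sample(rng, 5.0, 1.0, -0.1, n=100)
        cov = np.linspace(0, 1, 100)
        m = NonstationaryGEV().fit(cov, y)
        res = llr_test(m.stationary_, m)
        assert res.lambda_stat >= 0.0 and res.df == 1
        if res.lambda_stat == 0.0:
            assert res.p_value == 1.0 and res.selected == "stationary"

    def test_mismatched_data_rejected(self, rng):
        cov = np.linspace(0, 1, 60)
        m1 = NonstationaryGEV().fit(cov, gev_sample(rng, 5, 1, -0.1, n=60))
        m2 = NonstationaryGEV().fit(cov, gev_sample(rng, 5, 1, -0.1, n=60))
        with pytest.raises(ValueError, match="different data"):
            llr_test(m1.stationary_, m2)

    def test_null_rejection_rate_sane(self):
        # quick-look calibration; the full 2000-replicate run lives in the
        # acceptance suite
        rng = np.random.default_rng(11)
        cov = np.linspace(0, 1, 50)
        rej = 0
        for _ in range(300):
            y = gev_sample(rng, 5.0, 1.0, -0.1, n=50)
            m = NonstationaryGEV().fit(cov, y)
            rej += llr_test(m.stationary_, m).selected == "nonstationary"
        assert 0.01 <= rej / 300 <= 0.12

    def test_power_against_strong_trend(self):
        rng = np.random.default_rng(12)
        cov = np.linspace(0, 1, 50)
        rej = 0
        for _ in range(200):
            y = gev_sample(rng, 5.0 + 3.0 * cov, 1.0, -0.1)
            m = NonstationaryGEV().fit(cov, y)
            rej += llr_test(m.stationary_, m).selected == "nonstationary"
        assert rej / 200 > 0.95


def make_model(a1, a2, sigma, xi):
    m = NonstationaryGEV.__new__(NonstationaryGEV)
    m.a1_, m.a2_, m.scale_, m.shape_ = a1, a2, sigma, xi
    return m


class TestReturnPeriods:
    def test_median_threshold_gives_two_years(self):
        m = make_model(0.0, 3.0, 1.0, -0.1)
        median = gev_ppf(0.5, m.loc(2.0), 1.0, -0.1)
        rp = return_period(m, 2.0, threshold=median)
        assert rp.years == pytest.approx(2.0, abs=1e-12)

    def test_gumbel_location_at_threshold_closed_form(self):
        m = make_model(0.0, 0.5, 1.0, 0.0)  # location == 0 at dT where a2*dT = 0
        rp = return_period(m, 1e-12, threshold=0.0)
        assert rp.years == pytest.approx(1.0 / (1.0 - np.exp(-1.0)), abs=1e-6)

    def test_matches_million_sample_frequency(self, rng):
        m = make_model(-12.0, 3.0, 1.0, -0.1)
        rp = return_period(m, 3.0)
        samples = gev_ppf(rng.uniform(size=10**6), m.loc(3.0), 1.0, -0.1)
        p_hat = np.mean(samples > 0.0)
        se = np.sqrt(p_hat * (1 - p_hat) / 1e6)
        assert abs(1.0 / rp.years - p_hat) < 4 * se

    def test_censored_beyond_bounded_endpoint(self):
        m = make_model(-20.0, 1.0, 1.0, -0.2)  # upper endpoint -20+1/0.2+dT < 0
        rp = return_period(m, 1.0)
        assert rp.censored and rp.years == 10_000.0

    def test_strictly_decreasing_in_warming_when_trend_positive(self):
        m = make_model(-12.0, 3.0, 1.0, -0.1)
        levels = [2.0, 2.5, 3.0, 3.5]
        rps = [return_period(m, l).years for l in levels]
        assert all(a > b for a, b in zip(rps, rps[1:]))


class TestClassification:
    def test_single_station_fifty_years_in_middle_bin(self):
        table = pd.DataFrame(
            {"station_id": ["s"], "warming_level_c": [2.0],
             "return_period_years": [50.0], "censored": [False]}
        )
        shares = classify_return_periods(table)
        assert shares.loc[2.0, "10-100y"] == pytest.approx(100.0)

    def test_known_fixture_matches_hand_count(self):
        rps = [2, 5, 9, 10, 50, 99, 100, 500, 5000, 10000]
        censored = [False] * 9 + [True]
        table = pd.DataFrame(
            {"station_id": [f"s{i}" for i in range(10)],
             "warming_level_c": 2.0,
             "return_period_years": rps,
             "censored": censored}
        )
        shares = classify_return_periods(table)
        # hand count: <10y: {2,5,9}; 10-100y: {10,50,99}; >=100y: rest
        assert shares.loc[2.0, "<10y"] == pytest.approx(30.0)
        assert shares.loc[2.0, "10-100y"] == pytest.approx(30.0)
        assert shares.loc[2.0, ">=100y"] == pytest.approx(40.0)

    def test_shares_partition_to_hundred_percent(self):
        models = {f"s{i}": make_model(-12.0 + i, 3.0, 1.0, -0.1) for i in range(5)}
        table = compute_return_period_table(models)
        shares = classify_return_periods(table)
        np.testing.assert_allclose(shares.sum(axis=1), 100.0)

    def test_empty_table_gives_empty_summary(self):
        assert classify_return_periods(pd.DataFrame()).empty
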