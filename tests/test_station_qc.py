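"""Station filters, two-tier gap filling, autocorrelation screen."""

import numpy as np
import pandas as pd
import pytest

from heatlimits.station_qc import (
    GapTooLongError,
    Station,
    StationMeta,
    check_autocorrelation,
    fill_long_gaps,
    fill_short_gaps,
    filter_stations,
    haversine_km,
)
from .conftest import make_daily, make_station


class TestFilters:
    def test_polar_station_removed(self, exact_threshold):
        kept, report = filter_stations([make_station("N65", lat=65.0)],
                                       threshold=exact_threshold)
        assert kept == [] and report.removals == {"latitude": 1}

    def test_over_missing_station_removed(self, exact_threshold):
        daily = make_daily()
        mask = (daily.index >= "1970-01-01") & (daily.index < "2020-01-01")
        idx = np.flatnonzero(mask)
        daily.iloc[idx[: int(0.6 * idx.size)], :] = np.nan
        kept, report = filter_stations([make_station("GAPPY", daily=daily)],
                                       threshold=exact_threshold)
        assert report.removals == {"missing": 1}

    def test_fixture_hits_every_filter_with_designed_counts(
        self, qc_fixture_stations, exact_threshold
    ):
        kept, report = filter_stations(qc_fixture_stations, threshold=exact_threshold)
        assert report.removals == {
            "nonland": 1,
            "latitude": 1,
            "missing": 2,
            "early_maximum": 1,
            "inhomogeneity": 1,
        }
        assert len(kept) == 4
        assert {s.station_id for s in kept} == {f"CLEAN{i}" for i in range(4)}
        assert report.check_partition()

    def test_filtering_is_idempotent(self, qc_fixture_stations, exact_threshold):
        kept, _ = filter_stations(qc_fixture_stations, threshold=exact_threshold)
        kept2, report2 = filter_stations(kept, threshold=exact_threshold)
        assert len(kept2) == len(kept) and report2.removals == {}

    def test_empty_input_gives_empty_report(self):
        kept, report = filter_stations([])
        assert kept == [] and report.n_input == 0 and report.removals == {}


class TestHaversine:
    def test_identity_and_symmetry(self):
        assert haversine_km(10.0, 20.0, 10.0, 20.0) == 0.0
        d1 = haversine_km(10.0, 20.0, 11.0, 21.0)
        d2 = haversine_km(11.0, 21.0, 10.0, 20.0)
        assert d1 == pytest.approx(d2)

    def test_one_degree_latitude_is_about_111_km(self):
        assert haversine_km(0.0, 0.0, 1.0, 0.0) == pytest.approx(111.2, abs=0.5)


def seasonal_series(n_days=730, noise=0.0, seed=0):
    dates = pd.date_range("2000-01-01", periods=n_days, freq="D")
    t = np.arange(n_days, dtype=float)
    values = 15.0 + 8.0 * np.cos(2 * np.pi * t / 365.25) + 0.001 * t
    if noise:
        values = values + np.random.default_rng(seed).normal(0, noise, n_days)
    return pd.Series(values, index=dates)


class TestShortGapFilling:
    def test_gapless_series_unchanged(self):
        s = seasonal_series()
        pd.testing.assert_series_equal(fill_short_gaps(s), s)

    def test_noiseless_seasonal_gap_recovered(self):
        s = seasonal_series()
        truth = s.iloc[100]
        s_g = s.copy()
        s_g.iloc[100] = np.nan
        filled = fill_short_gaps(s_g)
        assert filled.iloc[100] == pytest.approx(truth, abs=0.1)

    def test_four_day_run_accepted_five_day_refused(self):
        s = seasonal_series()
        s4 = s.copy()
        s4.iloc[50:54] = np.nan
        assert fill_short_gaps(s4).notna().all()
        s5 = s.copy()
        s5.iloc[50:55] = np.nan
        with pytest.raises(GapTooLongError):
            fill_short_gaps(s5)

    def test_observed_values_never_altered(self):
        s = seasonal_series(noise=1.0)
        s_g = s.copy()
        s_g.iloc[200:203] = np.nan
        filled = fill_short_gaps(s_g)
        obs = s_g.notna()
        pd.testing.assert_series_equal(filled[obs], s[obs])


def _station_from_values(sid, values, dates, lat=30.0, lon=10.0):
    daily = pd.DataFrame({c: values for c in
                          ["t_max", "t_min", "t_mean", "rh_max", "rh_min", "rh_mean"]},
                         index=dates)
    return make_station(sid, lat=lat, lon=lon, daily=daily)


class TestLongGapFilling:
    period = (1970, 1972)

    def _dates(self):
        return pd.date_range("1970-01-01", "1972-01-01", freq="D", inclusive="left")

    def test_perfect_predictor_neighbor_reproduced(self, rng):
        dates = self._dates()
        base = rng.normal(20, 5, size=len(dates))
        target_vals = base.copy()
        target = _station_from_values("T", target_vals, dates)
        target.daily.iloc[100:110, :] = np.nan
        twin = _station_from_values("A", base, dates, lat=30.05)
        n2 = _station_from_values("B", rng.normal(20, 5, len(dates)), dates, lat=30.10)
        n3 = _station_from_values("C", rng.normal(20, 5, len(dates)), dates, lat=30.15)
        fill = fill_long_gaps(target, [twin, n2, n3], period=self.period)
        assert not fill.rejected
        np.testing.assert_allclose(
            fill.station.daily["t_mean"].iloc[100:110], base[100:110], atol=1e-6
        )

    def test_exact_linear_construction_recovered(self, rng):
        dates = self._dates()
        s1, s2, s3 = (rng.normal(20, 5, len(dates)) for _ in range(3))
        target_vals = 0.5 * s1 + 0.3 * s2 + 0.2 * s3 + 4.0
        target = _station_from_values("T", target_vals.copy(), dates)
        target.daily.iloc[300:320, :] = np.nan
        neighbors = [
            _station_from_values("A", s1, dates, lat=30.05),
            _station_from_values("B", s2, dates, lat=30.10),
            _station_from_values("C", s3, dates, lat=30.15),
        ]
        fill = fill_long_gaps(target, neighbors, period=self.period)
        assert not fill.rejected
        beta = fill.coefficients["t_mean"]
        np.testing.assert_allclose(sorted(beta[1:]), [0.2, 0.3, 0.5], atol=1e-6)
        np.testing.assert_allclose(
            fill.station.daily["t_mean"].iloc[300:320], target_vals[300:320], atol=1e-6
        )

    def test_two_neighbors_within_radius_rejected(self, rng):
        dates = self._dates()
        target = _station_from_values("T", rng.normal(20, 5, len(dates)), dates)
        target.daily.iloc[10:20, :] = np.nan
        near1 = _station_from_values("A", rng.normal(20, 5, len(dates)), dates, lat=30.1)
        near2 = _station_from_values("B", rng.normal(20, 5, len(dates)), dates, lat=30.2)
        far = _station_from_values("FAR", rng.normal(20, 5, len(dates)), dates, lat=45.0)
        fill = fill_long_gaps(target, [near1, near2, far], period=self.period)
        assert fill.rejected and "2 complete stations" in fill.reason

    def test_incomplete_neighbors_do_not_qualify(self, rng):
        dates = self._dates()
        target = _station_from_values("T", rng.normal(20, 5, len(dates)), dates)
        target.daily.iloc[10:20, :] = np.nan
        gappy = _station_from_values("A", rng.normal(20, 5, len(dates)), dates, lat=30.1)
        gappy.daily.iloc[500, :] = np.nan
        n2 = _station_from_values("B", rng.normal(20, 5, len(dates)), dates, lat=30.2)
        n3 = _station_from_values("C", rng.normal(20, 5, len(dates)), dates, lat=30.3)
        fill = fill_long_gaps(target, [gappy, n2, n3], period=self.period)
        assert fill.rejected


class TestAutocorrelation:
    def test_null_flag_rate_near_nominal(self):
        # 2/sqrt(n) two-sided band: ~5% nominal, slightly conservative at
        # n=50 because E[r1] ~ -1/n
        rng = np.random.default_rng(7)
        flags = sum(
            check_autocorrelation(rng.normal(size=50)).flagged for _ in range(1000)
        )
        assert 0.015 <= flags / 1000 <= 0.08

    def test_strong_ar1_dependence_flagged(self):
        rng = np.random.default_rng(8)
        x = np.zeros(200)
        for t in range(1, 200):
            x[t] = 0.8 * x[t - 1] + rng.normal()
        res = check_autocorrelation(x)
        assert res.flagged and res.r1 > 0.5

    def test_constant_series_degenerate(self):
        res = check_autocorrelation(np.full(20, 3.0))
        assert res.degenerate and res.flagged and np.isnan(res.r1)

    def test_short_series_refused(self):
        with pytest.raises(ValueError):
            check_autocorrelation(np.arange(5.0))
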