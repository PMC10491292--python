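import numpy as np
import pandas as pd
import pytest

from heatlimits.station_qc import Station, StationMeta
from heatlimits.synthetic import TRUE_CALIBRATION_COEF, generate_calibration_points
from heatlimits.threshold import fit_threshold


@pytest.fixture(scope="session")
def exact_threshold():
    """Threshold fit to noiseless calibration points: curve == generating quadratic."""
    return fit_threshold(generate_calibration_points(seed=0, noise_sd=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_daily(
    start="1950-01-01",
    end="2021-01-01",
    t_base=20.0,
    t_seasonal=10.0,
    t_amp=5.0,
    rh=40.0,
    t_trend=0.02,
):
    """Deterministic seasonal daily-statistics frame (no noise; a mild
    warming trend so recent extremes dominate early ones)."""
    dates = pd.date_range(start, end, freq="D", inclusive="left")
    doy = dates.dayofyear.to_numpy(dtype=float)
    yr = dates.year.to_numpy(dtype=float)
    t_mean = (
        t_base
        + t_trend * (yr - yr[0])
        + t_seasonal * np.cos(2 * np.pi * (doy - 200.0) / 365.25)
    )
    return pd.DataFrame(
        {
            "t_max": t_mean + t_amp,
            "t_min": t_mean - t_amp,
            "t_mean": t_mean,
            "rh_max": np.full(len(dates), rh + 10.0),
            "rh_min": np.full(len(dates), rh - 10.0),
            "rh_mean": np.full(len(dates), rh),
        },
        index=dates,
    )


def make_station(sid, lat=30.0, lon=10.0, is_land=True, inhom=0.2, daily=None):
    meta = StationMeta(
        station_id=sid,
        latitude=lat,
        longitude=lon,
        is_land=is_land,
        temp_inhomogeneity_c=inhom,
    )
    return Station(meta, daily if daily is not None else make_daily())


@pytest.fixture(scope="session")
def qc_fixture_stations():
    """Ten constructed stations hitting each selection filter a known number
    of times: 1 nonland, 1 polar, 2 over-missing, 1 early-era maximum,
    1 over-inhomogeneous, 4 clean."""
    stations = []
    stations.append(make_station("OCEAN", is_land=False))
    stations.append(make_station("POLAR", lat=65.0))
    for i in range(2):
        daily = make_daily()
        mask = (daily.index >= "1970-01-01") & (daily.index < "2020-01-01")
        sub = np.flatnonzero(mask)
        rng = np.random.default_rng(100 + i)
        drop = rng.choice(sub, size=int(0.6 * sub.size), replace=False)
        daily.iloc[drop, :] = np.nan
        stations.append(make_station(f"GAPPY{i}", daily=daily))
    # one hot, very humid planted day in 1960 and nothing comparable later
    daily = make_daily()
    d = pd.Timestamp("1960-07-15")
    daily.loc[d, ["t_max", "t_min", "t_mean"]] = 40.0
    daily.loc[d, ["rh_max", "rh_min", "rh_mean"]] = 90.0
    stations.append(make_station("EARLYMAX", daily=daily))
    stations.append(make_station("INHOMOG", inhom=1.5))
    for i in range(4):
        stations.append(make_station(f"CLEAN{i}", lat=30.0 + i * 0.1))
    return stations
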