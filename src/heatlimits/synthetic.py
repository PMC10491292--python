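"""Synthetic station networks, GMST series, calibration points and ensembles.

Every pipeline stage is exercised against data with known ground truth, so
the generator controls exactly the statistical structure the analysis
assumes:

* an annual GMST anomaly series (linear trend plus noise);
* six compensability calibration points on a known quadratic (labelled
  synthetic stand-ins for laboratory averages, which are not public here);
* a network of stations with seasonal and diurnal structure, a warming
  trend tied to GMST, spatially correlated clusters, missing-data runs and
  injected inhomogeneity metadata;
* a multi-member model ensemble whose members differ in climate
  sensitivity.

The heavy right tail that makes annual block maxima GEV-distributed is
induced *through* the pipeline rather than sampled directly: once per year
the generator plants a regional extreme day whose flat daily humidity is
solved — using the same sinusoidal reconstruction and rolling-window
machinery as the analysis — so that the year's maximum 6-hour-mean
exceedance equals a draw from GEV(a1 + a2*GMST_year, sigma, xi).  Running
the full diurnal + block-maxima path therefore recovers maxima that are
exactly GEV with location linear in GMST, and the nonstationary fit has a
well-defined target.  Planted extreme days are never covered by injected
missing runs, so gap-filled series preserve the annual maxima.

All generators are deterministic under a fixed seed (independent
SeedSequence children per component), and the recorded ground truth plus
config reproduce any series bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .diurnal import DAILY_COLUMNS, TEMPERATURE_PEAK_HOUR
from .station_qc import Station, StationMeta
from .threshold import CalibrationPoint

__all__ = [
    "SyntheticConfig",
    "TRUE_CALIBRATION_COEF",
    "generate_gmst",
    "generate_calibration_points",
    "generate_station_network",
    "EnsembleMember",
    "generate_ensemble",
    "generate_member_daily",
]

#: Generating quadratic for synthetic calibration points: critical humidity
#: q(T) = 0.1*T^2 - 12*T + 370 (convex, decreasing from ~68% RH at 36 degC
#: to ~24% at 48 degC; extrapolates above 100% RH below ~33 degC so mild
#: temperatures can never register as noncompensable).
TRUE_CALIBRATION_COEF = (0.1, -12.0, 370.0)

KM_PER_DEG_LAT = 111.0


@dataclass
class SyntheticConfig:
    """Ground-truth parameters for the synthetic station network.

    The GEV block (``gev_a1``, ``gev_a2``, ``gev_sigma``, ``gev_xi``)
    describes the target distribution of annual 6-h block maxima of the
    exceedance scalar, with location a1 + a2*GMST; ``gev_a2`` is the local
    trend the nonstationary fit should recover (scalar units per degC of
    global warming).
    """

    seed: int = 0
    n_stations: int = 12
    period: tuple = (1970, 2020)  # half-open year range
    # climatology
    base_temperature_c: float = 18.0
    seasonal_amplitude_c: float = 12.0
    diurnal_amplitude_c: float = 6.0
    base_humidity_pct: float = 45.0
    diurnal_amplitude_rh: float = 15.0
    warming_sensitivity: float = 1.0  # local degC per global degC
    heat_day_bump_c: float = 4.0
    # target GEV for annual block maxima of the exceedance scalar
    gev_a1: float = 5.0
    gev_a2: float = 3.0
    gev_sigma: float = 1.0
    gev_xi: float = -0.1
    # spatial structure
    n_clusters: int = 4
    correlation_length_km: float = 50.0
    station_jitter_km: float = 25.0
    lat_center: float = 30.0
    lon_center: float = 10.0
    cluster_noise_sd_c: float = 2.0
    station_noise_sd_c: float = 1.0
    # data defects
    short_gap_rate: float = 0.0  # probability per station-year of a 1-4 day run
    long_gap_rate: float = 0.0  # probability per station-year of a 5-15 day run
    inhomogeneities: tuple = ()  # (station_index, inhomogeneity_degC) pairs
    default_inhomogeneity_c: float = 0.2
    # GMST
    gmst_trend_c_per_year: float = 0.02
    gmst_noise_sd_c: float = 0.08
    gmst_offset_c: float = 0.1
    # threshold the exceedance scalar is measured against
    threshold_coef: tuple = TRUE_CALIBRATION_COEF
    window_hours: int = 6

    def validate(self) -> None:
        if not 0.0 <= self.short_gap_rate <= 1.0 or not 0.0 <= self.long_gap_rate <= 1.0:
            raise ValueError("gap rates must be probabilities in [0, 1]")
        if self.gev_sigma <= 0:
            raise ValueError("gev_sigma must be positive")
        if self.period[1] <= self.period[0]:
            raise ValueError("period must be a nonempty [start, end) year range")
        if self.n_stations < 1 or self.n_clusters < 1:
            raise ValueError("need at least one station and one cluster")


# ---------------------------------------------------------------------------
# GMST


def generate_gmst(
    start_year: int,
    end_year: int,
    trend_c_per_year: float = 0.02,
    noise_sd_c: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    offset_c: float = 0.0,
) -> pd.Series:
    """Annual GMST anomaly series over the half-open year range [start, end).

    Linear trend plus iid noise; with zero noise the endpoints differ by
    exactly ``trend * (n_years - 1)``.
    """
    years = np.arange(start_year, end_year)
    rng = np.random.default_rng(seed)
    values = offset_c + trend_c_per_year * (years - start_year)
    if noise_sd_c > 0:
        values = values + rng.normal(0.0, noise_sd_c, size=years.size)
    return pd.Series(values, index=years, name="gmst_anomaly_c")


# ---------------------------------------------------------------------------
# Calibration points


def generate_calibration_points(
    seed: int = 0, noise_sd: float = 1.0, coef=TRUE_CALIBRATION_COEF
) -> list[CalibrationPoint]:
    """Six synthetic calibration points: three hot-humid, three hot-dry.

    Points lie on the generating quadratic ``coef`` plus truncated Gaussian
    noise (clipped to +/-2 percentage points, which keeps the points
    monotone decreasing in humidity along increasing temperature for the
    default curve).  With ``noise_sd=0`` a quadratic fit recovers ``coef``
    exactly.
    """
    rng = np.random.default_rng(seed)
    temps = np.array([36.0, 38.0, 40.0, 44.0, 46.0, 48.0])
    labels = ["high-humidity"] * 3 + ["high-heat"] * 3
    hums = np.polyval(coef, temps)
    if noise_sd > 0:
        hums = hums + np.clip(rng.normal(0.0, noise_sd, size=6), -2.0, 2.0)
    return [
        CalibrationPoint(float(t), float(h), lab)
        for t, h, lab in zip(temps, hums, labels)
    ]


# ---------------------------------------------------------------------------
# Station network


def _gev_draws(rng: np.random.Generator, loc, sigma: float, xi: float) -> np.ndarray:
    """Draw one GEV variate per element of ``loc`` via inverse transform."""
    loc = np.asarray(loc, dtype=float)
    u = rng.uniform(1e-12, 1.0 - 1e-12, size=loc.shape)
    if abs(xi) < 1e-6:
        return loc - sigma * np.log(-np.log(u))
    return loc + sigma * (np.power(-np.log(u), -xi) - 1.0) / xi


def _required_flat_humidity(
    t_mean: float, t_amp: float, target_max: float, window_hours: int, coef
) -> float:
    """Flat daily humidity making the day's best window-mean exceedance equal
    ``target_max``, given the sinusoidal temperature reconstruction."""
    hours = np.arange(24)
    temp = t_mean + t_amp * np.cos(2 * np.pi * (hours - TEMPERATURE_PEAK_HOUR) / 24.0)
    q = np.polyval(coef, temp)
    qbar_min = np.convolve(q, np.ones(window_hours) / window_hours, mode="valid").min()
    return target_max + float(qbar_min)


def _inject_gap(missing: np.ndarray, start: int, length: int, protect: set) -> None:
    idx = np.arange(start, min(start + length, missing.size))
    if any(int(i) in protect for i in idx):
        return  # never wipe a planted extreme day
    missing[idx] = True


def generate_station_network(config: SyntheticConfig):
    """Generate a spatially clustered station network with known ground truth.

    Returns ``(stations, metadata, gmst, ground_truth)``: a list of
    :class:`~heatlimits.station_qc.Station`, a metadata DataFrame, the
    annual GMST anomaly series, and a dict recording the planted annual
    maxima per station plus the generating configuration.

    Stations in the same cluster share the seasonal signal, the day-to-day
    weather noise and the planted extreme days (a regional heat wave), and
    differ only by idiosyncratic noise — with ``station_noise_sd_c=0`` and
    ``station_jitter_km=0`` co-located stations are identical.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    ss_gmst, ss_clusters, ss_stations = ss.spawn(3)

    start_year, end_year = config.period
    gmst = generate_gmst(
        start_year,
        end_year,
        trend_c_per_year=config.gmst_trend_c_per_year,
        noise_sd_c=config.gmst_noise_sd_c,
        seed=ss_gmst,
        offset_c=config.gmst_offset_c,
    )

    dates = pd.date_range(f"{start_year}-01-01", f"{end_year}-01-01", freq="D",
                          inclusive="left")
    n_days = len(dates)
    doy = dates.dayofyear.to_numpy(dtype=float)
    year_of_day = dates.year.to_numpy()
    years = gmst.index.to_numpy()
    gmst_of_day = gmst.reindex(year_of_day).to_numpy()

    # seasonal cycle peaking at day-of-year 200 (northern-hemisphere summer)
    seasonal = config.seasonal_amplitude_c * np.cos(2 * np.pi * (doy - 200.0) / 365.25)

    # cluster-level shared structure
    cluster_rngs = [np.random.default_rng(s) for s in ss_clusters.spawn(config.n_clusters)]
    clusters = []
    for ci, crng in enumerate(cluster_rngs):
        lat = config.lat_center + 5.0 * (ci - (config.n_clusters - 1) / 2.0)
        lon = config.lon_center + 3.0 * ci
        shared_noise = crng.normal(0.0, config.cluster_noise_sd_c, size=n_days)
        rh_noise = crng.normal(0.0, 3.0, size=n_days)
        # one regional extreme day per year, near the seasonal peak
        extreme_doy = crng.integers(195, 216, size=years.size)
        planted = _gev_draws(
            crng, config.gev_a1 + config.gev_a2 * gmst.to_numpy(),
            config.gev_sigma, config.gev_xi,
        )
        clusters.append(
            {
                "lat": lat,
                "lon": lon,
                "shared_noise": shared_noise,
                "rh_noise": rh_noise,
                "extreme_doy": extreme_doy,
                "planted": planted,
            }
        )

    inhom = dict(config.inhomogeneities)
    a_t = config.diurnal_amplitude_c
    a_rh = config.diurnal_amplitude_rh
    rh_lo, rh_hi = a_rh + 0.5, 100.0 - a_rh - 0.5

    stations: list[Station] = []
    meta_rows = []
    truth_maxima: dict[str, pd.Series] = {}
    station_cluster: dict[str, int] = {}

    for si, s_seed in enumerate(ss_stations.spawn(config.n_stations)):
        srng = np.random.default_rng(s_seed)
        ci = si % config.n_clusters
        cl = clusters[ci]
        sid = f"SYN{si:04d}"

        jitter_deg = config.station_jitter_km / KM_PER_DEG_LAT
        lat = cl["lat"] + srng.uniform(-jitter_deg, jitter_deg)
        lon = cl["lon"] + srng.uniform(-jitter_deg, jitter_deg)

        own_noise = (
            srng.normal(0.0, config.station_noise_sd_c, size=n_days)
            if config.station_noise_sd_c > 0
            else np.zeros(n_days)
        )
        t_mean = (
            config.base_temperature_c
            + seasonal
            + config.warming_sensitivity * gmst_of_day
            + cl["shared_noise"]
            + own_noise
        )
        rh_mean = np.clip(config.base_humidity_pct + cl["rh_noise"], rh_lo, rh_hi)
        rh_max = np.clip(rh_mean + a_rh, 0.0, 100.0)
        rh_min = np.clip(rh_mean - a_rh, 0.0, 100.0)

        # plant the regional extreme days through the diurnal machinery
        extreme_idx: list[int] = []
        planted_values = []
        for yi, year in enumerate(years):
            d = int(np.flatnonzero((year_of_day == year) & (doy == cl["extreme_doy"][yi]))[0])
            extreme_idx.append(d)
            t_mean[d] += config.heat_day_bump_c
            target = float(cl["planted"][yi])
            r = _required_flat_humidity(
                float(t_mean[d]), a_t, target, config.window_hours, config.threshold_coef
            )
            r = float(np.clip(r, 0.5, 99.5))
            rh_mean[d] = rh_max[d] = rh_min[d] = r
            planted_values.append(target)

        daily = pd.DataFrame(
            {
                "t_max": t_mean + a_t,
                "t_min": t_mean - a_t,
                "t_mean": t_mean,
                "rh_max": rh_max,
                "rh_min": rh_min,
                "rh_mean": rh_mean,
            },
            index=dates,
        )[DAILY_COLUMNS]

        # missing-data runs (never on a planted extreme day)
        missing = np.zeros(n_days, dtype=bool)
        protect = set(extreme_idx)
        for yi, year in enumerate(years):
            ydays = np.flatnonzero(year_of_day == year)
            if config.short_gap_rate > 0 and srng.uniform() < config.short_gap_rate:
                start = int(srng.choice(ydays))
                _inject_gap(missing, start, int(srng.integers(1, 5)), protect)
            if config.long_gap_rate > 0 and srng.uniform() < config.long_gap_rate:
                start = int(srng.choice(ydays))
                _inject_gap(missing, start, int(srng.integers(5, 16)), protect)
        if missing.any():
            daily.loc[missing, :] = np.nan

        meta = StationMeta(
            station_id=sid,
            latitude=float(lat),
            longitude=float(lon),
            elevation_m=100.0,
            is_land=True,
            record_start=dates[0],
            temp_inhomogeneity_c=float(inhom.get(si, config.default_inhomogeneity_c)),
        )
        stations.append(Station(meta, daily))
        meta_rows.append(
            {
                "station_id": sid,
                "latitude": meta.latitude,
                "longitude": meta.longitude,
                "elevation_m": meta.elevation_m,
                "is_land": meta.is_land,
                "record_start": meta.record_start,
                "temp_inhomogeneity_c": meta.temp_inhomogeneity_c,
                "cluster": ci,
            }
        )
        truth_maxima[sid] = pd.Series(planted_values, index=years, name="planted_maximum")
        station_cluster[sid] = ci

    metadata = pd.DataFrame(meta_rows)
    ground_truth = {
        "config": asdict(config),
        "gmst": gmst,
        "planted_maxima": truth_maxima,
        "station_cluster": station_cluster,
    }
    return stations, metadata, gmst, ground_truth


# ---------------------------------------------------------------------------
# Ensemble


@dataclass(frozen=True)
class EnsembleMember:
    """One synthetic climate-model realization.

    ``sensitivity_c`` is the member's anomaly at the end of its simulation
    span (a stand-in for differing model climate sensitivities); the GMST
    ramp is quadratic in time so warming accelerates, and the warming-level
    windows therefore differ across members.
    """

    name: str
    gmst: pd.Series
    sensitivity_c: float
    entropy: int  # per-member seed root for daily-stat generation


def generate_ensemble(
    config: SyntheticConfig,
    n_members: int = 17,
    start_year: int = 1950,
    end_year: int = 2101,
    sensitivity_range: tuple = (4.5, 6.5),
) -> list[EnsembleMember]:
    """Generate per-member GMST trajectories with differing sensitivities."""
    config.validate()
    ss = np.random.SeedSequence([config.seed, 0x5E5])
    members = []
    years = np.arange(start_year, end_year)
    frac = (years - start_year) / (end_year - 1 - start_year)
    for mi, child in enumerate(ss.spawn(n_members)):
        rng = np.random.default_rng(child)
        sens = float(rng.uniform(*sensitivity_range))
        gmst = pd.Series(
            sens * frac**2 + rng.normal(0.0, config.gmst_noise_sd_c, size=years.size),
            index=years,
            name="gmst_anomaly_c",
        )
        members.append(
            EnsembleMember(
                name=f"member-{mi:02d}",
                gmst=gmst,
                sensitivity_c=sens,
                entropy=int(np.random.default_rng(child).integers(2**31)),
            )
        )
    return members


def generate_member_daily(
    config: SyntheticConfig,
    member: EnsembleMember,
    start_year: int,
    end_year: int,
) -> pd.DataFrame:
    """Daily statistics for one member over [start_year, end_year] inclusive.

    Seeded per (member, year) so overlapping windows reproduce identical
    days.  Structure matches the station generator: seasonal + warming
    signal, one planted extreme day per year whose 6-h block-maximum
    exceedance is a GEV(a1 + a2*GMST_year) draw.
    """
    config.validate()
    frames = []
    a_t = config.diurnal_amplitude_c
    a_rh = config.diurnal_amplitude_rh
    rh_lo, rh_hi = a_rh + 0.5, 100.0 - a_rh - 0.5
    for year in range(start_year, end_year + 1):
        rng = np.random.default_rng([member.entropy, year])
        dates = pd.date_range(f"{year}-01-01", f"{year + 1}-01-01", freq="D",
                              inclusive="left")
        doy = dates.dayofyear.to_numpy(dtype=float)
        g = float(member.gmst.loc[year])
        seasonal = config.seasonal_amplitude_c * np.cos(2 * np.pi * (doy - 200.0) / 365.25)
        t_mean = (
            config.base_temperature_c
            + seasonal
            + config.warming_sensitivity * g
            + rng.normal(0.0, config.cluster_noise_sd_c, size=doy.size)
        )
        rh_mean = np.clip(
            config.base_humidity_pct + rng.normal(0.0, 3.0, size=doy.size), rh_lo, rh_hi
        )
        rh_max = np.clip(rh_mean + a_rh, 0.0, 100.0)
        rh_min = np.clip(rh_mean - a_rh, 0.0, 100.0)

        d = int(rng.integers(195, 216)) - 1
        t_mean[d] += config.heat_day_bump_c
        target = float(
            _gev_draws(rng, config.gev_a1 + config.gev_a2 * g,
                       config.gev_sigma, config.gev_xi)
        )
        r = _required_flat_humidity(
            float(t_mean[d]), a_t, target, config.window_hours, config.threshold_coef
        )
        r = float(np.clip(r, 0.5, 99.5))
        rh_mean[d] = rh_max[d] = rh_min[d] = r

        frames.append(
            pd.DataFrame(
                {
                    "t_max": t_mean + a_t,
                    "t_min": t_mean - a_t,
                    "t_mean": t_mean,
                    "rh_max": rh_max,
                    "rh_min": rh_min,
                    "rh_mean": rh_mean,
                },
                index=dates,
            )
        )
    return pd.concat(frames)[DAILY_COLUMNS]
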