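"""Station selection filters and gap filling for daily weather records.

The analysis needs complete daily series of temperature / humidity statistics
over a fixed period (by default the 50 analysis years 1970-2020, treated as
the half-open year range [1970, 2020)).  Raw archives fall short in several
ways, handled here in a fixed order:

1.  nonland (marine/buoy) stations are dropped;
2.  stations poleward of 60 degrees latitude are dropped;
3.  stations missing more than half of their daily records in the analysis
    period are dropped;
4.  stations whose single highest 6-h mean exceedance during an early
    reference era (1950-1990) exceeds every window after 2000 are dropped —
    such records imply a cooling trend at the extremes that is more likely a
    site or instrument artifact than climate;
5.  stations without a pairwise temperature-inhomogeneity estimate, or with
    one larger than 1 degC, are dropped (inhomogeneity values are consumed
    as metadata; computing them is out of scope).

Each removal is attributed to the first failing filter, so the per-filter
counts in the audit report partition the input.

Remaining gaps are filled in two tiers.  Runs of fewer than five consecutive
missing days are filled from the station's own series with a least-squares
regression on a seasonal-harmonic (annual + semiannual) plus linear-trend
basis — the pluggable stand-in for a generic smooth-seasonal regression.
Runs of five or more days are filled by multivariate linear regression on
the three geographically closest stations with complete records; a station
lacking three complete neighbors within 100 km is rejected rather than
filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diurnal import DAILY_COLUMNS, annual_block_maxima, hourly_exceedance, reconstruct_hourly
from .threshold import DEFAULT_WINDOW_HOURS, CompensabilityThreshold

__all__ = [
    "StationMeta",
    "Station",
    "QCReport",
    "haversine_km",
    "filter_stations",
    "fill_short_gaps",
    "fill_long_gaps",
    "check_autocorrelation",
    "GapTooLongError",
    "read_station_csv",
    "read_metadata_csv",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class StationMeta:
    """Location and quality metadata for one weather station."""

    station_id: str
    latitude: float
    longitude: float
    elevation_m: float = 0.0
    is_land: bool = True
    record_start: pd.Timestamp | None = None
    temp_inhomogeneity_c: float = np.nan

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError("latitude out of range")
        if not -180.0 <= self.longitude < 180.0:
            raise ValueError("longitude out of range")


@dataclass
class Station:
    """Station metadata plus its daily-statistics series.

    ``daily`` is indexed by date with columns
    t_max, t_min, t_mean, rh_max, rh_min, rh_mean (NaN marks missing).
    """

    meta: StationMeta
    daily: pd.DataFrame

    @property
    def station_id(self) -> str:
        return self.meta.station_id


@dataclass
class QCReport:
    """Audit of a filtering pass: per-filter removal counts and dispositions."""

    n_input: int = 0
    removals: dict = field(default_factory=dict)   # filter name -> count
    dispositions: dict = field(default_factory=dict)  # station_id -> reason
    n_kept: int = 0

    def record(self, station_id: str, reason: str) -> None:
        self.dispositions[station_id] = reason
        if reason != "kept":
            self.removals[reason] = self.removals.get(reason, 0) + 1
            logger.info("station %s removed: %s", station_id, reason)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(sid, r) for sid, r in self.dispositions.items()],
            columns=["station_id", "disposition"],
        )

    def check_partition(self) -> bool:
        return self.n_kept + sum(self.removals.values()) == self.n_input


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km between two (latitude, longitude) points."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def _missing_fraction(daily: pd.DataFrame, period: tuple[int, int]) -> float:
    """Fraction of analysis-period days with any daily statistic missing."""
    start, end = pd.Timestamp(f"{period[0]}-01-01"), pd.Timestamp(f"{period[1]}-01-01")
    full_index = pd.date_range(start, end - pd.Timedelta(days=1), freq="D")
    sub = daily.reindex(full_index)[DAILY_COLUMNS]
    return float(sub.isna().any(axis=1).mean())


def _era_peak_exceedance(
    station: Station,
    threshold: CompensabilityThreshold,
    era: tuple[int, int],
    window_hours: int,
) -> float:
    """Highest window-mean exceedance over an era; NaN when no data."""
    mask = (station.daily.index.year >= era[0]) & (station.daily.index.year < era[1])
    sub = station.daily.loc[mask].dropna(subset=DAILY_COLUMNS)
    if len(sub) == 0:
        return np.nan
    hourly = reconstruct_hourly(sub)
    exc = hourly_exceedance(hourly, threshold)
    if len(exc) < window_hours:
        return np.nan
    maxima = annual_block_maxima(exc, window_hours=window_hours)
    return float(maxima["value"].max())


def filter_stations(
    stations: list[Station],
    period: tuple[int, int] = (1970, 2020),
    lat_band_deg: float = 60.0,
    max_missing_frac: float = 0.5,
    threshold: CompensabilityThreshold | None = None,
    early_era: tuple[int, int] = (1950, 1990),
    late_era: tuple[int, int] = (2000, 9999),
    max_inhomogeneity_c: float = 1.0,
    window_hours: int = DEFAULT_WINDOW_HOURS,
) -> tuple[list[Station], QCReport]:
    """Apply the staged station filters in order; first failure wins.

    The early-maximum filter (stage 4) needs a fitted compensability
    threshold to evaluate exceedances; pass ``threshold=None`` to skip it
    (e.g. when screening metadata only).  Idempotent: filtering an already
    filtered set removes nothing.
    """
    report = QCReport(n_input=len(stations))
    kept: list[Station] = []
    for st in stations:
        if not st.meta.is_land:
            report.record(st.station_id, "nonland")
            continue
        if abs(st.meta.latitude) > lat_band_deg:
            report.record(st.station_id, "latitude")
            continue
        if _missing_fraction(st.daily, period) > max_missing_frac:
            report.record(st.station_id, "missing")
            continue
        if threshold is not None:
            early = _era_peak_exceedance(st, threshold, early_era, window_hours)
            late = _era_peak_exceedance(st, threshold, late_era, window_hours)
            if np.isfinite(early) and np.isfinite(late) and early > late:
                report.record(st.station_id, "early_maximum")
                continue
        inhom = st.meta.temp_inhomogeneity_c
        if not np.isfinite(inhom) or inhom > max_inhomogeneity_c:
            report.record(st.station_id, "inhomogeneity")
            continue
        report.record(st.station_id, "kept")
        kept.append(st)
    report.n_kept = len(kept)
    return kept, report


# ---------------------------------------------------------------------------
# Gap filling


class GapTooLongError(ValueError):
    """A missing run is too long for within-station filling."""


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of each run of True in a boolean mask."""
    runs = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, ends):
        runs.append((int(idx[s]), int(idx[e] - idx[s] + 1)))
    return runs


def _seasonal_design(dates: pd.DatetimeIndex) -> np.ndarray:
    """Regression basis: intercept, linear trend, annual + semiannual harmonics."""
    t = (dates - dates[0]).days.to_numpy(dtype=float)
    omega = 2.0 * np.pi / 365.25
    return np.column_stack(
        [
            np.ones_like(t),
            t / 365.25,
            np.cos(omega * t),
            np.sin(omega * t),
            np.cos(2 * omega * t),
            np.sin(2 * omega * t),
        ]
    )


def fill_short_gaps(series: pd.Series, max_run: int = 4) -> pd.Series:
    """Fill short missing runs from the station's own seasonal structure.

    Fits intercept + trend + annual and semiannual harmonics to the
    non-missing values by least squares and predicts the missing days.
    Refuses (raises :class:`GapTooLongError`) if any missing run exceeds
    ``max_run`` days; such gaps belong to :func:`fill_long_gaps`.
    Never alters non-missing values.
    """
    missing = series.isna().to_numpy()
    if not missing.any():
        return series.copy()
    for start, length in _missing_runs(missing):
        if length > max_run:
            raise GapTooLongError(
                f"missing run of {length} days at index {start} exceeds "
                f"max_run={max_run}; use neighbor-based filling"
            )
    design = _seasonal_design(pd.DatetimeIndex(series.index))
    beta, *_ = np.linalg.lstsq(design[~missing], series.to_numpy()[~missing], rcond=None)
    out = series.copy()
    out.iloc[missing] = design[missing] @ beta
    return out


def fill_short_gaps_frame(daily: pd.DataFrame, max_run: int = 4) -> pd.DataFrame:
    """Column-wise :func:`fill_short_gaps` over the daily-statistics frame."""
    out = daily.copy()
    for col in DAILY_COLUMNS:
        if col in out:
            out[col] = fill_short_gaps(out[col], max_run=max_run)
    return out


@dataclass
class LongGapFill:
    """Outcome of neighbor-based filling: a filled station or a rejection."""

    station: Station | None
    rejected: bool
    reason: str = ""
    neighbor_ids: tuple = ()
    coefficients: dict = field(default_factory=dict)


def _is_complete(station: Station, period: tuple[int, int]) -> bool:
    return _missing_fraction(station.daily, period) == 0.0


def fill_long_gaps(
    target: Station,
    candidates: list[Station],
    period: tuple[int, int] = (1970, 2020),
    max_distance_km: float = 100.0,
    n_neighbors: int = 3,
) -> LongGapFill:
    """Fill long missing runs from the three nearest complete neighbors.

    Candidate stations with complete analysis-period records within
    ``max_distance_km`` (great-circle) are ranked by distance; the closest
    ``n_neighbors`` become predictors in a per-variable multivariate linear
    regression fitted on the target's non-missing days and used to predict
    all of its missing days.  Fewer than ``n_neighbors`` qualifying
    candidates is a rejection (returned, not raised), mirroring how such
    stations are dropped from the analysis.
    """
    complete = [
        (haversine_km(target.meta.latitude, target.meta.longitude,
                      c.meta.latitude, c.meta.longitude), c)
        for c in candidates
        if c.station_id != target.station_id and _is_complete(c, period)
    ]
    nearby = sorted(
        (pair for pair in complete if pair[0] <= max_distance_km), key=lambda p: p[0]
    )
    if len(nearby) < n_neighbors:
        return LongGapFill(
            None,
            rejected=True,
            reason=f"only {len(nearby)} complete stations within "
            f"{max_distance_km:g} km (need {n_neighbors})",
        )
    neighbors = [c for _, c in nearby[:n_neighbors]]
    filled = target.daily.copy()
    coefs: dict[str, np.ndarray] = {}
    for col in DAILY_COLUMNS:
        y = target.daily[col]
        preds = pd.concat(
            [n.daily[col].reindex(target.daily.index) for n in neighbors], axis=1
        )
        X = np.column_stack([np.ones(len(preds)), preds.to_numpy()])
        obs = y.notna().to_numpy() & ~np.isnan(X).any(axis=1)
        mis = y.isna().to_numpy() & ~np.isnan(X).any(axis=1)
        beta, *_ = np.linalg.lstsq(X[obs], y.to_numpy()[obs], rcond=None)
        filled.loc[mis, col] = X[mis] @ beta
        coefs[col] = beta
    return LongGapFill(
        Station(target.meta, filled),
        rejected=False,
        neighbor_ids=tuple(n.station_id for n in neighbors),
        coefficients=coefs,
    )


# ---------------------------------------------------------------------------
# Autocorrelation screen


@dataclass(frozen=True)
class AutocorrelationResult:
    r1: float
    n: int
    flagged: bool
    degenerate: bool = False


def check_autocorrelation(block_maxima, n_min: int = 10) -> AutocorrelationResult:
    """Lag-1 sample autocorrelation of annual block maxima.

    Flags |r1| > 2/sqrt(n) (an approximate 5% two-sided band under serial
    independence).  The flag is informational — no downstream action is
    taken on it.  A constant series has undefined r1 and is flagged
    degenerate.
    """
    x = np.asarray(block_maxima, dtype=float).ravel()
    x = x[np.isfinite(x)]
    n = x.size
    if n < n_min:
        raise ValueError(f"need at least {n_min} annual values, got {n}")
    xc = x - x.mean()
    denom = float(np.sum(xc**2))
    if denom == 0.0:
        return AutocorrelationResult(np.nan, n, flagged=True, degenerate=True)
    r1 = float(np.sum(xc[:-1] * xc[1:]) / denom)
    return AutocorrelationResult(r1, n, flagged=abs(r1) > 2.0 / np.sqrt(n))


# ---------------------------------------------------------------------------
# I/O


def read_metadata_csv(path) -> dict[str, StationMeta]:
    """Station metadata CSV: id, lat, lon, elev, land, start, inhomogeneity_c."""
    df = pd.read_csv(path)
    out = {}
    for r in df.itertuples():
        out[str(r.station_id)] = StationMeta(
            station_id=str(r.station_id),
            latitude=float(r.latitude),
            longitude=float(r.longitude),
            elevation_m=float(getattr(r, "elevation_m", 0.0)),
            is_land=bool(getattr(r, "is_land", True)),
            record_start=pd.Timestamp(r.record_start)
            if getattr(r, "record_start", None) is not None
            else None,
            temp_inhomogeneity_c=float(getattr(r, "temp_inhomogeneity_c", np.nan)),
        )
    return out


def read_station_csv(path, metadata: dict[str, StationMeta]) -> list[Station]:
    """Flat daily-statistics CSV with columns station_id, date, t_max, ...,
    rh_mean; one Station per id, matched to ``metadata``."""
    df = pd.read_csv(path, parse_dates=["date"])
    stations = []
    for sid, grp in df.groupby("station_id"):
        daily = grp.set_index("date")[DAILY_COLUMNS].sort_index()
        stations.append(Station(metadata[str(sid)], daily))
    return stations


def station_to_netcdf(station: Station, path) -> None:
    """One-station NetCDF (classic format) with a time dimension per variable."""
    import xarray as xr

    ds = xr.Dataset(
        {col: ("time", station.daily[col].to_numpy()) for col in DAILY_COLUMNS},
        coords={"time": station.daily.index.to_numpy()},
        attrs={
            "station_id": station.meta.station_id,
            "latitude": station.meta.latitude,
            "longitude": station.meta.longitude,
        },
    )
    ds.to_netcdf(path, engine="scipy")


def station_from_netcdf(path, meta: StationMeta | None = None) -> Station:
    """Read a one-station NetCDF written by :func:`station_to_netcdf`."""
    import xarray as xr

    with xr.open_dataset(path, engine="scipy") as ds:
        daily = pd.DataFrame(
            {col: ds[col].to_numpy() for col in DAILY_COLUMNS},
            index=pd.DatetimeIndex(ds["time"].to_numpy()),
        )
        if meta is None:
            meta = StationMeta(
                station_id=str(ds.attrs["station_id"]),
                latitude=float(ds.attrs["latitude"]),
                longitude=float(ds.attrs["longitude"]),
                temp_inhomogeneity_c=float(ds.attrs.get("temp_inhomogeneity_c", np.nan)),
            )
    return Station(meta, daily)
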