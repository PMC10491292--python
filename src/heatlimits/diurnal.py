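"""Diurnal reconstruction and windowed exceedance extremes.

Weather archives and daily climate-model output carry only daily statistics
(max / min / mean of temperature and relative humidity).  The analyses here
need hourly states, so each day is rebuilt as a fixed-frequency sinusoid:

    T(h)  = t_mean  + A_T  * cos(2*pi*(h - 15) / 24),   A_T  = (t_max - t_min)/2
    RH(h) = rh_mean + A_RH * cos(2*pi*(h - 3) / 24),    A_RH = (rh_max - rh_min)/2

Only the amplitude is fitted; the frequency is 24 h and the two variables are
held 180 degrees out of phase (humidity bottoms out when temperature peaks).
The absolute phase — temperature peaking at 15:00 local, humidity at 03:00 —
is a climatological convention; only the relative phase matters for the
windowed maxima on stationary days.  Because a pure sinusoid cannot honor
max, min and a mean different from (max+min)/2 simultaneously, the offset is
the mean and the amplitude the half-range; the residual against the recorded
extremes is logged at DEBUG level.  Reconstructed humidity is clipped to
[0, 100].

From the hourly exceedance scalar the module extracts the annual block
maximum of the rolling ``window_hours``-mean (default 6 h, the lethal-exposure
window; 9 and 12 h supported for sensitivity analyses) and counts
non-overlapping noncompensable events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .threshold import DEFAULT_WINDOW_HOURS, CompensabilityThreshold, exceedance_scalar

__all__ = [
    "TEMPERATURE_PEAK_HOUR",
    "reconstruct_hourly",
    "hourly_exceedance",
    "windowed_block_maximum",
    "annual_block_maxima",
    "count_noncompensable_events",
    "hourly_to_netcdf",
]

logger = logging.getLogger(__name__)

TEMPERATURE_PEAK_HOUR = 15  # humidity peak is 12 h opposite, at 03:00

DAILY_COLUMNS = ["t_max", "t_min", "t_mean", "rh_max", "rh_min", "rh_mean"]


def reconstruct_hourly(daily: pd.DataFrame, peak_hour: int = TEMPERATURE_PEAK_HOUR) -> pd.DataFrame:
    """Rebuild hourly temperature and humidity from daily statistics.

    Parameters
    ----------
    daily : DataFrame
        One row per day with a ``date`` column (or DatetimeIndex) and columns
        ``t_max, t_min, t_mean, rh_max, rh_min, rh_mean``.  Rows with any
        missing field yield missing hourly values (gap filling is an upstream
        responsibility).
    peak_hour : int
        Local hour of the temperature maximum; humidity peaks 12 h later.

    Returns
    -------
    DataFrame indexed by hourly timestamps with columns ``temperature_c``
    and ``humidity_pct`` (24 rows per input day).
    """
    if isinstance(daily.index, pd.DatetimeIndex):
        dates = daily.index
    else:
        dates = pd.DatetimeIndex(daily["date"])
    n = len(daily)
    hours = np.arange(24)

    t_mean = daily["t_mean"].to_numpy(dtype=float)[:, None]
    a_t = ((daily["t_max"] - daily["t_min"]).to_numpy(dtype=float) / 2.0)[:, None]
    rh_mean = daily["rh_mean"].to_numpy(dtype=float)[:, None]
    a_rh = ((daily["rh_max"] - daily["rh_min"]).to_numpy(dtype=float) / 2.0)[:, None]

    temp = t_mean + a_t * np.cos(2 * np.pi * (hours - peak_hour) / 24.0)
    hum = rh_mean + a_rh * np.cos(2 * np.pi * (hours - peak_hour - 12) / 24.0)
    hum = np.clip(hum, 0.0, 100.0)

    if logger.isEnabledFor(logging.DEBUG) and n:
        resid = np.nanmax(np.abs(np.nanmax(temp, axis=1) - daily["t_max"].to_numpy(float)))
        logger.debug("max reconstruction residual vs recorded t_max: %.3f degC", resid)

    index = pd.DatetimeIndex(
        np.repeat(dates.values, 24) + np.tile(hours, n) * np.timedelta64(1, "h")
    )
    return pd.DataFrame(
        {"temperature_c": temp.ravel(), "humidity_pct": hum.ravel()}, index=index
    )


def hourly_exceedance(hourly: pd.DataFrame, threshold: CompensabilityThreshold) -> pd.Series:
    """Signed exceedance scalar for each reconstructed hourly state."""
    return pd.Series(
        exceedance_scalar(
            hourly["temperature_c"].to_numpy(), hourly["humidity_pct"].to_numpy(), threshold
        ),
        index=hourly.index,
        name="exceedance",
    )


def _rolling_window_means(values: np.ndarray, window_hours: int) -> np.ndarray:
    """Means of every contiguous window; NaN where the window touches a gap."""
    if values.size < window_hours:
        raise ValueError("series shorter than the averaging window")
    kernel = np.ones(window_hours) / window_hours
    return np.convolve(values, kernel, mode="valid")


@dataclass(frozen=True)
class BlockMaximum:
    """Maximum windowed-mean exceedance within one block (typically a year)."""

    value: float
    window_hours: int
    start_index: int
    missing: bool = False


def windowed_block_maximum(
    exceedance: np.ndarray | pd.Series, window_hours: int = DEFAULT_WINDOW_HOURS
) -> BlockMaximum:
    """Largest mean exceedance over any contiguous ``window_hours`` window.

    Windows roll hour by hour and may cross day boundaries.  Windows that
    contain missing hours are excluded; if no complete window exists the
    result is flagged missing with a NaN value.
    """
    values = np.asarray(exceedance, dtype=float)
    means = _rolling_window_means(values, window_hours)
    if np.all(np.isnan(means)):
        return BlockMaximum(np.nan, window_hours, -1, missing=True)
    idx = int(np.nanargmax(means))
    return BlockMaximum(float(means[idx]), window_hours, idx)


def annual_block_maxima(
    exceedance: pd.Series,
    window_hours: int = DEFAULT_WINDOW_HOURS,
    gmst: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-year maxima of the rolling window-mean exceedance scalar.

    The rolling mean is computed over the station's continuous hourly series
    so windows may cross calendar-year boundaries; each window is attributed
    to the year of its start hour.  If ``gmst`` (an annual global-mean
    temperature anomaly series indexed by year) is given, each year's
    covariate is attached.

    Returns a DataFrame indexed by year with columns ``value`` (NaN where a
    year has no complete window), ``missing`` and optionally ``covariate``.
    """
    values = exceedance.to_numpy(dtype=float)
    means = _rolling_window_means(values, window_hours)
    start_years = exceedance.index.year[: len(means)]
    frame = pd.DataFrame({"year": start_years, "mean": means})
    grouped = frame.groupby("year")["mean"]
    maxima = grouped.max()  # pandas max skips NaN; all-NaN year -> NaN
    out = pd.DataFrame({"value": maxima})
    out["missing"] = out["value"].isna()
    out["window_hours"] = window_hours
    if gmst is not None:
        out["covariate"] = gmst.reindex(out.index).to_numpy()
    out.index.name = "year"
    return out


def count_noncompensable_events(
    exceedance: np.ndarray | pd.Series, window_hours: int = DEFAULT_WINDOW_HOURS
) -> int:
    """Number of non-overlapping ``window_hours``-long noncompensable events.

    An event is a window whose every hour has exceedance scalar > 0; events
    are tiled greedily left to right within each run of consecutive
    noncompensable hours, so a run of length L contributes ``L // window_hours``
    events.  The count is invariant to binarizing the scalar first.
    """
    flags = np.asarray(exceedance, dtype=float) > 0
    if flags.size == 0:
        return 0
    # run-length encode the boolean series
    change = np.flatnonzero(np.diff(flags.astype(np.int8)))
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [flags.size]))
    run_lengths = ends[flags[starts]] - starts[flags[starts]]
    return int(np.sum(run_lengths // window_hours))


def hourly_to_netcdf(hourly: pd.DataFrame, path, exceedance: pd.Series | None = None) -> None:
    """Write an hourly series to NetCDF (classic format via the scipy engine)."""
    import xarray as xr

    data = {
        "temperature_c": ("time", hourly["temperature_c"].to_numpy()),
        "humidity_pct": ("time", hourly["humidity_pct"].to_numpy()),
    }
    if exceedance is not None:
        data["exceedance"] = ("time", exceedance.to_numpy())
    ds = xr.Dataset(data, coords={"time": hourly.index.to_numpy()})
    ds["temperature_c"].attrs["units"] = "degC"
    ds["humidity_pct"].attrs["units"] = "percent"
    ds.to_netcdf(path, engine="scipy")
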