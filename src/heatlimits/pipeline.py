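"""End-to-end pipelines: stations to return periods, ensembles to pools.

These functions compose the module stages in the order the analysis runs
them — threshold fit, station QC and gap filling, diurnal reconstruction,
annual block maxima, GEV model selection, return periods at warming levels —
and return tidy result tables.  They exist so the whole chain can be driven
(and validated) from one call; each stage remains independently usable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import extremes, station_qc
from .diurnal import annual_block_maxima, hourly_exceedance, reconstruct_hourly
from .extremes import (
    DEFAULT_WARMING_LEVELS,
    NonstationaryGEV,
    StationaryGEV,
    classify_return_periods,
    compute_return_period_table,
    ks_test,
    llr_test,
)
from .station_qc import Station, fill_long_gaps, fill_short_gaps_frame, filter_stations
from .threshold import DEFAULT_WINDOW_HOURS, CompensabilityThreshold

__all__ = ["StationPipelineResult", "station_block_maxima", "run_station_pipeline",
           "ensemble_pooled_return_periods"]


def station_block_maxima(
    station: Station,
    threshold: CompensabilityThreshold,
    gmst: pd.Series,
    window_hours: int = DEFAULT_WINDOW_HOURS,
    period: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Annual windowed block maxima of the exceedance scalar for one station."""
    daily = station.daily
    if period is not None:
        mask = (daily.index.year >= period[0]) & (daily.index.year < period[1])
        daily = daily.loc[mask]
    hourly = reconstruct_hourly(daily)
    exc = hourly_exceedance(hourly, threshold)
    return annual_block_maxima(exc, window_hours=window_hours, gmst=gmst)


@dataclass
class StationPipelineResult:
    """Everything the station branch produces, per station and pooled."""

    qc_report: station_qc.QCReport
    fits: pd.DataFrame  # per-station parameters, KS/LLR outcomes
    return_periods: pd.DataFrame  # long format, selected stations only
    class_shares: pd.DataFrame  # % of stations per return-period class
    models: dict = field(default_factory=dict)
    block_maxima: dict = field(default_factory=dict)

    @property
    def n_trend_selected(self) -> int:
        return int((self.fits["selected"] == "nonstationary").sum())


def run_station_pipeline(
    stations: list[Station],
    threshold: CompensabilityThreshold,
    gmst: pd.Series,
    period: tuple[int, int] = (1970, 2020),
    window_hours: int = DEFAULT_WINDOW_HOURS,
    warming_levels=DEFAULT_WARMING_LEVELS,
    alpha: float = 0.05,
    n_min: int = 20,
    apply_filters: bool = True,
) -> StationPipelineResult:
    """Run the full observational branch.

    Stages: station filters -> two-tier gap filling (stations needing
    neighbor filling without three complete neighbors within 100 km are
    dropped) -> hourly reconstruction -> annual 6-h block maxima with GMST
    covariate -> stationary GEV + KS screen -> nonstationary GEV + LLR
    selection -> return periods at the warming levels for stations where the
    trend model wins.

    The ``fits`` table records every station's disposition; return-period
    class shares are computed over the stations retained by the GEV
    pipeline.  Expect ~alpha of truly trendless stations to slip through
    the LLR screen by chance; no multiplicity correction is applied.
    """
    if apply_filters:
        kept, report = filter_stations(stations, period=period, threshold=threshold,
                                       window_hours=window_hours)
    else:
        kept, report = list(stations), station_qc.QCReport(n_input=len(stations))

    # two-tier gap filling
    complete: list[Station] = []
    for st in kept:
        daily = st.daily
        has_missing = daily[station_qc.DAILY_COLUMNS].isna().any().any()
        if not has_missing:
            complete.append(st)
            continue
        runs = station_qc._missing_runs(
            daily[station_qc.DAILY_COLUMNS].isna().any(axis=1).to_numpy()
        )
        if all(length < 5 for _, length in runs):
            complete.append(Station(st.meta, fill_short_gaps_frame(daily)))
            report.dispositions[st.station_id] = "kept (short-gap filled)"
        else:
            fill = fill_long_gaps(st, kept, period=period)
            if fill.rejected:
                report.record(st.station_id, "no_neighbors")
                continue
            daily_filled = fill_short_gaps_frame(fill.station.daily)
            complete.append(Station(st.meta, daily_filled))
            report.dispositions[st.station_id] = "kept (neighbor filled)"
    report.n_kept = len(complete)

    rows = []
    models: dict[str, NonstationaryGEV] = {}
    maxima_store: dict[str, pd.DataFrame] = {}
    for st in complete:
        bm = station_block_maxima(st, threshold, gmst, window_hours, period)
        maxima_store[st.station_id] = bm
        data = bm.dropna(subset=["value", "covariate"])
        y = data["value"].to_numpy()
        cov = data["covariate"].to_numpy()
        row = {"station_id": st.station_id, "n_years": int(y.size)}
        try:
            stat = StationaryGEV(n_min=n_min).fit(y)
        except (ValueError, RuntimeError) as exc:
            row.update(status=f"fit_failed: {exc}", selected="none")
            rows.append(row)
            continue
        ks = ks_test(y, stat, alpha=alpha)
        ac = station_qc.check_autocorrelation(y) if y.size >= 10 else None
        row.update(
            mu=stat.loc_, sigma=stat.scale_, xi=stat.shape_,
            loglik_stationary=stat.log_likelihood_,
            ks_statistic=ks.statistic, ks_p=ks.p_value,
            autocorr_r1=ac.r1 if ac else np.nan,
            autocorr_flag=ac.flagged if ac else False,
        )
        if not ks.passed:
            row.update(status="ks_rejected", selected="none")
            rows.append(row)
            continue
        try:
            nonstat = NonstationaryGEV(n_min=n_min).fit(cov, y)
        except (ValueError, RuntimeError) as exc:
            row.update(status=f"fit_failed: {exc}", selected="none")
            rows.append(row)
            continue
        llr = llr_test(nonstat.stationary_, nonstat, alpha=alpha)
        row.update(
            a1=nonstat.a1_, a2=nonstat.a2_,
            sigma_ns=nonstat.scale_, xi_ns=nonstat.shape_,
            loglik_nonstationary=nonstat.log_likelihood_,
            llr_lambda=llr.lambda_stat, llr_p=llr.p_value,
            selected=llr.selected, status="ok",
        )
        if llr.selected == "nonstationary":
            models[st.station_id] = nonstat
        rows.append(row)

    fits = pd.DataFrame(rows)
    table = compute_return_period_table(models, warming_levels)
    shares = classify_return_periods(table) if not table.empty else pd.DataFrame()
    return StationPipelineResult(
        qc_report=report,
        fits=fits,
        return_periods=table,
        class_shares=shares,
        models=models,
        block_maxima=maxima_store,
    )


def ensemble_pooled_return_periods(
    members,
    config,
    threshold: CompensabilityThreshold,
    warming_levels=DEFAULT_WARMING_LEVELS,
    window_years: int = 30,
    window_hours: int = DEFAULT_WINDOW_HOURS,
) -> pd.DataFrame:
    """Pooled empirical return periods across an ensemble, per warming level.

    For each member and level: select the earliest 30-year warming window
    from the member's GMST, generate/collect its daily statistics, run the
    diurnal + block-maxima machinery, and pool all member-years.  Members
    that never reach a level are skipped (the pool notes how many
    contributed).
    """
    from .ensemble import WarmingLevelNotReached, pooled_return_period, select_warming_window
    from .synthetic import generate_member_daily

    rows = []
    for level in warming_levels:
        member_maxima = []
        contributing = 0
        for m in members:
            try:
                win = select_warming_window(m.gmst, level, window_years, member=m.name)
            except WarmingLevelNotReached:
                continue
            daily = generate_member_daily(config, m, win.start_year, win.end_year)
            hourly = reconstruct_hourly(daily)
            exc = hourly_exceedance(hourly, threshold)
            bm = annual_block_maxima(exc, window_hours=window_hours)
            member_maxima.append(bm["value"].dropna().to_numpy())
            contributing += 1
        if not member_maxima:
            continue
        rp = pooled_return_period(member_maxima)
        rows.append(
            {
                "warming_level_c": level,
                "return_period_years": rp.years,
                "censored": rp.censored,
                "pooled_years": rp.n_years,
                "exceeding_years": rp.n_exceedances,
                "members": contributing,
            }
        )
    return pd.DataFrame(rows)
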