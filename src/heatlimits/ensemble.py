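"""Warming-level sampling and pooled return periods from model ensembles.

Climate models disagree on how fast the planet warms, so projections are
organized by warming level rather than calendar period: for each ensemble
member the earliest 30-year window whose mean global-mean surface
temperature (GMST) anomaly reaches the level is extracted.  Each member's
window is then treated as an independent 30-year sample of the same climate
state, and the pooled empirical return period of noncompensable heat is the
total pooled years divided by the number of exceeding years (N/k).  With
the full 17-member ensemble this pools 510 member-years per warming level,
roughly ten times the 50 years available from direct observation.  A pool
with no exceedances is right-censored and read as "> N years".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WarmingWindow",
    "WarmingLevelNotReached",
    "select_warming_window",
    "PooledReturnPeriod",
    "pooled_return_period",
    "DEFAULT_WINDOW_YEARS",
]

DEFAULT_WINDOW_YEARS = 30


class WarmingLevelNotReached(ValueError):
    """The member's GMST never sustains the requested warming level."""


@dataclass(frozen=True)
class WarmingWindow:
    """Earliest 30-year span over which a member's mean GMST reaches a level."""

    member: str
    warming_level_c: float
    start_year: int
    end_year: int  # inclusive; end_year - start_year + 1 == window length
    mean_anomaly_c: float


def select_warming_window(
    gmst: pd.Series,
    level: float,
    window_years: int = DEFAULT_WINDOW_YEARS,
    member: str = "",
) -> WarmingWindow:
    """Earliest ``window_years`` window whose mean GMST anomaly >= ``level``.

    ``gmst`` is an annual anomaly series indexed by consecutive years.
    Raises :class:`WarmingLevelNotReached` when no window qualifies.
    """
    if level <= 0:
        raise ValueError("warming level must be positive")
    years = np.asarray(gmst.index, dtype=int)
    if years.size < window_years:
        raise WarmingLevelNotReached(
            f"series of {years.size} years is shorter than the {window_years}-year window"
        )
    if np.any(np.diff(years) != 1):
        raise ValueError("GMST series must cover consecutive years")
    values = gmst.to_numpy(dtype=float)
    means = np.convolve(values, np.ones(window_years) / window_years, mode="valid")
    hits = np.flatnonzero(means >= level)
    if hits.size == 0:
        raise WarmingLevelNotReached(
            f"mean anomaly never reaches {level:g} degC over any "
            f"{window_years}-year window"
        )
    i = int(hits[0])
    return WarmingWindow(
        member=member,
        warming_level_c=level,
        start_year=int(years[i]),
        end_year=int(years[i + window_years - 1]),
        mean_anomaly_c=float(means[i]),
    )


@dataclass(frozen=True)
class PooledReturnPeriod:
    years: float
    censored: bool  # True: zero exceedances; read as "> years"
    n_years: int
    n_exceedances: int

    def __str__(self) -> str:
        return f"> {self.years:g} years" if self.censored else f"{self.years:g} years"


def pooled_return_period(
    member_maxima: Sequence[np.ndarray], threshold: float = 0.0
) -> PooledReturnPeriod:
    """Empirical return period from pooled per-member annual block maxima.

    Each element of ``member_maxima`` holds one member's annual maxima inside
    its warming window.  The estimator is the direct frequency N/k over the
    pooled years; it is invariant to member ordering and to how the pool is
    partitioned into members.  k = 0 gives a right-censored "> N years".
    """
    if len(member_maxima) == 0:
        raise ValueError("need at least one member's maxima")
    pooled = np.concatenate([np.asarray(m, dtype=float).ravel() for m in member_maxima])
    pooled = pooled[np.isfinite(pooled)]
    n = int(pooled.size)
    if n == 0:
        raise ValueError("pool contains no finite maxima")
    k = int(np.sum(pooled > threshold))
    if k == 0:
        return PooledReturnPeriod(float(n), censored=True, n_years=n, n_exceedances=0)
    return PooledReturnPeriod(n / k, censored=False, n_years=n, n_exceedances=k)
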