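"""Compensability threshold in temperature-humidity space.

Laboratory heat-stress experiments identify, for a handful of controlled
environments, the dry-bulb temperature / relative-humidity combinations at
which a healthy subject's core temperature can no longer be held steady
("noncompensable" heat stress).  This module fits a quadratic critical-
humidity curve q(T) to such calibration points and converts arbitrary
temperature-humidity states into

* a signed exceedance scalar  s = RH - q(T)  (humidity percentage points;
  0 on the curve, positive above it = noncompensable), and
* a binary compensability flag (1 iff s > 0; the boundary s = 0 is
  classified compensable).

Sustained exposure above the curve drives core temperature upward at about
1 degC per hour; starting from a healthy 37 degC, the 43 degC lethal limit is
reached after six hours, which is why downstream analyses use a 6-hour
exposure window by default.

A psychrometric wet-bulb utility is included for comparing the empirical
threshold against constant wet-bulb isopleths; it feeds no pipeline stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "CalibrationPoint",
    "CompensabilityThreshold",
    "fit_threshold",
    "exceedance_scalar",
    "binarize",
    "wet_bulb",
    "lethal_exposure_hours",
    "read_calibration_csv",
    "DEFAULT_WINDOW_HOURS",
]

#: Default exposure window (hours): (43 - 37) degC core-temperature headroom
#: at ~1 degC/hour rise under noncompensable conditions.
DEFAULT_WINDOW_HOURS = 6

HEALTHY_CORE_TEMP_C = 37.0
LETHAL_CORE_TEMP_C = 43.0
CORE_WARMING_RATE_C_PER_HOUR = 1.0


def lethal_exposure_hours(
    core_start_c: float = HEALTHY_CORE_TEMP_C,
    core_lethal_c: float = LETHAL_CORE_TEMP_C,
    warming_rate_c_per_hour: float = CORE_WARMING_RATE_C_PER_HOUR,
) -> float:
    """Hours of noncompensable exposure for core temperature to reach lethality.

    With the physiological defaults (37 degC healthy core, 43 degC lethal,
    ~1 degC/hour rise) this evaluates to 6 hours, the default analysis window.
    """
    if warming_rate_c_per_hour <= 0:
        raise ValueError("warming rate must be positive")
    return (core_lethal_c - core_start_c) / warming_rate_c_per_hour


@dataclass(frozen=True)
class CalibrationPoint:
    """One averaged critical environment from a controlled heat experiment."""

    temperature_c: float
    humidity_pct: float
    label: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.temperature_c):
            raise ValueError("temperature must be finite")
        if not 0.0 <= self.humidity_pct <= 100.0:
            raise ValueError("humidity must be in [0, 100]")


class CompensabilityThreshold(BaseEstimator):
    """Quadratic critical-humidity curve separating compensable from
    noncompensable temperature-humidity states.

    The curve q(T) = c2*T^2 + c1*T + c0 is fit by ordinary least squares on
    vertical (humidity-axis) residuals.  ``decision_function`` returns the
    signed exceedance scalar RH - q(T) and ``predict`` the binary flag.

    Attributes (after :meth:`fit`)
    ------------------------------
    coef_ : ndarray of shape (3,)
        Quadratic coefficients ``(c2, c1, c0)``.
    r_squared_ : float
        1 - SS_res/SS_tot of the calibration fit, in [0, 1].
    fit_domain_ : tuple of float
        (min, max) calibration temperature; the curve is an extrapolation
        outside it.
    """

    def __init__(self, min_points: int = 3):
        self.min_points = min_points

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None) -> "CompensabilityThreshold":
        """Fit the quadratic to calibration temperatures X and humidities y.

        ``X`` may be a 1-D array of temperatures (with ``y`` the humidities)
        or an (n, 2) array of (temperature, humidity) columns.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 2 and y is None:
            temps, hums = X[:, 0], X[:, 1]
        else:
            temps = X.ravel()
            hums = np.asarray(y, dtype=float).ravel()
        if temps.shape != hums.shape:
            raise ValueError("temperature and humidity arrays must align")
        if not np.all(np.isfinite(temps)) or not np.all(np.isfinite(hums)):
            raise ValueError("calibration points must be finite")
        if temps.size < self.min_points or np.unique(temps).size < 3:
            raise ValueError(
                "degenerate design: need >= 3 points with >= 3 distinct "
                "temperatures to fit a quadratic"
            )
        coef = np.polyfit(temps, hums, deg=2)
        resid = hums - np.polyval(coef, temps)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((hums - hums.mean()) ** 2))
        self.coef_ = coef
        # perfect interpolation can leave ss_res at rounding level
        self.r_squared_ = 1.0 if ss_tot == 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))
        self.fit_domain_ = (float(temps.min()), float(temps.max()))
        return self

    # -- evaluation --------------------------------------------------------

    def curve(self, temperature_c):
        """Critical humidity q(T) in % at dry-bulb temperature T (degC)."""
        self._check_fitted()
        return np.polyval(self.coef_, np.asarray(temperature_c, dtype=float))

    def decision_function(self, X):
        """Signed exceedance scalar RH - q(T) for (temperature, humidity) rows.

        Zero on the curve; positive above it (noncompensable); negative
        below (compensable).  Units: humidity percentage points.
        """
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, 2)
        return X[:, 1] - np.polyval(self.coef_, X[:, 0])

    def predict(self, X):
        """Binary compensability flag: 1 iff strictly above the curve."""
        return binarize(self.decision_function(X))

    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise AttributeError("threshold is not fitted; call fit() first")

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        self._check_fitted()
        c2, c1, c0 = (float(c) for c in self.coef_)
        return {
            "c2": c2,
            "c1": c1,
            "c0": c0,
            "r_squared": float(self.r_squared_),
            "fit_domain": [self.fit_domain_[0], self.fit_domain_[1]],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompensabilityThreshold":
        thr = cls()
        thr.coef_ = np.array([d["c2"], d["c1"], d["c0"]], dtype=float)
        thr.r_squared_ = float(d["r_squared"])
        thr.fit_domain_ = (float(d["fit_domain"][0]), float(d["fit_domain"][1]))
        return thr

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path) -> "CompensabilityThreshold":
        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_threshold(points: Sequence[CalibrationPoint] | pd.DataFrame) -> CompensabilityThreshold:
    """Fit the noncompensable-heat threshold curve to calibration points.

    Accepts a sequence of :class:`CalibrationPoint` or a DataFrame with
    ``temperature_c`` and ``humidity_pct`` columns.
    """
    if isinstance(points, pd.DataFrame):
        temps = points["temperature_c"].to_numpy(dtype=float)
        hums = points["humidity_pct"].to_numpy(dtype=float)
    else:
        temps = np.array([p.temperature_c for p in points], dtype=float)
        hums = np.array([p.humidity_pct for p in points], dtype=float)
    return CompensabilityThreshold().fit(temps, hums)


def exceedance_scalar(temperature_c, humidity_pct, threshold: CompensabilityThreshold):
    """Signed scalar distance RH - q(T) from the threshold curve (vectorized)."""
    t = np.asarray(temperature_c, dtype=float)
    h = np.asarray(humidity_pct, dtype=float)
    return h - np.polyval(threshold.coef_, t)


def binarize(scalar):
    """Map the exceedance scalar to {0, 1}: 1 iff scalar > 0.

    The boundary (a state exactly on the curve) is classified compensable.
    """
    arr = np.asarray(scalar)
    out = (arr > 0).astype(int)
    return out if arr.ndim else int(out)


def read_calibration_csv(path) -> list[CalibrationPoint]:
    """Read calibration points from CSV (temperature_c, humidity_pct, label)."""
    df = pd.read_csv(path)
    label_col = "label" if "label" in df.columns else None
    return [
        CalibrationPoint(
            float(r.temperature_c),
            float(r.humidity_pct),
            str(getattr(r, label_col)) if label_col else "",
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Psychrometrics

_MAGNUS_A = 6.112   # hPa
_MAGNUS_B = 17.62
_MAGNUS_C = 243.12  # degC


def saturation_vapor_pressure(temperature_c):
    """Saturation vapor pressure over water (hPa), Magnus form."""
    t = np.asarray(temperature_c, dtype=float)
    return _MAGNUS_A * np.exp(_MAGNUS_B * t / (_MAGNUS_C + t))


def _psychrometer_residual(tw, t, e, pressure_hpa):
    # Psychrometer equation: e = es(Tw) - gamma * P * (T - Tw),
    # gamma = 6.6e-4 * (1 + 0.00115 Tw) K^-1 (standard Assmann coefficient).
    gamma = 6.6e-4 * (1.0 + 0.00115 * tw)
    return saturation_vapor_pressure(tw) - gamma * pressure_hpa * (t - tw) - e


def wet_bulb(
    temperature_c: float,
    humidity_pct: float,
    pressure_hpa: float = 1013.25,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> float:
    """Thermodynamic wet-bulb temperature (degC) by iterative psychrometric solve.

    Solves es(Tw) - gamma(Tw)*P*(T - Tw) = e for Tw with a damped Newton
    iteration, where e is the actual vapor pressure RH/100 * es(T).  The
    solution satisfies Tw <= T with equality at saturation.

    Raises
    ------
    ValueError for humidity outside (0, 100] or non-positive pressure;
    RuntimeError if the iteration fails to converge.
    """
    if not 0.0 < humidity_pct <= 100.0:
        raise ValueError("humidity must be in (0, 100]")
    if pressure_hpa <= 0:
        raise ValueError("pressure must be positive")
    t = float(temperature_c)
    e = humidity_pct / 100.0 * float(saturation_vapor_pressure(t))
    tw = t  # start at the dry-bulb; residual there is >= 0
    for _ in range(max_iter):
        f = _psychrometer_residual(tw, t, e, pressure_hpa)
        if abs(f) < tol:
            return min(tw, t)
        h = 1e-4
        df = (
            _psychrometer_residual(tw + h, t, e, pressure_hpa)
            - _psychrometer_residual(tw - h, t, e, pressure_hpa)
        ) / (2 * h)
        step = f / df
        # damp: never step past physical bracket [-100, T]
        tw_new = tw - step
        tw_new = min(max(tw_new, -100.0), t)
        if abs(tw_new - tw) < 1e-12:
            return min(tw_new, t)
        tw = tw_new
    raise RuntimeError("wet-bulb iteration did not converge")
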