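"""Single-sine degree-day accumulation.

Degree-days measure thermal accumulation above a developmental threshold.
The single sine method (Baskerville & Emin) models the diurnal temperature
trace as one sine wave through the daily minimum and maximum and
integrates the portion above the lower threshold in closed form.  The
default configuration — lower threshold 4 C, no upper threshold — is the
standard parameterization for *D. suzukii* development in early-season
cherry.

With alpha = (tmax - tmin)/2 and tmean = (tmax + tmin)/2, the daily value
for lower threshold TL is

* tmin >= TL:            dd = tmean - TL            (whole day above)
* tmax <= TL:            dd = 0                     (whole day below)
* otherwise: theta = arcsin((TL - tmean)/alpha) and
  dd = (1/pi) * [(tmean - TL) * (pi/2 - theta) + alpha * cos(theta)].

When an upper threshold is configured it is applied as a horizontal
cutoff: time spent above it accrues at the fixed rate (TU - TL).
Mean-only weather series cannot support the sine and fall back to the
simple average max(0, tmean - TL), with a warning.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import warnings
from typing import Optional, Union

import numpy as np
import pandas as pd

from .weather import DailyWeather, WeatherSeries, WeatherError

__all__ = ["DegreeDayConfig", "daily_dd", "accumulate_dd"]


@dataclasses.dataclass(frozen=True)
class DegreeDayConfig:
    """Degree-day method configuration.

    ``method`` is ``"single-sine"`` or ``"simple-average"``.  The upper
    threshold is optional and, when set, applied as a horizontal cutoff.
    """

    lower_threshold: float = 4.0
    upper_threshold: Optional[float] = None
    method: str = "single-sine"

    def __post_init__(self) -> None:
        if self.method not in ("single-sine", "simple-average"):
            raise ValueError(f"unknown degree-day method {self.method!r}")
        if self.upper_threshold is not None and not (
            self.upper_threshold > self.lower_threshold
        ):
            raise ValueError("upper threshold must exceed lower threshold")


def _single_sine_above(tmin: np.ndarray, tmax: np.ndarray, thr: float) -> np.ndarray:
    """Closed-form degree-days above ``thr`` for a sine day (vectorized)."""
    tmean = (tmin + tmax) / 2.0
    alpha = (tmax - tmin) / 2.0
    out = np.where(tmin >= thr, tmean - thr, 0.0)
    mid = (tmin < thr) & (tmax > thr)
    if np.any(mid):
        a = alpha[mid]
        m = tmean[mid]
        theta = np.arcsin(np.clip((thr - m) / a, -1.0, 1.0))
        out[mid] = ((m - thr) * (np.pi / 2.0 - theta) + a * np.cos(theta)) / np.pi
    return out


def daily_dd(
    day: Union[DailyWeather, tuple[float, float]],
    config: DegreeDayConfig = DegreeDayConfig(),
    mean_only: bool = False,
) -> float:
    """Degree-days accumulated on one day.

    ``day`` is a :class:`DailyWeather` or a bare (tmin, tmax) pair.  With
    ``mean_only=True`` (or the simple-average method) the value is
    max(0, tmean - TL), clipped at the upper threshold if configured.
    """
    if isinstance(day, DailyWeather):
        tmin, tmax, tmean = day.tmin, day.tmax, day.tmean
    else:
        tmin, tmax = day
        tmean = (tmin + tmax) / 2.0
    if tmin > tmax:
        raise WeatherError(f"tmin ({tmin}) exceeds tmax ({tmax})")
    tl = config.lower_threshold
    tu = config.upper_threshold
    if config.method == "simple-average" or mean_only:
        if mean_only and config.method == "single-sine":
            warnings.warn(
                "mean-only weather: single-sine unavailable, using simple average",
                stacklevel=2,
            )
        eff = min(tmean, tu) if tu is not None else tmean
        return float(max(0.0, eff - tl))
    lo = np.asarray([tmin], dtype=float)
    hi = np.asarray([tmax], dtype=float)
    dd = _single_sine_above(lo, hi, tl)
    if tu is not None:
        # horizontal cutoff: excess above TU does not accrue
        dd = dd - _single_sine_above(lo, hi, tu)
    return float(dd[0])


def accumulate_dd(
    weather: WeatherSeries,
    config: DegreeDayConfig = DegreeDayConfig(),
    start: Union[dt.date, str, None] = None,
) -> pd.DataFrame:
    """Running degree-day sum from ``start`` (default: series start).

    Returns a DataFrame with columns ``date``, ``daily_dd`` and
    ``cumulative_dd``; the cumulative column is non-decreasing.
    """
    i0 = weather.index_of(start) if start is not None else 0
    frame = weather.frame.iloc[i0:].reset_index(drop=True)
    if config.method == "simple-average" or weather.mean_only:
        if weather.mean_only and config.method == "single-sine":
            warnings.warn(
                "mean-only weather: single-sine unavailable, using simple average",
                stacklevel=2,
            )
        tmean = frame["tmean"].to_numpy(dtype=float)
        eff = (
            np.minimum(tmean, config.upper_threshold)
            if config.upper_threshold is not None
            else tmean
        )
        daily = np.maximum(0.0, eff - config.lower_threshold)
    else:
        tmin = frame["tmin"].to_numpy(dtype=float)
        tmax = frame["tmax"].to_numpy(dtype=float)
        daily = _single_sine_above(tmin, tmax, config.lower_threshold)
        if config.upper_threshold is not None:
            daily = daily - _single_sine_above(tmin, tmax, config.upper_threshold)
    return pd.DataFrame(
        {
            "date": frame["date"].dt.strftime("%Y-%m-%d"),
            "daily_dd": daily,
            "cumulative_dd": np.cumsum(daily),
        }
    )
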