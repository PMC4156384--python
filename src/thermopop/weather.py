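"""Daily weather series: reading, validation, and synthesis.

The projection model is driven entirely by daily air temperature.  A
:class:`WeatherSeries` holds one record per calendar day with minimum,
maximum and mean temperature in degrees Celsius.  Series must be gap-free
at daily resolution; a missing day is an error, never silently
interpolated.

Station exports rarely agree on column names, so :func:`read_weather`
accepts a column-name mapping.  When a file carries only a daily mean the
series is accepted but flagged ``mean_only``; downstream degree-day code
then falls back from the single-sine method to the simple average.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import io
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "DailyWeather",
    "WeatherSeries",
    "WeatherError",
    "read_weather",
    "write_weather",
    "synth_weather",
    "REGION_PRESETS",
]


class WeatherError(ValueError):
    """Raised for malformed, gapped, or inconsistent weather input."""


@dataclasses.dataclass(frozen=True)
class DailyWeather:
    """One day's temperature record (degrees Celsius)."""

    date: dt.date
    tmin: float
    tmax: float
    tmean: float

    def __post_init__(self) -> None:
        if self.tmin > self.tmax:
            raise WeatherError(
                f"{self.date}: tmin ({self.tmin}) exceeds tmax ({self.tmax})"
            )


class WeatherSeries:
    """A contiguous, strictly daily sequence of :class:`DailyWeather`.

    Parameters
    ----------
    frame:
        DataFrame with columns ``date`` (datetime-like), ``tmin``, ``tmax``,
        ``tmean``.
    site, year:
        Free-text labels carried through to outputs.
    mean_only:
        True when the source supplied only a daily mean; tmin and tmax are
        then copies of tmean and the single-sine degree-day method is
        unavailable.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        site: str = "",
        year: str = "",
        mean_only: bool = False,
    ) -> None:
        required = {"date", "tmin", "tmax", "tmean"}
        missing = required - set(frame.columns)
        if missing:
            raise WeatherError(f"weather frame missing columns: {sorted(missing)}")
        if len(frame) == 0:
            raise WeatherError("weather series is empty")
        frame = frame.copy()
        frame["date"] = pd.to_datetime(frame["date"]).dt.normalize()
        frame = frame.sort_values("date").reset_index(drop=True)
        self._validate(frame)
        self.frame = frame
        self.site = site
        self.year = year
        self.mean_only = mean_only

    @staticmethod
    def _validate(frame: pd.DataFrame) -> None:
        dates = frame["date"]
        if dates.duplicated().any():
            dup = dates[dates.duplicated()].iloc[0].date()
            raise WeatherError(f"duplicate date in weather series: {dup}")
        expected = pd.date_range(dates.iloc[0], dates.iloc[-1], freq="D")
        if len(expected) != len(dates):
            missing = expected.difference(pd.DatetimeIndex(dates))
            shown = ", ".join(str(d.date()) for d in missing[:10])
            more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
            raise WeatherError(f"weather series has gaps: missing {shown}{more}")
        bad = frame["tmin"] > frame["tmax"]
        if bad.any():
            row = frame[bad].iloc[0]
            raise WeatherError(
                f"{row['date'].date()}: tmin ({row['tmin']}) exceeds tmax ({row['tmax']})"
            )

    # -- sequence protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        for row in self.frame.itertuples(index=False):
            yield DailyWeather(row.date.date(), row.tmin, row.tmax, row.tmean)

    def __getitem__(self, i: int) -> DailyWeather:
        row = self.frame.iloc[i]
        return DailyWeather(row["date"].date(), row["tmin"], row["tmax"], row["tmean"])

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.frame["date"])

    @property
    def tmean(self) -> np.ndarray:
        return self.frame["tmean"].to_numpy(dtype=float)

    def index_of(self, date: Union[dt.date, str, pd.Timestamp]) -> int:
        ts = pd.Timestamp(date).normalize()
        loc = self.frame.index[self.frame["date"] == ts]
        if len(loc) == 0:
            raise WeatherError(f"date {ts.date()} not in weather series")
        return int(loc[0])

    def slice_from(self, date) -> "WeatherSeries":
        i = self.index_of(date)
        return WeatherSeries(
            self.frame.iloc[i:].reset_index(drop=True),
            site=self.site,
            year=self.year,
            mean_only=self.mean_only,
        )


_DEFAULT_DIALECT = {"date": "date", "tmin": "tmin", "tmax": "tmax", "tmean": "tmean"}


def read_weather(
    source: Union[str, io.TextIOBase],
    dialect: Mapping[str, str] | None = None,
    site: str = "",
    year: str = "",
) -> WeatherSeries:
    """Read a weather CSV into a validated :class:`WeatherSeries`.

    ``dialect`` maps canonical names (``date``, ``tmin``, ``tmax``,
    ``tmean``) to the column names actually present in the file.  The file
    must supply ``date`` plus either ``tmean`` or both ``tmin`` and
    ``tmax``.  When tmean is absent it is filled with (tmin + tmax)/2; when
    tmin/tmax are absent the series is flagged mean-only.
    """
    names = dict(_DEFAULT_DIALECT)
    if dialect:
        names.update(dialect)
    raw = pd.read_csv(source)
    cols: dict[str, pd.Series] = {}
    for canon, actual in names.items():
        if actual in raw.columns:
            cols[canon] = raw[actual]
    if "date" not in cols:
        raise WeatherError(f"no date column (looked for {names['date']!r})")
    try:
        date = pd.to_datetime(cols["date"], format="ISO8601")
    except ValueError:
        try:
            date = pd.to_datetime(cols["date"])
        except ValueError as exc:
            raise WeatherError(f"unparseable date column: {exc}") from exc

    have_minmax = "tmin" in cols and "tmax" in cols
    have_mean = "tmean" in cols
    if not (have_minmax or have_mean):
        raise WeatherError("need either tmean or both tmin and tmax columns")

    mean_only = not have_minmax
    if have_minmax:
        tmin = pd.to_numeric(cols["tmin"])
        tmax = pd.to_numeric(cols["tmax"])
        tmean = (
            pd.to_numeric(cols["tmean"]) if have_mean else (tmin + tmax) / 2.0
        )
    else:
        tmean = pd.to_numeric(cols["tmean"])
        tmin = tmean.copy()
        tmax = tmean.copy()

    frame = pd.DataFrame(
        {"date": date, "tmin": tmin, "tmax": tmax, "tmean": tmean}
    )
    return WeatherSeries(frame, site=site, year=year, mean_only=mean_only)


def write_weather(series: WeatherSeries, dest: Union[str, io.TextIOBase]) -> None:
    """Write a series to CSV with canonical columns and ISO dates."""
    out = series.frame.copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(dest, index=False)


def synth_weather(
    annual_mean: float,
    annual_amplitude: float,
    diurnal_range: float,
    noise_sd: float,
    start: Union[dt.date, str],
    n_days: int,
    seed: int,
    site: str = "synthetic",
    year: str = "",
    phase_doy: float = 105.0,
) -> WeatherSeries:
    """Generate a sinusoidal annual temperature cycle with daily noise.

    The daily mean follows

        tmean(d) = annual_mean
                   + annual_amplitude * sin(2*pi*(doy(d) - phase_doy)/365)
                   + N(0, noise_sd**2)

    with tmax/tmin placed symmetrically ``diurnal_range/2`` either side of
    the mean.  ``phase_doy`` = 105 puts the warmest day near mid-July and
    the coldest near mid-January, the usual Northern-hemisphere timing.
    Identical seeds give bitwise-identical series.
    """
    if n_days < 1:
        raise WeatherError("n_days must be >= 1")
    if annual_amplitude < 0 or diurnal_range < 0 or noise_sd < 0:
        raise WeatherError("amplitude, diurnal_range and noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    dates = pd.date_range(pd.Timestamp(start), periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)
    det = annual_mean + annual_amplitude * np.sin(
        2.0 * np.pi * (doy - phase_doy) / 365.0
    )
    tmean = det + rng.normal(0.0, noise_sd, size=n_days)
    half = diurnal_range / 2.0
    frame = pd.DataFrame(
        {"date": dates, "tmin": tmean - half, "tmax": tmean + half, "tmean": tmean}
    )
    return WeatherSeries(frame, site=site, year=year, mean_only=False)


# Synthetic stand-ins for the two contrasting climates discussed in the
# region comparison: a hot interior-valley profile whose midsummer mean
# overshoots the fly's fecundity optimum, and a mild maritime profile that
# never does.  Values are plausible annual statistics for such climates,
# not station data.
REGION_PRESETS: dict[str, dict[str, float]] = {
    "hot-summer": {
        "annual_mean": 17.5,
        "annual_amplitude": 10.0,
        "diurnal_range": 14.0,
        "noise_sd": 1.5,
    },
    "temperate": {
        "annual_mean": 11.5,
        "annual_amplitude": 7.0,
        "diurnal_range": 10.0,
        "noise_sd": 1.5,
    },
}
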