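"""Trap-correlation statistics.

Field monitoring of *D. suzukii* uses baited traps read weekly.  To ask
whether model predictions track observed activity, weekly trap means and
daily log10 population estimates are both aggregated to calendar-month
means and the monthly trap mean is regressed on the monthly log
population by ordinary least squares.  With ~6 shared months this is a
single-predictor regression with F degrees of freedom (1, n - 2); the
report mirrors the conventional table: adjusted R^2, F, df, p, slope,
intercept, n.
"""

from __future__ import annotations

import dataclasses
import io
from typing import Mapping, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "TrapSeries",
    "RegressionReport",
    "TrapStatsError",
    "read_traps",
    "monthly_means",
    "trap_regression",
]


class TrapStatsError(ValueError):
    """Raised for invalid trap data or degenerate regressions."""


@dataclasses.dataclass
class TrapSeries:
    """Dated weekly mean flies-per-trap counts."""

    frame: pd.DataFrame  # columns: date, mean_flies_per_trap
    site: str = ""
    year: str = ""

    def __post_init__(self) -> None:
        required = {"date", "mean_flies_per_trap"}
        missing = required - set(self.frame.columns)
        if missing:
            raise TrapStatsError(f"trap series missing columns: {sorted(missing)}")
        f = self.frame.copy()
        f["date"] = pd.to_datetime(f["date"])
        if not f["date"].is_monotonic_increasing:
            f = f.sort_values("date").reset_index(drop=True)
        if (f["mean_flies_per_trap"] < 0).any():
            raise TrapStatsError("trap counts must be >= 0")
        self.frame = f


def read_traps(source: Union[str, io.TextIOBase], site: str = "", year: str = "") -> TrapSeries:
    return TrapSeries(frame=pd.read_csv(source), site=site, year=year)


@dataclasses.dataclass(frozen=True)
class RegressionReport:
    """OLS summary for monthly trap means vs monthly log population."""

    adjusted_r2: float
    r2: float
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    slope: float
    intercept: float
    n_months: int

    def as_row(self, location: str = "") -> dict:
        return {
            "location": location,
            "adjusted_R2": self.adjusted_r2,
            "p": self.p_value,
            "df": f"{self.df[0]}, {self.df[1]}",
            "F": self.f_statistic,
        }


def monthly_means(series: pd.Series) -> pd.Series:
    """Calendar-month means of a date-indexed series.

    Input: values indexed by datetime (any spacing).  Output: one mean per
    calendar month present in the input, indexed by month period; months
    with no observations are absent, never interpolated.  NaN values are
    dropped before averaging.
    """
    if len(series) == 0:
        raise TrapStatsError("cannot aggregate an empty series")
    s = series.dropna()
    return s.groupby(s.index.to_period("M")).mean()


def trap_regression(
    traps: pd.Series,
    logpop: pd.Series,
) -> RegressionReport:
    """Regress monthly trap means on monthly log population estimates.

    Both inputs are month-period-indexed means (from
    :func:`monthly_means`); only calendar months present in both are used,
    and at least 3 shared months are required.  Returns the full OLS
    report; adjusted R^2 = 1 - (1 - R^2)(n - 1)/(n - 2) and the p-value is
    from F(1, n - 2).
    """
    shared = traps.index.intersection(logpop.index)
    n = len(shared)
    if n < 3:
        raise TrapStatsError(
            f"need >= 3 shared months for regression, got {n}"
        )
    y = traps.loc[shared].to_numpy(dtype=float)
    x = logpop.loc[shared].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise TrapStatsError("zero variance in log population predictor")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return RegressionReport(
        adjusted_r2=float(fit.rsquared_adj),
        r2=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        df=(int(fit.df_model), int(fit.df_resid)),
        p_value=float(fit.f_pvalue),
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        n_months=n,
    )
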