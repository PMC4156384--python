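"""Temperature-driven Leslie matrix projection.

The population is a vector of 50 daily age classes of females.  Each day a
fresh 50x50 Leslie matrix is built from that day's mean temperature —
fecundities f_x(T) in the first row, daily survival probabilities p_x(T)
on the subdiagonal, nothing else — and applied to the vector.  There is no
survival out of the last class: a female reaching age 50 dies that day.
The model is deterministic and linear: no density dependence, Allee
effects, migration, or host limitation.

The season starts at a *biofix*, the earliest date when temperature allows
the population to grow.  Biofix is detected by a trailing-window rule: the
first date on which the dominant eigenvalue of the matrix built from the
mean temperature of the preceding ``window`` days exceeds 1, sustained for
``persistence`` consecutive days.  A fixed calendar date may be supplied
instead.  At biofix the vector is seeded with 100 flies spread over age
classes 41-50, representing post-diapause females in spring.

Daily output is the full age vector, the egg/larva/pupa/adult stage
tallies (ages 1-3 / 4-7 / 8-9 / 10-50), and log10 of the vector sum — the
total population estimate.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import signal

from .demography import STAGE_BANDS, DemographicSchedule
from .weather import WeatherSeries

__all__ = [
    "LeslieMatrix",
    "StageTally",
    "Trajectory",
    "ProjectionError",
    "NoBiofix",
    "build_matrix",
    "project_day",
    "init_population",
    "detect_biofix",
    "run_season",
    "stage_tally",
    "dominant_eigen",
    "seasonal_peaks",
]

DEFAULT_MAX_AGE = 50
DEFAULT_INIT_TOTAL = 100.0
DEFAULT_INIT_AGES = (41, 50)


class ProjectionError(ValueError):
    """Raised for invalid projection inputs."""


class NoBiofix(Exception):
    """Raised when no date in the series satisfies the biofix criterion."""


@dataclasses.dataclass(frozen=True)
class LeslieMatrix:
    """A 50x50 projection matrix built at one temperature."""

    array: np.ndarray
    temperature: float

    @property
    def order(self) -> int:
        return self.array.shape[0]


@dataclasses.dataclass(frozen=True)
class StageTally:
    eggs: float
    larvae: float
    pupae: float
    adults: float

    @property
    def total(self) -> float:
        return self.eggs + self.larvae + self.pupae + self.adults


def build_matrix(schedule: DemographicSchedule, temperature: float) -> LeslieMatrix:
    """Build the Leslie matrix M(T) for one day's mean temperature.

    Row 1 holds f_x(T); the subdiagonal holds p_x(T) for x = 1..max_age-1.
    Class ``max_age`` has no outgoing survival.
    """
    if not np.isfinite(temperature):
        raise ProjectionError(f"temperature must be finite, got {temperature}")
    k = schedule.max_age
    M = np.zeros((k, k))
    M[0, :] = schedule.fecundity_vector(temperature)
    p = schedule.survival_vector(temperature)
    M[np.arange(1, k), np.arange(k - 1)] = p[: k - 1]
    return LeslieMatrix(array=M, temperature=float(temperature))


def project_day(n: np.ndarray, M: LeslieMatrix) -> np.ndarray:
    """Advance the population vector one day: n' = M @ n."""
    n = np.asarray(n, dtype=float)
    if n.shape != (M.order,):
        raise ProjectionError(
            f"vector length {n.shape} does not match matrix order {M.order}"
        )
    if np.any(n < 0):
        raise ProjectionError("population vector has negative entries")
    return M.array @ n


def init_population(
    total: float = DEFAULT_INIT_TOTAL,
    ages: tuple[int, int] = DEFAULT_INIT_AGES,
    max_age: int = DEFAULT_MAX_AGE,
) -> np.ndarray:
    """Initial vector: ``total`` females spread uniformly over ``ages``.

    The default — 100 flies over ages 41-50, ten per class — represents
    old post-diapause females seeding the spring population.
    """
    lo, hi = ages
    if not (1 <= lo <= hi <= max_age):
        raise ProjectionError(f"age range {ages} outside 1..{max_age}")
    if total < 0:
        raise ProjectionError("total must be >= 0")
    n = np.zeros(max_age)
    k = hi - lo + 1
    n[lo - 1 : hi] = total / k
    # guarantee the exact total despite division
    if total > 0:
        n *= total / n.sum()
    return n


def dominant_eigen(M: LeslieMatrix) -> tuple[float, Optional[np.ndarray]]:
    """Spectral radius and stable age distribution of a Leslie matrix.

    Returns (lambda, w) with w the nonnegative right eigenvector of the
    dominant eigenvalue, normalized to sum 1.  For a nonnegative matrix the
    spectral radius is itself an eigenvalue (Perron–Frobenius), so lambda
    is real.  An all-zero or reproduction-free (nilpotent) matrix returns
    (0.0, None).
    """
    A = M.array
    if np.any(A < 0):
        raise ProjectionError("Leslie matrix must be nonnegative")
    if not A.any():
        return 0.0, None
    vals, vecs = np.linalg.eig(A)
    lam = float(np.max(np.abs(vals)))
    if lam <= 0:
        return 0.0, None
    idx = int(np.argmax(np.abs(vals)))
    w = np.real(vecs[:, idx])
    if w.sum() < 0:
        w = -w
    w = np.clip(w, 0.0, None)
    s = w.sum()
    if s == 0:
        return lam, None
    return lam, w / s


def detect_biofix(
    weather: WeatherSeries,
    schedule: DemographicSchedule,
    window: int = 7,
    persistence: int = 3,
) -> dt.date:
    """First spring date when temperature sustains population growth.

    Returns the first date ``d`` such that, for ``persistence`` consecutive
    days starting at ``d``, the dominant eigenvalue of the matrix built
    from the trailing ``window``-day mean temperature exceeds 1.  Raises
    :class:`NoBiofix` if no such date exists.
    """
    if window < 1 or persistence < 1:
        raise ProjectionError("window and persistence must be >= 1")
    if len(weather) < window + persistence - 1:
        raise ProjectionError(
            f"weather series ({len(weather)} d) shorter than window + persistence"
        )
    tmean = weather.tmean
    # trailing-window means: index i covers days i-window+1 .. i
    csum = np.concatenate(([0.0], np.cumsum(tmean)))
    trail = (csum[window:] - csum[:-window]) / window  # length n - window + 1
    growing = np.array(
        [dominant_eigen(build_matrix(schedule, t))[0] > 1.0 for t in trail]
    )
    run = 0
    for i, g in enumerate(growing):
        run = run + 1 if g else 0
        if run == persistence:
            start = i - persistence + 1 + window - 1  # index into the series
            return weather.dates[start].date()
    raise NoBiofix(
        f"no {persistence}-day run with trailing {window}-day mean "
        "temperature supporting growth"
    )


def stage_tally(n: np.ndarray) -> StageTally:
    """Aggregate an age vector into egg/larva/pupa/adult totals."""
    n = np.asarray(n, dtype=float)
    out = {}
    for stage, (lo, hi) in STAGE_BANDS.items():
        hi = min(hi, len(n))
        out[stage] = float(n[lo - 1 : hi].sum())
    # ages beyond the named adult band (if max_age > 50) count as adults
    named = sum(out.values())
    out["adult"] += float(n.sum() - named)
    return StageTally(
        eggs=out["egg"], larvae=out["larva"], pupae=out["pupa"], adults=out["adult"]
    )


class Trajectory:
    """Dated sequence of daily population vectors with stage tallies.

    ``vectors`` is an (n_days, max_age) array; row 0 is the initial vector
    on the biofix date.  ``frame`` renders the standard output table with
    columns date, age_1..age_N, eggs, larvae, pupae, adults, total and
    log10_total (NaN on zero-total days, which are also flagged in the
    boolean ``extinct`` column).
    """

    def __init__(
        self,
        dates: pd.DatetimeIndex,
        vectors: np.ndarray,
        biofix: dt.date,
        site: str = "",
        year: str = "",
    ) -> None:
        if len(dates) != vectors.shape[0]:
            raise ProjectionError("dates and vectors disagree in length")
        self.dates = dates
        self.vectors = vectors
        self.biofix = biofix
        self.site = site
        self.year = year

    @property
    def totals(self) -> np.ndarray:
        return self.vectors.sum(axis=1)

    @property
    def log10_totals(self) -> np.ndarray:
        tot = self.totals
        with np.errstate(divide="ignore"):
            out = np.where(tot > 0, np.log10(np.where(tot > 0, tot, 1.0)), np.nan)
        return out

    def tallies(self) -> list[StageTally]:
        return [stage_tally(v) for v in self.vectors]

    @property
    def frame(self) -> pd.DataFrame:
        k = self.vectors.shape[1]
        data = {"date": self.dates.strftime("%Y-%m-%d")}
        for x in range(k):
            data[f"age_{x + 1}"] = self.vectors[:, x]
        tallies = self.tallies()
        data["eggs"] = [t.eggs for t in tallies]
        data["larvae"] = [t.larvae for t in tallies]
        data["pupae"] = [t.pupae for t in tallies]
        data["adults"] = [t.adults for t in tallies]
        data["total"] = self.totals
        data["log10_total"] = self.log10_totals
        data["extinct"] = self.totals == 0
        return pd.DataFrame(data)

    def to_csv(self, dest) -> None:
        self.frame.to_csv(dest, index=False)


def run_season(
    weather: WeatherSeries,
    schedule: DemographicSchedule,
    biofix: Union[dt.date, str, None] = "auto",
    init: Optional[np.ndarray] = None,
    mortality_multiplier: Optional[Sequence[float]] = None,
    biofix_window: int = 7,
    biofix_persistence: int = 3,
) -> Trajectory:
    """Project the population from biofix to the end of the weather series.

    The vector on the biofix date is ``init`` (default: 100 post-diapause
    females over ages 41-50).  Each following day's vector is obtained by
    applying the matrix built from the *previous* day's mean temperature —
    the matrix of day d governs the transition from day d to day d+1.

    ``biofix`` may be a date within the series or ``"auto"`` to apply
    :func:`detect_biofix`.  ``mortality_multiplier`` is an optional
    per-age factor in [0, 1] applied to all survival entries, a hook for
    what-if scenarios such as stage-targeted control (default: all 1.0).
    """
    if biofix is None or (isinstance(biofix, str) and biofix == "auto"):
        biofix_date = detect_biofix(
            weather, schedule, window=biofix_window, persistence=biofix_persistence
        )
    else:
        biofix_date = pd.Timestamp(biofix).date()
    start = weather.index_of(biofix_date)  # raises if outside range

    if init is None:
        init = init_population(max_age=schedule.max_age)
    init = np.asarray(init, dtype=float)
    if init.shape != (schedule.max_age,):
        raise ProjectionError("init vector length does not match max_age")
    if np.any(init < 0):
        raise ProjectionError("init vector has negative entries")

    mult = None
    if mortality_multiplier is not None:
        mult = np.asarray(mortality_multiplier, dtype=float)
        if mult.shape != (schedule.max_age,):
            raise ProjectionError("mortality multiplier length must equal max_age")

    tmean = weather.tmean[start:]
    n_days = len(tmean)
    vectors = np.empty((n_days, schedule.max_age))
    vectors[0] = init
    for i in range(1, n_days):
        M = build_matrix(schedule, tmean[i - 1])
        if mult is not None:
            A = M.array.copy()
            sub = np.arange(1, schedule.max_age)
            A[sub, sub - 1] *= mult[: schedule.max_age - 1]
            M = LeslieMatrix(array=A, temperature=M.temperature)
        vectors[i] = project_day(vectors[i - 1], M)
    return Trajectory(
        dates=weather.dates[start:],
        vectors=vectors,
        biofix=biofix_date,
        site=weather.site,
        year=weather.year,
    )


def seasonal_peaks(
    trajectory: Trajectory,
    smooth_days: int = 21,
    min_prominence: float = 0.3,
) -> list[int]:
    """Indices of distinct seasonal peaks in the log10 population curve.

    The log-total series is smoothed with a centred moving average over
    ``smooth_days`` and peaks are located with a prominence threshold (in
    log10 units, so 0.3 is about a two-fold dip between peaks).  A final
    maximum at the series end (a still-rising curve) counts as a peak.
    Zero-total days are treated as minus infinity.
    """
    y = trajectory.log10_totals.copy()
    y[~np.isfinite(y)] = np.nanmin(y[np.isfinite(y)]) - 10 if np.isfinite(y).any() else 0.0
    kernel = np.ones(smooth_days) / smooth_days
    pad = smooth_days // 2
    yp = np.pad(y, pad, mode="edge")
    ys = np.convolve(yp, kernel, mode="valid")[: len(y)]
    peaks, _ = signal.find_peaks(ys, prominence=min_prominence)
    out = list(peaks)
    # an endpoint maximum is a peak find_peaks cannot see
    if len(ys) > smooth_days:
        interior_max = ys[peaks].max() if len(peaks) else -np.inf
        if ys[-1] >= ys.max() - 1e-12 and ys[-1] > interior_max:
            out.append(len(ys) - 1)
    return out
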