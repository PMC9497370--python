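"""Nonparametric circadian metrics from epoch-level actigraphy.

Works on wrist-actigraph records binned to 1-min epochs (activity counts and
illuminance). Hourly aggregation and the interdaily stability (IS),
intradaily variability (IV), M10/L5 and relative amplitude (RA) statistics
follow the Witting-style nonparametric rest-activity analysis:

    IS = (N * sum_h (xbar_h - xbar)^2) / (24 * sum_i (x_i - xbar)^2)
    IV = (N * sum_{i=2..N} (x_i - x_{i-1})^2) / ((N-1) * sum_i (x_i - xbar)^2)

where the x_i are the N hourly activity values, xbar_h the 24 hour-of-day
means and xbar the grand mean. IS is 1 for a perfectly repeated daily
pattern and near 1/(number of days) for white noise; IV approaches 2 for
white noise and is small for a smooth 24-h waveform.

M10 and L5 are the most active 10-h and least active 5-h window totals of
the average day (1-h steps, wrapping across midnight); the relative
amplitude RA = (m10 - l5)/(m10 + l5) uses the per-hour window means
m10 = M10/10 and l5 = L5/5, so RA is 0 for a flat profile and 1 when the
least active 5 h are completely still.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UndefinedMetricError

__all__ = [
    "EpochSeries",
    "HourlyProfile",
    "NonparametricMetrics",
    "bin_to_hours",
    "interdaily_stability",
    "intradaily_variability",
    "m10_l5_ra",
    "average_day_profile",
]

HOURS_PER_DAY = 24
#: an hour with more than this fraction of its epochs absent is flagged missing
MISSING_HOUR_FRACTION = 0.20


@dataclass
class EpochSeries:
    """One subject's multi-day actigraphy record at a fixed epoch length.

    `data` is indexed by timestamp (strictly increasing, constant spacing up
    to gaps) with columns ``activity`` (counts >= 0) and ``lux`` (>= 0).
    """

    data: pd.DataFrame
    epoch_minutes: int = 1

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex):
            raise ValueError("EpochSeries.data must be indexed by timestamps")
        if not {"activity", "lux"}.issubset(self.data.columns):
            raise ValueError("EpochSeries.data needs 'activity' and 'lux' columns")
        if len(self.data) == 0:
            raise InsufficientDataError("empty epoch series")
        if not self.data.index.is_monotonic_increasing or self.data.index.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")
        if (self.data["activity"] < 0).any():
            raise ValueError("activity counts must be nonnegative")
        if 60 % self.epoch_minutes != 0:
            raise ValueError("epoch length must divide 60 minutes")

    @property
    def epochs_per_hour(self) -> int:
        return 60 // self.epoch_minutes

    def n_days(self) -> int:
        return len(np.unique(self.data.index.normalize()))


@dataclass
class HourlyProfile:
    """Hour-of-day matrix of summed activity, one row per calendar day.

    ``matrix`` is days x 24 with NaN marking missing hours (an hour is
    missing when more than 20% of its epochs are absent); partial days at
    the record edges are trimmed before the matrix is built.
    """

    matrix: np.ndarray  # days x 24, NaN = missing
    dates: pd.DatetimeIndex

    @property
    def n_days(self) -> int:
        return self.matrix.shape[0]

    def hourly_series(self) -> np.ndarray:
        """Concatenated hourly values in time order (may contain NaN)."""
        return self.matrix.reshape(-1)

    def hour_means(self) -> np.ndarray:
        """Mean over days for each of the 24 hour-of-day slots (NaN-aware)."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slot -> NaN
            return np.nanmean(self.matrix, axis=0)

    def grand_mean(self) -> float:
        return float(np.nanmean(self.matrix))


@dataclass(frozen=True)
class NonparametricMetrics:
    """IS/IV plus M10/L5/RA of one record."""

    IS: float
    IV: float
    M10: float
    L5: float
    M10_onset: int
    L5_onset: int
    RA: float


def _trim_to_whole_days(series: EpochSeries) -> pd.DataFrame:
    """Drop leading/trailing partial calendar days (they bias hour-of-day means).

    A day is trimmed only when the record does not span it end to end
    (recording started or stopped mid-day); interior gaps are kept and
    handled by the missing-hour flags.
    """
    df = series.data
    step = pd.Timedelta(minutes=series.epoch_minutes)
    days = sorted(np.unique(df.index.normalize()))
    # leading day: record must start at the day's first epoch
    while days and df.index[0] > days[0]:
        days = days[1:]
        if days:
            df = df[df.index >= days[0]]
    # trailing day: record must reach the day's last epoch
    while days and df.index[-1] < days[-1] + pd.Timedelta(days=1) - step:
        days = days[:-1]
        if days:
            df = df[df.index < days[-1] + pd.Timedelta(days=1)]
    if not len(days):
        raise InsufficientDataError("no complete day after trimming partial edge days")
    return df


def bin_to_hours(series: EpochSeries) -> HourlyProfile:
    """Aggregate epoch counts to hourly totals on a day x hour grid.

    The hourly value is the SUM of epoch counts within the clock hour.
    Hours with more than 20% of their epochs missing are flagged missing
    (NaN), never silently zero.
    """
    df = _trim_to_whole_days(series)
    eph = series.epochs_per_hour

    day = df.index.normalize()
    hour = df.index.hour
    grouped = df["activity"].groupby([day, hour])
    sums = grouped.sum()
    counts = grouped.size()

    dates = pd.DatetimeIndex(sorted(day.unique()))
    matrix = np.full((len(dates), HOURS_PER_DAY), np.nan)
    day_pos = {d: i for i, d in enumerate(dates)}
    for (d, h), total in sums.items():
        if counts[(d, h)] >= (1.0 - MISSING_HOUR_FRACTION) * eph:
            matrix[day_pos[d], h] = total
    return HourlyProfile(matrix=matrix, dates=dates)


def _variance_terms(profile: HourlyProfile) -> tuple[np.ndarray, float, float, int]:
    x = profile.hourly_series()
    x = x[~np.isnan(x)]
    n = x.size
    if profile.n_days < 2:
        raise InsufficientDataError("IS/IV need at least 2 complete days")
    xbar = float(x.mean())
    ss_total = float(np.sum((x - xbar) ** 2))
    if ss_total == 0.0:
        raise UndefinedMetricError("constant activity series: IS/IV undefined (zero variance)")
    return x, xbar, ss_total, n


def interdaily_stability(profile: HourlyProfile) -> float:
    """Interdaily stability of the hourly activity series (0..1)."""
    _, xbar, ss_total, n = _variance_terms(profile)
    hour_means = profile.hour_means()
    if np.isnan(hour_means).any():
        # hour-of-day means exist as long as each slot has >= 1 day of data
        raise UndefinedMetricError("an hour-of-day slot has no data in any day")
    ss_hours = float(np.sum((hour_means - xbar) ** 2))
    return (n * ss_hours) / (HOURS_PER_DAY * ss_total)


def intradaily_variability(profile: HourlyProfile) -> float:
    """Intradaily variability of the concatenated hourly series (~2 for noise)."""
    x, _, ss_total, n = _variance_terms(profile)
    # successive differences only over contiguous (non-missing) pairs
    series = profile.hourly_series()
    valid = ~np.isnan(series)
    pairs = valid[1:] & valid[:-1]
    diffs = series[1:][pairs] - series[:-1][pairs]
    if diffs.size == 0:
        raise UndefinedMetricError("no contiguous hourly pairs for IV")
    return (n * float(np.sum(diffs**2))) / ((n - 1) * ss_total)


def m10_l5_ra(profile: HourlyProfile) -> NonparametricMetrics:
    """M10/L5 window totals and relative amplitude from the average day.

    Windows slide in 1-h steps over the 24-h hour-of-day mean profile and
    wrap across midnight. M10 is the largest 10-h window total, L5 the
    smallest 5-h window total; onsets are the starting clock hours. IS/IV
    are computed alongside when >= 2 days are available (NaN otherwise).
    """
    means = profile.hour_means()
    if np.isnan(means).any():
        raise UndefinedMetricError("M10/L5 need a complete 24-h mean profile")

    wrapped = np.concatenate([means, means])

    def window_sums(width: int) -> np.ndarray:
        return np.array([wrapped[s : s + width].sum() for s in range(HOURS_PER_DAY)])

    m10_sums = window_sums(10)
    l5_sums = window_sums(5)
    m10_onset = int(np.argmax(m10_sums))
    l5_onset = int(np.argmin(l5_sums))
    m10 = float(m10_sums[m10_onset])
    l5 = float(l5_sums[l5_onset])
    # RA is computed on the per-hour window MEANS (M10/10 vs L5/5) so that a
    # constant profile yields RA = 0; M10 and L5 themselves are reported as
    # window totals, the scale actigraphy tables print.
    m10_mean, l5_mean = m10 / 10.0, l5 / 5.0
    ra = (m10_mean - l5_mean) / (m10_mean + l5_mean) if (m10_mean + l5_mean) > 0 else 0.0

    try:
        is_ = interdaily_stability(profile)
        iv = intradaily_variability(profile)
    except (InsufficientDataError, UndefinedMetricError):
        is_ = iv = float("nan")

    return NonparametricMetrics(
        IS=is_, IV=iv, M10=m10, L5=l5, M10_onset=m10_onset, L5_onset=l5_onset, RA=ra
    )


def average_day_profile(series: EpochSeries, bin_minutes: int = 60) -> pd.DataFrame:
    """Mean +/- SE of activity and lux per time-of-day bin, across days.

    Returns a DataFrame indexed by bin start (decimal hours) with columns
    ``activity_mean``, ``activity_se``, ``lux_mean``, ``lux_se``, ``n_days``.
    Activity is summed within each bin per day before averaging across days
    (so at 60-min bins the values match the hourly profile); lux is averaged
    within bins.
    """
    if 1440 % bin_minutes != 0:
        raise ValueError("bin_minutes must divide 1440")
    df = series.data
    if series.n_days() < 2:
        raise InsufficientDataError("average-day profile needs >= 2 days for a standard error")

    minutes = df.index.hour * 60 + df.index.minute
    bin_start = (minutes // bin_minutes) * bin_minutes
    day = df.index.normalize()

    act = df["activity"].groupby([day, bin_start]).sum().unstack(fill_value=np.nan)
    lux = df["lux"].groupby([day, bin_start]).mean().unstack(fill_value=np.nan)

    out = pd.DataFrame(index=np.array(act.columns, dtype=float) / 60.0)
    out.index.name = "hour"
    n = act.notna().sum(axis=0).to_numpy(dtype=float)
    out["activity_mean"] = act.mean(axis=0).to_numpy()
    out["activity_se"] = act.std(axis=0, ddof=1).to_numpy() / np.sqrt(n)
    out["lux_mean"] = lux.mean(axis=0).to_numpy()
    out["lux_se"] = lux.std(axis=0, ddof=1).to_numpy() / np.sqrt(n)
    out["n_days"] = n
    return out
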