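"""Aggregation of cleaned hourly series to daily means, annual summaries
and binned exposure distributions.

The exposure metric for long-term health-impact assessment is the
annual distribution of 24-h mean concentrations.  A day enters the
daily series only if at least ``min_completeness`` of its 24 hours
survived cleaning (default 0.75, the conventional 18-of-24 validity
rule).  The binned distribution discretises the daily means into
left-closed bins aligned to multiples of the bin width; the bin
midpoints and day proportions are the (c, P(c)) pairs the attributable
proportion sums over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParameterError, ValidationError
from .io_ingest import HourlySeries

__all__ = [
    "DailySeries",
    "AnnualExposureSummary",
    "ExposureCategory",
    "daily_means",
    "annual_summary",
    "bin_distribution",
    "summary_frame",
]


@dataclass
class DailySeries:
    """24-h mean concentrations, one record per retained calendar day."""

    dates: pd.DatetimeIndex  # normalised to midnight
    daily_mean: np.ndarray
    n_hours_used: np.ndarray
    variable_name: str = ""

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates).normalize()
        self.daily_mean = np.asarray(self.daily_mean, dtype=float)
        self.n_hours_used = np.asarray(self.n_hours_used, dtype=int)
        if not (len(self.dates) == len(self.daily_mean) == len(self.n_hours_used)):
            raise ValidationError("dates, means and hour counts differ in length")
        if np.any((self.n_hours_used < 1) | (self.n_hours_used > 24)):
            raise ValidationError("n_hours_used must lie in [1, 24]")

    def __len__(self) -> int:
        return len(self.daily_mean)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "daily_mean": self.daily_mean, "n_hours_used": self.n_hours_used}
        )


@dataclass(frozen=True)
class AnnualExposureSummary:
    """Mean ± SD and range of daily means over a study period."""

    mean: float
    sd: float
    min: float
    max: float
    n_days: int

    def __post_init__(self) -> None:
        if not (self.min <= self.mean <= self.max):
            raise ValidationError("require min <= mean <= max")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")


@dataclass(frozen=True)
class ExposureCategory:
    """One concentration stratum [lower, upper) with day proportion P_c."""

    lower: float
    upper: float
    midpoint: float
    proportion: float


def daily_means(series: HourlySeries, min_completeness: float = 0.75) -> DailySeries:
    """Aggregate an hourly series to per-day arithmetic means.

    Days with fewer than ``min_completeness * 24`` hourly values are
    excluded.
    """
    if not 0 < min_completeness <= 1:
        raise ParameterError(
            f"min_completeness must be in (0, 1], got {min_completeness}"
        )
    if len(series) == 0:
        return DailySeries(pd.DatetimeIndex([]), np.array([]), np.array([], dtype=int),
                           series.variable_name)

    s = pd.Series(series.values, index=series.timestamps)
    grouped = s.groupby(s.index.normalize())
    means = grouped.mean()
    counts = grouped.size()
    required = min_completeness * 24
    keep = counts >= required - 1e-9
    return DailySeries(
        means.index[keep], means.to_numpy()[keep.to_numpy()],
        counts.to_numpy()[keep.to_numpy()], series.variable_name,
    )


def annual_summary(daily: DailySeries) -> AnnualExposureSummary:
    """Mean, sample SD (n−1), min and max of the daily means."""
    if len(daily) == 0:
        raise EmptyInputError("annual_summary requires a non-empty daily series")
    x = daily.daily_mean
    sd = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    return AnnualExposureSummary(
        mean=float(np.mean(x)), sd=sd, min=float(np.min(x)), max=float(np.max(x)),
        n_days=len(x),
    )


def bin_distribution(daily: DailySeries, bin_width: float = 1.0) -> list[ExposureCategory]:
    """Bin daily means into left-closed strata of width ``bin_width``.

    Bin edges are aligned to multiples of the width and span the
    observed range; proportions (fraction of days per bin) sum to 1.
    Empty interior bins are kept so the strata cover the range.
    """
    if bin_width <= 0:
        raise ParameterError(f"bin_width must be > 0, got {bin_width}")
    if len(daily) == 0:
        raise EmptyInputError("bin_distribution requires a non-empty daily series")

    x = daily.daily_mean
    idx = np.floor(x / bin_width).astype(int)  # left-closed bin index
    first, last = int(idx.min()), int(idx.max())
    counts = np.bincount(idx - first, minlength=last - first + 1)
    n = len(x)
    cats = []
    for k, cnt in enumerate(counts):
        lower = (first + k) * bin_width
        cats.append(
            ExposureCategory(
                lower=lower, upper=lower + bin_width,
                midpoint=lower + bin_width / 2.0, proportion=cnt / n,
            )
        )
    assert math.isclose(sum(c.proportion for c in cats), 1.0, abs_tol=1e-12)
    return cats


def summary_frame(summaries: dict[str, dict[str, AnnualExposureSummary]]) -> pd.DataFrame:
    """Tabulate per-city, per-variable annual summaries.

    ``summaries`` maps city -> variable -> summary; the output mirrors
    the conventional air-quality reporting layout (city, variable, max,
    min, mean, sd, n_days).
    """
    records = [
        {"city": city, "variable": var, "max": s.max, "min": s.min,
         "mean": s.mean, "sd": s.sd, "n_days": s.n_days}
        for city, per_var in summaries.items()
        for var, s in per_var.items()
    ]
    return pd.DataFrame.from_records(records)
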