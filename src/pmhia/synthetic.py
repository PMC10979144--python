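"""Synthetic hourly PM2.5 and meteorology with known ground truth.

The study's raw monitoring feeds were never released, so every stage
of the pipeline is exercised on simulated data drawn from exactly the
generative model the seasonal regression assumes: the daily PM2.5 mean
is a linear function of month effects, a day-index trend and daily
meteorological covariates plus i.i.d. Gaussian noise; covariates follow
seasonal sinusoids with their own noise, calibrated so that annual
summaries fall inside the ranges observed in Iranian cities.

Hourly values are the daily mean plus within-day noise that is centred
per day, so the 24-h average of a complete day reproduces the model
value exactly — with noise_sd = 0, no missing hours and no sentinels,
OLS on the aggregated daily series recovers the true coefficients to
machine precision.  A configurable fraction of zero/negative sentinel
values is injected into the pollutant series to exercise the cleaning
rules; the truth record counts them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .crf import CRFSpec, IERParams
from .errors import ValidationError
from .io_ingest import EndpointTable, HourlySeries, PopulationSpec, write_hourly
from .reference import ALL_CAUSE_RR, endpoint_table
from .timeseries import MONTH_NAMES

__all__ = [
    "CovariateGen",
    "SimConfig",
    "SimResult",
    "simulate_hourly",
    "write_sim_dir",
    "fixture_endpoints",
    "fixture_crfs",
]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class CovariateGen:
    """Seasonal sinusoid generator for one daily meteorological covariate.

    value(d) = mean + amplitude * cos(2π (doy(d) − peak_day) / 365.25) + N(0, noise_sd²),
    clipped to [clip_min, clip_max] where given.
    """

    mean: float
    amplitude: float
    peak_day: float  # day of year at the seasonal maximum
    noise_sd: float
    clip_min: float | None = None
    clip_max: float | None = None


def _default_covariates() -> dict[str, CovariateGen]:
    # ranges chosen to resemble published annual summaries for Iranian cities
    return {
        "temperature": CovariateGen(15.0, 15.0, 200.0, 3.0),
        "relative_humidity": CovariateGen(65.0, 15.0, 15.0, 5.0, clip_min=5.0, clip_max=100.0),
        "wind_direction": CovariateGen(38.0, 8.0, 100.0, 5.0, clip_min=0.0, clip_max=360.0),
        "wind_speed": CovariateGen(35.0, 10.0, 150.0, 8.0, clip_min=0.5),
        "pressure": CovariateGen(170.0, 50.0, 30.0, 25.0, clip_min=0.0),
    }


def _default_slopes() -> dict[str, float]:
    return {
        "temperature": 0.15,
        "relative_humidity": 0.05,
        "wind_direction": 0.05,
        "wind_speed": -0.05,
        "pressure": 0.01,
    }


def _default_month_effects() -> dict[str, float]:
    # summer dust-season elevation relative to the January reference
    return {"May": 2.0, "June": 4.0, "July": 6.0, "August": 3.0, "February": -1.0}


@dataclass
class SimConfig:
    """Parameters of the synthetic city generator.

    The regression truth is (intercept, month_effects relative to the
    January reference, trend per day, covariate slopes) with noise
    standard deviation ``noise_sd`` (µg/m³).
    """

    seed: int = 0
    start: str = "2019-01-01"
    n_days: int = 365
    intercept: float = 12.0
    month_effects: dict[str, float] = field(default_factory=_default_month_effects)
    trend: float = 0.005  # µg/m³ per day
    covariate_slopes: dict[str, float] = field(default_factory=_default_slopes)
    covariates: dict[str, CovariateGen] = field(default_factory=_default_covariates)
    noise_sd: float = 5.0  # daily model noise, µg/m³
    within_day_sd: float = 2.0  # hourly scatter around the daily mean
    missing_prob: float = 0.05  # independent per-hour drop probability
    sentinel_prob: float = 0.01  # zero/negative injection into PM2.5 hours

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.within_day_sd < 0:
            raise ValidationError("noise standard deviations must be >= 0")
        if not 0 <= self.missing_prob < 1:
            raise ValidationError("missing_prob must lie in [0, 1)")
        if not 0 <= self.sentinel_prob < 1:
            raise ValidationError("sentinel_prob must lie in [0, 1)")
        if self.n_days < 1:
            raise ValidationError("date range must be non-empty")
        unknown = set(self.covariate_slopes) - set(self.covariates)
        if unknown:
            raise ValidationError(f"slopes for undefined covariates: {sorted(unknown)}")
        bad = set(self.month_effects) - set(MONTH_NAMES)
        if bad:
            raise ValidationError(f"unknown month(s) in month_effects: {sorted(bad)}")


@dataclass
class SimResult:
    """Generated series plus the ground-truth record."""

    pm25: HourlySeries
    covariates: dict[str, HourlySeries]
    truth: dict
    daily_model_mean: pd.Series  # exact Eq-model daily mean per date


def _hourly_from_daily(
    rng: np.random.Generator,
    dates: pd.DatetimeIndex,
    daily: np.ndarray,
    within_day_sd: float,
) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Expand daily values to 24 hourly ones with per-day-centred noise."""
    n_days = len(dates)
    noise = rng.standard_normal((n_days, 24))
    noise -= noise.mean(axis=1, keepdims=True)  # keep the 24-h mean exact
    hours = (daily[:, None] + within_day_sd * noise).ravel()
    ts = pd.DatetimeIndex(
        np.repeat(dates.to_numpy(), 24) + np.tile(pd.to_timedelta(np.arange(24), "h"), n_days)
    )
    return ts, hours


def _thin(rng, ts, values, missing_prob):
    if missing_prob == 0:
        return ts, values, 0
    keep = rng.random(len(values)) >= missing_prob
    return ts[keep], values[keep], int((~keep).sum())


def simulate_hourly(config: SimConfig) -> SimResult:
    """Generate one synthetic city.

    The same seed always yields byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(config.start, periods=config.n_days, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)

    # daily covariates
    daily_cov: dict[str, np.ndarray] = {}
    for name, gen in config.covariates.items():
        x = (
            gen.mean
            + gen.amplitude * np.cos(2 * np.pi * (doy - gen.peak_day) / DAYS_PER_YEAR)
            + gen.noise_sd * rng.standard_normal(config.n_days)
        )
        daily_cov[name] = np.clip(
            x,
            -np.inf if gen.clip_min is None else gen.clip_min,
            np.inf if gen.clip_max is None else gen.clip_max,
        )

    # daily PM2.5 mean from the linear model
    month_effect = np.array(
        [config.month_effects.get(MONTH_NAMES[m - 1], 0.0) for m in dates.month]
    )
    trend_term = config.trend * np.arange(config.n_days, dtype=float)
    pm_daily = config.intercept + month_effect + trend_term
    for name, slope in config.covariate_slopes.items():
        pm_daily = pm_daily + slope * daily_cov[name]
    eps = config.noise_sd * rng.standard_normal(config.n_days)
    pm_daily = pm_daily + eps

    # hourly expansion
    ts_pm, pm_hours = _hourly_from_daily(rng, dates, pm_daily, config.within_day_sd)
    cov_hourly: dict[str, HourlySeries] = {}
    n_missing = {}
    for name in config.covariates:
        ts_c, vals_c = _hourly_from_daily(rng, dates, daily_cov[name], config.within_day_sd)
        ts_c, vals_c, dropped = _thin(rng, ts_c, vals_c, config.missing_prob)
        n_missing[name] = dropped
        cov_hourly[name] = HourlySeries(ts_c, vals_c, name, 0)

    ts_pm, pm_hours, n_missing["pm25"] = _thin(rng, ts_pm, pm_hours, config.missing_prob)

    # sentinel injection: zero or negative values the cleaning step must remove
    pm_hours = pm_hours.copy()
    n_sentinels = 0
    if config.sentinel_prob > 0 and len(pm_hours):
        hit = rng.random(len(pm_hours)) < config.sentinel_prob
        n_sentinels = int(hit.sum())
        pm_hours[hit] = np.where(
            rng.random(n_sentinels) < 0.5, 0.0, -rng.uniform(0.5, 5.0, n_sentinels)
        )
    pm25 = HourlySeries(ts_pm, pm_hours, "pm25", 0)

    truth = {
        "seed": config.seed,
        "start": config.start,
        "n_days": config.n_days,
        "intercept": config.intercept,
        "month_effects": dict(config.month_effects),
        "trend": config.trend,
        "covariate_slopes": dict(config.covariate_slopes),
        "noise_sd": config.noise_sd,
        "within_day_sd": config.within_day_sd,
        "n_missing": n_missing,
        "n_sentinels_injected": n_sentinels,
        "n_nonpositive": int((pm_hours <= 0).sum()),
    }
    return SimResult(
        pm25=pm25,
        covariates=cov_hourly,
        truth=truth,
        daily_model_mean=pd.Series(pm_daily, index=dates),
    )


def write_sim_dir(result: SimResult, outdir) -> None:
    """Write a simulated city as the CSV dialect the readers ingest,
    plus the ground-truth record as ``truth.json``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_hourly(result.pm25, outdir / "pm25.csv")
    for name, series in result.covariates.items():
        write_hourly(series, outdir / f"{name}.csv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(result.truth, fh, indent=2)


# ---------------------------------------------------------------------------
# published-table fixtures

#: synthetic round at-risk populations per city (persons); the study's
#: true at-risk counts were not published, so these are invented values
#: of realistic magnitude, not estimates of the real populations.
FIXTURE_POPULATIONS = {
    "Arak":    (600_000,   dict([(">=30", 300_000), (">=25", 340_000), ("<=5", 60_000)])),
    "Esfahan": (2_000_000, dict([(">=30", 1_000_000), (">=25", 1_160_000), ("<=5", 180_000)])),
    "Ahvaz":   (1_300_000, dict([(">=30", 650_000), (">=25", 750_000), ("<=5", 120_000)])),
    "Tabriz":  (1_600_000, dict([(">=30", 800_000), (">=25", 930_000), ("<=5", 140_000)])),
    "Shiraz":  (1_900_000, dict([(">=30", 950_000), (">=25", 1_100_000), ("<=5", 170_000)])),
    "Karaj":   (1_600_000, dict([(">=30", 800_000), (">=25", 930_000), ("<=5", 140_000)])),
    "Mashhad": (3_300_000, dict([(">=30", 1_650_000), (">=25", 1_910_000), ("<=5", 300_000)])),
}


def fixture_endpoints() -> tuple[EndpointTable, list[PopulationSpec]]:
    """Published baseline incidences plus synthetic round populations.

    The endpoint table carries the published per-city baseline
    incidences and age groups; the population counts are synthetic
    (see ``FIXTURE_POPULATIONS``).
    """
    populations = [
        PopulationSpec(city=city, n_total=total, n_at_risk=groups)
        for city, (total, groups) in FIXTURE_POPULATIONS.items()
    ]
    return endpoint_table(), populations


def fixture_crfs() -> dict[str, CRFSpec]:
    """CRF set matching :func:`fixture_endpoints`.

    The all-cause curve is the published log-linear RR 1.062
    (1.04–1.083) per 10 µg/m³.  The cause-specific integrated
    exposure–response parameter sets are synthetic placeholders of
    plausible shape (no parameter values were published); they exist so
    the full pipeline runs end to end, not to reproduce published
    cause-specific estimates.
    """
    ier = {
        "ihd":    IERParams(alpha=1.2, gamma=0.04, delta=0.7, z_cf=7.5),
        "stroke": IERParams(alpha=1.0, gamma=0.03, delta=0.7, z_cf=7.5),
        "copd":   IERParams(alpha=0.6, gamma=0.02, delta=0.8, z_cf=7.5),
        "lc":     IERParams(alpha=0.7, gamma=0.02, delta=0.8, z_cf=7.5),
        "alri":   IERParams(alpha=1.5, gamma=0.05, delta=0.6, z_cf=7.5),
    }
    crfs = {"all_cause_loglinear": ALL_CAUSE_RR}
    for name, params in ier.items():
        crfs[f"{name}_ier"] = CRFSpec(form="ier", ier_params=params, name=f"{name}_ier")
    return crfs
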