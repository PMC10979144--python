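"""Reading, cleaning and writing hourly series; configuration parsing.

Hourly pollutant and meteorology feeds arrive as two-column CSV
(``timestamp,value``).  Pollutant series are cleaned by removing zero
and negative records (instrument sentinels); meteorology series keep
non-positive values since e.g. winter temperatures are legitimately
negative.  Timestamps must be unique; duplicates are treated as a feed
fault rather than silently averaged.

The study configuration (cities, health endpoints with baseline
incidences, at-risk populations, CRF definitions) is a YAML file; see
:func:`read_config`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crf import CRFSpec, IERParams
from .errors import ConfigurationError, InputFormatError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "HourlySeries",
    "EndpointRow",
    "EndpointTable",
    "PopulationSpec",
    "read_hourly",
    "write_hourly",
    "clean_pollutant",
    "read_config",
]


@dataclass
class HourlySeries:
    """An hourly time series of one variable.

    ``timestamps`` are strictly increasing calendar datetimes,
    ``values`` the matching measurements.  ``n_dropped`` counts records
    removed during cleaning (non-positive pollutant values, unparseable
    or missing values).
    """

    timestamps: pd.DatetimeIndex
    values: np.ndarray
    variable_name: str
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.timestamps) != len(self.values):
            raise ValidationError("timestamps and values differ in length")
        if len(self.timestamps) > 1 and not self.timestamps.is_monotonic_increasing:
            raise ValidationError("timestamps must be increasing")
        if self.timestamps.has_duplicates:
            dup = self.timestamps[self.timestamps.duplicated()][0]
            raise ValidationError(f"duplicate timestamp {dup}")
        if self.n_dropped < 0:
            raise ValidationError("n_dropped must be >= 0")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"timestamp": self.timestamps, "value": self.values})


@dataclass(frozen=True)
class EndpointRow:
    """One (city, endpoint) row: baseline incidence and its CRF."""

    city: str
    endpoint: str
    age_group: str
    baseline_incidence: float  # cases per 100,000 per year
    crf: str  # name of the CRFSpec this endpoint uses

    def __post_init__(self) -> None:
        if self.baseline_incidence < 0:
            raise ValidationError(
                f"baseline incidence must be >= 0 "
                f"({self.city}/{self.endpoint}: {self.baseline_incidence})"
            )


@dataclass
class EndpointTable:
    """Collection of endpoint rows; (city, endpoint) pairs unique."""

    rows: list[EndpointRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for r in self.rows:
            key = (r.city, r.endpoint)
            if key in seen:
                raise ValidationError(f"duplicate endpoint row {key}")
            seen.add(key)

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def for_city(self, city: str) -> list[EndpointRow]:
        return [r for r in self.rows if r.city == city]


@dataclass(frozen=True)
class PopulationSpec:
    """Total and age-group-specific at-risk populations for one city."""

    city: str
    n_total: int
    n_at_risk: dict  # age-group label -> persons

    def __post_init__(self) -> None:
        for group, n in self.n_at_risk.items():
            if not 0 <= n <= self.n_total:
                raise ValidationError(
                    f"{self.city}: at-risk population for {group!r} ({n}) "
                    f"outside [0, {self.n_total}]"
                )


def clean_pollutant(values: np.ndarray) -> tuple[np.ndarray, int]:
    """Remove zero and negative pollutant values.

    Returns the retained values and the number removed.  Idempotent.
    """
    values = np.asarray(values, dtype=float)
    keep = values > 0
    return values[keep], int((~keep).sum())


def read_hourly(path, variable_name: str, pollutant: bool = False) -> HourlySeries:
    """Read an hourly CSV (columns ``timestamp,value``) into a series.

    With ``pollutant=True``, records with value <= 0 are removed and
    counted in ``n_dropped`` (zero and negative concentrations are
    instrument sentinels).  Meteorology series retain non-positive
    values.  Rows whose value is missing are dropped in both modes.
    """
    df = pd.read_csv(path)
    missing = {"timestamp", "value"} - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        return HourlySeries(pd.DatetimeIndex([]), np.array([]), variable_name, 0)

    ts = pd.to_datetime(df["timestamp"], errors="coerce", format="ISO8601")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise InputFormatError(
            f"{path}: unparseable timestamp {df['timestamp'].iloc[row]!r} at row {row + 2}"
        )

    values = pd.to_numeric(df["value"], errors="coerce").to_numpy(dtype=float)
    n_dropped = int(np.isnan(values).sum())
    keep = ~np.isnan(values)
    ts, values = ts[keep], values[keep]
    if pollutant:
        drop = values <= 0
        n_dropped += int(drop.sum())
        ts, values = ts[~drop], values[~drop]

    order = np.argsort(ts.to_numpy(), kind="stable")
    series = HourlySeries(
        pd.DatetimeIndex(ts.to_numpy()[order]),
        values[order],
        variable_name,
        n_dropped,
    )
    if n_dropped:
        logger.info("%s: dropped %d record(s) from %s", variable_name, n_dropped, path)
    return series


def write_hourly(series: HourlySeries, path) -> None:
    """Write a series back to the two-column CSV dialect read_hourly reads."""
    series.to_frame().assign(
        timestamp=series.timestamps.strftime("%Y-%m-%dT%H:%M:%S")
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration


def _parse_crf(name: str, spec: dict) -> CRFSpec:
    kwargs = dict(spec)
    form = kwargs.pop("form", None)
    if form is None:
        raise ConfigurationError(f"CRF {name!r}: missing 'form'")
    for key in ("ier_params", "ier_params_low", "ier_params_high"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = IERParams(**kwargs[key])
    try:
        return CRFSpec(form=form, name=name, **kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"CRF {name!r}: {exc}") from exc


def read_config(path) -> tuple[EndpointTable, list[PopulationSpec], dict[str, CRFSpec]]:
    """Read a study configuration YAML file.

    Expected top-level sections::

        crfs:        {name: {form: ..., rr_central: ..., ...}, ...}
        endpoints:   [{city, endpoint, age_group, baseline_incidence, crf}, ...]
        populations: [{city, n_total, n_at_risk: {">=30": ..., ...}}, ...]

    Every endpoint row must reference a CRF defined in ``crfs``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}

    crfs = {name: _parse_crf(name, spec) for name, spec in (cfg.get("crfs") or {}).items()}

    rows = []
    for entry in cfg.get("endpoints") or []:
        row = EndpointRow(
            city=entry["city"],
            endpoint=entry["endpoint"],
            age_group=str(entry.get("age_group", "")),
            baseline_incidence=float(entry["baseline_incidence"]),
            crf=entry["crf"],
        )
        if row.crf not in crfs:
            raise ConfigurationError(
                f"endpoint {row.city}/{row.endpoint} references undefined CRF {row.crf!r}"
            )
        rows.append(row)
    endpoints = EndpointTable(rows)

    populations = [
        PopulationSpec(
            city=entry["city"],
            n_total=int(entry["n_total"]),
            n_at_risk={str(k): int(v) for k, v in (entry.get("n_at_risk") or {}).items()},
        )
        for entry in cfg.get("populations") or []
    ]
    return endpoints, populations, crfs
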