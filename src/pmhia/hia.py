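"""Attributable proportion, attributable rate and excess cases.

The population attributable proportion (AP) of a health outcome under
an exposure distribution {(c, P(c))} with relative risks RR(c) is

    AP = Σ_c (RR(c) − 1) · P(c)  /  Σ_c RR(c) · P(c)

With a single exposure category this reduces to (RR − 1) / RR.  The
attributable rate is IE = I × AP (cases per 100,000 per year, with I
the baseline incidence on the same scale), and the absolute excess case
count in an at-risk population of N persons is NE = IE × N / 100,000.

All three quantities are propagated separately at the low / central /
high relative-risk bounds; rounding happens only at report emission
(AP as percent to 2 decimals, IE to 2 decimals, NE to integers).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import pandas as pd

from .crf import CRFSpec, RRTriple, relative_risk
from .errors import ConfigurationError, EmptyInputError, ParameterError, ValidationError
from .exposure import DailySeries, ExposureCategory, annual_summary, bin_distribution
from .io_ingest import EndpointTable, PopulationSpec

__all__ = [
    "Triple",
    "ImpactResult",
    "attributable_proportion",
    "attributable_rate",
    "excess_cases",
    "run_hia",
    "results_frame",
]


class Triple(NamedTuple):
    """A quantity at the low / central / high relative-risk bounds."""

    low: float
    central: float
    high: float

    def map(self, fn) -> "Triple":
        return Triple(fn(self.low), fn(self.central), fn(self.high))


@dataclass(frozen=True)
class ImpactResult:
    """AP, IE, NE triples for one city × endpoint."""

    city: str
    endpoint: str
    ap: Triple  # fraction
    ie: Triple  # cases per 100,000 per year
    ne: Triple  # cases
    n_at_risk: int

    def __post_init__(self) -> None:
        for name, t in (("ap", self.ap), ("ie", self.ie), ("ne", self.ne)):
            if not (t.low <= t.central <= t.high):
                raise ValidationError(f"{name} bounds out of order for "
                                      f"{self.city}/{self.endpoint}: {t}")
        if not 0 <= self.ap.central < 1:
            raise ValidationError(f"AP must lie in [0, 1): {self.ap.central}")


def attributable_proportion(
    categories: Sequence[ExposureCategory], spec: CRFSpec
) -> Triple:
    """Evaluate the category-sum AP at each relative-risk bound."""
    if len(categories) == 0:
        raise EmptyInputError("attributable_proportion requires >= 1 category")
    rrs: list[RRTriple] = [relative_risk(spec, c.midpoint) for c in categories]
    out = []
    for bound in range(3):  # low, central, high
        num = sum((rr[bound] - 1.0) * c.proportion for rr, c in zip(rrs, categories))
        den = sum(rr[bound] * c.proportion for rr, c in zip(rrs, categories))
        out.append(num / den)
    return Triple(*out)


def attributable_rate(baseline_incidence: float, ap: float) -> float:
    """IE = I × AP, cases per 100,000 per year."""
    if baseline_incidence < 0:
        raise ValidationError(f"baseline incidence must be >= 0, got {baseline_incidence}")
    if not 0 <= ap < 1:
        raise ParameterError(f"AP must lie in [0, 1), got {ap}")
    return baseline_incidence * ap


def excess_cases(ie: float, n_at_risk: float) -> float:
    """NE = IE × N / 100,000 — absolute attributable cases.

    ``ie`` is per 100,000 persons, so the at-risk population is scaled
    by the same factor.  Returned unrounded; report emission rounds to
    the nearest integer.
    """
    if n_at_risk < 0:
        raise ValidationError(f"population must be >= 0, got {n_at_risk}")
    return ie * n_at_risk / 100_000.0


def _single_category(mean_concentration: float) -> list[ExposureCategory]:
    c = float(mean_concentration)
    return [ExposureCategory(lower=c, upper=c, midpoint=c, proportion=1.0)]


def run_hia(
    exposure: dict[str, DailySeries],
    endpoints: EndpointTable,
    populations: Sequence[PopulationSpec],
    crfs: dict[str, CRFSpec],
    mode: str = "binned",
    bin_width: float = 1.0,
) -> list[ImpactResult]:
    """Chain exposure → RR → AP → IE → NE for every endpoint row.

    Parameters
    ----------
    exposure
        Per-city daily PM2.5 series.
    endpoints, populations, crfs
        Study configuration (see :func:`pmhia.io_ingest.read_config`).
    mode
        ``"binned"`` evaluates the AP over the binned daily-mean
        distribution; ``"annual_mean"`` uses a single category at the
        annual mean concentration.
    """
    if mode not in ("binned", "annual_mean"):
        raise ParameterError(f"mode must be 'binned' or 'annual_mean', got {mode!r}")
    pops = {p.city: p for p in populations}
    results = []
    for row in endpoints:
        if row.city not in exposure:
            raise ConfigurationError(f"no exposure series for city {row.city!r}")
        if row.city not in pops:
            raise ConfigurationError(f"no population entry for city {row.city!r}")
        if row.crf not in crfs:
            raise ConfigurationError(
                f"endpoint {row.city}/{row.endpoint} references undefined CRF {row.crf!r}"
            )
        pop = pops[row.city]
        if row.age_group not in pop.n_at_risk:
            raise ConfigurationError(
                f"{row.city}: no at-risk population for age group {row.age_group!r}"
            )
        daily = exposure[row.city]
        if mode == "binned":
            cats = bin_distribution(daily, bin_width=bin_width)
        else:
            cats = _single_category(annual_summary(daily).mean)
        n = pop.n_at_risk[row.age_group]
        ap = attributable_proportion(cats, crfs[row.crf])
        ie = ap.map(lambda a: attributable_rate(row.baseline_incidence, a))
        ne = ie.map(lambda e: excess_cases(e, n))
        results.append(
            ImpactResult(city=row.city, endpoint=row.endpoint,
                         ap=ap, ie=ie, ne=ne, n_at_risk=n)
        )
    return results


def results_frame(results: Sequence[ImpactResult], rounded: bool = True) -> pd.DataFrame:
    """Tabulate impact results; rounding applied only here.

    AP is reported as percent (2 decimals), IE per 100,000 (2 decimals)
    and NE as integer counts, the conventional reporting precision.
    """
    rows = []
    for r in results:
        ap = r.ap.map(lambda v: v * 100.0)
        if rounded:
            ap = ap.map(lambda v: round(v, 2))
            ie = r.ie.map(lambda v: round(v, 2))
            ne = r.ne.map(lambda v: int(round(v)))
        else:
            ie, ne = r.ie, r.ne
        rows.append(
            {"city": r.city, "endpoint": r.endpoint,
             "ap_low": ap.low, "ap": ap.central, "ap_high": ap.high,
             "ie_low": ie.low, "ie": ie.central, "ie_high": ie.high,
             "ne_low": ne.low, "ne": ne.central, "ne_high": ne.high,
             "n_at_risk": r.n_at_risk}
        )
    return pd.DataFrame(rows)
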