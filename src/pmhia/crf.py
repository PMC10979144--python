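"""Concentration–response functions for long-term PM2.5 exposure.

A concentration–response function (CRF) maps an ambient concentration
``c`` (µg/m³) to a relative risk RR(c) ≥ 1 relative to a counterfactual
concentration below which no excess risk is attributed.  Three forms are
supported:

``log_linear``
    The AirQ+-style log-linear curve.  Given a published relative risk
    ``rr`` per ``increment`` µg/m³ (conventionally 10) above a cutoff
    ``c0``::

        RR(c) = exp( ln(rr) / increment * max(0, c - c0) )

    so one full increment above the cutoff reproduces the published RR
    and RR(c0 + k·increment) = rr**k.

``ier``
    The integrated exposure–response form used for cause-specific
    mortality (IHD, stroke, COPD, lung cancer, ALRI)::

        RR(z) = 1                                      for z <= z_cf
        RR(z) = 1 + alpha * (1 - exp(-gamma * (z - z_cf)**delta))   otherwise

    bounded above by 1 + alpha.  Parameters are user-supplied.

``implied_ap``
    Single-category inversion of an already-published attributable
    proportion: RR = 1 / (1 - ap).  Useful for reproducing published
    impact tables whose underlying CRF configuration is not recoverable.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import ParameterError, ValidationError

__all__ = ["IERParams", "CRFSpec", "RRTriple", "relative_risk", "rr_curve", "export_rr_curve"]

#: default counterfactual: the WHO annual PM2.5 guideline, µg/m³
DEFAULT_CUTOFF = 10.0


class RRTriple(NamedTuple):
    """Relative risk evaluated at the low / central / high CRF bounds."""

    low: float
    central: float
    high: float


@dataclass(frozen=True)
class IERParams:
    """Parameters of the integrated exposure–response curve."""

    alpha: float
    gamma: float
    delta: float
    z_cf: float

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValidationError(f"IER alpha must be >= 0, got {self.alpha}")
        if self.gamma <= 0:
            raise ValidationError(f"IER gamma must be > 0, got {self.gamma}")
        if self.delta <= 0:
            raise ValidationError(f"IER delta must be > 0, got {self.delta}")
        if self.z_cf < 0:
            raise ValidationError(f"IER z_cf must be >= 0, got {self.z_cf}")


@dataclass(frozen=True)
class CRFSpec:
    """Definition of one concentration–response function.

    Parameters
    ----------
    form
        One of ``log_linear``, ``ier``, ``implied_ap``.
    rr_central, rr_low, rr_high
        Relative risk per ``increment`` µg/m³ (log_linear form); the low
        and high values are the bounds of the published 95% CI.
    increment
        Concentration increment the published RR refers to, µg/m³.
    cutoff
        Counterfactual concentration c0, µg/m³; no excess risk below it.
    ier_params
        Central IER parameter set (``ier`` form).
    ier_params_low, ier_params_high
        Optional bound parameter sets; when absent only the central
        estimate is propagated (low = high = central).
    ap_value
        Published attributable proportion, as a fraction (``implied_ap``).
    """

    form: str
    rr_central: float | None = None
    rr_low: float | None = None
    rr_high: float | None = None
    increment: float = 10.0
    cutoff: float = DEFAULT_CUTOFF
    ier_params: IERParams | None = None
    ier_params_low: IERParams | None = None
    ier_params_high: IERParams | None = None
    ap_value: float | None = None
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.form not in ("log_linear", "ier", "implied_ap"):
            raise ValidationError(f"unknown CRF form {self.form!r}")
        if self.increment <= 0:
            raise ValidationError("increment must be > 0")
        if self.cutoff < 0:
            raise ValidationError("cutoff must be >= 0")
        if self.form == "log_linear":
            if self.rr_central is None:
                raise ValidationError("log_linear CRF requires rr_central")
            low = self.rr_low if self.rr_low is not None else self.rr_central
            high = self.rr_high if self.rr_high is not None else self.rr_central
            if not (low <= self.rr_central <= high):
                raise ValidationError(
                    f"require rr_low <= rr_central <= rr_high, got "
                    f"{low} / {self.rr_central} / {high}"
                )
        elif self.form == "ier":
            if self.ier_params is None:
                raise ValidationError("ier CRF requires ier_params")
        elif self.form == "implied_ap":
            if self.ap_value is None:
                raise ValidationError("implied_ap CRF requires ap_value")
            if self.ap_value >= 1:
                raise ParameterError(f"ap_value must be < 1, got {self.ap_value}")


def _log_linear_rr(rr: float, increment: float, cutoff: float, c: float) -> float:
    return math.exp(math.log(rr) / increment * max(0.0, c - cutoff))


def _ier_rr(p: IERParams, c: float) -> float:
    if c <= p.z_cf:
        return 1.0
    return 1.0 + p.alpha * (1.0 - math.exp(-p.gamma * (c - p.z_cf) ** p.delta))


def relative_risk(spec: CRFSpec, c: float) -> RRTriple:
    """Evaluate a CRF at concentration ``c`` (µg/m³).

    Returns the (low, central, high) relative risks.  For forms without
    uncertainty information the three values coincide.
    """
    if c < 0:
        raise ParameterError(f"concentration must be >= 0, got {c}")
    if spec.form == "log_linear":
        central = _log_linear_rr(spec.rr_central, spec.increment, spec.cutoff, c)
        low = (
            _log_linear_rr(spec.rr_low, spec.increment, spec.cutoff, c)
            if spec.rr_low is not None
            else central
        )
        high = (
            _log_linear_rr(spec.rr_high, spec.increment, spec.cutoff, c)
            if spec.rr_high is not None
            else central
        )
        return RRTriple(low, central, high)
    if spec.form == "ier":
        central = _ier_rr(spec.ier_params, c)
        low = _ier_rr(spec.ier_params_low, c) if spec.ier_params_low else central
        high = _ier_rr(spec.ier_params_high, c) if spec.ier_params_high else central
        return RRTriple(low, central, high)
    # implied_ap: RR = 1 / (1 - AP), concentration-independent
    rr = 1.0 / (1.0 - spec.ap_value)
    return RRTriple(rr, rr, rr)


def rr_curve(spec: CRFSpec, concentrations: Sequence[float]) -> dict:
    """Evaluate a CRF on a concentration grid.

    Returns a dict with keys ``concentration``, ``rr_low``, ``rr``,
    ``rr_high`` (lists of floats), suitable for JSON export.
    """
    grid = [float(c) for c in np.asarray(concentrations, dtype=float)]
    triples = [relative_risk(spec, c) for c in grid]
    return {
        "name": spec.name,
        "form": spec.form,
        "concentration": grid,
        "rr_low": [t.low for t in triples],
        "rr": [t.central for t in triples],
        "rr_high": [t.high for t in triples],
    }


def export_rr_curve(spec: CRFSpec, concentrations: Sequence[float], path) -> None:
    """Write :func:`rr_curve` output as JSON to ``path``."""
    with open(path, "w") as fh:
        json.dump(rr_curve(spec, concentrations), fh, indent=2)
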