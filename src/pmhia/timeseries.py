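"""Seasonal linear model of daily PM2.5 concentrations.

The model regresses the 24-h mean concentration on calendar-month
indicator variables (one reference month omitted), a linear day-index
trend, and daily-mean meteorological covariates:

    PM2.5_t = b0 + b_Feb·[Feb] + … + b_Dec·[Dec] + b_trend·t
              + b_1·X_1 + … + b_K·X_K + e_t,     e_t iid N(0, s²)

fitted by ordinary least squares.  Standard errors come from
s²(XᵀX)⁻¹ with s² = RSS/(n − p) and two-sided p-values from the t
distribution with n − p degrees of freedom.  No autocorrelation
correction is applied: the model is a plain linear model by design.
"""

from __future__ import annotations

import calendar
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import CollinearityError, EmptyInputError, ValidationError
from .exposure import DailySeries

__all__ = ["TSDesign", "RegressionFit", "build_design", "fit_ols", "coefficient_table"]

MONTH_NAMES = list(calendar.month_name)[1:]  # January .. December


@dataclass
class TSDesign:
    """Response and design matrix for the seasonal linear model.

    ``X`` holds an intercept column ``const``, the meteorological
    covariates, the ``trend`` day index and one 0/1 column per calendar
    month present in the data except the reference month.  Rows with
    any missing covariate are dropped; ``n_dropped`` counts them.
    """

    y: pd.Series
    X: pd.DataFrame
    reference_month: str
    covariates: list[str]
    month_columns: list[str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if len(self.y) != len(self.X):
            raise ValidationError("response and design differ in length")
        months = self.X[self.month_columns]
        if len(self.month_columns) and (months.sum(axis=1) > 1).any():
            raise ValidationError("month indicators must be mutually exclusive")

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class RegressionFit:
    """OLS estimates with their standard errors and t-test p-values."""

    terms: list[str]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2: float  # residual variance RSS/(n-p)
    n_used: int
    r_squared: float
    df_resid: int
    resid: np.ndarray = field(repr=False)
    design: TSDesign = field(repr=False)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-term t-based confidence intervals."""
        from scipy import stats

        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )


def build_design(
    pm25: DailySeries,
    met: dict[str, DailySeries] | None = None,
    reference_month: str | None = None,
) -> TSDesign:
    """Assemble the seasonal design from daily PM2.5 and covariates.

    Dates are inner-joined across the response and every covariate;
    the trend is the 0-based index over the retained dates.  The
    reference (omitted) month defaults to the first calendar month
    appearing in the retained series.
    """
    met = met or {}
    frame = pm25.to_frame().set_index("date")[["daily_mean"]].rename(
        columns={"daily_mean": "pm25"}
    )
    for name, cov in met.items():
        frame = frame.join(
            cov.to_frame().set_index("date")[["daily_mean"]].rename(
                columns={"daily_mean": name}
            ),
            how="outer",
        )
    n_raw = len(frame)
    frame = frame.dropna().sort_index()
    if frame.empty:
        raise EmptyInputError("no overlapping dates across response and covariates")
    n_dropped = n_raw - len(frame)

    months_present = [MONTH_NAMES[m - 1] for m in sorted(set(frame.index.month))]
    if reference_month is None:
        reference_month = MONTH_NAMES[frame.index[0].month - 1]
    elif reference_month not in MONTH_NAMES:
        raise ValidationError(f"unknown month {reference_month!r}")

    covariates = list(met)
    X = pd.DataFrame(index=frame.index)
    X["const"] = 1.0
    for name in covariates:
        X[name] = frame[name]
    X["trend"] = np.arange(len(frame), dtype=float)
    month_columns = []
    month_of_row = frame.index.month
    for name in months_present:
        if name == reference_month:
            continue
        X[name] = (month_of_row == MONTH_NAMES.index(name) + 1).astype(float)
        month_columns.append(name)

    return TSDesign(
        y=frame["pm25"], X=X, reference_month=reference_month,
        covariates=covariates, month_columns=month_columns, n_dropped=n_dropped,
    )


def _dependent_columns(X: pd.DataFrame) -> list[str]:
    """Name columns involved in a rank deficiency via pivoted QR."""
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    _, r, piv = __import__("scipy.linalg", fromlist=["qr"]).qr(
        arr, mode="economic", pivoting=True
    )
    return sorted(X.columns[piv[rank:]].tolist())


def fit_ols(design: TSDesign) -> RegressionFit:
    """Fit the seasonal model by ordinary least squares.

    Raises :class:`CollinearityError` naming the dependent columns if
    the design matrix is rank deficient.  A constant response (zero
    total variance) is legal; its R² is reported as 0.
    """
    X = design.X
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < X.shape[1]:
        bad = _dependent_columns(X)
        raise CollinearityError(f"design matrix rank deficient; dependent column(s): {bad}")
    if design.n < X.shape[1] + 1:
        raise ValidationError(
            f"need at least p+1 = {X.shape[1] + 1} rows, got {design.n}"
        )
    res = sm.OLS(design.y.to_numpy(dtype=float), arr).fit()
    terms = list(X.columns)
    idx = pd.Index(terms)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(res.rsquared)
    if not np.isfinite(r2):  # zero-variance response
        r2 = 0.0
    return RegressionFit(
        terms=terms,
        params=pd.Series(res.params, index=idx),
        bse=pd.Series(res.bse, index=idx),
        tvalues=pd.Series(res.tvalues, index=idx),
        pvalues=pd.Series(res.pvalues, index=idx),
        sigma2=float(res.mse_resid),
        n_used=design.n,
        r_squared=r2,
        df_resid=int(res.df_resid),
        resid=np.asarray(res.resid, dtype=float),
        design=design,
    )


def coefficient_table(fit: RegressionFit) -> pd.DataFrame:
    """Report rows (term, Est, SE, P), conventional rounding applied.

    Rows are ordered intercept, covariates, trend, months; estimates
    and standard errors are rounded to 2 decimals, p-values to 3.
    """
    design = fit.design
    order = ["const"] + design.covariates + ["trend"] + design.month_columns
    rows = [
        {
            "term": term,
            "est": round(float(fit.params[term]), 2),
            "se": round(float(fit.bse[term]), 2),
            "p": round(float(fit.pvalues[term]), 3),
        }
        for term in order
    ]
    return pd.DataFrame(rows)
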