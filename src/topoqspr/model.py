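"""Univariate QSPR regression: P = A + B·TI with small-sample inference.

A physicochemical property P (melting point or formula weight) is modelled as
a linear function of a single topological index TI over n compounds.  The
least-squares estimates are

    B = Sxy / Sxx,        A = ȳ − B·x̄,

with Pearson correlation r = Sxy/√(Sxx·Syy), coefficient of determination
r² and the overall-regression F statistic

    F = r²(n − 2) / (1 − r²),

whose p-value is the upper tail of the F(1, n−2) distribution (equivalently a
two-sided t test on the slope, t² = F).  The standard error of the estimate
is √(SSres/(n−2)).  A model is labelled significant when p < 0.05.

Report tables print |r| (so negative-slope models still show a positive
correlation entry) while the signed slope and signed r are kept internally.

The :class:`TopoIndexQSPR` model / :class:`QSPRResults` pair wraps these
computations statsmodels-style: build the model from compound records, call
``fit()``, read estimates and diagnostics off the results object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .graph import CompoundRecord
from .indices import INDEX_IDS, index_table

__all__ = [
    "PROPERTY_IDS",
    "DegenerateDataError",
    "TopoIndexQSPR",
    "QSPRResults",
    "fit_simple_ols",
    "regression_stats",
    "f_upper_tail",
    "correlation_table",
    "prediction_table",
    "fit_all_models",
]

#: Closed enumeration of modelled properties.
PROPERTY_IDS: tuple[str, ...] = ("melting_point", "formula_weight")

SIGNIFICANCE_LEVEL = 0.05


class DegenerateDataError(ValueError):
    """Predictor or response has zero variance, or too few observations."""


def _as_xy(x: Sequence[float], y: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    return x, y


def fit_simple_ols(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Least-squares (A, B) for y = A + B·x; the line passes through (x̄, ȳ).

    Requires n >= 3 and a non-constant predictor.
    """
    x, y = _as_xy(x, y)
    n = x.size
    if n < 3:
        raise DegenerateDataError(f"need at least 3 observations, got {n}")
    xbar = x.mean()
    sxx = float(((x - xbar) ** 2).sum())
    if sxx == 0.0:
        raise DegenerateDataError("predictor has zero variance")
    sxy = float(((x - xbar) * (y - y.mean())).sum())
    b = sxy / sxx
    a = float(y.mean() - b * xbar)
    return a, b


def f_upper_tail(f: float, df1: int, df2: int) -> float:
    """P(F(df1, df2) > f): upper-tail probability of the F distribution."""
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    if not math.isfinite(f) or f < 0:
        raise ValueError(f"F statistic must be finite and >= 0, got {f}")
    return float(stats.f.sf(f, df1, df2))


def regression_stats(
    x: Sequence[float], y: Sequence[float], a: float, b: float
) -> dict:
    """Inference statistics for a fitted line y ≈ a + b·x.

    Returns r_signed, r_abs, r2, f_stat, p_value, se_estimate, significant.
    A perfect fit (r² = 1) yields f_stat = inf and p_value = 0.0, flagged
    ``boundary=True``.
    """
    x, y = _as_xy(x, y)
    n = x.size
    sxx = float(((x - x.mean()) ** 2).sum())
    syy = float(((y - y.mean()) ** 2).sum())
    if syy == 0.0:
        raise DegenerateDataError("response has zero variance")
    sxy = float(((x - x.mean()) * (y - y.mean())).sum())
    r_signed = sxy / math.sqrt(sxx * syy)
    r_signed = max(-1.0, min(1.0, r_signed))
    r2 = r_signed * r_signed
    resid = y - (a + b * x)
    ss_res = float((resid**2).sum())
    se_estimate = math.sqrt(ss_res / (n - 2))
    boundary = 1.0 - r2 < 1e-14
    if boundary:
        f_stat = math.inf
        p_value = 0.0
    else:
        f_stat = r2 * (n - 2) / (1.0 - r2)
        p_value = f_upper_tail(f_stat, 1, n - 2)
    return {
        "n": n,
        "r_signed": r_signed,
        "r_abs": abs(r_signed),
        "r2": r2,
        "f_stat": f_stat,
        "p_value": p_value,
        "se_estimate": se_estimate,
        "significant": p_value < SIGNIFICANCE_LEVEL,
        "boundary": boundary,
    }


@dataclass
class QSPRResults:
    """Estimates and diagnostics of one property-on-index regression."""

    property: str
    index: str
    n: int
    A: float
    B: float
    r_signed: float
    r_abs: float
    r2: float
    f_stat: float
    p_value: float
    se_estimate: float
    significant: bool
    boundary: bool
    x: np.ndarray
    y: np.ndarray

    def predict(self, x0):
        """Fitted value(s) A + B·x0."""
        return self.A + self.B * np.asarray(x0, dtype=float)

    @property
    def residuals(self) -> np.ndarray:
        return self.y - self.predict(self.x)

    @property
    def indicator(self) -> str:
        return "Significant" if self.significant else "Non-Significant"

    def summary(self) -> pd.DataFrame:
        """One-row report table in the published layout (N A B r r² F p)."""
        return pd.DataFrame(
            [
                {
                    "property": self.property,
                    "index": self.index,
                    "N": self.n,
                    "A": self.A,
                    "B": self.B,
                    "r": self.r_abs,
                    "r2": self.r2,
                    "F": self.f_stat,
                    "p": self.p_value,
                    "indicator": self.indicator,
                }
            ]
        )

    def __str__(self) -> str:
        s = self.summary().iloc[0]
        return (
            f"{self.property} = {self.A:.6f} + ({self.B:.6f})·{self.index}   "
            f"[n={self.n}, |r|={self.r_abs:.4f}, r²={self.r2:.4f}, "
            f"F={self.f_stat:.4g}, p={self.p_value:.4g}, {s['indicator']}]"
        )


class TopoIndexQSPR:
    """Simple linear QSPR model of one property on one topological index.

    Parameters
    ----------
    x, y
        Index values (predictor) and property values (response).
    index, property
        Identifiers used in report tables.
    """

    def __init__(
        self,
        x: Sequence[float],
        y: Sequence[float],
        *,
        index: str = "TI",
        property: str = "property",
    ) -> None:
        self.x, self.y = _as_xy(x, y)
        self.index = index
        self.property = property

    @classmethod
    def from_compounds(
        cls,
        compounds: Sequence[CompoundRecord],
        index: str,
        property: str,
        *,
        mm2_variant: str = "default",
    ) -> "TopoIndexQSPR":
        if property not in PROPERTY_IDS:
            raise KeyError(
                f"unknown property {property!r}; expected one of {PROPERTY_IDS}"
            )
        table = index_table(compounds, mm2_variant=mm2_variant)
        y = [getattr(rec, property) for rec in compounds]
        return cls(table[index].to_numpy(), y, index=index, property=property)

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, index: str, property: str
    ) -> "TopoIndexQSPR":
        return cls(
            data[index].to_numpy(), data[property].to_numpy(),
            index=index, property=property,
        )

    def fit(self) -> QSPRResults:
        a, b = fit_simple_ols(self.x, self.y)
        st = regression_stats(self.x, self.y, a, b)
        return QSPRResults(
            property=self.property,
            index=self.index,
            n=st["n"],
            A=a,
            B=b,
            r_signed=st["r_signed"],
            r_abs=st["r_abs"],
            r2=st["r2"],
            f_stat=st["f_stat"],
            p_value=st["p_value"],
            se_estimate=st["se_estimate"],
            significant=st["significant"],
            boundary=st["boundary"],
            x=self.x,
            y=self.y,
        )


def fit_all_models(
    compounds: Sequence[CompoundRecord],
    *,
    indices: Sequence[str] = INDEX_IDS,
    properties: Sequence[str] = PROPERTY_IDS,
    mm2_variant: str = "default",
) -> dict[tuple[str, str], QSPRResults]:
    """Fit every (property, index) pair; keys are (property, index)."""
    fits: dict[tuple[str, str], QSPRResults] = {}
    for prop in properties:
        for idx in indices:
            fits[(prop, idx)] = TopoIndexQSPR.from_compounds(
                compounds, idx, prop, mm2_variant=mm2_variant
            ).fit()
    return fits


def correlation_table(
    compounds: Sequence[CompoundRecord],
    *,
    mm2_variant: str = "default",
) -> pd.DataFrame:
    """|Pearson r| of every index with every property (index rows, property
    columns).  A degenerate cell carries NaN rather than failing the table."""
    if len(compounds) < 3:
        raise DegenerateDataError("need at least 3 compounds for correlations")
    table = index_table(compounds, mm2_variant=mm2_variant)
    out = pd.DataFrame(index=list(INDEX_IDS), columns=list(PROPERTY_IDS), dtype=float)
    out.index.name = "index"
    for prop in PROPERTY_IDS:
        y = np.asarray([getattr(rec, prop) for rec in compounds], dtype=float)
        for idx in INDEX_IDS:
            x = table[idx].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                out.loc[idx, prop] = np.nan
            else:
                out.loc[idx, prop] = abs(float(np.corrcoef(x, y)[0, 1]))
    return out


def prediction_table(
    fits: dict[tuple[str, str], QSPRResults],
    compounds: Sequence[CompoundRecord],
    property: str,
    *,
    indices: Sequence[str] = INDEX_IDS,
    mm2_variant: str = "default",
) -> pd.DataFrame:
    """Actual property value plus one fitted column per index, full precision.

    Rows follow compound order; columns are ``actual`` then the index ids.
    """
    table = index_table(compounds, mm2_variant=mm2_variant)
    out = pd.DataFrame(index=[rec.name for rec in compounds])
    out.index.name = "compound"
    out["actual"] = [getattr(rec, property) for rec in compounds]
    for idx in indices:
        fit = fits[(property, idx)]
        out[idx] = fit.predict(table[idx].to_numpy())
    return out
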