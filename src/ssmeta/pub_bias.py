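"""Publication-bias and time-trend diagnostics.

* Egger regression: the standardized effect z_i = y_i / se_i regressed
  on precision 1/se_i by ordinary least squares; a non-zero intercept
  signals funnel-plot asymmetry.  A precision-weighted meta-regression
  variant (effect on standard error, weighted by 1/v) is available for
  sensitivity analysis.
* Trend regressions of effect size on publication year or journal
  impact factor (time-lag and prestige bias), unweighted by default so
  that t carries k-2 degrees of freedom over the rows with a usable
  covariate.
* Funnel-table export: (effect, SE) pairs plus the pooled mean and
  pseudo-confidence envelopes at 95% and 99.8%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError

Z_95 = 1.959963984540054
Z_998 = stats.norm.ppf(0.999)  # two-sided 99.8% envelope


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se_intercept: float
    z: float
    p: float
    slope: float
    k: int
    variant: str = "classical"


@dataclass(frozen=True)
class TrendResult:
    covariate: str
    slope: float
    se_slope: float
    t: float
    df: int
    p: float
    intercept: float


@dataclass
class BiasResult:
    """Bundle of the publication-bias diagnostics for one measure."""

    egger: EggerResult
    trend_year: Optional[TrendResult] = None
    trend_impact_factor: Optional[TrendResult] = None
    funnel: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        out = {
            "egger": {
                "intercept": self.egger.intercept,
                "se": self.egger.se_intercept,
                "z": self.egger.z,
                "p": self.egger.p,
                "slope": self.egger.slope,
                "k": self.egger.k,
                "variant": self.egger.variant,
            }
        }
        for name, tr in (
            ("year", self.trend_year),
            ("impact_factor", self.trend_impact_factor),
        ):
            if tr is not None:
                out[f"trend_{name}"] = {
                    "slope": tr.slope,
                    "se": tr.se_slope,
                    "t": tr.t,
                    "df": tr.df,
                    "p": tr.p,
                }
        return out


def egger_test(
    values: Sequence[float],
    variances: Sequence[float],
    variant: str = "classical",
) -> EggerResult:
    """Egger funnel-plot asymmetry test.

    ``classical``: OLS of y_i/se_i on 1/se_i; the intercept estimates
    asymmetry and is tested with a normal z statistic.
    ``weighted``: inverse-variance weighted regression of y_i on se_i;
    here the *slope* estimates asymmetry (reported in the intercept
    slot for a uniform interface).
    """
    y = np.asarray(values, dtype=float)
    v = np.asarray(variances, dtype=float)
    if len(y) < 3:
        raise ValueError(f"Egger test needs k >= 3, got {len(y)}")
    if np.any(v <= 0):
        raise ValueError("sampling variances must be > 0")
    se = np.sqrt(v)
    if np.allclose(se, se[0]):
        raise DegenerateInputError(
            "all records share one precision; funnel asymmetry is undefined"
        )
    if variant == "classical":
        x = 1.0 / se
        z_std = y / se
        slope, intercept, b0_se, b1_se = _ols(x, z_std)
        asym, asym_se = intercept, b0_se
        trend = slope
    elif variant == "weighted":
        w = 1.0 / v
        X = np.column_stack([np.ones_like(se), se])
        Xw = X * w[:, None]
        A = X.T @ Xw
        coef = np.linalg.solve(A, Xw.T @ y)
        resid = y - X @ coef
        dof = len(y) - 2
        s2 = float(resid @ (w * resid)) / dof
        cov = s2 * np.linalg.inv(A)
        asym, asym_se = float(coef[1]), math.sqrt(cov[1, 1])
        trend = float(coef[0])
    else:
        raise ValueError(f"unknown Egger variant {variant!r}")
    with np.errstate(divide="ignore"):  # exact-fit fixtures have SE = 0
        z = np.float64(asym) / np.float64(asym_se)
    p = 2.0 * stats.norm.sf(abs(z))
    return EggerResult(
        intercept=float(asym),
        se_intercept=float(asym_se),
        z=float(z),
        p=float(p),
        slope=float(trend),
        k=len(y),
        variant=variant,
    )


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Simple OLS returning slope, intercept, SE(intercept), SE(slope)."""
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.intercept_stderr, res.stderr


def trend_regression(
    values: Sequence[float],
    covariate: Sequence[float],
    name: str = "covariate",
) -> TrendResult:
    """Unweighted least-squares trend of effect size on a covariate.

    Rows with a missing covariate are dropped; the t statistic carries
    df = (rows used) - 2.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(covariate, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    y, x = y[keep], x[keep]
    if len(y) < 3:
        raise ValueError(f"trend regression needs >= 3 usable rows, got {len(y)}")
    if np.allclose(x, x[0]):
        raise DegenerateInputError(f"covariate {name!r} is constant")
    res = stats.linregress(x, y)
    df = len(y) - 2
    with np.errstate(divide="ignore"):  # exact lines have zero residual
        t = np.float64(res.slope) / np.float64(res.stderr)
    p = 2.0 * stats.t.sf(abs(t), df)
    return TrendResult(
        covariate=name,
        slope=float(res.slope),
        se_slope=float(res.stderr),
        t=float(t),
        df=df,
        p=float(p),
        intercept=float(res.intercept),
    )


def funnel_table(
    values: Sequence[float],
    variances: Sequence[float],
    pooled_mean: Optional[float] = None,
) -> pd.DataFrame:
    """(effect, SE) pairs plus pseudo-CI envelope columns.

    The envelope around the pooled mean m at standard error s is
    m +/- z * s with z for the 95% and 99.8% levels; at SE = 0 the
    envelope collapses to the mean.  When ``pooled_mean`` is not given,
    the fixed-effect (inverse-variance weighted) mean is used.
    """
    y = np.asarray(values, dtype=float)
    v = np.asarray(variances, dtype=float)
    se = np.sqrt(v)
    if pooled_mean is None:
        w = 1.0 / v
        pooled_mean = float(np.sum(w * y) / np.sum(w))
    return pd.DataFrame(
        {
            "value": y,
            "se": se,
            "pooled_mean": pooled_mean,
            "env95_low": pooled_mean - Z_95 * se,
            "env95_high": pooled_mean + Z_95 * se,
            "env998_low": pooled_mean - Z_998 * se,
            "env998_high": pooled_mean + Z_998 * se,
        }
    )
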