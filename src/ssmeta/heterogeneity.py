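"""Multilevel heterogeneity quantification (I-squared partitioning).

I^2 expresses the proportion of total variance in effect sizes that is
attributable to true heterogeneity rather than sampling error, using
the "typical" sampling variance

    v_bar = (k - 1) * sum(w) / [ (sum w)^2 - sum(w^2) ],  w_i = 1/v_i.

With variance components sigma2_l from a multilevel REML fit,

    I2_l     = 100 * sigma2_l / (sum_l sigma2_l + v_bar)
    I2_total = 100 * sum_l sigma2_l / (sum_l sigma2_l + v_bar)

so the per-level percentages sum exactly to the total.  Optional
confidence intervals come from a seeded parametric bootstrap that
re-simulates effect sizes from the fitted model and refits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .meta_model import FitResult, reml_fit


@dataclass
class HeterogeneityResult:
    """Typical sampling variance plus total and per-level I^2 (%)."""

    typical_v: float
    i2_total: float
    i2_per_level: dict[str, float]
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    method_ci: str = "none"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "level": name,
                "i2_percent": val,
                "lci": self.ci95.get(name, (np.nan, np.nan))[0],
                "uci": self.ci95.get(name, (np.nan, np.nan))[1],
            }
            for name, val in {**self.i2_per_level, "total": self.i2_total}.items()
        ]
        return pd.DataFrame(rows)


def typical_v(v: np.ndarray) -> float:
    """Typical within-study sampling variance v_bar (Higgins-style)."""
    v = np.asarray(v, dtype=float)
    k = len(v)
    if k < 2:
        raise ValueError(f"need at least 2 sampling variances, got {k}")
    if np.any(v <= 0):
        raise ValueError("sampling variances must be > 0")
    w = 1.0 / v
    sw = float(np.sum(w))
    return (k - 1) * sw / (sw * sw - float(np.sum(w * w)))


def i2_point(sigma2: dict[str, float], v: np.ndarray) -> HeterogeneityResult:
    """Point estimates of the I^2 partition from variance components."""
    vb = typical_v(v)
    total_s2 = sum(sigma2.values())
    denom = total_s2 + vb
    per = {name: 100.0 * s / denom for name, s in sigma2.items()}
    return HeterogeneityResult(
        typical_v=vb,
        i2_total=100.0 * total_s2 / denom,
        i2_per_level=per,
    )


def i2_partition(
    fit: FitResult,
    v: np.ndarray,
    *,
    bootstrap: int = 0,
    seed: Optional[int] = None,
    X: Optional[np.ndarray] = None,
    z_matrices: Optional[dict[str, np.ndarray]] = None,
) -> HeterogeneityResult:
    """I^2 partition for a fitted multilevel model.

    When ``bootstrap`` > 0 (and the design/Z matrices are supplied),
    percentile 95% CIs are attached by parametric bootstrap: B new
    response vectors are simulated from N(X beta_hat, V_hat), each is
    refitted by REML and its partition recomputed.
    """
    v = np.asarray(v, dtype=float)
    result = i2_point(fit.sigma2, v)
    if bootstrap <= 0:
        return result
    if X is None or z_matrices is None:
        raise ValueError("bootstrap CIs need the X and Z matrices of the fit")

    rng = np.random.default_rng(seed)
    names = list(fit.sigma2.keys())
    Zs = [z_matrices[n] for n in names]
    k = len(v)
    mean = X @ fit.beta
    draws: dict[str, list[float]] = {n: [] for n in names + ["total"]}
    for _ in range(bootstrap):
        y_star = mean + rng.normal(0.0, np.sqrt(v), size=k)
        for name, Z in zip(names, Zs):
            s2 = fit.sigma2[name]
            if s2 > 0:
                u = rng.normal(0.0, np.sqrt(s2), size=Z.shape[1])
                y_star = y_star + Z @ u
        refit = reml_fit(y_star, v, X, dict(zip(names, Zs)))
        part = i2_point(refit.sigma2, v)
        for name in names:
            draws[name].append(part.i2_per_level[name])
        draws["total"].append(part.i2_total)

    ci = {
        name: (
            float(np.percentile(vals, 2.5)),
            float(np.percentile(vals, 97.5)),
        )
        for name, vals in draws.items()
    }
    # A level estimated exactly at the boundary keeps a degenerate lower CI.
    for name in names:
        if fit.sigma2[name] == 0.0:
            ci[name] = (0.0, ci[name][1])
    result.ci95 = ci
    result.method_ci = f"parametric bootstrap (B={bootstrap})"
    return result
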