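"""Effect-size computation: Hedges' g, lnRR, lnCVR and lnVR.

All four measures compare a high-sexual-selection group against a
low-sexual-selection group and come with an analytic sampling variance
that downstream meta-analytic models use as an inverse weight.

* Hedges' ``g`` — small-sample-corrected standardized mean difference.
  Computed from two-group summaries, or converted from ``t``, ``F``,
  one-df ``chi^2`` statistics or from a difference in proportions
  (Cox logit transform).
* ``lnRR`` — log ratio of the two group means.
* ``lnCVR`` — log ratio of the two coefficients of variation, which
  contrasts variability while controlling for the mean-variance
  relationship typical of fitness data.
* ``lnVR`` — bias-corrected log ratio of the two standard deviations.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

from .errors import DegenerateInputError, NotApplicableError, UnsupportedInputError
from .records import EffectRecord, GroupSummary

logger = logging.getLogger(__name__)

#: Divisor of the Cox logit conversion from a proportion difference to d.
COX_LOGIT_DIVISOR = 1.65


@dataclass(frozen=True)
class ConversionDetail:
    """Intermediates of a standardized-mean-difference computation."""

    d: float  # uncorrected standardized mean difference
    j: float  # small-sample correction factor, in (0, 1]
    df: int   # degrees of freedom of the pooled SD

    def __post_init__(self) -> None:
        if not (0.0 < self.j <= 1.0):
            raise ValueError(f"J correction must lie in (0, 1], got {self.j}")


@dataclass(frozen=True)
class EffectSize:
    """A computed effect measure with its sampling variance."""

    measure: str  # one of {"g", "lnRR", "lnCVR", "lnVR"}
    value: float
    variance: float
    record: Optional[EffectRecord] = None
    detail: Optional[ConversionDetail] = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"effect size value must be finite, got {self.value}")
        if not (self.variance > 0 and math.isfinite(self.variance)):
            raise ValueError(f"sampling variance must be positive, got {self.variance}")

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


def hedges_j(df: int) -> float:
    """Small-sample correction factor J = 1 - 3/(4 df - 1)."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def _g_from_d(
    d: float,
    n_high: int,
    n_low: int,
    record: Optional[EffectRecord] = None,
) -> EffectSize:
    """J-correct an uncorrected d and attach the Hedges sampling variance.

    var(g) = J^2 * [ (n_h + n_l)/(n_h n_l) + d^2 / (2 (n_h + n_l)) ].
    """
    ntot = n_high + n_low
    df = ntot - 2
    j = hedges_j(df)
    var_d = ntot / (n_high * n_low) + d * d / (2.0 * ntot)
    return EffectSize(
        measure="g",
        value=j * d,
        variance=j * j * var_d,
        record=record,
        detail=ConversionDetail(d=d, j=j, df=df),
    )


def g_from_summaries(
    high: GroupSummary, low: GroupSummary, record: Optional[EffectRecord] = None
) -> EffectSize:
    """Hedges' g from two-group means, SDs and sample sizes."""
    df = high.n + low.n - 2
    pooled_ss = (high.n - 1) * high.s ** 2 + (low.n - 1) * low.s ** 2
    s_pooled = math.sqrt(pooled_ss / df)
    if s_pooled == 0.0:
        raise DegenerateInputError("pooled standard deviation is zero")
    d = (high.m - low.m) / s_pooled
    return _g_from_d(d, high.n, low.n, record)


def g_from_t(
    t: float, n_high: int, n_low: int, record: Optional[EffectRecord] = None
) -> EffectSize:
    """Hedges' g from a two-sample t statistic (sign carried by t)."""
    d = t * math.sqrt((n_high + n_low) / (n_high * n_low))
    return _g_from_d(d, n_high, n_low, record)


def g_from_f(
    f: float,
    n_high: int,
    n_low: int,
    direction: int = 1,
    record: Optional[EffectRecord] = None,
) -> EffectSize:
    """Hedges' g from a one-way, 1-numerator-df F statistic.

    F carries no sign, so ``direction`` (+1/-1) supplies the sign of the
    high-minus-low difference.
    """
    if f < 0:
        raise ValueError(f"F statistic must be >= 0, got {f}")
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    d = direction * math.sqrt(f * (n_high + n_low) / (n_high * n_low))
    return _g_from_d(d, n_high, n_low, record)


def g_from_chisq(
    chisq: float,
    total_n: int,
    direction: int = 1,
    n_high: Optional[int] = None,
    n_low: Optional[int] = None,
    df: int = 1,
    record: Optional[EffectRecord] = None,
) -> EffectSize:
    """Hedges' g from a 1-df chi-square statistic with total sample size N.

    Route: r = sqrt(chi^2 / N), d = 2 r / sqrt(1 - r^2), signed by
    ``direction``.  When the per-group sizes are unknown, an even split
    of N is assumed for the variance.
    """
    if df != 1:
        raise UnsupportedInputError(
            f"chi-square conversion is only defined for df = 1, got df = {df}"
        )
    if chisq < 0:
        raise ValueError(f"chi-square statistic must be >= 0, got {chisq}")
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    r2 = chisq / total_n
    if r2 >= 1.0:
        raise DegenerateInputError("chi-square implies |r| >= 1; no finite d")
    r = math.sqrt(r2)
    d = direction * 2.0 * r / math.sqrt(1.0 - r2)
    if n_high is None or n_low is None:
        n_high = total_n // 2
        n_low = total_n - n_high
    return _g_from_d(d, n_high, n_low, record)


def g_from_proportions(
    p_high: float,
    p_low: float,
    n_high: Optional[int],
    n_low: Optional[int],
    record: Optional[EffectRecord] = None,
) -> EffectSize:
    """Hedges' g from a difference of two proportions (Cox logit transform).

    d = [logit(p_h) - logit(p_l)] / 1.65.  Boundary proportions are
    handled with the continuity rule applied to the implied count:
    a proportion of 1 becomes (n-1)/n (one subtracted from the
    numerator) and a proportion of 0 becomes 1/n.  Boundary proportions
    with an unknown group count cannot be continuity-corrected and
    raise an error.
    """
    for name, p in (("p_high", p_high), ("p_low", p_low)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1], got {p}")

    def _adjust(p: float, n: Optional[int]) -> float:
        if p in (0.0, 1.0):
            if n is None:
                raise DegenerateInputError(
                    "boundary proportion with unknown group count: "
                    "cannot apply the continuity correction"
                )
            return (n - 1) / n if p == 1.0 else 1 / n
        return p

    ph = _adjust(p_high, n_high)
    pl = _adjust(p_low, n_low)
    if n_high is None or n_low is None:
        raise DegenerateInputError("group sizes required for the sampling variance")
    d = (math.log(ph / (1 - ph)) - math.log(pl / (1 - pl))) / COX_LOGIT_DIVISOR
    return _g_from_d(d, n_high, n_low, record)


def lnrr(
    high: GroupSummary, low: GroupSummary, record: Optional[EffectRecord] = None
) -> EffectSize:
    """Log response ratio ln(m_h / m_l) with delta-method variance."""
    if high.m <= 0 or low.m <= 0:
        raise NotApplicableError(
            f"lnRR requires positive means, got {high.m} and {low.m}"
        )
    value = math.log(high.m / low.m)
    variance = high.s ** 2 / (high.n * high.m ** 2) + low.s ** 2 / (low.n * low.m ** 2)
    if variance <= 0:
        raise NotApplicableError("lnRR variance is zero (both SDs are zero)")
    return EffectSize(measure="lnRR", value=value, variance=variance, record=record)


def lncvr(
    high: GroupSummary,
    low: GroupSummary,
    rho: float = 0.0,
    record: Optional[EffectRecord] = None,
) -> EffectSize:
    """Log coefficient-of-variation ratio ln(CV_h / CV_l).

    ``rho`` is the assumed correlation between the log mean and log SD
    within a group (0 by default; can be estimated dataset-wide).
    """
    if high.m <= 0 or low.m <= 0:
        raise NotApplicableError("lnCVR requires positive means")
    if high.s <= 0 or low.s <= 0:
        raise NotApplicableError("lnCVR requires positive SDs")
    if not (-1.0 <= rho <= 1.0):
        raise ValueError(f"rho must lie in [-1, 1], got {rho}")
    value = math.log((high.s / high.m) / (low.s / low.m))
    vm_h = high.s ** 2 / (high.n * high.m ** 2)   # var of the log mean
    vs_h = 1.0 / (2.0 * (high.n - 1))             # var of the log SD
    vm_l = low.s ** 2 / (low.n * low.m ** 2)
    vs_l = 1.0 / (2.0 * (low.n - 1))
    variance = (
        vm_h + vs_h + vm_l + vs_l
        - 2.0 * rho * (math.sqrt(vm_h) * math.sqrt(vs_h) + math.sqrt(vm_l) * math.sqrt(vs_l))
    )
    if variance <= 0:
        raise DegenerateInputError("lnCVR variance non-positive under given rho")
    return EffectSize(measure="lnCVR", value=value, variance=variance, record=record)


def lnvr(
    high: GroupSummary, low: GroupSummary, record: Optional[EffectRecord] = None
) -> EffectSize:
    """Bias-corrected log variability ratio ln(s_h / s_l)."""
    if high.s <= 0 or low.s <= 0:
        raise NotApplicableError("lnVR requires positive SDs")
    value = (
        math.log(high.s / low.s)
        + 1.0 / (2.0 * (high.n - 1))
        - 1.0 / (2.0 * (low.n - 1))
    )
    variance = 1.0 / (2.0 * (high.n - 1)) + 1.0 / (2.0 * (low.n - 1))
    return EffectSize(measure="lnVR", value=value, variance=variance, record=record)


def g_for_record(record: EffectRecord) -> EffectSize:
    """Dispatch Hedges' g computation on the record's input kind.

    The returned value is on the raw high-minus-low scale; sign
    orientation for negatively fitness-related traits is applied by
    :func:`ssmeta.dataio.orient_sign` downstream.
    """
    kind = record.input_kind
    if kind == "summaries":
        return g_from_summaries(record.group_high, record.group_low, record)
    if kind == "t":
        nh, nl = _group_sizes(record)
        return g_from_t(record.statistic_value, nh, nl, record)
    if kind == "F":
        nh, nl = _group_sizes(record)
        return g_from_f(record.statistic_value, nh, nl, record.direction, record)
    if kind == "chisq":
        if record.total_n is None:
            raise DegenerateInputError("chisq record without total_n")
        nh = record.group_high.n if record.group_high is not None else None
        nl = record.group_low.n if record.group_low is not None else None
        return g_from_chisq(
            record.statistic_value, record.total_n, record.direction, nh, nl,
            record=record,
        )
    if kind == "proportions":
        nh, nl = _group_sizes(record)
        return g_from_proportions(record.p_high, record.p_low, nh, nl, record)
    raise UnsupportedInputError(f"unknown input kind {kind!r}")


def _group_sizes(record: EffectRecord) -> tuple[int, int]:
    if record.group_high is not None and record.group_low is not None:
        return record.group_high.n, record.group_low.n
    if record.total_n is not None:
        nh = record.total_n // 2
        return nh, record.total_n - nh
    raise DegenerateInputError(
        f"record {record.study_id!r}/{record.trait!r} has no usable group sizes"
    )


def ratio_measure_for_record(
    record: EffectRecord, measure: str, rho: float = 0.0
) -> EffectSize:
    """Compute lnRR/lnCVR/lnVR for a record; requires two-group summaries."""
    if not record.has_summaries:
        raise NotApplicableError(
            f"{measure} needs two-group summaries; record reports a "
            f"{record.input_kind} statistic only"
        )
    if measure == "lnRR":
        return lnrr(record.group_high, record.group_low, record)
    if measure == "lnCVR":
        return lncvr(record.group_high, record.group_low, rho, record)
    if measure == "lnVR":
        return lnvr(record.group_high, record.group_low, record)
    raise ValueError(f"unknown ratio measure {measure!r}")
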