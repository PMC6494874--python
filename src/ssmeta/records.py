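"""Core record types for experimental-evolution effect-size tables.

One :class:`EffectRecord` describes a single comparison between a
high-sexual-selection treatment and a low-sexual-selection treatment
(e.g. polygamy vs. enforced monogamy) for one fitness component,
together with the moderator variables used in meta-regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

FITNESS_CLASSES = frozenset({"direct", "indirect", "ambiguous"})
SEXES = frozenset({"male", "female", "both"})
ENVIRONMENTS = frozenset({"stressful", "benign", "undefined"})
INPUT_KINDS = frozenset({"summaries", "t", "F", "chisq", "proportions"})

#: Reference levels used in treatment-coded designs.
REFERENCE_SEX = "male"
REFERENCE_ENVIRONMENT = "benign"


@dataclass(frozen=True)
class GroupSummary:
    """Arithmetic mean, standard deviation and sample size of one group."""

    m: float
    s: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group sample size must be >= 2, got {self.n}")
        if self.s < 0:
            raise ValueError(f"standard deviation must be >= 0, got {self.s}")


@dataclass
class EffectRecord:
    """One treatment comparison extracted from a study.

    ``group_high`` / ``group_low`` hold two-group summaries when the
    source reported means; otherwise ``statistic_value`` holds a test
    statistic of kind ``input_kind`` with ``direction`` giving the sign
    of the high-minus-low difference.
    """

    study_id: str
    taxon: str
    trait: str
    fitness_class: str = "ambiguous"
    sex: str = "both"
    environment: str = "undefined"
    manipulation: str = "enforced monogamy"
    generations: int = 1
    line: str = ""
    blind: Optional[bool] = None
    year: Optional[int] = None
    impact_factor: Optional[float] = None
    input_kind: str = "summaries"
    group_high: Optional[GroupSummary] = None
    group_low: Optional[GroupSummary] = None
    statistic_value: Optional[float] = None
    total_n: Optional[int] = None
    # For proportion inputs the two "statistics" are the proportions.
    p_high: Optional[float] = None
    p_low: Optional[float] = None
    direction: int = 1
    negatively_related: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.input_kind not in INPUT_KINDS:
            raise ValueError(f"unknown input_kind {self.input_kind!r}")
        if self.input_kind == "summaries":
            if self.group_high is None or self.group_low is None:
                raise ValueError(
                    "input_kind='summaries' requires both group summaries"
                )
        elif self.input_kind == "proportions":
            if self.p_high is None or self.p_low is None:
                raise ValueError(
                    "input_kind='proportions' requires p_high and p_low"
                )
        else:
            if self.statistic_value is None:
                raise ValueError(
                    f"input_kind={self.input_kind!r} requires statistic_value"
                )

    @property
    def has_summaries(self) -> bool:
        return self.group_high is not None and self.group_low is not None
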