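"""Reading, validating, orienting and filtering effect-size tables.

The canonical CSV schema has one row per treatment comparison.  Columns:

===================  =====================================================
column               meaning
===================  =====================================================
study_id             study label (65 studies in the motivating dataset)
taxon                study organism group (flies, beetles, mice, ...)
trait                fitness component measured
fitness_class        direct | indirect | ambiguous relation to fitness
sex                  male | female | both (sex of measured individuals)
environment          stressful | benign | undefined evolution environment
manipulation         how sexual selection was manipulated
generations          generations of experimental evolution (last reported)
line                 replicate line label (may be empty)
blind                whether measurement was blind (true/false/empty)
year                 publication year (may be empty)
impact_factor        journal impact factor (may be empty)
input_kind           summaries | t | F | chisq | proportions
mean_high, sd_high,  two-group summaries for the high- and
n_high, mean_low,    low-sexual-selection groups (input_kind=summaries)
sd_low, n_low
statistic_value      the test statistic (input_kind in {t, F, chisq})
total_n              total sample size for statistic-based records
p_high, p_low        the two proportions (input_kind=proportions)
direction            +1/-1 sign of the high-minus-low difference
negatively_related   true if the trait is negatively related to fitness
                     (filled from the packaged trait list when empty)
===================  =====================================================

Unparseable enum cells degrade to ``undefined``/missing with a logged
warning rather than aborting; missing mandatory columns raise
:class:`~ssmeta.errors.SchemaError`.
"""

from __future__ import annotations

import logging
import math
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from .errors import SchemaError
from .records import (
    ENVIRONMENTS,
    FITNESS_CLASSES,
    INPUT_KINDS,
    SEXES,
    EffectRecord,
    GroupSummary,
)

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = (
    "study_id",
    "taxon",
    "trait",
    "fitness_class",
    "sex",
    "environment",
    "input_kind",
)

OPTIONAL_COLUMNS = (
    "manipulation",
    "generations",
    "line",
    "blind",
    "year",
    "impact_factor",
    "mean_high",
    "sd_high",
    "n_high",
    "mean_low",
    "sd_low",
    "n_low",
    "statistic_value",
    "total_n",
    "p_high",
    "p_low",
    "direction",
    "negatively_related",
)

ALL_COLUMNS = MANDATORY_COLUMNS + OPTIONAL_COLUMNS

_ENUM_DOMAINS = {
    "fitness_class": (FITNESS_CLASSES, "ambiguous"),
    "sex": (SEXES, "both"),
    "environment": (ENVIRONMENTS, "undefined"),
    "input_kind": (INPUT_KINDS, None),
}


def load_negative_traits(path: Optional[Union[str, Path]] = None) -> frozenset[str]:
    """Load the set of traits whose sign convention is inverted.

    Reads the packaged default list unless ``path`` points at a user
    override (same YAML layout, key ``negatively_related_traits``).
    """
    if path is None:
        text = (
            resources.files("ssmeta") / "data" / "negatively_related.yaml"
        ).read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    return frozenset(t.strip().lower() for t in doc["negatively_related_traits"])


def _clean_cell(x) -> str:
    """Normalise a raw CSV cell: strip, lower, map Unicode minus to '-'."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return ""
    return str(x).strip().replace("−", "-")


def _parse_float(x) -> Optional[float]:
    s = _clean_cell(x)
    if not s:
        return None
    return float(s)


def _parse_int(x) -> Optional[int]:
    v = _parse_float(x)
    return None if v is None else int(round(v))


def _parse_bool(x) -> Optional[bool]:
    s = _clean_cell(x).lower()
    if not s:
        return None
    if s in {"true", "t", "yes", "y", "1"}:
        return True
    if s in {"false", "f", "no", "n", "0"}:
        return False
    logger.warning("unparseable boolean %r treated as missing", x)
    return None


def read_dataset(path: Union[str, Path]) -> list[EffectRecord]:
    """Read a CSV effect-size table into typed :class:`EffectRecord` rows."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {', '.join(missing)}")
    negative = load_negative_traits()
    records: list[EffectRecord] = []
    for idx, row in frame.iterrows():
        records.append(_row_to_record(row, idx, negative))
    return records


def _row_to_record(row: pd.Series, idx, negative: frozenset[str]) -> EffectRecord:
    def enum(col: str) -> str:
        raw = _clean_cell(row.get(col)).lower()
        domain, fallback = _ENUM_DOMAINS[col]
        if raw in domain:
            return raw
        if col == "input_kind":
            # 'F' is stored upper-case; accept any casing of the kinds.
            for k in domain:
                if raw == k.lower():
                    return k
            raise SchemaError(f"row {idx}: unparseable input_kind {raw!r}")
        if raw:
            logger.warning(
                "row %s: unparseable %s %r replaced by %r", idx, col, raw, fallback
            )
        return fallback

    def summary(side: str) -> Optional[GroupSummary]:
        m = _parse_float(row.get(f"mean_{side}"))
        s = _parse_float(row.get(f"sd_{side}"))
        n = _parse_int(row.get(f"n_{side}"))
        if m is None or s is None or n is None:
            return None
        return GroupSummary(m=m, s=s, n=n)

    trait = _clean_cell(row.get("trait")).lower()
    neg_cell = _parse_bool(row.get("negatively_related"))
    direction = _parse_int(row.get("direction"))
    return EffectRecord(
        study_id=_clean_cell(row.get("study_id")),
        taxon=_clean_cell(row.get("taxon")).lower(),
        trait=trait,
        fitness_class=enum("fitness_class"),
        sex=enum("sex"),
        environment=enum("environment"),
        manipulation=_clean_cell(row.get("manipulation")) or "enforced monogamy",
        generations=_parse_int(row.get("generations")) or 1,
        line=_clean_cell(row.get("line")),
        blind=_parse_bool(row.get("blind")),
        year=_parse_int(row.get("year")),
        impact_factor=_parse_float(row.get("impact_factor")),
        input_kind=enum("input_kind"),
        group_high=summary("high"),
        group_low=summary("low"),
        statistic_value=_parse_float(row.get("statistic_value")),
        total_n=_parse_int(row.get("total_n")),
        p_high=_parse_float(row.get("p_high")),
        p_low=_parse_float(row.get("p_low")),
        direction=direction if direction in (1, -1) else 1,
        negatively_related=(
            neg_cell if neg_cell is not None else trait in negative
        ),
    )


def records_to_frame(records: Iterable[EffectRecord]) -> pd.DataFrame:
    """Flatten records into the canonical tabular schema."""
    rows = []
    for r in records:
        rows.append(
            {
                "study_id": r.study_id,
                "taxon": r.taxon,
                "trait": r.trait,
                "fitness_class": r.fitness_class,
                "sex": r.sex,
                "environment": r.environment,
                "manipulation": r.manipulation,
                "generations": r.generations,
                "line": r.line,
                "blind": r.blind,
                "year": r.year,
                "impact_factor": r.impact_factor,
                "input_kind": r.input_kind,
                "mean_high": r.group_high.m if r.group_high else None,
                "sd_high": r.group_high.s if r.group_high else None,
                "n_high": r.group_high.n if r.group_high else None,
                "mean_low": r.group_low.m if r.group_low else None,
                "sd_low": r.group_low.s if r.group_low else None,
                "n_low": r.group_low.n if r.group_low else None,
                "statistic_value": r.statistic_value,
                "total_n": r.total_n,
                "p_high": r.p_high,
                "p_low": r.p_low,
                "direction": r.direction,
                "negatively_related": r.negatively_related,
            }
        )
    return pd.DataFrame(rows, columns=list(ALL_COLUMNS))


def write_dataset(records: Iterable[EffectRecord], path: Union[str, Path]) -> None:
    """Write records back to the canonical CSV schema."""
    records_to_frame(records).to_csv(path, index=False)


def orient_sign(record: EffectRecord, raw_effect: float) -> float:
    """Orient a raw high-minus-low effect onto the fitness scale.

    Positive oriented values always mean sexual selection was associated
    with higher fitness; traits negatively related to fitness (parasite
    load, extinction rate, ...) have their sign inverted.
    """
    return -raw_effect if record.negatively_related else raw_effect


def filter_moderator_subset(records: Sequence[EffectRecord]) -> list[EffectRecord]:
    """Subset used by the sex-by-environment meta-regressions.

    Keeps records whose fitness class is unambiguous (direct or
    indirect) and whose evolution environment is defined (stressful or
    benign).  Order-preserving and idempotent.
    """
    return [
        r
        for r in records
        if r.fitness_class in ("direct", "indirect")
        and r.environment in ("stressful", "benign")
    ]


def drop_superseded_generations(records: Sequence[EffectRecord]) -> list[EffectRecord]:
    """Defensive guard: keep only the last reported generation.

    When the same (study, line, trait, sex) combination appears at
    several generation counts, only the row with the largest generation
    number is retained (ties keep the first occurrence).
    """
    best: dict[tuple, int] = {}
    for i, r in enumerate(records):
        key = (r.study_id, r.line, r.trait, r.sex)
        if key not in best or r.generations > records[best[key]].generations:
            best[key] = i
    keep = sorted(best.values())
    return [records[i] for i in keep]


def validation_report(records: Sequence[EffectRecord]) -> dict:
    """Summary counts used by the ``validate`` CLI subcommand."""
    frame = records_to_frame(records)
    n = len(records)
    return {
        "n_records": n,
        "n_studies": int(frame["study_id"].nunique()) if n else 0,
        "n_traits": int(frame["trait"].nunique()) if n else 0,
        "n_taxa": int(frame["taxon"].nunique()) if n else 0,
        "sex_counts": frame["sex"].value_counts().to_dict() if n else {},
        "environment_counts": (
            frame["environment"].value_counts().to_dict() if n else {}
        ),
        "fitness_class_counts": (
            frame["fitness_class"].value_counts().to_dict() if n else {}
        ),
        "input_kind_counts": (
            frame["input_kind"].value_counts().to_dict() if n else {}
        ),
        "n_with_summaries": int(sum(r.has_summaries for r in records)),
        "n_moderator_subset": len(filter_moderator_subset(records)),
    }
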