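"""End-to-end orchestration of the meta-analytic report.

``run_all`` drives the full model suite on one effect-size table:

1. grand weighted mean (intercept-only multilevel model),
2. fitness-class model with per-class predictions,
3. fitness-component model, plus separate per-trait meta-analyses,
4. sex-by-environment meta-regressions for Hedges' g, lnRR, lnCVR and
   lnVR on the unambiguous/defined-environment subsets, with the
   standard hypothesis contrasts and cell means,
5. multilevel I^2 partitions for the g and lnCVR models,
6. publication-bias diagnostics (Egger, year and impact-factor trends,
   funnel export).

Every stage is wrapped so a failure produces an error manifest entry
and a partial bundle rather than an abort.  Report tables are written
as CSV rounded to 3 decimals with a full-precision JSON manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import published
from .dataio import filter_moderator_subset, orient_sign, read_dataset
from .effect_sizes import g_for_record, ratio_measure_for_record
from .errors import NotApplicableError, SSMetaError
from .heterogeneity import i2_partition
from .meta_model import (
    ModelSpec,
    build_design,
    cell_mean_contrast,
    contrast,
    fit_model,
    level_matrices,
    per_trait_models,
    predict_levels,
)
from .pub_bias import egger_test, funnel_table, trend_regression
from .records import EffectRecord

logger = logging.getLogger(__name__)

MEASURES = ("g", "lnRR", "lnCVR", "lnVR")

#: Random levels of the moderated multilevel models.
FULL_LEVELS = ("study", "trait", "taxon", "effect")

#: Sex-by-environment hypothesis contrasts in printed-table order.
SEX_ENV_CONTRASTS = (
    ("female_gt_male_benign", "Female > male, benign"),
    ("female_gt_male_stressful", "Female > male, stressful"),
    ("female_stressful_gt_benign", "Females: stressful > benign"),
    ("male_benign_gt_stressful", "Males: benign > stressful"),
    ("both_stressful_gt_benign", "Both sexes: stressful > benign"),
)


@dataclass
class AnalysisConfig:
    """Configuration of a full pipeline run."""

    input_path: Optional[Union[str, Path]] = None
    measures: tuple[str, ...] = MEASURES
    bootstrap: int = 0
    seed: int = 0
    output_dir: Optional[Union[str, Path]] = None
    rho: float = 0.0
    deposited: bool = False  # True only when input is the deposited table

    def __post_init__(self) -> None:
        unknown = set(self.measures) - set(MEASURES)
        if unknown:
            raise ValueError(f"unknown measures: {sorted(unknown)}")


def effect_table(
    records: Sequence[EffectRecord], measure: str, rho: float = 0.0
) -> tuple[pd.DataFrame, int]:
    """Per-record effect sizes of one measure as an analysis frame.

    Hedges' g and lnRR are sign-oriented so that positive values mean
    higher fitness under sexual selection; the variability ratios keep
    their natural variance-direction sign.  Records for which the
    measure is undefined are skipped and counted.
    """
    rows = []
    skipped = 0
    for i, rec in enumerate(records):
        try:
            if measure == "g":
                es = g_for_record(rec)
            else:
                es = ratio_measure_for_record(rec, measure, rho)
        except (NotApplicableError, SSMetaError) as exc:
            logger.debug("record %d skipped for %s: %s", i, measure, exc)
            skipped += 1
            continue
        value = (
            orient_sign(rec, es.value) if measure in ("g", "lnRR") else es.value
        )
        rows.append(
            {
                "record": i,
                "study_id": rec.study_id,
                "trait": rec.trait,
                "taxon": rec.taxon,
                "fitness_class": rec.fitness_class,
                "sex": rec.sex,
                "environment": rec.environment,
                "year": rec.year,
                "impact_factor": rec.impact_factor,
                "has_summaries": rec.has_summaries,
                "value": value,
                "variance": es.variance,
            }
        )
    return pd.DataFrame(rows), skipped


def _fit_to_row(name: str, fit) -> dict:
    tab = fit.summary_frame()
    row = {
        "model": name,
        "k": fit.k,
        "converged": fit.converged,
        "loglik_reml": fit.loglik_reml,
    }
    for _, r in tab.iterrows():
        row[f"{r['parameter']}"] = r["estimate"]
    for lev, s2 in fit.sigma2.items():
        row[f"sigma2_{lev}"] = s2
    return row


def run_all(
    config: AnalysisConfig,
    records: Optional[Sequence[EffectRecord]] = None,
) -> dict:
    """Run the full analysis and return a report bundle.

    The bundle maps table names to DataFrames plus ``"manifest"`` (run
    metadata, row counts, skip counts, errors) and ``"bias"`` (nested
    dict of test statistics).  Pass ``records`` directly or set
    ``config.input_path``.
    """
    if records is None:
        if config.input_path is None:
            raise ValueError("need records or config.input_path")
        records = read_dataset(config.input_path)
    records = list(records)

    bundle: dict = {"tables": {}, "manifest": {
        "seed": config.seed,
        "deposited": bool(config.deposited),
        "n_records": len(records),
        "counts": {},
        "skipped": {},
        "errors": {},
    }}
    manifest = bundle["manifest"]

    tables_by_measure: dict[str, pd.DataFrame] = {}
    for measure in config.measures:
        tab, skipped = effect_table(records, measure, config.rho)
        tables_by_measure[measure] = tab
        manifest["skipped"][measure] = skipped
        manifest["counts"][f"{measure}_computed"] = len(tab)

    g_tab = tables_by_measure.get("g")

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - error manifest by design
                logger.warning("stage %s failed: %s", name, exc)
                manifest["errors"][name] = f"{type(exc).__name__}: {exc}"
        return deco

    @stage("grand_mean")
    def _grand():
        fit = fit_model(g_tab, ModelSpec("1", FULL_LEVELS))
        bundle["tables"]["grand_mean"] = fit.summary_frame()
        bundle["grand_mean_fit"] = fit

    @stage("fitness_class")
    def _classes():
        fit = fit_model(g_tab, ModelSpec("fitness_class", ("study", "taxon", "effect")))
        bundle["tables"]["fitness_class_predictions"] = predict_levels(
            fit, "fitness_class"
        )
        bundle["fitness_class_fit"] = fit

    @stage("fitness_component")
    def _components():
        fit = fit_model(g_tab, ModelSpec("trait", ("study", "taxon", "effect")))
        bundle["tables"]["fitness_component_predictions"] = predict_levels(
            fit, "trait"
        )

    @stage("per_trait")
    def _per_trait():
        fits, skipped_traits = per_trait_models(g_tab)
        rows = []
        for trait, fit in fits.items():
            tab = fit.summary_frame().iloc[0]
            rows.append(
                {
                    "trait": trait,
                    "k": fit.k,
                    "estimate": tab["estimate"],
                    "se": tab["se"],
                    "lci": tab["lci"],
                    "uci": tab["uci"],
                    "converged": fit.converged,
                }
            )
        bundle["tables"]["per_trait"] = pd.DataFrame(rows)
        manifest["counts"]["per_trait_models"] = len(rows)
        manifest["counts"]["per_trait_skipped"] = len(skipped_traits)
        manifest["per_trait_skipped"] = skipped_traits

    coef_rows, contrast_rows, cell_rows = [], [], []
    for measure in config.measures:
        tab = tables_by_measure[measure]
        sub = tab[
            tab["fitness_class"].isin(["direct", "indirect"])
            & tab["environment"].isin(["stressful", "benign"])
        ].reset_index(drop=True)
        if measure != "g":
            sub = sub[sub["has_summaries"]].reset_index(drop=True)
        manifest["counts"][f"{measure}_sex_env_subset"] = len(sub)

        @stage(f"sex_env_{measure}")
        def _sex_env(measure=measure, sub=sub):
            fit = fit_model(sub, ModelSpec("sex*environment", FULL_LEVELS))
            bundle[f"sex_env_fit_{measure}"] = fit
            bundle[f"sex_env_frame_{measure}"] = sub
            coef = fit.summary_frame()
            coef.insert(0, "measure", measure)
            coef_rows.append(coef)
            for key, label in SEX_ENV_CONTRASTS:
                c = contrast(fit, published.CONTRAST_WEIGHTS[key], label)
                contrast_rows.append(
                    {
                        "measure": measure,
                        "contrast": key,
                        "label": label,
                        "estimate": c.estimate,
                        "se": c.se,
                        "z": c.z,
                        "p": c.p_two_sided,
                        "lci": c.ci95[0],
                        "uci": c.ci95[1],
                    }
                )
            for sex in ("male", "female", "both"):
                for env in ("benign", "stressful"):
                    L = cell_mean_contrast(fit, sex, env)
                    c = contrast(fit, L, f"{sex}/{env}")
                    cell_rows.append(
                        {
                            "measure": measure,
                            "sex": sex,
                            "environment": env,
                            "estimate": c.estimate,
                            "se": c.se,
                            "lci": c.ci95[0],
                            "uci": c.ci95[1],
                        }
                    )

    if coef_rows:
        bundle["tables"]["sex_env_coefficients"] = pd.concat(
            coef_rows, ignore_index=True
        )
        bundle["tables"]["sex_env_contrasts"] = pd.DataFrame(contrast_rows)
        bundle["tables"]["sex_env_cell_means"] = pd.DataFrame(cell_rows)

    @stage("heterogeneity")
    def _het():
        rows = []
        for measure in ("g", "lnCVR"):
            fit = bundle.get(f"sex_env_fit_{measure}")
            sub = bundle.get(f"sex_env_frame_{measure}")
            if fit is None:
                continue
            kwargs = {}
            if config.bootstrap > 0:
                design = build_design(sub, ModelSpec("sex*environment", FULL_LEVELS))
                kwargs = {
                    "bootstrap": config.bootstrap,
                    "seed": config.seed,
                    "X": design.X,
                    "z_matrices": level_matrices(sub, FULL_LEVELS),
                }
            het = i2_partition(fit, sub["variance"].to_numpy(), **kwargs)
            part = het.to_frame()
            part.insert(0, "measure", measure)
            rows.append(part)
        bundle["tables"]["heterogeneity"] = pd.concat(rows, ignore_index=True)

    @stage("bias")
    def _bias():
        values = g_tab["value"].to_numpy()
        variances = g_tab["variance"].to_numpy()
        egger = egger_test(values, variances)
        bias: dict = {"egger": egger.__dict__}
        for cov in ("year", "impact_factor"):
            x = pd.to_numeric(g_tab[cov], errors="coerce").to_numpy(dtype=float)
            tr = trend_regression(values, x, name=cov)
            bias[f"trend_{cov}"] = tr.__dict__
        bundle["bias"] = bias
        bundle["tables"]["funnel"] = funnel_table(values, variances)

    manifest["counts"]["moderator_subset"] = len(filter_moderator_subset(records))
    if config.output_dir is not None:
        write_bundle(bundle, config.output_dir)
    return bundle


def write_bundle(bundle: dict, outdir: Union[str, Path]) -> None:
    """Write CSV tables (3 decimals) and the full-precision manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, tab in bundle["tables"].items():
        rounded = tab.copy()
        for col in rounded.columns:
            if pd.api.types.is_float_dtype(rounded[col]):
                rounded[col] = rounded[col].round(3)
        rounded.to_csv(outdir / f"{name}.csv", index=False)
    manifest = dict(bundle["manifest"])
    if "bias" in bundle:
        manifest["bias"] = _jsonable(bundle["bias"])
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def reproduce_report(bundle: dict) -> pd.DataFrame:
    """Side-by-side comparison of a deposited-data rerun against the
    published values.

    Refuses bundles produced from synthetic or otherwise non-deposited
    inputs, because the published numbers describe one specific
    dataset.  Deviations are reported, not asserted.
    """
    if not bundle["manifest"].get("deposited", False):
        raise SSMetaError(
            "this bundle was not produced from the deposited dataset; "
            "comparison against published values would be meaningless"
        )
    rows = []

    def add(name, computed, printed):
        rows.append(
            {
                "quantity": name,
                "computed": computed,
                "published": printed,
                "abs_deviation": (
                    abs(computed - printed) if computed is not None else None
                ),
            }
        )

    gm = bundle["tables"].get("grand_mean")
    add(
        "grand_mean",
        float(gm["estimate"].iloc[0]) if gm is not None else None,
        published.HEADLINE["grand_mean"],
    )
    fc = bundle["tables"].get("fitness_class_predictions")
    if fc is not None:
        fc = fc.set_index("level")
        for cls in ("direct", "indirect", "ambiguous"):
            if cls in fc.index:
                add(
                    f"class_{cls}",
                    float(fc.loc[cls, "estimate"]),
                    published.HEADLINE[f"class_{cls}"],
                )
    pt = bundle["tables"].get("per_trait")
    if pt is not None and "immunity" in set(pt["trait"]):
        add(
            "trait_immunity",
            float(pt.set_index("trait").loc["immunity", "estimate"]),
            published.HEADLINE["trait_immunity"],
        )
    cells = bundle["tables"].get("sex_env_cell_means")
    if cells is not None:
        idx = cells.set_index(["measure", "sex", "environment"])
        for sex, key in (("female", "lncvr_female_stressful"),
                         ("both", "lncvr_both_stressful")):
            if ("lnCVR", sex, "stressful") in idx.index:
                add(
                    key,
                    float(idx.loc[("lnCVR", sex, "stressful"), "estimate"]),
                    published.HEADLINE[key],
                )
    het = bundle["tables"].get("heterogeneity")
    if het is not None:
        hidx = het.set_index(["measure", "level"])
        if ("g", "total") in hidx.index:
            add("i2_g_total", float(hidx.loc[("g", "total"), "i2_percent"]),
                published.I2_G["total"])
        if ("lnCVR", "total") in hidx.index:
            add("i2_lncvr_total", float(hidx.loc[("lnCVR", "total"), "i2_percent"]),
                published.I2_LNCVR["total"])
    if "bias" in bundle:
        add("egger_z", float(bundle["bias"]["egger"]["z"]), published.EGGER_Z)
    counts = bundle["manifest"]["counts"]
    add("n_records", bundle["manifest"]["n_records"], published.COUNTS["records"])
    add("n_g_subset", counts.get("g_sex_env_subset"),
        published.COUNTS["g_moderator_subset"])
    add("n_ratio_subset", counts.get("lnCVR_sex_env_subset"),
        published.COUNTS["ratio_moderator_subset"])
    return pd.DataFrame(rows)
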