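"""Published reference values from the motivating synthesis.

These printed numbers serve two purposes: they are the *inputs* of the
desk-scale worked example (evaluating linear contrasts on the printed
coefficient table), and they are the expectations that
:func:`ssmeta.pipeline.reproduce_report` compares a rerun of the
deposited dataset against.  They are never used inside any estimator.
"""

from __future__ import annotations

import numpy as np

#: Order of the sex-by-environment fixed effects as printed.
SEX_ENV_PARAMETERS = (
    "intercept",
    "sex[both]",
    "sex[female]",
    "environment[stressful]",
    "sex[both]:environment[stressful]",
    "sex[female]:environment[stressful]",
)

#: Printed 3-decimal coefficient column of the sex-by-environment model
#: (Hedges' g response).
SEX_ENV_COEF_3DP = np.array([0.188, 0.003, 0.113, -0.156, 0.182, 0.264])

#: Printed standard errors of the same column.
SEX_ENV_COEF_SE = np.array([0.18, 0.07, 0.03, 0.04, 0.09, 0.05])

#: Printed 2-decimal REML coefficient column of the same model.
SEX_ENV_COEF_REML = np.array([0.19, 0.00, 0.11, -0.16, 0.18, 0.26])

#: Printed sex-by-environment hypothesis contrasts (Hedges' g scale).
HYPOTHESIS_CONTRASTS = {
    "female_gt_male_benign": 0.113,
    "female_gt_male_stressful": 0.377,
    "female_stressful_gt_benign": 0.108,
    "male_benign_gt_stressful": 0.156,
    "both_stressful_gt_benign": 0.028,
}

#: Contrast weight vectors on the printed 6-parameter design.
CONTRAST_WEIGHTS = {
    "female_gt_male_benign": np.array([0, 0, 1, 0, 0, 0], dtype=float),
    "female_gt_male_stressful": np.array([0, 0, 1, 0, 0, 1], dtype=float),
    "female_stressful_gt_benign": np.array([0, 0, 0, 1, 0, 1], dtype=float),
    "male_benign_gt_stressful": np.array([0, 0, 0, -1, 0, 0], dtype=float),
    "both_stressful_gt_benign": np.array([0, 0, 0, 1, 1, 0], dtype=float),
}

#: Headline pooled / per-class estimates (Hedges' g, REML column).
HEADLINE = {
    "grand_mean": 0.24,
    "class_direct": 0.13,
    "class_indirect": 0.24,
    "class_ambiguous": 0.21,
    "trait_immunity": -0.42,
    "lncvr_female_stressful": -0.78,
    "lncvr_both_stressful": -0.76,
}

#: Heterogeneity of the sex-by-environment Hedges' g model (%).
I2_G = {"total": 95.2, "study": 36.0, "trait": 0.4, "taxon": 1.4}

#: Heterogeneity of the lnCVR model (%).
I2_LNCVR = {"total": 98.9, "study": 0.0, "trait": 12.7, "taxon": 7.7,
            "effect": 78.6}

#: Publication-bias statistics.
EGGER_Z = 5.9
TREND_DF = 437

#: Dataset shape.
COUNTS = {
    "records": 459,
    "studies": 65,
    "traits": 22,
    "g_moderator_subset": 330,
    "ratio_moderator_subset": 269,
}
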