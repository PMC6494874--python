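"""Multilevel REML engine: closed forms, cross-checks and invariants."""

import numpy as np
import pandas as pd
import pytest

from ssmeta.errors import DesignError
from ssmeta.meta_model import (
    ModelSpec,
    _reml_nll_grad,
    build_design,
    cell_mean_contrast,
    contrast,
    fit_model,
    grouping_matrix,
    level_matrices,
    per_trait_models,
    predict_levels,
    profile_beta,
    reml_fit,
)
from ssmeta.published import CONTRAST_WEIGHTS, SEX_ENV_COEF_3DP, SEX_ENV_COEF_SE


def _fixture_frame() -> pd.DataFrame:
    """Deterministic 40-effect dataset; the metafor oracle refits this
    exact table (see tests/oracles/)."""
    rng = np.random.default_rng(20240917)
    k = 40
    sex = np.where(rng.random(k) < 0.5, "male", "female")
    env = np.where(rng.random(k) < 0.6, "benign", "stressful")
    v = np.round(rng.uniform(0.02, 0.2, k), 6)
    y = np.round(0.3 + rng.normal(0.0, 0.3, k), 6)
    return pd.DataFrame(
        {
            "study_id": [f"s{i//4:02d}" for i in range(k)],
            "taxon": [f"tax{i%3}" for i in range(k)],
            "trait": [f"tr{i%5}" for i in range(k)],
            "sex": sex,
            "environment": env,
            "value": y,
            "variance": v,
        }
    )


class TestRemlClosedForms:
    def test_balanced_single_level_matches_closed_form(self):
        # equal v, one group per effect: sigma2 = SS/(k-1) - v, beta = ybar
        y = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        v = np.ones(5)
        fit = reml_fit(y, v, np.ones((5, 1)), {"study": np.eye(5)})
        assert fit.converged
        assert fit.sigma2["study"] == pytest.approx(1.5, abs=1e-6)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-10)
        assert np.sqrt(fit.cov_beta[0, 0]) == pytest.approx(
            np.sqrt(2.5 / 5), abs=1e-6
        )

    def test_constant_response_gives_zero_heterogeneity(self):
        y = np.full(6, 0.7)
        v = np.linspace(0.5, 1.5, 6)
        fit = reml_fit(y, v, np.ones((6, 1)), {"study": np.eye(6)})
        assert fit.sigma2["study"] == 0.0
        assert fit.beta[0] == pytest.approx(0.7, abs=1e-10)

    def test_zero_components_reduce_to_weighted_least_squares(self):
        frame = _fixture_frame()
        y = frame["value"].to_numpy()
        v = frame["variance"].to_numpy()
        X = np.column_stack([np.ones(len(y)), (frame["sex"] == "female").astype(float)])
        Zs = [np.eye(len(y))]
        beta, cov = profile_beta(y, v, X, Zs, [0.0])
        w = 1.0 / v
        A = X.T @ (X * w[:, None])
        expect = np.linalg.solve(A, X.T @ (w * y))
        np.testing.assert_allclose(beta, expect, rtol=1e-12)
        np.testing.assert_allclose(cov, np.linalg.inv(A), rtol=1e-10)


class TestAgainstMetafor:
    """Cross-checks against metafor::rma.mv refits of the same fixture
    (expected values frozen from tests/oracles/metafor_oracle.R)."""

    def test_intercept_only_three_levels(self):
        fit = fit_model(_fixture_frame(), ModelSpec("1", ("study", "trait", "taxon")))
        assert fit.beta[0] == pytest.approx(0.3698218, abs=2e-5)
        assert fit.se[0] == pytest.approx(0.07685031, abs=2e-5)
        # metafor reports study/trait at ~1e-7 (its boundary); ours snap to 0
        assert fit.sigma2["study"] == pytest.approx(0.0, abs=1e-5)
        assert fit.sigma2["trait"] == pytest.approx(0.0, abs=1e-5)
        assert fit.sigma2["taxon"] == pytest.approx(0.01160274, abs=2e-4)

    def test_moderated_with_observation_level(self):
        fit = fit_model(
            _fixture_frame(), ModelSpec("sex*environment", ("study", "effect"))
        )
        np.testing.assert_allclose(
            fit.beta,
            [0.3207592, 0.006296465, 0.2920257, -0.3305786],
            atol=2e-4,
        )
        np.testing.assert_allclose(
            fit.se, [0.07313087, 0.1140083, 0.1287918, 0.2117173], atol=2e-4
        )
        assert fit.sigma2["study"] == pytest.approx(0.0, abs=1e-4)
        assert fit.sigma2["effect"] == pytest.approx(0.00478138, abs=2e-4)


class TestOptimizerQuality:
    def test_no_better_point_on_grid_around_optimum(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            k = 30
            study = rng.integers(0, 8, k)
            v = rng.uniform(0.02, 0.3, k)
            y = 0.3 + rng.normal(0, 0.25, k)
            X = np.ones((k, 1))
            Zs = {"study": grouping_matrix(study), "effect": np.eye(k)}
            fit = reml_fit(y, v, X, Zs)
            zl = list(Zs.values())
            gl = [Z @ Z.T for Z in zl]
            s2 = np.array([max(fit.sigma2[n], 1e-10) for n in Zs])
            base, _ = _reml_nll_grad(np.log(s2), y, v, X, zl, gl)
            for factor in np.linspace(0.7, 1.4, 20):
                for j in range(len(s2)):
                    trial = s2.copy()
                    trial[j] = max(trial[j] * factor, 1e-10)
                    val, _ = _reml_nll_grad(np.log(trial), y, v, X, zl, gl)
                    assert val >= base - 1e-7

    def test_row_permutation_invariance(self, small_dataset):
        _, frame = small_dataset
        spec = ModelSpec("1", ("study", "trait", "taxon"))
        fit = fit_model(frame, spec)
        rng = np.random.default_rng(0)
        perm = frame.sample(frac=1.0, random_state=7).reset_index(drop=True)
        fit_p = fit_model(perm, spec)
        np.testing.assert_allclose(fit.beta, fit_p.beta, atol=1e-7)
        for lev in fit.sigma2:
            assert fit.sigma2[lev] == pytest.approx(fit_p.sigma2[lev], abs=1e-6)

    def test_label_renaming_invariance(self, small_dataset):
        _, frame = small_dataset
        spec = ModelSpec("1", ("study", "trait", "taxon"))
        fit = fit_model(frame, spec)
        renamed = frame.copy()
        renamed["study_id"] = "X_" + renamed["study_id"]
        fit_r = fit_model(renamed, spec)
        np.testing.assert_allclose(fit.beta, fit_r.beta, atol=1e-9)


class TestDesign:
    def test_intercept_only_is_column_of_ones(self):
        frame = _fixture_frame()
        d = build_design(frame, ModelSpec("1", ("study",)))
        assert d.X.shape == (len(frame), 1)
        assert np.all(d.X == 1.0)

    def test_sex_environment_has_six_printed_columns(self, paperlike_bundle):
        coef = paperlike_bundle["tables"]["sex_env_coefficients"]
        g_params = coef[coef["measure"] == "g"]["parameter"].tolist()
        assert g_params == [
            "intercept",
            "sex[both]",
            "sex[female]",
            "environment[stressful]",
            "sex[both]:environment[stressful]",
            "sex[female]:environment[stressful]",
        ]

    def test_unknown_moderator_column_errors(self):
        with pytest.raises(DesignError):
            build_design(_fixture_frame(), ModelSpec("flavour", ("study",)))

    def test_rank_deficient_design_names_aliased_columns(self):
        frame = _fixture_frame().copy()
        # make environment a deterministic function of sex -> aliasing
        frame["environment"] = np.where(
            frame["sex"] == "female", "stressful", "benign"
        )
        with pytest.raises(DesignError, match="aliased"):
            build_design(frame, ModelSpec("sex*environment", ("study",)))


class TestContrasts:
    def make_printed_fit(self):
        from ssmeta.meta_model import FitResult

        return FitResult(
            beta=SEX_ENV_COEF_3DP.copy(),
            cov_beta=np.diag(SEX_ENV_COEF_SE**2),
            sigma2={"study": 0.0},
            loglik_reml=0.0,
            k=330,
            p=6,
            converged=True,
        )

    def test_printed_coefficients_reproduce_hypothesis_table(self):
        fit = self.make_printed_fit()
        c1 = contrast(fit, CONTRAST_WEIGHTS["female_gt_male_stressful"])
        assert c1.estimate == pytest.approx(0.377, abs=1e-12)
        c2 = contrast(fit, CONTRAST_WEIGHTS["male_benign_gt_stressful"])
        assert c2.estimate == pytest.approx(0.156, abs=1e-12)

    def test_zero_contrast(self):
        c = contrast(self.make_printed_fit(), np.zeros(6))
        assert c.estimate == 0.0 and c.se == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            contrast(self.make_printed_fit(), np.ones(4))

    def test_contrast_invariants(self):
        fit = self.make_printed_fit()
        L = CONTRAST_WEIGHTS["female_stressful_gt_benign"]
        c = contrast(fit, L)
        assert c.estimate == pytest.approx(float(L @ fit.beta), rel=1e-12)
        assert c.se == pytest.approx(
            float(np.sqrt(L @ fit.cov_beta @ L)), rel=1e-12
        )
        lo, hi = c.ci95
        assert lo < c.estimate < hi


class TestPredictions:
    def test_intercept_only_prediction_is_grand_mean(self, small_dataset):
        _, frame = small_dataset
        fit = fit_model(frame, ModelSpec("1", ("study",)))
        pred = predict_levels(fit, "1")
        assert len(pred) == 1
        assert pred["estimate"].iloc[0] == pytest.approx(fit.beta[0], rel=1e-12)

    def test_class_predictions_recover_known_group_means(self):
        # two trait classes with distinct true means, tiny noise
        rng = np.random.default_rng(9)
        k = 60
        cls = np.where(np.arange(k) % 2 == 0, "direct", "indirect")
        mu = np.where(cls == "direct", 0.1, 0.6)
        v = np.full(k, 0.01)
        frame = pd.DataFrame(
            {
                "study_id": [f"s{i//3}" for i in range(k)],
                "fitness_class": cls,
                "value": mu + rng.normal(0, 0.1, k),
                "variance": v,
            }
        )
        fit = fit_model(frame, ModelSpec("fitness_class", ("study",)))
        pred = predict_levels(fit, "fitness_class").set_index("level")
        for level, true in (("direct", 0.1), ("indirect", 0.6)):
            est, se = pred.loc[level, "estimate"], pred.loc[level, "se"]
            assert abs(est - true) < 2 * max(se, 0.05)

    def test_unknown_moderator_errors(self, small_dataset):
        _, frame = small_dataset
        fit = fit_model(frame, ModelSpec("1", ("study",)))
        with pytest.raises(DesignError):
            predict_levels(fit, "sex")

    def test_cell_mean_contrast_reference_cell_is_intercept(self, small_dataset):
        _, frame = small_dataset
        fit = fit_model(frame, ModelSpec("sex*environment", ("study",)))
        L = cell_mean_contrast(fit, "male", "benign")
        assert L[0] == 1.0 and L.sum() == 1.0


class TestPerTrait:
    def test_threshold_and_consistency(self):
        rng = np.random.default_rng(11)
        rows = []
        for trait, n in (("lifespan", 8), ("immunity", 3)):
            for i in range(n):
                rows.append(
                    {
                        "study_id": f"s{i % 4}",
                        "taxon": "flies",
                        "trait": trait,
                        "value": rng.normal(0.2, 0.3),
                        "variance": rng.uniform(0.02, 0.1),
                    }
                )
        frame = pd.DataFrame(rows)
        fits, skipped = per_trait_models(frame)
        assert skipped == ["immunity"]  # exactly 3 effects -> below threshold
        assert set(fits) == {"lifespan"}
        # a single-trait frame must agree with a direct fit
        sub = frame[frame["trait"] == "lifespan"].reset_index(drop=True)
        direct = fit_model(sub, ModelSpec("1", ("study", "taxon")))
        assert fits["lifespan"].beta[0] == pytest.approx(direct.beta[0], abs=1e-9)
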