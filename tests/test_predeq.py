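"""Prediction-equation registry, design, fitting and surfaces."""

import numpy as np
import pandas as pd
import pytest

from glyconcord.predeq import (
    FittedPredictionModel,
    PredictionInputError,
    design_matrix,
    fit_prediction_model,
    predict_probability,
    probability_surface,
    registry_of_specs,
)
from glyconcord.synthetic import simulate_prediction_cohort

REGIONS4 = (
    "high_income_western",
    "central_eastern_europe",
    "south_asia",
    "sub_saharan_africa",
)


def spec5_truth(direction="fpg_to_hba1c"):
    spec = registry_of_specs(direction)[4]
    bio = spec.conditioning_biomarker
    coef = {
        "intercept": -2.0,
        bio: 1.5,
        "male": 0.15,
        "age10": 0.12,
        "bmi5": 0.10,
        "method_portable": 0.3,
    }
    for r in REGIONS4[1:]:
        coef[f"region_{r}"] = 0.3
        coef[f"{bio}_x_region_{r}"] = 0.08 if r == "sub_saharan_africa" else -0.05
    return spec, coef


class TestRegistry:
    @pytest.mark.parametrize("direction", ["fpg_to_hba1c", "hba1c_to_fpg"])
    def test_nine_specs(self, direction):
        specs = registry_of_specs(direction)
        assert [s.model_id for s in specs] == list(range(1, 10))
        assert all(s.direction == direction for s in specs)

    def test_spec5_has_bmi_and_region_slope(self):
        spec5 = registry_of_specs("fpg_to_hba1c")[4]
        assert spec5.include_bmi and spec5.region_specific_slope
        spec8 = registry_of_specs("fpg_to_hba1c")[7]
        assert spec8.include_bmi and spec8.region_specific_slope
        assert spec8.region_parameterization == "nested"

    def test_spec1_minimal(self):
        spec1 = registry_of_specs("fpg_to_hba1c")[0]
        assert not any(
            [
                spec1.include_sex,
                spec1.include_age,
                spec1.include_bmi,
                spec1.include_method,
                spec1.include_region_intercepts,
                spec1.region_specific_slope,
                spec1.sex_specific_slope,
            ]
        )

    def test_directions_structurally_identical(self):
        a = registry_of_specs("fpg_to_hba1c")
        b = registry_of_specs("hba1c_to_fpg")
        for sa, sb in zip(a, b):
            da, db = sa.__dict__.copy(), sb.__dict__.copy()
            da.pop("direction"), db.pop("direction")
            assert da == db

    def test_unknown_direction(self):
        with pytest.raises(ValueError, match="direction"):
            registry_of_specs("upwards")


class TestDesignMatrix:
    def test_missing_covariate_named(self):
        spec = registry_of_specs("fpg_to_hba1c")[1]  # needs sex + age
        cov = pd.DataFrame({"fpg": [5.5], "sex": ["male"]})
        with pytest.raises(PredictionInputError, match="age"):
            design_matrix(spec, cov)

    def test_spec1_columns(self):
        spec = registry_of_specs("fpg_to_hba1c")[0]
        X, names = design_matrix(spec, pd.DataFrame({"fpg": [5.5, 7.0]}))
        assert names == ["intercept", "fpg"]
        assert X.shape == (2, 2)

    def test_nested_parameterization_spans_deviation(self):
        # models 5 and 8 parameterize the same column space
        spec5, coef = spec5_truth()
        parts, studies, _, _ = simulate_prediction_cohort(
            spec5, coef, n_studies=8, rows_per_study=50, regions=REGIONS4, seed=0
        )
        spec8 = registry_of_specs("fpg_to_hba1c")[7]
        X5, _ = design_matrix(spec5, parts, studies)
        X8, _ = design_matrix(spec8, parts, studies)
        assert X5.shape == X8.shape
        proj = X8 @ np.linalg.lstsq(X8, X5, rcond=None)[0]
        np.testing.assert_allclose(proj, X5, atol=1e-8)


class TestFitAndPredict:
    def test_all_zero_coefficients_give_half(self):
        spec = registry_of_specs("fpg_to_hba1c")[0]
        model = FittedPredictionModel(
            spec=spec,
            coefficients={"intercept": 0.0, "fpg": 0.0},
            re_variance=0.0,
            regions=None,
            study_effects={},
            deviance=0.0,
            converged=True,
            n_obs=0,
            data_hash="",
            seed=0,
        )
        p = predict_probability(model, {"fpg": 6.0})
        assert p[0] == pytest.approx(0.5)

    def test_monotone_in_conditioning_biomarker(self):
        spec, coef = spec5_truth()
        parts, studies, _, _ = simulate_prediction_cohort(
            spec, coef, n_studies=10, rows_per_study=300, regions=REGIONS4, seed=1
        )
        model = fit_prediction_model(spec, parts, studies)
        grid = pd.DataFrame(
            {
                "fpg": np.linspace(4, 9, 30),
                "sex": "female",
                "age": 50.0,
                "bmi": 27.0,
                "region": "south_asia",
                "fpg_portable": False,
                "hba1c_portable": False,
            }
        )
        p = predict_probability(model, grid)
        assert np.all(np.diff(p) > 0)

    def test_refit_identical(self):
        spec, coef = spec5_truth()
        parts, studies, _, _ = simulate_prediction_cohort(
            spec, coef, n_studies=8, rows_per_study=200, regions=REGIONS4, seed=2
        )
        m1 = fit_prediction_model(spec, parts, studies, seed=9)
        m2 = fit_prediction_model(spec, parts, studies, seed=9)
        assert m1.coefficients == m2.coefficients
        assert m1.re_variance == m2.re_variance

    def test_predictions_close_to_ground_truth_probabilities(self):
        spec, coef = spec5_truth()
        parts, studies, p_true, u = simulate_prediction_cohort(
            spec, coef, n_studies=20, rows_per_study=800, regions=REGIONS4, seed=3
        )
        model = fit_prediction_model(spec, parts, studies)
        g, ids = pd.factorize(parts["study_id"])
        u_hat = np.array([model.study_effects[s] for s in ids])
        p_hat = predict_probability(model, parts, studies, random_effect=u_hat[g])
        assert np.mean((p_hat - p_true) ** 2) < 1e-3

    def test_nested_specs_never_increase_deviance(self):
        spec, coef = spec5_truth()
        parts, studies, _, _ = simulate_prediction_cohort(
            spec, coef, n_studies=10, rows_per_study=400, regions=REGIONS4, seed=4
        )
        deviances = {}
        for s in registry_of_specs("fpg_to_hba1c"):
            deviances[s.model_id] = fit_prediction_model(s, parts, studies).deviance
        # nesting chains: 1 < 2 < 3 < 4 < {5,7}; 5 < 6; 8 == 5-span; 8 < 9
        tol = 1e-4
        assert deviances[2] <= deviances[1] + tol
        assert deviances[3] <= deviances[2] + tol
        assert deviances[4] <= deviances[3] + tol
        assert deviances[5] <= deviances[4] + tol
        assert deviances[7] <= deviances[4] + tol
        assert deviances[6] <= deviances[5] + tol
        assert deviances[8] == pytest.approx(deviances[5], abs=1.0)
        assert deviances[9] <= deviances[8] + 1.0

    def test_constant_outcome_raises(self):
        spec = registry_of_specs("fpg_to_hba1c")[0]
        parts, studies, _, _ = simulate_prediction_cohort(
            spec, {"intercept": -30.0, "fpg": 0.0}, n_studies=4, rows_per_study=50, seed=5
        )
        with pytest.raises(ValueError, match="constant"):
            fit_prediction_model(spec, parts, studies)

    def test_training_excludes_diagnosed(self):
        spec = registry_of_specs("fpg_to_hba1c")[0]
        parts, studies, _, _ = simulate_prediction_cohort(
            spec, {"intercept": -0.5, "fpg": 0.8}, n_studies=4, rows_per_study=100, seed=6
        )
        m_all = fit_prediction_model(spec, parts, studies)
        parts2 = parts.copy()
        extra = parts.iloc[:100].copy()
        extra["participant_id"] = extra["participant_id"] + "_dx"
        extra["diagnosed_previously"] = True
        extra["outcome"] = 1
        parts2 = pd.concat([parts2, extra], ignore_index=True)
        m_filtered = fit_prediction_model(spec, parts2, studies)
        assert m_filtered.coefficients == m_all.coefficients
        assert m_filtered.n_obs == m_all.n_obs


class TestSerialization:
    def test_json_round_trip(self, tmp_path):
        spec, coef = spec5_truth()
        parts, studies, _, _ = simulate_prediction_cohort(
            spec, coef, n_studies=8, rows_per_study=100, regions=REGIONS4, seed=7
        )
        model = fit_prediction_model(spec, parts, studies, seed=3)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = FittedPredictionModel.from_json(path)
        assert loaded.coefficients == model.coefficients
        assert loaded.spec == model.spec
        assert loaded.re_variance == model.re_variance
        # loaded model predicts identically without refitting
        cov = parts.head(20)
        np.testing.assert_allclose(
            predict_probability(loaded, cov, studies),
            predict_probability(model, cov, studies),
        )


class TestSurface:
    @pytest.fixture(scope="class")
    def model(self):
        spec, coef = spec5_truth()
        regions7 = (
            "high_income_western",
            "central_eastern_europe",
            "central_asia_middle_east_north_africa",
            "latin_america_caribbean",
            "south_asia",
            "east_southeast_asia_pacific",
            "sub_saharan_africa",
        )
        coef = {
            "intercept": -2.0,
            "fpg": 1.5,
            "male": 0.15,
            "age10": 0.12,
            "bmi5": 0.10,
            "method_portable": 0.3,
        }
        for r in regions7[1:]:
            coef[f"region_{r}"] = 0.2
            coef[f"fpg_x_region_{r}"] = 0.02
        spec = registry_of_specs("fpg_to_hba1c")[4]
        parts, studies, _, _ = simulate_prediction_cohort(
            spec, coef, n_studies=14, rows_per_study=300, regions=regions7, seed=8
        )
        return fit_prediction_model(spec, parts, studies)

    def test_grid_cardinality(self, model):
        bins = ((4.5, 5.0), (5.0, 5.5), (5.5, 6.0), (6.0, 6.5), (6.5, 7.0), (7.0, 7.5))
        surface = probability_surface(model, biomarker_bins=bins)
        assert len(surface) == 2 * 3 * 7 * 3 * 6 == 756

    def test_rows_reproduce_pointwise_prediction(self, model):
        surface = probability_surface(model)
        cov = surface[["sex", "age", "bmi", "fpg", "region"]].copy()
        cov["fpg_portable"] = False
        cov["hba1c_portable"] = False
        np.testing.assert_allclose(
            surface["probability"].to_numpy(), predict_probability(model, cov)
        )

    def test_monotone_within_cells(self, model):
        surface = probability_surface(model)
        keys = ["sex", "age_band", "region", "bmi_band"]
        for _, cell in surface.groupby(keys):
            ordered = cell.sort_values("fpg")
            assert ordered["probability"].is_monotonic_increasing

    def test_empty_grid_raises(self, model):
        with pytest.raises(ValueError, match="empty"):
            probability_surface(model, sexes=())
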