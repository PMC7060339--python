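"""Resistance landscapes: class mapping, buffer reductions, collinearity
screening, all-subsets AIC averaging, tertile scoring, social surface."""

import numpy as np
import pandas as pd
import pytest
import shapely

from conftest import TRANSFORM, make_surface
from gardenflow.errors import (
    ConfigurationError,
    ConvergenceError,
    DegenerateInputError,
    SchemaError,
)
from gardenflow.grid import GridTransform, RasterGrid
from gardenflow.resistance import (
    FittedLogistic,
    ModelSet,
    VariableScorecard,
    akaike_weights,
    apply_reductions,
    base_from_landcover,
    build_scorecard,
    enumerate_models,
    extend_boundary,
    fit_logistic,
    screen_collinear,
    select_variables,
    social_surface,
    tertile_scores,
)
from gardenflow.scenario import (
    COVARIATE_NAMES,
    AmenityLayer,
    LandClass,
    ScenarioConfig,
    generate_blockgroups,
)


def landcover_raster(codes):
    return RasterGrid(np.asarray(codes, dtype=int), TRANSFORM)


class TestBaseFromLandcover:
    def test_range_spans_1_to_180(self):
        raster = landcover_raster(
            [[int(LandClass.CANOPY), int(LandClass.BUILDING)]]
        )
        surface = base_from_landcover(raster)
        assert surface.values.min() == 1.0
        assert surface.values.max() == 180.0

    def test_uniform_grass_is_constant(self):
        raster = landcover_raster(np.full((4, 4), int(LandClass.GRASS_SHRUB)))
        surface = base_from_landcover(raster)
        assert np.all(surface.values == 5.0)

    def test_toy_histogram(self):
        codes = np.array(
            [int(LandClass.CANOPY)] * 10 + [int(LandClass.BUILDING)] * 5
        ).reshape(3, 5)
        surface = base_from_landcover(landcover_raster(codes))
        vals, counts = np.unique(surface.values, return_counts=True)
        assert dict(zip(vals, counts)) == {1.0: 10, 180.0: 5}

    def test_water_becomes_nodata(self):
        raster = landcover_raster([[int(LandClass.WATER), int(LandClass.CANOPY)]])
        surface = base_from_landcover(raster)
        assert not surface.mask[0, 0]
        assert surface.mask[0, 1]

    def test_unmapped_class_raises(self):
        with pytest.raises(SchemaError):
            base_from_landcover(landcover_raster([[99]]))

    def test_out_of_range_mapping_rejected(self):
        raster = landcover_raster([[int(LandClass.CANOPY)]])
        with pytest.raises(ConfigurationError):
            base_from_landcover(raster, {int(LandClass.CANOPY): 200.0})


def point_layer(xy, buffer_m, reduction=0.10, target="social"):
    return AmenityLayer("layer", np.atleast_2d(xy), buffer_m, reduction, target)


class TestApplyReductions:
    def test_single_buffer_reduces_by_ten_percent(self):
        surface = make_surface(np.full((3, 3), 100.0))
        layer = point_layer([15.0, 15.0], buffer_m=50.0)
        out = apply_reductions(surface, [layer])
        assert out.values[1, 1] == pytest.approx(90.0)

    def test_outside_buffer_unchanged(self):
        surface = make_surface(np.full((3, 3), 100.0))
        layer = point_layer([15.0, 15.0], buffer_m=4.0)  # covers only centre
        out = apply_reductions(surface, [layer])
        assert out.values[0, 0] == 100.0

    def test_two_overlapping_buffers_stack_multiplicatively(self):
        surface = make_surface(np.full((3, 3), 100.0))
        layers = [point_layer([15.0, 15.0], 50.0), point_layer([16.0, 16.0], 50.0)]
        out = apply_reductions(surface, layers)
        assert out.values[1, 1] == pytest.approx(81.0)

    def test_reduction_out_of_range_rejected(self):
        surface = make_surface(np.full((2, 2), 100.0))
        with pytest.raises(ConfigurationError):
            apply_reductions(surface, [point_layer([5.0, 5.0], 50.0, reduction=1.5)])

    def test_never_increases_and_floors_at_one(self):
        rng = np.random.default_rng(0)
        surface = make_surface(rng.uniform(1.0, 2.0, (5, 5)))
        layers = [
            point_layer(rng.uniform(0, 50, 2), 60.0, reduction=0.5) for _ in range(4)
        ]
        out = apply_reductions(surface, layers)
        assert np.all(out.values <= surface.values + 1e-12)
        assert np.all(out.values >= 1.0)


class TestExtendBoundary:
    def test_zero_distance_is_identity(self):
        surface = make_surface(np.full((3, 3), 7.0))
        assert extend_boundary(surface, 0.0) is surface

    def test_1km_pad_at_10m_cells(self):
        surface = make_surface(np.full((4, 4), 7.0), cell=10.0)
        out = extend_boundary(surface, 1000.0)
        assert out.shape == (204, 204)
        assert out.pad == 100

    def test_padding_excluded_from_core_mask(self):
        surface = make_surface(np.full((4, 4), 7.0), cell=10.0)
        out = extend_boundary(surface, 20.0)
        core = out.core_mask()
        assert core.sum() == 16
        assert not core[0, 0]
        # padded values replicate the edge
        assert out.values[0, 0] == 7.0


class TestScreening:
    def test_duplicated_variable_drops_one(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        table = pd.DataFrame(
            {"a": x, "b": x, "garden_present": rng.integers(0, 2, 100)}
        )
        report = screen_collinear(table, ["a", "b"])
        assert len(report.dropped) == 1
        assert len(report.retained) == 1

    def test_independent_variables_retained(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame(
            {
                "a": rng.normal(size=200),
                "b": rng.normal(size=200),
                "garden_present": rng.integers(0, 2, 200),
            }
        )
        report = screen_collinear(table, ["a", "b"])
        assert report.dropped == []
        assert report.retained == ["a", "b"]

    def test_rank_preserving_transform_is_perfectly_correlated(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        y = rng.integers(0, 2, 100)
        table = pd.DataFrame({"a": x, "b": np.exp(x), "garden_present": y})
        report = screen_collinear(table, ["a", "b"])
        pair_rho = report.pairs.loc[0, "rho"]
        assert pair_rho == pytest.approx(1.0)
        assert len(report.dropped) == 1

    def test_constant_variable_dropped_with_warning(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(
            {
                "a": np.ones(50),
                "b": rng.normal(size=50),
                "garden_present": rng.integers(0, 2, 50),
            }
        )
        with pytest.warns(UserWarning, match="constant"):
            report = screen_collinear(table, ["a", "b"])
        assert "a" in report.dropped


class TestLogisticFit:
    def test_balanced_intercept_only(self):
        table = pd.DataFrame({"garden_present": [1] * 5 + [0] * 5})
        fit = fit_logistic(table, [])
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-8)
        assert fit.aic == pytest.approx(2 * 1 - 2 * (10 * np.log(0.5)), abs=1e-6)

    def test_single_class_outcome_rejected(self):
        table = pd.DataFrame({"x": np.arange(10.0), "garden_present": np.ones(10)})
        with pytest.raises(DegenerateInputError):
            fit_logistic(table, ["x"])

    def test_complete_separation_raises(self):
        x = np.arange(20.0)
        table = pd.DataFrame({"x": x, "garden_present": (x >= 10).astype(int)})
        with pytest.raises(ConvergenceError):
            fit_logistic(table, ["x"])

    def test_standardized_coefficients(self):
        rng = np.random.default_rng(5)
        x = rng.normal(10.0, 3.0, 500)
        p = 1 / (1 + np.exp(-((x - 10.0) / 3.0)))
        table = pd.DataFrame(
            {"x": x, "garden_present": (rng.random(500) < p).astype(int)}
        )
        fit = fit_logistic(table, ["x"])
        # coefficient is per-SD because covariates are z-scored before the fit
        assert fit.params["x"] == pytest.approx(1.0, abs=0.3)


class TestModelEnumeration:
    def test_akaike_weight_formula(self):
        w = akaike_weights(np.array([100.0, 102.0]))
        assert w == pytest.approx([0.731, 0.269], abs=5e-4)

    def test_single_model_weight_is_one(self):
        assert akaike_weights(np.array([50.0])) == pytest.approx([1.0])

    def test_three_variables_give_eight_models(self, blockgroups_2000):
        ms = enumerate_models(blockgroups_2000, list(COVARIATE_NAMES[:3]))
        assert len(ms.models) == 8
        assert ms.models["weight"].sum() == pytest.approx(1.0, abs=1e-9)
        assert ms.models["delta_aic"].min() == 0.0
        assert (ms.models["delta_aic"] >= 0).all()

    def test_aic_identity(self, blockgroups_2000):
        ms = enumerate_models(blockgroups_2000, list(COVARIATE_NAMES[:2]))
        for _, row in ms.models.iterrows():
            assert row["aic"] == pytest.approx(
                2 * row["k"] - 2 * row["loglik"], abs=1e-9
            )

    def test_too_many_variables_rejected(self, blockgroups_2000):
        fake = [f"v{i}" for i in range(17)]
        with pytest.raises(ConfigurationError, match="screen"):
            enumerate_models(blockgroups_2000, fake)


def _toy_model_set(weights, var_sets, coefs=None):
    """Hand-built ModelSet: weights must already be sorted descending."""
    table = pd.DataFrame(
        {"a": np.arange(9.0), "b": np.arange(9.0)[::-1], "garden_present": [0, 1] * 4 + [0]}
    )
    aic = -2 * np.log(np.asarray(weights))  # reproduces the given weights
    models = pd.DataFrame(
        {
            "variables": [tuple(v) for v in var_sets],
            "k": [len(v) + 1 for v in var_sets],
            "loglik": 0.0,
            "aic": aic,
        }
    )
    models["delta_aic"] = models["aic"] - models["aic"].min()
    models["weight"] = akaike_weights(models["aic"].to_numpy())
    fits = {}
    for vs in models["variables"]:
        params = pd.Series(0.0, index=["const", *vs])
        for v in vs:
            params[v] = (coefs or {}).get(v, 1.0)
        fits[vs] = FittedLogistic(vs, params, 0.0, 0.0, 9)
    return ModelSet(models=models, variables=["a", "b"], table=table, fits=fits)


class TestScorecard:
    def test_variable_in_every_model_has_importance_one(self):
        ms = _toy_model_set([0.6, 0.4], [("a",), ("a", "b")])
        card = build_scorecard(ms, cutoff=0.97)
        assert card.importance("a") == pytest.approx(1.0)

    def test_variable_in_no_model_has_importance_zero(self):
        ms = _toy_model_set([0.7, 0.3], [("a",), ("a",)])
        card = build_scorecard(ms, cutoff=0.97)
        assert card.importance("b") == 0.0

    def test_two_model_renormalized_importance(self):
        ms = _toy_model_set([0.7, 0.3], [("a",), ("b",)])
        card = build_scorecard(ms, cutoff=1.0)
        assert card.importance("a") == pytest.approx(0.7, abs=1e-6)

    def test_confidence_set_is_smallest_prefix(self):
        ms = _toy_model_set([0.9, 0.08, 0.02], [("a",), ("b",), ("a", "b")])
        card = build_scorecard(ms, cutoff=0.97)
        assert card.confidence_set_size == 2

    def test_select_threshold_zero_returns_all(self):
        ms = _toy_model_set([0.7, 0.3], [("a",), ("b",)])
        card = build_scorecard(ms, cutoff=1.0)
        assert select_variables(card, threshold=1e-9) == ["a", "b"]

    def test_empty_selection_warns(self):
        ms = _toy_model_set([0.7, 0.3], [("a",), ("b",)])
        card = build_scorecard(ms, cutoff=1.0)
        with pytest.warns(UserWarning, match="no variable"):
            assert select_variables(card, threshold=1.0) == []


def _manual_scorecard(signs, breakpoints):
    rows = {
        v: {
            "importance": 1.0,
            "coefficient": 1.0 if s == "+" else -1.0,
            "sign": s,
            "tertile_low": breakpoints[v][0],
            "tertile_high": breakpoints[v][1],
        }
        for v, s in signs.items()
    }
    return VariableScorecard(pd.DataFrame(rows).T, 0.97, 1)


class TestTertileScores:
    def test_equal_count_split_with_positive_sign(self):
        table = pd.DataFrame({"v": np.arange(1.0, 10.0)})
        q1, q2 = np.quantile(table["v"], [1 / 3, 2 / 3])
        card = _manual_scorecard({"v": "+"}, {"v": (q1, q2)})
        scores = tertile_scores(table, card, "v")
        assert scores.tolist() == [30, 30, 30, 20, 20, 20, 10, 10, 10]

    def test_negative_sign_reverses_ladder(self):
        table = pd.DataFrame({"v": np.arange(1.0, 10.0)})
        q1, q2 = np.quantile(table["v"], [1 / 3, 2 / 3])
        card = _manual_scorecard({"v": "-"}, {"v": (q1, q2)})
        scores = tertile_scores(table, card, "v")
        assert scores.tolist() == [10, 10, 10, 20, 20, 20, 30, 30, 30]

    def test_middle_tertile_scores_20_for_either_sign(self):
        table = pd.DataFrame({"v": np.arange(1.0, 10.0)})
        q1, q2 = np.quantile(table["v"], [1 / 3, 2 / 3])
        for sign in "+-":
            card = _manual_scorecard({"v": sign}, {"v": (q1, q2)})
            assert set(tertile_scores(table, card, "v")[3:6]) == {20}

    def test_monotone_in_variable(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame({"v": np.sort(rng.normal(size=30))})
        q1, q2 = np.quantile(table["v"], [1 / 3, 2 / 3])
        card = _manual_scorecard({"v": "+"}, {"v": (q1, q2)})
        scores = tertile_scores(table, card, "v")
        assert np.all(np.diff(scores) <= 0)  # non-increasing when sign is +

    def test_constant_variable_unsplittable(self):
        table = pd.DataFrame({"v": np.ones(9)})
        card = _manual_scorecard({"v": "+"}, {"v": (1.0, 1.0)})
        with pytest.raises(DegenerateInputError):
            tertile_scores(table, card, "v")

    def test_missing_variable_raises(self):
        table = pd.DataFrame({"v": np.arange(9.0)})
        card = _manual_scorecard({"v": "+"}, {"v": (2.0, 5.0)})
        with pytest.raises(KeyError):
            tertile_scores(table, card, "w")


def _six_variable_table():
    """Nine block groups tiling a 30x30 m extent; six perfectly aligned
    covariates so tertile membership is identical across variables."""
    polys = [
        shapely.box(c * 10, 20 - r * 10, (c + 1) * 10, 30 - r * 10)
        for r in range(3)
        for c in range(3)
    ]
    table = pd.DataFrame({f"v{i}": np.arange(1.0, 10.0) for i in range(6)})
    table["geometry"] = polys
    signs = {f"v{i}": "+" for i in range(6)}
    q1, q2 = np.quantile(np.arange(1.0, 10.0), [1 / 3, 2 / 3])
    card = _manual_scorecard(signs, {f"v{i}": (q1, q2) for i in range(6)})
    return table, card


class TestSocialSurface:
    def test_six_variables_span_60_to_180(self):
        table, card = _six_variable_table()
        surface = social_surface(
            table, card, GridTransform(0, 0, 10.0), (3, 3),
            variables=[f"v{i}" for i in range(6)],
        )
        assert surface.values.max() == 180.0
        assert surface.values.min() == 60.0

    def test_single_variable_constant_middle_tertile(self):
        polys = [shapely.box(i * 10, 0, (i + 1) * 10, 10) for i in range(3)]
        table = pd.DataFrame({"v": [5.0, 5.5, 6.0], "geometry": polys})
        card = _manual_scorecard({"v": "+"}, {"v": (1.0, 10.0)})  # all middle
        surface = social_surface(
            table, card, GridTransform(0, 0, 10.0), (1, 3), variables=["v"]
        )
        assert np.all(surface.values == 20.0)

    def test_rescale_flag_maps_to_full_range(self):
        table, card = _six_variable_table()
        surface = social_surface(
            table, card, GridTransform(0, 0, 10.0), (3, 3),
            variables=[f"v{i}" for i in range(6)], rescale_to_full_range=True,
        )
        assert surface.values.max() == pytest.approx(180.0)
        assert surface.values.min() == pytest.approx(1.0)

    def test_cell_outside_blockgroups_is_nodata(self):
        polys = [shapely.box(0, 0, 10, 10)]
        table = pd.DataFrame({"v": [5.0], "geometry": polys})
        card = _manual_scorecard({"v": "+"}, {"v": (1.0, 10.0)})
        surface = social_surface(
            table, card, GridTransform(0, 0, 10.0), (1, 2), variables=["v"]
        )
        assert surface.mask[0, 0]
        assert not surface.mask[0, 1]


class TestPlantedRecovery:
    def test_exact_recovery_on_one_seed(self, blockgroups_2000):
        """Screen -> dredge -> 97% averaging -> importance-1.0 selection
        returns exactly the planted nonzero-beta covariates."""
        names = blockgroups_2000.attrs["covariate_names"]
        report = screen_collinear(blockgroups_2000, names)
        ms = enumerate_models(blockgroups_2000, report.retained)
        card = build_scorecard(ms, cutoff=0.97)
        assert set(select_variables(card, 1.0)) == set(COVARIATE_NAMES)

    def test_recovered_signs_match_planted(self, blockgroups_2000):
        truth = blockgroups_2000.attrs["planted_beta"]
        ms = enumerate_models(blockgroups_2000, list(COVARIATE_NAMES))
        card = build_scorecard(ms, cutoff=0.97)
        for v in COVARIATE_NAMES:
            expected = "+" if truth[v] >= 0 else "-"
            assert card.table.loc[v, "sign"] == expected
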