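"""MaxEnt estimator: features, convex fit, prediction policies, replicates."""

import numpy as np
import pytest

from nichemap.climate_pca import fit_pca, project_pca, select_components
from nichemap.grids import RasterStack, RegionMask
from nichemap.maxent import (
    ConfigurationError,
    FeatureExpander,
    FeatureSpec,
    MaxEntModel,
    default_feature_classes,
    fit_maxent,
    occurrences_to_cells,
    predict_suitability,
    run_replicates,
    sample_background,
)
from nichemap.occurrences import clean_records, thin_to_grid
from nichemap.synthetic_data import make_climate_stack, sample_occurrences

from conftest import make_points


@pytest.fixture(scope="module")
def pc_setup(request):
    """PC stack, region, and thinned presences on the reduced scenario."""
    from nichemap.synthetic_data import SyntheticScenario

    scenario = SyntheticScenario(n_rows=40, n_cols=50, seed=7)
    stack = make_climate_stack(scenario)
    region = scenario.accessible_region
    tr = fit_pca(stack, region=region)
    k = select_components(tr)
    pcs = project_pca(stack, tr).subset([f"PC{i + 1}" for i in range(k)])
    occ = thin_to_grid(
        clean_records(sample_occurrences(scenario, 400, seed=3)), scenario.grid
    )
    return scenario, pcs, region, occ


class TestFeatureExpansion:
    def test_linear_only_feature_count(self, rng):
        X = rng.uniform(0, 1, (50, 2))
        exp = FeatureExpander(FeatureSpec(classes=("linear",))).fit(X)
        assert exp.transform(X).shape[1] == 2

    def test_linear_quadratic_product_count(self, rng):
        X = rng.uniform(0, 1, (50, 3))
        exp = FeatureExpander(
            FeatureSpec(classes=("linear", "quadratic", "product"))
        ).fit(X)
        # 3 linear + 3 quadratic + C(3,2)=3 products
        assert exp.transform(X).shape[1] == 9

    def test_all_features_in_unit_interval_on_training_data(self, rng):
        X = rng.normal(size=(200, 4))
        exp = FeatureExpander(FeatureSpec()).fit(X)
        F = exp.transform(X)
        assert F.min() >= -1e-12 and F.max() <= 1 + 1e-12

    def test_linear_feature_is_one_at_training_max(self, rng):
        X = rng.uniform(-5, 5, (50, 2))
        exp = FeatureExpander(FeatureSpec(classes=("linear",))).fit(X)
        at_max = exp.transform(exp.maxs_[None, :])
        np.testing.assert_allclose(at_max, 1.0, atol=1e-12)

    def test_sample_size_schedule(self):
        assert default_feature_classes(5) == ("linear",)
        assert default_feature_classes(12) == ("linear", "quadratic")
        assert default_feature_classes(40) == ("linear", "quadratic", "hinge")
        assert "product" in default_feature_classes(200)


class TestFitContract:
    def test_raw_density_sums_to_one_over_normalization_sample(self, rng):
        X = rng.normal(size=(500, 3))
        y = (rng.uniform(size=500) < 0.2).astype(int)
        y[:2] = 1
        model = MaxEntModel().fit(X, y)
        raw = model.predict_raw(X)
        assert raw.sum() == pytest.approx(1.0, abs=1e-6)

    def test_overwhelming_penalty_gives_uniform_model(self, rng):
        X = rng.normal(size=(300, 3))
        y = np.zeros(300, int)
        y[:30] = 1
        model = MaxEntModel(beta_multiplier=1e6).fit(X, y)
        assert np.all(model.coef_ == 0.0)
        raw = model.predict_raw(X)
        np.testing.assert_allclose(raw, 1.0 / 300, rtol=1e-12)

    def test_monotone_truth_gives_positive_linear_coefficient(self, rng):
        # presences concentrated at high values of the single predictor
        bg = rng.uniform(-1, 1, (1000, 1))
        pres = rng.uniform(0.6, 1, (100, 1))
        X = np.vstack([bg, pres])
        y = np.r_[np.zeros(1000), np.ones(100)]
        model = MaxEntModel(feature_classes=("linear",)).fit(X, y)
        assert model.coef_[0] > 0

    def test_null_presences_give_small_linear_coefficients(self, rng):
        # presences drawn uniformly from the background: no signal to fit
        X = rng.normal(size=(8000, 3))
        y = np.zeros(8000, int)
        y[rng.choice(8000, 2000, replace=False)] = 1
        model = MaxEntModel(feature_classes=("linear",)).fit(X, y)
        assert np.abs(model.coef_).max() < 0.1

    def test_stronger_penalty_shrinks_l1_norm(self, pc_setup):
        scenario, pcs, region, occ = pc_setup
        cells, _ = occurrences_to_cells(occ, pcs, region)
        bg = sample_background(region, n=2000, seed=0,
                               valid_mask=pcs.joint_valid_mask())
        norms = []
        for c in (1.0, 2.0, 4.0):
            m = fit_maxent(cells, bg, pcs, beta_multiplier=c)
            norms.append(np.abs(m.coef_).sum())
        assert norms[0] >= norms[1] >= norms[2]

    def test_serialization_roundtrip(self, rng, tmp_path):
        X = rng.normal(size=(400, 3))
        y = np.zeros(400, int)
        y[:60] = 1
        model = MaxEntModel().fit(X, y)
        model.to_json(str(tmp_path / "m.json"))
        back = MaxEntModel.from_json(str(tmp_path / "m.json"))
        np.testing.assert_allclose(model.predict(X), back.predict(X))


class TestPredictionPolicy:
    @pytest.fixture
    def fitted(self, rng):
        X = rng.uniform(0, 1, (300, 2))
        y = np.zeros(300, int)
        y[:50] = 1
        return MaxEntModel(feature_classes=("linear", "quadratic")).fit(X, y)

    def test_clamp_and_extrapolate_mutually_exclusive(self, pc_setup):
        scenario, pcs, region, occ = pc_setup
        cells, _ = occurrences_to_cells(occ, pcs, region)
        bg = sample_background(region, n=500, seed=0,
                               valid_mask=pcs.joint_valid_mask())
        model = fit_maxent(cells, bg, pcs)
        with pytest.raises(ConfigurationError):
            predict_suitability(model, pcs, clamp=True, extrapolate=True)

    def test_out_of_range_cell_masked_without_clamping(self, fitted):
        X = np.array([[fitted.feature_maxs_[0] + 1.0, 0.5]])
        assert fitted.out_of_range(X)[0]

    def test_clamped_prediction_equals_training_max(self, fitted):
        beyond = np.array([[fitted.feature_maxs_[0] + 1.0, 0.5]])
        at_max = np.array([[fitted.feature_maxs_[0], 0.5]])
        np.testing.assert_allclose(
            fitted.predict(beyond, clamp=True), fitted.predict(at_max)
        )

    def test_training_stack_prediction_adds_no_nodata(self, pc_setup):
        scenario, pcs, region, occ = pc_setup
        cells, _ = occurrences_to_cells(occ, pcs, region)
        # background exhausts the region, so all region cells are training data
        bg = sample_background(region, n=10**6, seed=0,
                               valid_mask=pcs.joint_valid_mask())
        model = fit_maxent(cells, bg, pcs)
        masked = RasterStack(
            [lyr.with_values(lyr.values, valid_mask=lyr.valid_mask & region.inside)
             for lyr in pcs.layers]
        )
        pred = predict_suitability(model, masked, extrapolate=False)
        np.testing.assert_array_equal(pred.valid_mask, masked.joint_valid_mask())


class TestBackgroundSampling:
    def test_small_region_returns_all_cells(self, small_spec):
        inside = np.zeros(small_spec.shape, bool)
        inside.ravel()[:50] = True
        region = RegionMask(small_spec, inside)
        cells = sample_background(region, n=10000, seed=1)
        assert cells.size == min(50, inside.sum())
        assert set(cells) == set(np.flatnonzero(inside))

    def test_same_seed_identical_sample(self, pc_setup):
        scenario, pcs, region, occ = pc_setup
        a = sample_background(region, n=100, seed=5)
        b = sample_background(region, n=100, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_large_region_sample_is_distinct_and_inside(self, pc_setup):
        scenario, pcs, region, occ = pc_setup
        cells = sample_background(region, n=400, seed=2)
        assert cells.size == 400
        assert len(np.unique(cells)) == 400
        assert region.inside.ravel()[cells].all()


class TestReplicates:
    def test_single_replicate_median_equals_prediction(self, pc_setup):
        scenario, pcs, region, occ = pc_setup
        rep = run_replicates(occ, region, pcs, n_replicates=1, seed=4,
                             background_n=1000)
        only = rep.predictions.layers[0]
        np.testing.assert_array_equal(
            rep.median_layer.values[rep.median_layer.valid_mask],
            only.values[only.valid_mask],
        )

    def test_fixed_seed_bit_identical(self, pc_setup):
        scenario, pcs, region, occ = pc_setup
        a = run_replicates(occ, region, pcs, n_replicates=2, seed=4,
                           background_n=1000)
        b = run_replicates(occ, region, pcs, n_replicates=2, seed=4,
                           background_n=1000)
        assert a.seeds == b.seeds
        np.testing.assert_array_equal(
            a.median_layer.values[a.median_layer.valid_mask],
            b.median_layer.values[b.median_layer.valid_mask],
        )

    def test_median_invariant_to_member_order(self, pc_setup):
        from nichemap.suitability_maps import summarize_members

        scenario, pcs, region, occ = pc_setup
        rep = run_replicates(occ, region, pcs, n_replicates=3, seed=4,
                             background_n=1000)
        permuted = RasterStack(rep.predictions.layers[::-1])
        s1 = summarize_members(rep.predictions)
        s2 = summarize_members(permuted)
        np.testing.assert_array_equal(
            s1.median_layer.values[s1.median_layer.valid_mask],
            s2.median_layer.values[s2.median_layer.valid_mask],
        )
        np.testing.assert_array_equal(
            s1.range_layer.values[s1.range_layer.valid_mask],
            s2.range_layer.values[s2.range_layer.valid_mask],
        )

    def test_presences_outside_region_ignored_with_warning(self, pc_setup):
        scenario, pcs, region, occ = pc_setup
        spec = scenario.grid
        # a record clearly outside the accessible area (north-east corner)
        lon_out = spec.x_min + (spec.n_cols - 0.5) * spec.cell_size
        lat_out = spec.y_min + (spec.n_rows - 0.5) * spec.cell_size
        import pandas as pd

        df = occ.records.head(30).copy()
        df.loc[len(df)] = {"lon": lon_out, "lat": lat_out, "source": "stray"}
        from nichemap.occurrences import OccurrenceSet

        stray = OccurrenceSet(df)
        cells, n_dropped = occurrences_to_cells(stray, pcs, region)
        assert n_dropped >= 1
        with pytest.warns(UserWarning, match="ignored"):
            run_replicates(stray, region, pcs, n_replicates=1, seed=0,
                           background_n=300)
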