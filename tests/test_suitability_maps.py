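"""Ensemble summaries, omission thresholding, classification, change maps."""

import numpy as np
import pytest

from nichemap.grids import GridSpec, RasterStack
from nichemap.suitability_maps import (
    aggregate_gcms,
    area_change_stats,
    binarize,
    change_categories,
    classify_suitability,
    omission_threshold,
    summarize_members,
)

from conftest import make_layer


def brute_force_omission_threshold(values, E):
    """Oracle: scan every candidate order statistic for the largest threshold
    whose omission (strictly-below count) stays within E*n."""
    values = np.sort(np.asarray(values, float))
    n = values.size
    best = None
    for t in values:
        omitted = (values < t).sum()
        if omitted <= E * n:
            best = t if best is None else max(best, t)
    return best


class TestSummaries:
    def test_three_member_median_and_range(self, small_spec):
        members = RasterStack(
            [make_layer(small_spec, np.full(small_spec.shape, v), f"m{i}")
             for i, v in enumerate([0.2, 0.5, 0.9])]
        )
        s = summarize_members(members)
        assert np.allclose(s.median_layer.valid_values, 0.5)
        assert np.allclose(s.range_layer.valid_values, 0.7)

    def test_single_member_range_zero(self, small_spec, rng):
        vals = rng.uniform(size=small_spec.shape)
        s = summarize_members(RasterStack([make_layer(small_spec, vals, "m0")]))
        np.testing.assert_array_equal(s.median_layer.valid_values,
                                      vals[s.median_layer.valid_mask])
        assert np.all(s.range_layer.valid_values == 0.0)

    def test_identical_gcms_collapse(self, small_spec, rng):
        vals = rng.uniform(size=small_spec.shape)
        stack = RasterStack(
            [make_layer(small_spec, vals, f"gcm{i}") for i in range(8)]
        )
        s = aggregate_gcms(stack)
        np.testing.assert_allclose(s.median_layer.valid_values,
                                   vals[s.median_layer.valid_mask])
        assert np.all(s.range_layer.valid_values == 0.0)

    def test_two_gcm_median_is_mean(self, small_spec):
        stack = RasterStack(
            [make_layer(small_spec, np.full(small_spec.shape, 0.2), "g1"),
             make_layer(small_spec, np.full(small_spec.shape, 0.8), "g2")]
        )
        s = aggregate_gcms(stack)
        assert np.allclose(s.median_layer.valid_values, 0.5)
        assert np.allclose(s.range_layer.valid_values, 0.6)

    def test_dropping_median_member_keeps_range(self, small_spec):
        layers = [
            make_layer(small_spec, np.full(small_spec.shape, v), f"g{i}")
            for i, v in enumerate([0.1, 0.5, 0.9])
        ]
        full = aggregate_gcms(RasterStack(layers))
        wo_mid = aggregate_gcms(RasterStack([layers[0], layers[2]]))
        np.testing.assert_array_equal(full.range_layer.valid_values,
                                      wo_mid.range_layer.valid_values)

    def test_mask_propagates_to_summary(self, small_spec, rng):
        m = np.ones(small_spec.shape, bool)
        m[0, 0] = False
        stack = RasterStack(
            [make_layer(small_spec, rng.uniform(size=small_spec.shape), "a", m),
             make_layer(small_spec, rng.uniform(size=small_spec.shape), "b")]
        )
        s = summarize_members(stack)
        assert not s.median_layer.valid_mask[0, 0]


class TestOmissionThreshold:
    def test_hundred_values_five_percent(self):
        values = np.arange(1, 101) / 100.0  # 0.01 .. 1.00
        t = omission_threshold(values, E=0.05)
        assert t == pytest.approx(0.06)
        assert (values < t).sum() == 5

    def test_zero_e_gives_minimum(self, rng):
        values = rng.uniform(size=37)
        assert omission_threshold(values, E=0.0) == values.min()

    def test_small_sample_floor(self):
        values = np.arange(1, 11) / 10.0
        assert omission_threshold(values, E=0.05) == pytest.approx(0.1)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            omission_threshold([], E=0.05)

    @pytest.mark.parametrize("E", [0.0, 0.05, 0.1, 0.25])
    def test_matches_brute_force_scan(self, rng, E):
        for _ in range(50):
            values = rng.uniform(size=rng.integers(1, 40))
            assert omission_threshold(values, E) == brute_force_omission_threshold(
                values, E
            )


class TestBinarize:
    def test_threshold_at_minimum_all_suitable(self, small_spec, rng):
        layer = make_layer(small_spec, rng.uniform(0.3, 0.9, small_spec.shape))
        b = binarize(layer, 0.1)
        assert b.n_suitable == layer.valid_mask.sum()

    def test_threshold_above_maximum_all_unsuitable(self, small_spec, rng):
        layer = make_layer(small_spec, rng.uniform(0.3, 0.9, small_spec.shape))
        assert binarize(layer, 0.95).n_suitable == 0

    def test_three_by_three_count(self):
        spec = GridSpec(3, 3, 0, 0, 1.0)
        layer = make_layer(spec, np.arange(0.1, 1.0, 0.1).reshape(3, 3))
        assert binarize(layer, 0.5).n_suitable == 5

    def test_nested_thresholds_are_monotone(self, small_spec, rng):
        layer = make_layer(small_spec, rng.uniform(size=small_spec.shape))
        lo = binarize(layer, 0.3).suitable_mask
        hi = binarize(layer, 0.6).suitable_mask
        assert np.all(hi <= lo)


class TestClassify:
    def test_quartile_mode_equal_counts(self):
        spec = GridSpec(10, 10, 0, 0, 1.0)
        layer = make_layer(spec, np.linspace(0.5, 0.99, 100).reshape(10, 10))
        cm = classify_suitability(layer, 0.5, breaks_mode="quartile")
        counts = cm.counts()
        assert counts["unsuitable"] == 0
        assert [counts[c] for c in ("minimal", "low", "medium", "high")] == [25] * 4

    def test_constant_suprathreshold_warns(self, small_spec):
        layer = make_layer(small_spec, np.full(small_spec.shape, 0.7))
        with pytest.warns(UserWarning, match="degenerate"):
            cm = classify_suitability(layer, 0.5)
        counts = cm.counts()
        assert sum(v > 0 for v in counts.values()) == 1

    def test_equal_interval_breaks_are_evenly_spaced(self, small_spec, rng):
        layer = make_layer(small_spec, rng.uniform(0.4, 1.0, small_spec.shape))
        cm = classify_suitability(layer, 0.4, breaks_mode="equal_interval")
        widths = np.diff([0.0] + list(np.asarray(cm.class_breaks)))
        assert np.allclose(np.diff(cm.class_breaks), np.diff(cm.class_breaks)[0],
                           atol=1e-9)

    def test_all_below_threshold_warns_all_unsuitable(self, small_spec, rng):
        layer = make_layer(small_spec, rng.uniform(0.0, 0.2, small_spec.shape))
        with pytest.warns(UserWarning):
            cm = classify_suitability(layer, 0.9)
        assert cm.counts()["unsuitable"] == layer.valid_mask.sum()


def toy_change_map():
    """4x4 toy: 8 historical-suitable, 10 future-suitable, 7 overlapping."""
    spec = GridSpec(4, 4, 0, 0, 1.0)
    hist = np.zeros((4, 4))
    hist.ravel()[:8] = 1  # cells 0..7 suitable historically
    fut = np.zeros((4, 4))
    fut.ravel()[1:11] = 1  # cells 1..10 suitable in the future (7 overlap)
    h = binarize(make_layer(spec, hist), 0.5)
    f = binarize(make_layer(spec, fut), 0.5)
    return h, f


class TestChange:
    def test_identical_maps_only_stable(self, small_spec, rng):
        b = binarize(make_layer(small_spec, rng.uniform(size=small_spec.shape)), 0.5)
        ch = change_categories(b, b)
        assert ch.counts["expansion"] == 0 and ch.counts["contraction"] == 0

    def test_zero_to_full_is_all_expansion(self, small_spec):
        z = binarize(make_layer(small_spec, np.zeros(small_spec.shape)), 0.5)
        o = binarize(make_layer(small_spec, np.ones(small_spec.shape)), 0.5)
        ch = change_categories(z, o)
        assert ch.counts["expansion"] == np.prod(small_spec.shape)

    def test_toy_counts(self):
        h, f = toy_change_map()
        ch = change_categories(h, f)
        assert ch.counts == {
            "stable_absence": 5,
            "expansion": 3,
            "contraction": 1,
            "stable_presence": 7,
        }

    def test_unaligned_maps_rejected(self, small_spec, rng):
        other = GridSpec(6, 8, 5.0, 0.0, 1.0)
        a = binarize(make_layer(small_spec, rng.uniform(size=small_spec.shape)), 0.5)
        b_layer = make_layer(other, rng.uniform(size=other.shape))
        b_layer.spec = other
        from nichemap.grids import GridAlignmentError

        with pytest.raises(GridAlignmentError):
            change_categories(a, binarize(b_layer, 0.5))

    def test_counts_reconcile_with_suitable_totals(self, small_spec, rng):
        a = binarize(make_layer(small_spec, rng.uniform(size=small_spec.shape)), 0.5)
        b = binarize(make_layer(small_spec, rng.uniform(size=small_spec.shape)), 0.5)
        ch = change_categories(a, b)
        assert ch.counts["expansion"] + ch.counts["stable_presence"] == b.n_suitable
        assert ch.counts["contraction"] + ch.counts["stable_presence"] == a.n_suitable


class TestAreaStats:
    def test_toy_percentages_on_historical_denominator(self):
        h, f = toy_change_map()
        stats = area_change_stats(change_categories(h, f))
        assert stats.pct_increase == pytest.approx(100 * 3 / 8)
        assert stats.pct_decrease == pytest.approx(100 * 1 / 8)

    def test_identical_maps_zero_change(self, small_spec, rng):
        b = binarize(make_layer(small_spec, rng.uniform(size=small_spec.shape)), 0.5)
        stats = area_change_stats(change_categories(b, b))
        assert stats.pct_increase == 0.0 and stats.pct_decrease == 0.0

    def test_single_row_weighting_cancels(self, rng):
        spec = GridSpec(1, 20, 0, 40.0, 1.0)
        a = binarize(make_layer(spec, rng.uniform(size=spec.shape)), 0.5)
        b = binarize(make_layer(spec, rng.uniform(size=spec.shape)), 0.5)
        ch = change_categories(a, b)
        flat = area_change_stats(ch, latitude_weighted=False)
        weighted = area_change_stats(ch, latitude_weighted=True)
        assert flat.pct_increase == pytest.approx(weighted.pct_increase)
        assert flat.pct_decrease == pytest.approx(weighted.pct_decrease)

    def test_all_valid_denominator(self):
        h, f = toy_change_map()
        stats = area_change_stats(change_categories(h, f),
                                  denominator_mode="all_valid")
        assert stats.pct_increase == pytest.approx(100 * 3 / 16)

    def test_zero_denominator_errors(self, small_spec):
        z = binarize(make_layer(small_spec, np.zeros(small_spec.shape)), 0.5)
        ch = change_categories(z, z)
        with pytest.raises(ZeroDivisionError):
            area_change_stats(ch, denominator_mode="historical_suitable")
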