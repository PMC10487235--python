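"""Unit and property tests for the Mamdani engine."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ribofis as rf
from ribofis.errors import (
    FuzzyDefinitionError,
    MissingInputError,
    NoRuleFiredError,
    OutOfRangeError,
)


class TestTriangularMF:
    @pytest.mark.parametrize(
        "mf, x, expected",
        [
            ((5, 12.5, 20), 12.5, 1.0),       # membership is 1 at the peak
            ((0, 5, 10), 2.5, 0.5),            # midpoint of the rising edge
            ((5, 5, 12.5), 5, 1.0),            # left-shoulder degenerate form
            ((5, 12.5, 20), 21, 0.0),          # outside the support
            ((5, 12.5, 20), 4, 0.0),
            ((12.5, 20, 20), 20, 1.0),         # right-shoulder degenerate form
            ((0, 5, 10), 7.5, 0.5),
        ],
    )
    def test_membership_values(self, mf, x, expected):
        assert rf.membership(rf.TriangularMF(*mf), x) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [(5, 4, 10), (5, 11, 10), (5, 5, 5)])
    def test_invalid_geometry_rejected(self, bad):
        with pytest.raises(FuzzyDefinitionError):
            rf.TriangularMF(*bad)

    @given(
        st.floats(0, 100), st.floats(0, 100), st.floats(0, 100),
        st.floats(-50, 150),
    )
    def test_membership_in_unit_interval_and_peaks_at_b(self, a, b, c, x):
        a, b, c = sorted((a, b, c))
        if a == c:
            return
        mf = rf.TriangularMF(a, b, c)
        assert 0.0 <= mf(x) <= 1.0
        assert mf(b) == 1.0

    def test_vectorised_evaluation_matches_scalar(self):
        mf = rf.TriangularMF(5, 12.5, 20)
        xs = np.linspace(0, 25, 53)
        np.testing.assert_allclose(mf(xs), [mf(float(x)) for x in xs])


class TestFuzzify:
    def test_peak_membership_is_one_hot(self, catalog):
        np.testing.assert_allclose(catalog.casamino.fuzzify(12.5), [0, 1, 0])
        np.testing.assert_allclose(catalog.sodium_acetate.fuzzify(5), [1, 0, 0])

    def test_midpoint_between_peaks_splits_evenly(self, catalog):
        np.testing.assert_allclose(catalog.casamino.fuzzify(8.75), [0.5, 0.5, 0])

    def test_out_of_range_error_names_variable_and_bounds(self, catalog):
        with pytest.raises(OutOfRangeError, match=r"casamino.*\[5\.0, 20\.0\]|\[5\.0, 20\.0\].*casamino"):
            catalog.casamino.fuzzify(25)

    @given(st.floats(5, 20))
    def test_partition_of_unity_everywhere(self, x):
        var = rf.build_variables().casamino
        assert sum(var.fuzzify(x)) == pytest.approx(1.0, abs=1e-9)


class TestFiringStrength:
    def test_single_antecedent_at_peak_fires_fully(self, casamino_model):
        rule = casamino_model.rules[1]  # medium -> medium
        assert casamino_model.firing_strength(rule, {"casamino": 12.5}) == 1.0

    def test_two_antecedents_take_minimum(self, catalog):
        rules = [rf.Rule({"casamino": "low", "gtp": "high"}, "medium")]
        model = rf.build_joint_model(rules)
        # casamino 8.75 -> low degree 0.5; gtp 0.0325 -> high degree 0.5
        # casamino 6.5 -> low degree 0.8; gtp 0.0355 -> high degree 0.7
        s = model.firing_strength(rules[0], {"casamino": 6.5, "gtp": 0.0355})
        assert s == pytest.approx(0.7)

    def test_zero_membership_antecedent_kills_rule(self, casamino_model):
        rule = casamino_model.rules[2]  # high -> high, support (12.5, 20]
        assert casamino_model.firing_strength(rule, {"casamino": 5.0}) == 0.0

    def test_missing_input_named_in_error(self, casamino_model):
        with pytest.raises(MissingInputError, match="casamino"):
            casamino_model.firing_strength(casamino_model.rules[0], {})

    def test_weight_scales_strength(self, catalog):
        rule = rf.Rule({"casamino": "medium"}, "medium", weight=0.25)
        model = rf.build_single_factor_model("casamino", [rule])
        assert model.firing_strength(rule, {"casamino": 12.5}) == pytest.approx(0.25)


class TestInfer:
    def test_single_active_rule_reproduces_clipped_consequent(self, catalog):
        model = rf.build_single_factor_model(
            "casamino", [rf.Rule({"casamino": "medium"}, "medium")]
        )
        agg = model.infer({"casamino": 12.5})
        expected = catalog.riboflavin.term("medium").mf(agg.grid)
        np.testing.assert_allclose(agg.degrees, expected)

    def test_two_rules_aggregate_pointwise_max(self, catalog):
        rules = [
            rf.Rule({"casamino": "low"}, "low"),
            rf.Rule({"casamino": "medium"}, "high"),
        ]
        model = rf.build_single_factor_model("casamino", rules)
        x = 8.75  # both rules fire at 0.5
        agg = model.infer({"casamino": x})
        lo = np.minimum(0.5, catalog.riboflavin.term("low").mf(agg.grid))
        hi = np.minimum(0.5, catalog.riboflavin.term("high").mf(agg.grid))
        np.testing.assert_allclose(agg.degrees, np.maximum(lo, hi))

    def test_no_rule_fired_is_an_error_not_zero(self, catalog):
        model = rf.build_single_factor_model(
            "casamino", [rf.Rule({"casamino": "high"}, "high")]
        )
        with pytest.raises(NoRuleFiredError):
            model.infer({"casamino": 5.0})

    def test_out_of_universe_input_rejected(self, casamino_model):
        with pytest.raises(OutOfRangeError):
            casamino_model.infer({"casamino": 4.9})


class TestDefuzzify:
    def test_symmetric_clipped_triangle_centroid_is_peak(self, catalog):
        grid = np.linspace(340, 440, 1001)
        for height in (1.0, 0.4):
            degrees = np.minimum(height, catalog.riboflavin.term("medium").mf(grid))
            agg = rf.AggregatedOutput(grid=grid, degrees=degrees)
            assert rf.defuzzify_centroid(agg) == pytest.approx(390.0)

    def test_uniform_surface_centroid_is_midpoint(self):
        grid = np.linspace(340, 440, 1001)
        agg = rf.AggregatedOutput(grid=grid, degrees=np.ones_like(grid))
        assert rf.defuzzify_centroid(agg) == pytest.approx(390.0)

    def test_centroid_within_active_support(self, catalog):
        grid = np.linspace(340, 440, 1001)
        degrees = np.minimum(0.8, catalog.riboflavin.term("low").mf(grid))
        value = rf.defuzzify_centroid(rf.AggregatedOutput(grid=grid, degrees=degrees))
        active = grid[degrees > 0]
        assert active.min() <= value <= active.max()

    def test_all_zero_surface_rejected(self):
        grid = np.linspace(340, 440, 11)
        agg = rf.AggregatedOutput(grid=grid, degrees=np.zeros_like(grid))
        with pytest.raises(NoRuleFiredError):
            rf.defuzzify_centroid(agg)

    def test_matches_fine_grid_riemann_oracle(self, catalog, rng):
        """Asymmetric clipped surfaces defuzzify within 0.1% of a 10x oracle."""
        model = rf.build_single_factor_model(
            "casamino",
            [rf.Rule({"casamino": lab}, con) for lab, con in
             (("low", "low"), ("medium", "high"), ("high", "medium"))],
        )
        fine = np.linspace(340, 440, (model.grid_points - 1) * 10 + 1)
        for _ in range(100):
            x = float(rng.uniform(5, 20))
            value = model.predict({"casamino": x})
            surface = np.zeros_like(fine)
            for rule in model.rules:
                s = model.firing_strength(rule, {"casamino": x})
                mf = model.output.term(rule.consequent).mf
                surface = np.maximum(surface, np.minimum(s, mf(fine)))
            oracle = float(np.sum(fine * surface) / np.sum(surface))
            assert value == pytest.approx(oracle, rel=1e-3)


class TestPredict:
    def test_prediction_within_output_universe(self, catalog, rng):
        model = rf.build_single_factor_model(
            "casamino",
            [rf.Rule({"casamino": lab}, con) for lab, con in
             (("low", "low"), ("medium", "high"), ("high", "high"))],
        )
        for x in rng.uniform(5, 20, size=200):
            assert 340.0 <= model.predict({"casamino": float(x)}) <= 440.0

    def test_identical_consequents_give_constant_prediction(self, catalog, rng):
        model = rf.build_single_factor_model(
            "casamino",
            [rf.Rule({"casamino": lab}, "medium") for lab in ("low", "medium", "high")],
        )
        preds = {model.predict({"casamino": float(x)}) for x in rng.uniform(5, 20, 20)}
        assert all(p == pytest.approx(390.0) for p in preds)

    def test_deterministic(self, casamino_model):
        a = casamino_model.predict({"casamino": 7.3})
        b = casamino_model.predict({"casamino": 7.3})
        assert a == b  # bit-identical

    def test_order_preserving_model_is_monotone(self, casamino_model):
        grid = np.linspace(5, 20, 200)
        preds = [casamino_model.predict({"casamino": float(x)}) for x in grid]
        assert np.all(np.diff(preds) >= -1e-6)


class TestModelValidation:
    def test_conflicting_rules_rejected(self, catalog):
        rules = [
            rf.Rule({"casamino": "low"}, "low"),
            rf.Rule({"casamino": "low"}, "high"),
        ]
        with pytest.raises(FuzzyDefinitionError, match="onflict"):
            rf.build_single_factor_model("casamino", rules)

    def test_unknown_term_or_variable_rejected(self, catalog):
        with pytest.raises(FuzzyDefinitionError):
            rf.build_single_factor_model("casamino", [rf.Rule({"casamino": "huge"}, "low")])
        with pytest.raises(FuzzyDefinitionError):
            rf.build_joint_model([rf.Rule({"lactose": "low"}, "low")])

    def test_variable_invariants(self):
        terms = (
            rf.LinguisticTerm("low", rf.TriangularMF(0, 0, 5)),
            rf.LinguisticTerm("high", rf.TriangularMF(6, 10, 10)),
        )
        with pytest.raises(FuzzyDefinitionError, match="gap"):
            rf.FuzzyVariable("v", (0, 10), terms)
        with pytest.raises(FuzzyDefinitionError, match="increase"):
            rf.FuzzyVariable(
                "v", (0, 10),
                (
                    rf.LinguisticTerm("a", rf.TriangularMF(0, 5, 10)),
                    rf.LinguisticTerm("b", rf.TriangularMF(0, 5, 10)),
                ),
            )


class TestSerialization:
    def test_model_round_trip_is_lossless(self, casamino_model, tmp_path):
        for name in ("model.yaml", "model.json"):
            path = tmp_path / name
            rf.save_model(casamino_model, path)
            loaded = rf.load_model(path)
            assert rf.model_to_dict(loaded) == rf.model_to_dict(casamino_model)
            # and a second round trip is byte-stable
            rf.save_model(loaded, tmp_path / ("2" + name))
            assert (tmp_path / ("2" + name)).read_text() == path.read_text()

    def test_loaded_model_predicts_identically(self, casamino_model, tmp_path):
        path = tmp_path / "m.yaml"
        rf.save_model(casamino_model, path)
        loaded = rf.load_model(path)
        for x in (5.0, 9.21, 17.0):
            assert loaded.predict({"casamino": x}) == casamino_model.predict({"casamino": x})

    def test_wrong_kind_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("kind: something_else\n")
        with pytest.raises(FuzzyDefinitionError):
            rf.load_model(path)
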