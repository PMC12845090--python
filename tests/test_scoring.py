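"""Unit and property tests for the index scoring algorithms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wdindex import scoring
from wdindex.schema import (
    CoefficientTable,
    Component,
    ComponentSchema,
    ReferenceStats,
    SchemaError,
)
from wdindex.scoring import ZeroVarianceError

import oracles
from conftest import schema_as_dicts


class TestZscore:
    @pytest.mark.parametrize(
        "intake,mean,sd,expected",
        [(10, 8, 2, 1.0), (8, 8, 2, 0.0), (5, 8, 2, -1.5)],
    )
    def test_forced_arithmetic(self, intake, mean, sd, expected):
        assert scoring.zscore(intake, mean, sd) == pytest.approx(expected)

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroVarianceError):
            scoring.zscore(5, 5, 0.0)


class TestPopulationStats:
    def test_two_point_sample(self):
        schema = ComponentSchema([Component("x", "x", "g")])
        intakes = pd.DataFrame({"x": [4.0, 6.0]}, index=pd.Index(["a", "b"]))
        ref = scoring.compute_population_stats(intakes, schema)
        assert ref.source == "population"
        assert ref.mean["x"] == pytest.approx(5.0)
        assert ref.sd["x"] == pytest.approx(np.sqrt(2.0))

    def test_constant_column_zero_variance(self):
        schema = ComponentSchema([Component("x", "x", "g")])
        intakes = pd.DataFrame({"x": [3.0, 3.0, 3.0]})
        ref = scoring.compute_population_stats(intakes, schema)
        assert ref.mean["x"] == 3.0
        assert ref.sd["x"] == 0.0
        assert ref.zero_variance_ids(["x"]) == ["x"]

    def test_matches_two_pass_oracle(self, mixed_intakes, mixed_schema):
        ref = scoring.compute_population_stats(mixed_intakes, mixed_schema)
        # singles and mixed-group members: per-column statistics
        for col in ["sugar", "vit_c", "zinc", "red_meat"]:
            m, s = oracles.two_pass_mean_sd(list(mixed_intakes[col]))
            assert ref.mean[col] == pytest.approx(m, abs=1e-12)
            assert ref.sd[col] == pytest.approx(s, abs=1e-12)
        # same-unit group: statistics of the member sum
        sums = list(mixed_intakes["apple"] + mixed_intakes["orange"])
        m, s = oracles.two_pass_mean_sd(sums)
        assert ref.mean["fruit"] == pytest.approx(m, abs=1e-12)
        assert ref.sd["fruit"] == pytest.approx(s, abs=1e-12)

    def test_insufficient_observations_names_component(self):
        schema = ComponentSchema([Component("x", "x", "g")])
        intakes = pd.DataFrame({"x": [4.0, np.nan, np.nan]})
        with pytest.raises(ValueError, match="x"):
            scoring.compute_population_stats(intakes, schema)


class TestComponentZscore:
    def test_mixed_group_symmetric_mean(self):
        schema = ComponentSchema(
            [Component("g", "g", "z", "group_mixed_unit", ("a", "b"))]
        )
        intakes = pd.DataFrame({"a": [12.0], "b": [6.0]})
        ref = ReferenceStats(
            mean=pd.Series({"a": 10.0, "b": 8.0}),
            sd=pd.Series({"a": 2.0, "b": 2.0}),
            source="global",
        )
        # member z-scores are (+1, -1) -> mean 0
        z = scoring.component_zscore(intakes, "g", ref, schema)
        assert z.iloc[0] == pytest.approx(0.0)

    def test_same_unit_group_uses_sum_stats(self):
        schema = ComponentSchema(
            [Component("g", "g", "g/day", "group_same_unit", ("a", "b"))]
        )
        intakes = pd.DataFrame({"a": [2.0], "b": [3.0]})
        ref = ReferenceStats(
            mean=pd.Series({"g": 4.0}), sd=pd.Series({"g": 1.0}), source="global"
        )
        z = scoring.component_zscore(intakes, "g", ref, schema)
        assert z.iloc[0] == pytest.approx(1.0)

    def test_three_member_mixed_group_hand_enumeration(self):
        schema = ComponentSchema(
            [Component("g", "g", "z", "group_mixed_unit", ("a", "b", "c"))]
        )
        intakes = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0, 4.0], "b": [10.0, 20.0, 30.0, 40.0],
             "c": [5.0, 5.5, 6.0, 6.5]},
            index=pd.Index(list("wxyz")),
        )
        mean = pd.Series({"a": 2.0, "b": 25.0, "c": 6.0})
        sd = pd.Series({"a": 1.0, "b": 10.0, "c": 0.5})
        ref = ReferenceStats(mean=mean, sd=sd, source="global")
        z = scoring.component_zscore(intakes, "g", ref, schema)
        for i, sid in enumerate(intakes.index):
            hand = np.mean(
                [(intakes[m].iloc[i] - mean[m]) / sd[m] for m in ("a", "b", "c")]
            )
            assert z.loc[sid] == pytest.approx(hand, abs=1e-12)

    def test_missing_member_stats_listed(self):
        schema = ComponentSchema(
            [Component("g", "g", "z", "group_mixed_unit", ("a", "b"))]
        )
        intakes = pd.DataFrame({"a": [1.0], "b": [2.0]})
        ref = ReferenceStats(
            mean=pd.Series({"a": 0.0}), sd=pd.Series({"a": 1.0}), source="global"
        )
        with pytest.raises(KeyError, match="b"):
            scoring.component_zscore(intakes, "g", ref, schema)


class TestCentralize:
    def test_hand_ranked_three_elements(self):
        table = CoefficientTable(pd.Series({"a": 0.2, "b": 0.5, "c": 0.9}))
        cen = scoring.centralize_coefficients(table).centralized
        assert cen["a"] == pytest.approx(-1 / 3)
        assert cen["b"] == pytest.approx(1 / 3)
        assert cen["c"] == pytest.approx(1.0)

    def test_tie_rule_by_hand(self):
        table = CoefficientTable(pd.Series({"a": 0.4, "b": 0.4}))
        cen = scoring.centralize_coefficients(table).centralized
        # mean rank 1.5 each, fractional 0.75, centralized 0.5
        assert cen["a"] == pytest.approx(0.5)
        assert cen["b"] == pytest.approx(0.5)

    def test_single_coefficient_boundary(self):
        table = CoefficientTable(pd.Series({"a": -2.3}))
        cen = scoring.centralize_coefficients(table).centralized
        assert cen["a"] == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=-10, max_value=10, allow_nan=False), min_size=1, max_size=30
        )
    )
    def test_bounded_and_monotone(self, coefs):
        table = CoefficientTable(pd.Series(coefs, index=[f"c{i}" for i in range(len(coefs))]))
        cen = scoring.centralize_coefficients(table).centralized
        assert ((cen > -1) & (cen <= 1)).all()
        expected = oracles.centralized(coefs)
        np.testing.assert_allclose(cen.to_numpy(), expected, atol=1e-12)
        # rank order preserved
        raw = table.coefficient.to_numpy()
        for i in range(len(coefs)):
            for j in range(len(coefs)):
                if raw[i] < raw[j]:
                    assert cen.iloc[i] < cen.iloc[j]


class TestZrefVariants:
    def test_single_component_at_reference_mean(self):
        schema = ComponentSchema([Component("x", "x", "g")])
        intakes = pd.DataFrame({"x": [8.0]})
        table = CoefficientTable(pd.Series({"x": 1.0}))
        ref = ReferenceStats(pd.Series({"x": 8.0}), pd.Series({"x": 2.0}), "global")
        res = scoring.score_zref_variant(intakes, schema, table, ref)
        assert res.values.iloc[0] == pytest.approx(0.0)
        assert res.variant == "wdi_g"
        assert res.divisor == 1

    def test_two_component_cancellation(self):
        schema = ComponentSchema([Component("a", "a", "g"), Component("b", "b", "g")])
        intakes = pd.DataFrame({"a": [12.0], "b": [4.0]})
        table = CoefficientTable(pd.Series({"a": 0.5, "b": 0.5}))
        ref = ReferenceStats(
            pd.Series({"a": 10.0, "b": 6.0}), pd.Series({"a": 2.0, "b": 2.0}), "global"
        )
        # z-scores {+1, -1}, coefficients {0.5, 0.5} -> (0.5 - 0.5)/2 = 0
        res = scoring.score_zref_variant(intakes, schema, table, ref)
        assert res.values.iloc[0] == pytest.approx(0.0)

    @pytest.mark.parametrize("coeff_kind", ["raw", "centralized"])
    def test_matches_loop_oracle(
        self, mixed_intakes, mixed_schema, mixed_coefficients, mixed_global_ref, coeff_kind
    ):
        res = scoring.score_zref_variant(
            mixed_intakes, mixed_schema, mixed_coefficients, mixed_global_ref, coeff_kind
        )
        coef_src = (
            mixed_coefficients.coefficient
            if coeff_kind == "raw"
            else mixed_coefficients.centralized
        )
        rows = mixed_intakes.to_dict("records")
        expected = oracles.zref_scores(
            rows,
            schema_as_dicts(mixed_schema),
            coef_src.to_dict(),
            mixed_global_ref.mean.to_dict(),
            mixed_global_ref.sd.to_dict(),
        )
        np.testing.assert_allclose(res.values.to_numpy(), expected, atol=1e-10)
        assert res.divisor == 4

    def test_missing_intake_gives_missing_score(self, mixed_schema, mixed_coefficients,
                                                mixed_intakes, mixed_global_ref):
        intakes = mixed_intakes.copy()
        intakes.loc["s2", "apple"] = np.nan
        res = scoring.score_zref_variant(
            intakes, mixed_schema, mixed_coefficients, mixed_global_ref
        )
        assert np.isnan(res.values.loc["s2"])
        assert res.values.drop("s2").notna().all()

    def test_mean_imputation_switch_warns(self, mixed_schema, mixed_coefficients,
                                          mixed_intakes, mixed_global_ref):
        intakes = mixed_intakes.copy()
        intakes.loc["s2", "apple"] = np.nan
        with pytest.warns(UserWarning, match="imputing"):
            res = scoring.score_zref_variant(
                intakes, mixed_schema, mixed_coefficients, mixed_global_ref, impute="mean"
            )
        assert res.values.notna().all()

    def test_zero_variance_component_skipped_divisor_reduced(
        self, mixed_intakes, mixed_schema, mixed_coefficients
    ):
        mean = pd.Series({"sugar": 25.0, "fruit": 100.0, "vit_c": 80.0,
                          "zinc": 10.0, "red_meat": 70.0})
        sd = pd.Series({"sugar": 0.0, "fruit": 40.0, "vit_c": 25.0,
                        "zinc": 3.0, "red_meat": 50.0})
        ref = ReferenceStats(mean, sd, "global")
        with pytest.warns(UserWarning, match="zero"):
            res = scoring.score_zref_variant(
                mixed_intakes, mixed_schema, mixed_coefficients, ref
            )
        assert res.divisor == 3
        assert res.skipped == ["sugar"]

    def test_empty_component_set_errors(self, mixed_schema, mixed_coefficients,
                                        mixed_global_ref):
        intakes = pd.DataFrame(index=pd.Index(["s1"]))
        with pytest.raises((ValueError, SchemaError)):
            scoring.score_zref_variant(
                intakes, mixed_schema, mixed_coefficients, mixed_global_ref,
                component_ids=[],
            )


class TestStandardize:
    def test_two_point(self):
        out = scoring.standardize_scores(pd.Series([-1.0, 1.0]))
        np.testing.assert_allclose(out, [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_mean_zero_sd_one_by_construction(self):
        rng = np.random.default_rng(3)
        out = scoring.standardize_scores(pd.Series(rng.normal(5, 3, 100)))
        assert abs(out.mean()) < 1e-10
        assert abs(out.std(ddof=1) - 1.0) < 1e-10

    def test_affine_invariance(self):
        rng = np.random.default_rng(4)
        x = pd.Series(rng.normal(size=50))
        a, b = 3.7, -2.2
        np.testing.assert_allclose(
            scoring.standardize_scores(x), scoring.standardize_scores(a * x + b), atol=1e-10
        )

    def test_zero_sd_errors(self):
        with pytest.raises(ZeroVarianceError):
            scoring.standardize_scores(pd.Series([2.0, 2.0, 2.0]))


class TestWdiI:
    def test_degenerate_cohort_scores_zero(self, mixed_schema):
        items = ["sugar", "apple", "orange", "vit_c", "zinc", "red_meat"]
        intakes = pd.DataFrame({c: [5.0, 5.0, 5.0] for c in items})
        table = CoefficientTable(pd.Series({c: 0.5 for c in items}))
        with pytest.warns(UserWarning, match="zero-variance"):
            res = scoring.score_wdi_i(intakes, mixed_schema, table)
        assert (res.values == 0.0).all()
        assert res.divisor == 0

    def test_negative_coefficient_flips_sign_only(self):
        """z(c*x) = sign(c) * z(x): rescaling is magnitude-free."""
        schema = ComponentSchema([Component("x", "x", "g")])
        intakes = pd.DataFrame({"x": [1.0, 4.0, 10.0]})
        raw = scoring.score_wdi_i(
            intakes, schema, CoefficientTable(pd.Series({"x": 1.0}))
        )
        flipped = scoring.score_wdi_i(
            intakes, schema, CoefficientTable(pd.Series({"x": -2.0}))
        )
        np.testing.assert_allclose(flipped.values, -raw.values, atol=1e-12)
        scaled = scoring.score_wdi_i(
            intakes, schema, CoefficientTable(pd.Series({"x": 7.5}))
        )
        np.testing.assert_allclose(scaled.values, raw.values, atol=1e-12)

    def test_matches_weight_then_z_oracle(self, mixed_intakes, mixed_schema,
                                          mixed_coefficients):
        items = ["sugar", "apple", "orange", "vit_c", "zinc", "red_meat"]
        # items inherit their parent component's coefficient in this fixture
        item_coef = {"sugar": -0.8, "apple": 0.9, "orange": 0.9, "vit_c": 0.5,
                     "zinc": 0.5, "red_meat": -0.6}
        table = CoefficientTable(pd.Series(item_coef))
        res = scoring.score_wdi_i(mixed_intakes, mixed_schema, table, item_ids=items)
        expected = oracles.weight_then_z_scores(
            mixed_intakes.to_dict("records"), items, item_coef
        )
        np.testing.assert_allclose(res.values.to_numpy(), expected, atol=1e-10)
        assert res.divisor == len(items)


class TestWdiFG:
    def _schema(self):
        return ComponentSchema(
            [
                Component("fruit", "fruit", "g", "group_same_unit",
                          ("apple", "orange"), "fruits"),
                Component("red_meat", "red meat", "g", food_group_18="red meat"),
                Component("soda", "soda", "g", food_group_18="soft drinks"),
            ]
        )

    def test_single_group_at_mean_is_zero(self):
        schema = ComponentSchema(
            [Component("fruit", "fruit", "g", food_group_18="fruits")]
        )
        intakes = pd.DataFrame({"fruit": [10.0, 20.0, 30.0]})
        table = CoefficientTable(pd.Series({"fruits": 0.9}))
        res = scoring.score_wdi_fg(intakes, schema, table)
        assert res.values.iloc[1] == pytest.approx(0.0)  # subject at the mean

    def test_two_groups_score_is_mean_of_group_zscores(self):
        schema = ComponentSchema(
            [Component("a", "a", "g", food_group_18="ga"),
             Component("b", "b", "g", food_group_18="gb")]
        )
        intakes = pd.DataFrame(
            {"a": [10.0, 0.0, 5.0, 7.0], "b": [3.0, 9.0, 1.0, 4.0]}
        )
        table = CoefficientTable(pd.Series({"ga": 1.0, "gb": 0.5}))
        res = scoring.score_wdi_fg(intakes, schema, table)
        za = (intakes["a"] - intakes["a"].mean()) / intakes["a"].std(ddof=1)
        # positive weights cancel in the z-score, so z(w*x) = z(x)
        zb = (intakes["b"] - intakes["b"].mean()) / intakes["b"].std(ddof=1)
        np.testing.assert_allclose(res.values, (za + zb) / 2.0, atol=1e-10)

    def test_matches_group_sum_oracle(self):
        schema = self._schema()
        rng = np.random.default_rng(11)
        idx = pd.Index([f"s{i}" for i in range(4)])
        intakes = pd.DataFrame(
            rng.uniform(5, 150, size=(4, 4)),
            columns=["apple", "orange", "red_meat", "soda"],
            index=idx,
        )
        coef = {"fruits": 0.9, "red meat": -0.6, "soft drinks": -0.8}
        table = CoefficientTable(pd.Series(coef))
        res = scoring.score_wdi_fg(intakes, schema, table)
        rows = []
        for _, r in intakes.iterrows():
            rows.append({"fruits": r["apple"] + r["orange"],
                         "red meat": r["red_meat"], "soft drinks": r["soda"]})
        expected = oracles.weight_then_z_scores(rows, list(coef), coef)
        np.testing.assert_allclose(res.values.to_numpy(), expected, atol=1e-10)
        assert res.divisor == 3

    def test_unassigned_partition_is_not_scored(self, mixed_schema, mixed_intakes,
                                                mixed_coefficients):
        # only red_meat carries a food-group assignment in the mixed schema
        table = CoefficientTable(pd.Series({"red meat": -0.6}))
        res = scoring.score_wdi_fg(mixed_intakes, mixed_schema, table)
        assert res.divisor == 1

    def test_duplicate_group_membership_rejected(self):
        with pytest.raises(SchemaError):
            ComponentSchema(
                [
                    Component("a", "a", "g", "group_same_unit", ("x", "y"), "g1"),
                    Component("b", "b", "g", "group_same_unit", ("x", "z"), "g2"),
                ]
            )


class TestInvariants:
    def test_unit_invariance(self, mixed_intakes, mixed_schema, mixed_coefficients,
                             mixed_global_ref):
        """Rescaling a column and its reference stats leaves z-referenced
        scores unchanged."""
        base = scoring.score_zref_variant(
            mixed_intakes, mixed_schema, mixed_coefficients, mixed_global_ref
        )
        k = 28.3495  # grams -> ounces
        intakes2 = mixed_intakes.copy()
        intakes2["sugar"] = intakes2["sugar"] * k
        mean2 = mixed_global_ref.mean.copy()
        sd2 = mixed_global_ref.sd.copy()
        mean2["sugar"] *= k
        sd2["sugar"] *= k
        ref2 = ReferenceStats(mean2, sd2, "global")
        res2 = scoring.score_zref_variant(intakes2, mixed_schema, mixed_coefficients, ref2)
        np.testing.assert_allclose(base.values, res2.values, atol=1e-10)

    def test_global_equals_population_when_stats_match(self, mixed_intakes,
                                                       mixed_schema, mixed_coefficients):
        pop = scoring.compute_population_stats(mixed_intakes, mixed_schema)
        glob = ReferenceStats(pop.mean, pop.sd, "global")
        for kind in ("raw", "centralized"):
            g = scoring.score_zref_variant(
                mixed_intakes, mixed_schema, mixed_coefficients, glob, kind
            )
            p = scoring.score_zref_variant(
                mixed_intakes, mixed_schema, mixed_coefficients, pop, kind
            )
            np.testing.assert_allclose(g.values, p.values, atol=1e-12)


class TestRangeAndEffects:
    @pytest.mark.parametrize(
        "lo,hi,span", [(-2.03, 1.11, 3.14), (-0.36, 0.42, 0.78)]
    )
    def test_reported_score_spans(self, lo, hi, span):
        scores = pd.Series([lo, 0.0, hi])
        rs = scoring.summarize_range(scores, "v")
        assert rs.span == pytest.approx(span)
        assert rs.min == lo and rs.max == hi

    def test_constant_scores_zero_span(self):
        rs = scoring.summarize_range(pd.Series([1.5, 1.5]), "v")
        assert rs.span == 0.0

    def test_all_missing_errors(self):
        with pytest.raises(ValueError):
            scoring.summarize_range(pd.Series([np.nan, np.nan]), "v")

    @pytest.mark.parametrize(
        "beta,span,expected",
        [(-12.59, 3.14, 3.95), (-17.88, 0.78, 1.39), (0.0, 2.0, 0.0)],
    )
    def test_effect_per_tenth_of_range(self, beta, span, expected):
        assert scoring.effect_per_range_fraction(beta, span, 0.1) == pytest.approx(expected)

    def test_nonpositive_span_errors(self):
        with pytest.raises(ValueError):
            scoring.effect_per_range_fraction(1.0, 0.0, 0.1)
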