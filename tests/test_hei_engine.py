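"""Population-ratio density computation and HEI-2015 component scoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from outlethei.hei_engine import (
    ComponentTotals,
    ScoringError,
    ScoringStandard,
    aggregate,
    calorie_shares,
    densities,
    densities_for_scores,
    grade,
    score_component,
    score_group,
)
from outlethei.recall_io import CANONICAL_COMPONENTS


def _item(rid, energy, **components):
    row = {c: 0.0 for c in CANONICAL_COMPONENTS}
    row.update(components)
    row.update(respondent_id=rid, source_code="1", energy_kcal=energy)
    return row


def _weights(mapping):
    return pd.Series(mapping, dtype=float)


ADEQ5 = ScoringStandard(
    component="x", max_points=5, direction="adequacy", unit="per_1000kcal",
    source="total_fruits", max_score_at=0.8, zero_score_at=0.0,
)
MOD10 = ScoringStandard(
    component="y", max_points=10, direction="moderation", unit="percent_energy",
    source="added_sugars_tsp", kcal_per_unit=16.0, max_score_at=6.5, zero_score_at=26.0,
)


class TestAggregate:
    def test_weighted_sum(self):
        items = pd.DataFrame([_item("a", 500.0), _item("b", 1500.0)])
        totals = aggregate(items, _weights({"a": 1.0, "b": 1.0}))
        assert totals.energy_kcal == 2000.0

    def test_linearity_in_weights(self):
        items = pd.DataFrame([_item("a", 500.0, total_fruits=1.0), _item("b", 1500.0)])
        t1 = aggregate(items, _weights({"a": 2.0, "b": 3.0}))
        t2 = aggregate(items, _weights({"a": 4.0, "b": 6.0}))
        assert t2.energy_kcal == 2 * t1.energy_kcal
        assert t2.sums["total_fruits"] == 2 * t1.sums["total_fruits"]

    def test_item_split_invariance(self):
        whole = pd.DataFrame([_item("a", 600.0, dairy=0.9, sodium_mg=300.0)])
        split = pd.DataFrame(
            [_item("a", 300.0, dairy=0.45, sodium_mg=150.0)] * 2
        )
        w = _weights({"a": 1.7})
        ta, tb = aggregate(whole, w), aggregate(split, w)
        assert ta.energy_kcal == pytest.approx(tb.energy_kcal, rel=1e-12)
        for c in CANONICAL_COMPONENTS:
            assert ta.sums[c] == pytest.approx(tb.sums[c], abs=1e-12)

    def test_missing_weight_is_an_error(self):
        items = pd.DataFrame([_item("ghost", 100.0)])
        with pytest.raises(ScoringError, match="ghost"):
            aggregate(items, _weights({"a": 1.0}))


class TestDensities:
    def test_hand_arithmetic(self, standards):
        sums = {c: 0.0 for c in CANONICAL_COMPONENTS}
        sums.update(
            total_fruits=1.6, mufa_g=20.0, pufa_g=10.0, sfa_g=12.0,
            added_sugars_tsp=25.0, sodium_mg=2200.0,
        )
        dens = densities(ComponentTotals("g", sums, 2000.0), standards)
        assert dens["total_fruits"] == pytest.approx(0.8)
        assert dens["fatty_acids"] == pytest.approx(2.5)
        assert dens["added_sugars"] == pytest.approx(20.0)  # 25 * 16 / 2000 * 100
        assert dens["sodium"] == pytest.approx(1.1)  # mg -> g per 1000 kcal
        assert dens["saturated_fats"] == pytest.approx(12 * 9 / 2000 * 100)

    def test_zero_energy_names_group(self, standards):
        sums = {c: 0.0 for c in CANONICAL_COMPONENTS}
        with pytest.raises(ScoringError, match="empty_group"):
            densities(ComponentTotals("empty_group", sums, 0.0), standards)

    @pytest.mark.parametrize(
        "mufa, pufa, sfa, expected",
        [(5.0, 5.0, 0.0, math.inf), (0.0, 0.0, 0.0, 0.0)],
    )
    def test_degenerate_fatty_acid_denominator(self, standards, mufa, pufa, sfa, expected):
        sums = {c: 0.0 for c in CANONICAL_COMPONENTS}
        sums.update(mufa_g=mufa, pufa_g=pufa, sfa_g=sfa)
        dens = densities(ComponentTotals("g", sums, 1000.0), standards)
        assert dens["fatty_acids"] == expected


class TestScoreComponent:
    @pytest.mark.parametrize(
        "density, expected",
        [(0.0, 0.0), (0.8, 5.0), (2.0, 5.0), (0.4, 2.5)],
    )
    def test_adequacy(self, density, expected):
        assert score_component(density, ADEQ5) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "density, expected",
        [(6.5, 10.0), (0.0, 10.0), (26.0, 0.0), (40.0, 0.0), (16.25, 5.0)],
    )
    def test_moderation(self, density, expected):
        assert score_component(density, MOD10) == pytest.approx(expected)

    def test_infinite_ratio_earns_full_points(self, standards):
        (ratio,) = [s for s in standards if s.direction == "ratio"]
        assert score_component(math.inf, ratio) == ratio.max_points

    def test_equal_cutpoints_rejected(self):
        with pytest.raises(ScoringError, match="cut-points"):
            ScoringStandard(
                component="bad", max_points=5, direction="adequacy",
                unit="per_1000kcal", source="dairy", max_score_at=1.0, zero_score_at=1.0,
            )

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=0, max_value=50), st.floats(min_value=0, max_value=50))
    def test_monotone_and_clamped(self, d1, d2):
        for std, sign in ((ADEQ5, 1), (MOD10, -1)):
            s1, s2 = score_component(d1, std), score_component(d2, std)
            assert 0 <= s1 <= std.max_points
            if d1 < d2:
                assert sign * (s2 - s1) >= 0


class TestScoreGroup:
    def test_densities_at_cutpoints_score_100(self, standards):
        dens = densities_for_scores(
            {s.component: s.max_points for s in standards}, standards
        )
        items = pd.DataFrame([_synthesize_item("a", 1000.0, dens, standards)])
        result = score_group(items, _weights({"a": 3.0}), standards, "perfect")
        assert result.total == pytest.approx(100.0, abs=1e-9)

    def test_worst_mix_scores_0(self, standards):
        dens = densities_for_scores({s.component: 0.0 for s in standards}, standards)
        items = pd.DataFrame([_synthesize_item("a", 1000.0, dens, standards)])
        result = score_group(items, _weights({"a": 1.0}), standards, "worst")
        assert result.total == pytest.approx(0.0, abs=1e-9)

    def test_equal_weights_match_pooled_totals(self, standards, small_population):
        _, respondents, items = small_population
        w_equal = pd.Series(2.5, index=respondents["respondent_id"])
        via_weights = score_group(items, w_equal, standards)
        pooled = {c: items[c].sum() for c in CANONICAL_COMPONENTS}
        dens = densities(
            ComponentTotals("", pooled, items["energy_kcal"].sum()), standards
        )
        pooled_total = sum(score_component(dens[s.component], s) for s in standards)
        assert via_weights.total == pytest.approx(pooled_total, rel=1e-12)

    def test_weight_scale_invariance(self, standards, small_population):
        _, respondents, items = small_population
        a = score_group(items, respondents, standards)
        scaled = respondents.assign(day1_weight=respondents["day1_weight"] * 17.0)
        b = score_group(items, scaled, standards)
        assert a.total == pytest.approx(b.total, rel=1e-12)

    def test_unit_scale_invariance(self, standards, small_population):
        """Scaling every amount and energy by the same constant is a no-op."""
        _, respondents, items = small_population
        cols = ["energy_kcal", *CANONICAL_COMPONENTS]
        scaled = items.copy()
        scaled[cols] = scaled[cols] * 3.25
        a = score_group(items, respondents, standards)
        b = score_group(scaled, respondents, standards)
        for c in a.component_scores:
            assert a.component_scores[c] == pytest.approx(b.component_scores[c], rel=1e-12)

    def test_population_ratio_differs_from_mean_of_person_ratios(self, standards):
        """Two persons with unequal energies: scoring the pooled ratio is not
        the average of per-person scores; with equal energies it is."""
        dens_hi = densities_for_scores(
            {s.component: 0.9 * s.max_points for s in standards}, standards
        )
        # equal fat-component targets so the sfa-weighted pooled fatty-acid
        # ratio coincides with the per-person one in the equal-energy case
        lo_targets = {s.component: 0.1 * s.max_points for s in standards}
        for fat in ("fatty_acids", "saturated_fats"):
            lo_targets[fat] = 0.9 * next(
                s.max_points for s in standards if s.component == fat
            )
        dens_lo = densities_for_scores(lo_targets, standards)
        w = _weights({"a": 1.0, "b": 1.0})

        def pair_score(e_a, e_b):
            items = pd.DataFrame(
                [
                    _synthesize_item("a", e_a, dens_hi, standards),
                    _synthesize_item("b", e_b, dens_lo, standards),
                ]
            )
            return score_group(items, w, standards).total

        def person_mean(e_a, e_b):
            s_a = score_group(
                pd.DataFrame([_synthesize_item("a", e_a, dens_hi, standards)]), w, standards
            ).total
            s_b = score_group(
                pd.DataFrame([_synthesize_item("b", e_b, dens_lo, standards)]), w, standards
            ).total
            return (s_a + s_b) / 2

        assert pair_score(3000.0, 500.0) != pytest.approx(person_mean(3000.0, 500.0), abs=0.5)
        assert pair_score(1000.0, 1000.0) == pytest.approx(person_mean(1000.0, 1000.0), abs=1e-9)


class TestGrade:
    @pytest.mark.parametrize(
        "score, max_possible, letter",
        [
            (65.0, 100.0, "D"),
            (10.0, 10.0, "A"),
            (59.99, 100.0, "F"),
            (90.0, 100.0, "A"),
            (89.99, 100.0, "B"),
            (7.0, 10.0, "C"),
            (0.0, 100.0, "F"),
        ],
    )
    def test_bands(self, score, max_possible, letter):
        assert grade(score, max_possible) == letter

    def test_out_of_range(self):
        with pytest.raises(ScoringError):
            grade(101.0, 100.0)


class TestCalorieShares:
    def _population(self):
        respondents = pd.DataFrame(
            {
                "respondent_id": ["a", "b"],
                "age_years": [30.0, 30.0],
                "day1_weight": [1.0, 1.0],
            }
        )
        items = pd.DataFrame(
            [
                _item("a", 600.0),
                {**_item("b", 400.0), "source_code": "3"},
            ]
        )
        return respondents, items

    def test_hand_arithmetic(self):
        respondents, items = self._population()
        shares = calorie_shares(items, respondents, [(2.0, float("inf"))])
        assert shares.loc["2+", "store"] == pytest.approx(60.0)
        assert shares.loc["2+", "quick_service"] == pytest.approx(40.0)
        assert shares.loc["2+"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_single_outlet_is_100(self):
        respondents, items = self._population()
        items = items.iloc[:1]
        shares = calorie_shares(items, respondents, [(2.0, float("inf"))])
        assert shares.loc["2+", "store"] == pytest.approx(100.0)

    def test_weight_scale_invariance(self):
        respondents, items = self._population()
        a = calorie_shares(items, respondents, [(2.0, float("inf"))])
        respondents2 = respondents.assign(day1_weight=respondents["day1_weight"] * 9.0)
        b = calorie_shares(items, respondents2, [(2.0, float("inf"))])
        pd.testing.assert_frame_equal(a, b)

    def test_empty_bin_is_zero_row(self):
        respondents, items = self._population()
        shares = calorie_shares(items, respondents, [(2.0, 20.0), (20.0, float("inf"))])
        assert shares.loc["2-20"].sum() == 0.0
        assert shares.loc["20+"].sum() == pytest.approx(100.0)


def _synthesize_item(rid, energy, dens, standards):
    """Build one item whose densities equal *dens* exactly."""
    row = _item(rid, energy)
    for s in standards:
        d = dens[s.component]
        if s.unit == "per_1000kcal":
            row[s.source] = energy / 1000.0 * d / s.scale
        elif s.unit == "percent_energy":
            row[s.source] = energy * (d / 100.0) / s.kcal_per_unit
    (ratio,) = [s for s in standards if s.unit == "fat_ratio"]
    row["mufa_g"] = row["pufa_g"] = row["sfa_g"] * dens[ratio.component] / 2.0
    return row
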