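"""MAR/MER, energy standardization, added sugars, contribution reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietopt import (
    NutrientReference,
    ReferenceSet,
    category_contributions,
    density_report,
    diet_totals,
    estimate_added_sugars,
    mean_adequacy_ratio,
    mean_excess_ratio,
    standardize_to_energy,
)

from conftest import make_diet, make_food, make_foodlist


def _qual_ref(nid, lower, unit="mg"):
    return NutrientReference(nutrient_id=nid, lower=lower, upper=None, unit=unit, qualifying=True)


def _disq_ref(nid, upper, basis="absolute", factor=0.0, unit="mg"):
    return NutrientReference(
        nutrient_id=nid, lower=None, upper=upper, basis=basis,
        energy_factor=factor, unit=unit, disqualifying=True,
    )


def refset(*refs_):
    return ReferenceSet({r.nutrient_id: r for r in refs_}, 2000.0, 2000.0)


@pytest.fixture
def two_foods():
    return make_foodlist(
        make_food("a", energy=200, iron=2.0, zinc=1.0, vitamin_d=1.0),
        make_food("b", energy=100, iron=0.5, zinc=2.0, vitamin_d=0.0),
    )


class TestStandardizeToEnergy:
    def test_scales_to_target_exactly(self, two_foods):
        diet = make_diet([500, 500], two_foods)  # 1500 kcal
        out = standardize_to_energy(diet, two_foods, 2000.0)
        assert diet_totals(out, two_foods).energy == pytest.approx(2000.0, abs=1e-9)

    def test_identity_at_target(self, two_foods):
        diet = make_diet([1000, 0], two_foods)  # 2000 kcal
        out = standardize_to_energy(diet, two_foods, 2000.0)
        np.testing.assert_allclose(out.amounts, diet.amounts)

    def test_scale_then_total_equals_total_then_scale(self, two_foods):
        diet = make_diet([300, 700], two_foods)
        k = 2000.0 / diet_totals(diet, two_foods).energy
        t_std = diet_totals(standardize_to_energy(diet, two_foods, 2000.0), two_foods)
        t_raw = diet_totals(diet, two_foods)
        assert t_std["iron"] == pytest.approx(k * t_raw["iron"])

    def test_zero_energy_diet_rejected(self, two_foods):
        with pytest.raises(ValueError, match="zero-energy"):
            standardize_to_energy(make_diet([0, 0], two_foods), two_foods, 2000.0)


class TestMeanAdequacyRatio:
    def test_truncation_ceiling(self, two_foods):
        refs = refset(_qual_ref("iron", 1.0), _qual_ref("zinc", 1.0))
        diet = make_diet([1000, 1000], two_foods)  # far above both bounds
        assert mean_adequacy_ratio(diet, two_foods, refs) == 100.0

    def test_partial_adequacy_mean(self, two_foods):
        # iron at 50 % of reference, zinc >= 100 %: MAR = (100 + 50) / 2
        t = diet_totals(make_diet([100, 100], two_foods), two_foods)
        refs = refset(_qual_ref("iron", t["iron"] * 2), _qual_ref("zinc", t["zinc"]))
        diet = make_diet([100, 100], two_foods)
        assert mean_adequacy_ratio(diet, two_foods, refs) == pytest.approx(75.0)

    def test_26_nutrient_arithmetic(self):
        """25 nutrients at >=100 % and one at 50 % average to 98.08 %."""
        assert (25 * 100 + 50) / 26 == pytest.approx(98.0769, abs=1e-3)

    def test_all_zero_diet_scores_zero(self, two_foods):
        refs = refset(_qual_ref("iron", 1.0))
        assert mean_adequacy_ratio(make_diet([0, 0], two_foods), two_foods, refs) == 0.0

    def test_missing_lower_bound_errors(self, two_foods):
        bad = ReferenceSet(
            {"iron": NutrientReference("iron", None, 45.0, unit="mg", qualifying=True)},
            2000.0, 2000.0,
        )
        with pytest.raises(ValueError, match="lower"):
            mean_adequacy_ratio(make_diet([100, 100], two_foods), two_foods, bad)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        base=st.lists(st.floats(10, 400), min_size=2, max_size=2),
        bump=st.lists(st.floats(0, 200), min_size=2, max_size=2),
    )
    def test_monotone_under_pointwise_increase(self, base, bump):
        foods = make_foodlist(
            make_food("a", energy=200, iron=2.0, zinc=1.0),
            make_food("b", energy=100, iron=0.5, zinc=2.0),
        )
        refs = refset(_qual_ref("iron", 10.0), _qual_ref("zinc", 8.0))
        lo = mean_adequacy_ratio(make_diet(base, foods), foods, refs)
        hi = mean_adequacy_ratio(make_diet(np.add(base, bump), foods), foods, refs)
        assert hi >= lo - 1e-9


class TestMeanExcessRatio:
    def test_all_at_mrv_is_100(self):
        foods = make_foodlist(make_food("a", energy=100, sodium=200, cholesterol=30))
        t = diet_totals(make_diet([100], foods), foods)
        refs = refset(_disq_ref("sodium", t["sodium"]), _disq_ref("cholesterol", t["cholesterol"]))
        assert mean_excess_ratio(make_diet([100], foods), foods, refs) == pytest.approx(100.0)

    def test_untruncated_mean_of_ratios(self):
        """Component ratios 120 and 80 average to 100 without flooring."""
        foods = make_foodlist(make_food("a", energy=100, sodium=120, cholesterol=80))
        refs = refset(_disq_ref("sodium", 100.0), _disq_ref("cholesterol", 100.0))
        assert mean_excess_ratio(make_diet([100], foods), foods, refs) == pytest.approx(100.0)

    def test_can_exceed_100(self):
        foods = make_foodlist(make_food("a", energy=100, sodium=300))
        refs = refset(_disq_ref("sodium", 100.0))
        assert mean_excess_ratio(make_diet([100], foods), foods, refs) == pytest.approx(300.0)

    def test_zero_diet_scores_zero(self):
        foods = make_foodlist(make_food("a", sodium=100))
        refs = refset(_disq_ref("sodium", 100.0))
        assert mean_excess_ratio(make_diet([0], foods), foods, refs) == 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(amounts=st.lists(st.floats(1, 400), min_size=1, max_size=1), k=st.floats(0.1, 5))
    def test_homogeneous_degree_one_before_standardization(self, amounts, k):
        foods = make_foodlist(make_food("a", energy=100, sodium=150))
        refs = refset(_disq_ref("sodium", 100.0))
        m1 = mean_excess_ratio(make_diet(amounts, foods), foods, refs)
        mk = mean_excess_ratio(make_diet(np.multiply(amounts, k), foods), foods, refs)
        assert mk == pytest.approx(k * m1, rel=1e-9)


class TestEstimateAddedSugars:
    @pytest.fixture
    def sugar_foods(self):
        return make_foodlist(
            make_food("cola", "drinks", mono_di_saccharides=10.0),
            make_food("yoghurt", "dairy", mono_di_saccharides=12.0, lactose=10.0),
            make_food("cake", "cakes", mono_di_saccharides=5.0),
            make_food("apple", "fruits", mono_di_saccharides=11.0),
        )

    def test_category_sum_without_dairy(self, sugar_foods):
        # 300 g cola at 10 g/100 g = 30 g; fruit sugars are intrinsic
        diet = make_diet([300, 0, 0, 500], sugar_foods)
        assert estimate_added_sugars(diet, sugar_foods) == pytest.approx(30.0)

    def test_dairy_equal_to_lactose_contributes_zero(self):
        foods = make_foodlist(make_food("milk", "dairy", mono_di_saccharides=4.7, lactose=4.7))
        assert estimate_added_sugars(make_diet([500], foods), foods) == 0.0

    def test_dairy_excess_plus_cake(self, sugar_foods):
        # 100 g yoghurt: 12 - 10 = 2 g; 100 g cake: 5 g -> 7 g total
        diet = make_diet([0, 100, 100, 0], sugar_foods)
        assert estimate_added_sugars(diet, sugar_foods) == pytest.approx(7.0)


class TestCategoryContributions:
    @pytest.fixture
    def foods(self):
        return make_foodlist(
            make_food("herring", "fish", energy=210, carbon=0.45, vitamin_d=16.0, baseline=20),
            make_food("beef", "meat", energy=250, carbon=2.0, vitamin_d=0.5, baseline=100),
            make_food("apple", "fruits", energy=50, carbon=0.05, vitamin_d=0.0, baseline=150),
        )

    def test_identity_diet_all_folds_one(self, foods):
        base = foods.baseline_vector()
        rep = category_contributions(base, base, foods)
        for cat in ("fish", "meat", "fruits"):
            assert rep.fold_change(cat, "energy") == pytest.approx(1.0)
            assert rep.fold_change(cat, "carbon") == pytest.approx(1.0)

    def test_doubled_category_fold_two(self, foods):
        base = foods.baseline_vector()
        diet = make_diet([40, 100, 150], foods)  # fish doubled
        rep = category_contributions(diet, base, foods)
        assert rep.fold_change("fish", "vitamin_d") == pytest.approx(2.0)
        assert rep.fold_change("meat", "vitamin_d") == pytest.approx(1.0)

    def test_conservation_category_sums_equal_totals(self, foods):
        base = foods.baseline_vector()
        diet = make_diet([55, 80, 300], foods)
        rep = category_contributions(diet, base, foods)
        t = diet_totals(diet, foods)
        cats = rep.table.drop(index="total")
        assert cats["energy"].sum() == pytest.approx(t.energy, rel=1e-9)
        assert cats["carbon"].sum() == pytest.approx(t.carbon, rel=1e-9)
        assert cats["vitamin_d"].sum() == pytest.approx(t["vitamin_d"], rel=1e-9)
        assert rep.table.loc["total", "energy"] == pytest.approx(t.energy, rel=1e-12)

    def test_zero_baseline_category_flagged_infinite(self, foods):
        base = make_diet([0, 100, 150], foods)
        rep = category_contributions(make_diet([30, 100, 150], foods), base, foods)
        assert np.isinf(rep.fold_change("fish", "vitamin_d"))


class TestDensityReport:
    def test_first_limiting_is_argmin_with_ties(self, two_foods):
        t = diet_totals(make_diet([100, 100], two_foods), two_foods)
        refs = refset(
            _qual_ref("iron", t["iron"] * 2),  # 50 %
            _qual_ref("zinc", t["zinc"] * 2),  # 50 % (tie)
            _qual_ref("vitamin_d", t["vitamin_d"], unit="ug"),  # 100 %
            _disq_ref("sodium", 100.0),
        )
        rep = density_report(make_diet([100, 100], two_foods), two_foods, refs)
        assert rep.first_limiting == ("iron", "zinc")
        assert rep.mar == pytest.approx((50 + 50 + 100) / 3)
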