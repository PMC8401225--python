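"""Threshold classification, the scored model and FVNL estimation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutriprofile import (MissingValueError, NutrientPanel, ProductRecord,
                          QualifyingCriteria, SAHNCBands, ThresholdSet,
                          classify_cwo, classify_sa_proposed,
                          cwo2019_thresholds, derive_qualifying_criteria,
                          estimate_fvnl_percent, sahnc_compliant, score_sahnc,
                          table5_thresholds)
from nutriprofile.config import load_packaged

from .conftest import make_product


class TestThresholdSet:
    def test_packaged_sets_are_well_formed(self):
        t5 = table5_thresholds()
        assert (t5.solids.sodium_mg, t5.solids.total_sugar_g, t5.solids.sat_fat_g) == (400, 10, 4)
        assert (t5.liquids.sodium_mg, t5.liquids.total_sugar_g, t5.liquids.sat_fat_g) == (100, 5, 3)
        assert t5.includes_nss and not t5.includes_energy
        cwo = cwo2019_thresholds()
        assert cwo.includes_energy and not cwo.includes_nss
        assert cwo.solids.energy_kJ == pytest.approx(275 * 4.184)

    def test_liquid_cutpoints_must_not_exceed_solid(self):
        with pytest.raises(ValueError):
            ThresholdSet(name="bad",
                         solids={"sodium_mg": 100, "total_sugar_g": 5, "sat_fat_g": 3},
                         liquids={"sodium_mg": 400, "total_sugar_g": 10, "sat_fat_g": 4})


class TestCWO:
    def test_at_limit_is_compliant(self, all_qualified):
        product = make_product(sodium_mg=400.0)
        result = classify_cwo(product, qual=all_qualified)
        assert result.compliant and not result.flags

    def test_all_zero_panel_is_compliant(self, all_qualified):
        assert classify_cwo(make_product(), qual=all_qualified).compliant

    def test_liquid_sugar_above_cutpoint_flags_sugar_only(self, all_qualified):
        product = make_product(form="liquid", category="sodas", total_sugar_g=6.9)
        result = classify_cwo(product, qual=all_qualified)
        assert result.flags == {"sugar"} and not result.compliant

    def test_sugar_cutpoint_gated_by_added_sugar_qualifier(self):
        intrinsic = make_product(form="liquid", category="fruit_juice",
                                 total_sugar_g=10.4)
        qual = QualifyingCriteria(contains_added_sugar=False)
        assert classify_cwo(intrinsic, qual=qual).compliant
        qual = QualifyingCriteria(contains_added_sugar=True)
        assert classify_cwo(intrinsic, qual=qual).flags == {"sugar"}

    def test_missing_value_requires_policy(self, all_qualified):
        product = ProductRecord(product_id="m", category="dairy", form="solid",
                                panel=NutrientPanel(total_sugar_g=1.0))
        with pytest.raises(MissingValueError, match="missing"):
            classify_cwo(product, qual=all_qualified)
        assert "sodium" in classify_cwo(product, qual=all_qualified,
                                        missing="excessive").flags
        assert classify_cwo(product, qual=all_qualified,
                            missing="lenient").compliant


class TestSAProposed:
    def test_boundary_strict_exceed(self, all_qualified):
        product = make_product(sodium_mg=401.0, total_sugar_g=10.0, sat_fat_g=4.0)
        result = classify_sa_proposed(product, qual=all_qualified)
        assert result.flags == {"sodium"}

    def test_intrinsic_sugar_not_flagged(self):
        juice = make_product(category="fruit_juice", form="liquid",
                             total_sugar_g=10.4)
        qual = QualifyingCriteria(contains_free_sugar_source=False,
                                  contains_added_sodium=False,
                                  contains_added_sat_fat=False,
                                  contains_nss=False)
        assert classify_sa_proposed(juice, qual=qual).compliant

    def test_missing_qualified_nutrient_defaults_to_excessive(self):
        product = ProductRecord(product_id="m", category="dairy", form="solid",
                                panel=NutrientPanel(total_sugar_g=1.0, sat_fat_g=1.0,
                                                    total_fat_g=1.0))
        qual = QualifyingCriteria(contains_free_sugar_source=False,
                                  contains_added_sodium=True,
                                  contains_added_sat_fat=False,
                                  contains_nss=False)
        result = classify_sa_proposed(product, qual=qual)
        assert result.flags == {"sodium"}
        assert result.detail["sodium"]["missing"]

    def test_nss_flagged_on_presence_regardless_of_panel(self):
        product = make_product()
        qual = QualifyingCriteria(contains_free_sugar_source=False,
                                  contains_added_sodium=False,
                                  contains_added_sat_fat=False,
                                  contains_nss=True)
        assert classify_sa_proposed(product, qual=qual).flags == {"nss"}

    def test_unknown_qualifier_resolves_to_qualified_and_recorded(self):
        product = make_product(sodium_mg=500.0)
        result = classify_sa_proposed(product, qual=QualifyingCriteria(
            contains_nss=False, contains_free_sugar_source=False,
            contains_added_sat_fat=False))
        assert "sodium" in result.flags
        assert result.detail["sodium"]["qualifier_unknown"]

    def test_qualifier_soundness_all_false_only_nss_matters(self, none_qualified):
        extreme = make_product(sodium_mg=9000.0, total_sugar_g=90.0,
                               sat_fat_g=50.0)
        assert classify_sa_proposed(extreme, qual=none_qualified).compliant

    def test_as_consumed_panel_preferred_when_present(self, all_qualified):
        concentrate = ProductRecord(
            product_id="c", category="other_beverages", form="liquid",
            panel=NutrientPanel(energy_kJ=800.0, total_sugar_g=40.0,
                                total_fat_g=0.0, sat_fat_g=0.0, sodium_mg=10.0),
            as_consumed_panel=NutrientPanel(energy_kJ=100.0, total_sugar_g=4.5,
                                            total_fat_g=0.0, sat_fat_g=0.0,
                                            sodium_mg=2.0))
        assert classify_sa_proposed(concentrate, qual=all_qualified).compliant


sugar_vals = st.floats(min_value=0, max_value=60, allow_nan=False)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(base=sugar_vals, bump=st.floats(min_value=0.01, max_value=30))
def test_monotonicity_increasing_sugar_never_restores_compliance(base, bump):
    qual = QualifyingCriteria(contains_free_sugar_source=True,
                              contains_added_sugar=True,
                              contains_added_sodium=True,
                              contains_added_sat_fat=True, contains_nss=False)
    low = make_product(total_sugar_g=base)
    high = make_product(total_sugar_g=base + bump)
    for classify in (classify_sa_proposed, classify_cwo):
        lo, hi = classify(low, qual=qual), classify(high, qual=qual)
        assert lo.flags <= hi.flags
        assert hi.compliant <= lo.compliant


class TestSAHNC:
    def test_all_zero_panel_scores_zero_in_both_variants(self):
        product = make_product(category="mixed_dishes")
        for variant in ("final", "baseline"):
            score = score_sahnc(product, variant=variant)
            assert score.baseline_points == score.final_score == 0

    def test_band_lookup_matches_independent_reread_of_config(self):
        # Straight-line oracle: re-read the YAML and count thresholds
        # strictly exceeded, independent of the engine's lookup path.
        cfg = load_packaged("sahnc_bands.yaml")
        panel = dict(energy_kJ=1700.0, sat_fat_g=4.5, total_sugar_g=19.0,
                     sodium_mg=455.0, protein_g=3.3, fiber_g=2.0,
                     fvnl_percent=65.0, total_fat_g=4.5)
        product = make_product(category="mixed_dishes", **panel)

        expected_baseline = 0
        for field, bands in cfg["baseline"].items():
            expected_baseline += sum(panel[field] > b for b in bands)
        fvnl_idx = sum(panel["fvnl_percent"] > b for b in cfg["modifying"]["fvnl_percent"])
        fvnl_pts = cfg["modifying"]["fvnl_points"][fvnl_idx - 1] if fvnl_idx else 0
        protein_pts = sum(panel["protein_g"] > b for b in cfg["modifying"]["protein_g"])
        fiber_pts = sum(panel["fiber_g"] > b for b in cfg["modifying"]["fiber_g"])
        if (expected_baseline >= cfg["protein_cap"]["baseline_at_or_above"]
                and fvnl_pts < cfg["protein_cap"]["unless_fvnl_points_at_least"]):
            protein_pts = 0
        expected_final = expected_baseline - fvnl_pts - protein_pts - fiber_pts

        score = score_sahnc(product, variant="final")
        assert score.baseline_points == expected_baseline
        assert score.final_score == expected_final

    def test_protein_cap_suppresses_protein_points(self):
        heavy = make_product(category="mixed_dishes", total_sugar_g=50.0,
                             sodium_mg=1000.0, protein_g=9.0)
        score = score_sahnc(heavy, variant="final")
        assert score.baseline_points == 20
        assert score.breakdown["protein_points"] == 0
        with_fvnl = make_product(category="mixed_dishes", total_sugar_g=50.0,
                                 sodium_mg=1000.0, protein_g=9.0,
                                 fvnl_percent=90.0)
        score2 = score_sahnc(with_fvnl, variant="final")
        assert score2.breakdown["protein_points"] == 5

    def test_cheese_or_fat_uses_extended_ladders(self):
        fatty = make_product(category="dairy", sat_fat_g=25.0, total_fat_g=30.0)
        other = score_sahnc(fatty, scoring_category="other")
        cheese = score_sahnc(fatty, scoring_category="cheese_or_fat")
        assert other.breakdown["sat_fat_g"] == 10
        assert cheese.breakdown["sat_fat_g"] == 24  # 25 g strictly exceeds 1..24

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(sugar=sugar_vals, sodium=st.floats(min_value=0, max_value=2000),
           protein=st.floats(min_value=0, max_value=20))
    def test_final_never_exceeds_baseline(self, sugar, sodium, protein):
        product = make_product(category="mixed_dishes", total_sugar_g=sugar,
                               sodium_mg=sodium, protein_g=protein)
        final = score_sahnc(product, variant="final")
        baseline = score_sahnc(product, variant="baseline")
        assert final.final_score <= baseline.final_score
        assert baseline.modifying_points == 0

    @pytest.mark.parametrize("category, score, compliant", [
        ("beverage", 0, True), ("beverage", 1, False),
        ("other", 3, True), ("other", 4, False),
        ("cheese_or_fat", 27, True), ("cheese_or_fat", 28, False),
    ])
    def test_compliance_thresholds_are_strict(self, category, score, compliant):
        from nutriprofile.npm import SAHNCScore
        s = SAHNCScore(baseline_points=score, modifying_points=0,
                       final_score=score, scoring_category=category,
                       variant="baseline")
        assert sahnc_compliant(s) is compliant


class TestFVNL:
    def test_ineligible_category_scores_zero(self):
        dairy = make_product(category="dairy", ingredients="milk, cream")
        assert estimate_fvnl_percent(dairy) == 0.0

    def test_fvnl_first_with_negligible_others_hits_top_band(self):
        product = make_product(category="legumes",
                               ingredients="chickpeas, water, salt")
        assert estimate_fvnl_percent(product) == 100.0

    def test_no_fvnl_tokens_scores_zero(self):
        product = make_product(category="snack_foods",
                               ingredients="wheat flour, palm oil")
        assert estimate_fvnl_percent(product) == 0.0

    def test_eligible_without_text_is_unknown(self):
        product = make_product(category="legumes", ingredients=None)
        assert estimate_fvnl_percent(product) is None

    def test_order_penalty_lowers_band(self):
        first = make_product(category="soups_sauces",
                             ingredients="tomato, wheat flour")
        second = make_product(category="soups_sauces",
                              ingredients="wheat flour, tomato")
        assert estimate_fvnl_percent(first) > estimate_fvnl_percent(second)


def test_derive_qualifying_criteria_from_ingredients():
    product = make_product(ingredients="peas, sugar, salt, palm oil, sucralose")
    qual = derive_qualifying_criteria(product)
    assert qual.contains_free_sugar_source and qual.contains_added_sodium
    assert qual.contains_added_sat_fat and qual.contains_nss
    plain = make_product(ingredients="rolled oats")
    qual = derive_qualifying_criteria(plain)
    assert qual.contains_nss is False and qual.contains_added_sodium is False
    unknown = make_product(ingredients=None)
    assert derive_qualifying_criteria(unknown).contains_nss is None


def test_juice_is_free_sugar_source_but_not_added_sugar():
    juice = make_product(category="fruit_juice", form="liquid",
                         ingredients="orange juice")
    qual = derive_qualifying_criteria(juice)
    assert qual.contains_free_sugar_source is True
    assert qual.contains_added_sugar is False
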