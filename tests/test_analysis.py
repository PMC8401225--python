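"""Category summaries, regulated counts and model comparison tables."""

import pytest

from nutriprofile import (NPMResult, QualifyingCriteria, classify_cwo,
                          classify_sa_proposed, compare_models,
                          count_regulated, energy_only_share,
                          sugar_compliance_share, summarize_categories)
from nutriprofile.synth import fixture_supply

from .conftest import make_product


def _result(flags, model="cwo2019"):
    return NPMResult(model=model, flags=frozenset(flags), compliant=not flags)


class TestSummaries:
    def test_category_mean_over_two_products(self):
        products = [make_product("a", "dairy", sodium_mg=100.0),
                    make_product("b", "dairy", sodium_mg=300.0)]
        summary = summarize_categories(products, include_totals=False)
        assert summary.loc["dairy", "sodium_mg"] == pytest.approx(200.0)
        assert summary.loc["dairy", "n"] == 2

    def test_all_missing_nutrient_reports_missing_with_divisor_zero(self):
        products = [make_product("a", "dairy"), make_product("b", "dairy")]
        summary = summarize_categories(products, include_totals=False)
        assert summary.loc["dairy", "trans_fat_g_n"] == 0
        assert summary.loc["dairy", "trans_fat_g"] is None or \
            summary.loc["dairy", "trans_fat_g"] != summary.loc["dairy", "trans_fat_g"]

    def test_grand_rows_are_pooled_means_not_means_of_means(self):
        # dairy: 2 products at 100; sodas: 1 product at 400 -> pooled 200,
        # mean-of-means would be 250.
        products = [make_product("a", "dairy", sodium_mg=100.0),
                    make_product("b", "dairy", sodium_mg=100.0),
                    make_product("c", "sodas", form="liquid", sodium_mg=400.0)]
        summary = summarize_categories(products)
        assert summary.loc["all_total", "sodium_mg"] == pytest.approx(200.0)
        assert summary.loc["food_total", "n"] == 2
        assert summary.loc["beverage_total", "n"] == 1


class TestRegulatedCounts:
    def test_energy_only_semantics(self):
        products = [make_product("a"), make_product("b"), make_product("c")]
        results = {"a": _result({"energy"}),
                   "b": _result({"energy", "sugar"}),
                   "c": _result(set())}
        counts = count_regulated(products, results)
        row = counts.loc["all_total"]
        assert row["overall"] == 2
        assert row["energy"] == 2
        assert row["energy_only"] == 1
        assert row["sugar"] == 1

    def test_counts_equal_hand_tally_on_fixture(self, all_qualified):
        # Ten hand-classified products: tally recomputed by enumeration.
        flags = [{"sugar"}, {"sodium"}, {"sugar", "sodium"}, set(), {"energy"},
                 {"energy"}, {"sat_fat"}, set(), {"sugar", "energy"}, set()]
        products = [make_product(f"p{i}") for i in range(10)]
        results = {f"p{i}": _result(f) for i, f in enumerate(flags)}
        counts = count_regulated(products, results).loc["all_total"]
        assert counts["overall"] == sum(bool(f) for f in flags) == 7
        assert counts["sugar"] == 3
        assert counts["sodium"] == 2
        assert counts["energy"] == 3
        assert counts["energy_only"] == 2
        # union bound: overall <= sum of per-nutrient, >= max per-nutrient
        per_nutrient = [counts[n] for n in ("sugar", "sodium", "sat_fat", "energy")]
        assert max(per_nutrient) <= counts["overall"] <= sum(per_nutrient)

    def test_merged_parent_rollup(self):
        products = [make_product("a", "fruits_vegetables"),
                    make_product("b", "vegetables")]
        results = {"a": _result({"sugar"}), "b": _result(set())}
        counts = count_regulated(products, results)
        assert counts.loc["fruits_vegetables_all", "n"] == 2
        assert "vegetables" not in counts.index
        unmerged = count_regulated(products, results, merge_parents=False)
        assert unmerged.loc["vegetables", "n"] == 1


def test_energy_only_share_math():
    assert energy_only_share(100, 4344) == 2.3
    assert energy_only_share(0, 10) == 0.0
    assert energy_only_share(10, 10) == 100.0
    with pytest.raises(ValueError):
        energy_only_share(0, 0)


def test_sugar_compliance_share_math():
    assert sugar_compliance_share(385, 3) == 99.0   # the 100% juice row
    assert sugar_compliance_share(10, 0) == 100.0
    assert sugar_compliance_share(10, 10) == 0.0


class TestCompareModels:
    @staticmethod
    def _models(all_qualified):
        return {
            "cwo2019": lambda p: classify_cwo(p, qual=all_qualified,
                                              missing="excessive").compliant,
            "sa_proposed": lambda p: classify_sa_proposed(
                p, qual=all_qualified).compliant,
        }

    def test_all_zero_supply_fully_compliant(self, all_qualified):
        products = [make_product(f"p{i}") for i in range(5)]
        table = compare_models(products, self._models(all_qualified))
        assert (table.loc["all_total",
                          ["cwo2019_compliant_pct",
                           "sa_proposed_compliant_pct"]] == 100.0).all()

    def test_table_matches_hand_enumeration_on_boundary_fixture(self, all_qualified):
        fx = fixture_supply("table5_boundaries")
        products = [p for p in fx.products if p.product_id != "liquid-nss"]
        table = compare_models(products, self._models(all_qualified))
        expected_compliant = sum(
            not fx.expected[p.product_id]["sa_flags"] for p in products)
        assert table.loc["all_total", "sa_proposed_compliant_n"] == expected_compliant

    def test_totals_permutation_invariant(self, all_qualified):
        products = [make_product(f"p{i}", sodium_mg=100.0 * i) for i in range(8)]
        models = self._models(all_qualified)
        forward = compare_models(products, models)
        backward = compare_models(list(reversed(products)), models)
        assert forward.loc["all_total"].equals(backward.loc["all_total"])
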