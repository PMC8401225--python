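"""Synthetic packaged-food supplies with the category structure and
statistical profile of the 2018 SA survey.

Nutrient amounts are drawn from log-normal distributions parameterized to hit
each category's target mean at a configurable coefficient of variation
(default 0.6, a modeling choice: the survey publishes only means).  Saturated
and trans fat are tied to total fat, and free sugar to total sugar, through
fixed mean ratios so the ordering constraints hold by construction and the
target means are preserved exactly in expectation.  Everything is reproducible
from the seed.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .config import supply_stats
from .core import CategoryTaxonomy, NutrientPanel, ProductRecord, default_taxonomy

__all__ = ["CategoryParams", "GeneratorConfig", "generate_supply",
           "default_generator_config", "fixture_supply", "FixtureSupply",
           "FIXTURE_NAMES"]

_NSS_TOKENS = ["aspartame", "sucralose", "acesulfame k", "sodium cyclamate",
               "sodium saccharin", "steviol glycosides", "sorbitol", "xylitol"]

# Assumed protein/fibre means (g/100 g or mL): the survey publishes only
# nutrients of concern, but the scored model needs 'nutrients to encourage'
# to behave realistically.  Values are typical food-composition magnitudes
# per category, a modeling choice and not survey output.
_ASSUMED_ENCOURAGE_MEANS = {
    "breakfast_cereals":       {"protein_g": 9.0, "fiber_g": 7.0},
    "cereals_cereal_products": {"protein_g": 8.0, "fiber_g": 3.5},
    "confectionery_dessert":   {"protein_g": 4.0, "fiber_g": 1.5},
    "dairy":                   {"protein_g": 8.0, "fiber_g": 0.0},
    "fruits_vegetables":       {"protein_g": 1.0, "fiber_g": 2.5},
    "vegetables":              {"protein_g": 2.0, "fiber_g": 2.5},
    "legumes":                 {"protein_g": 7.0, "fiber_g": 6.0},
    "mixed_dishes":            {"protein_g": 5.0, "fiber_g": 2.0},
    "protein":                 {"protein_g": 18.0, "fiber_g": 0.5},
    "snack_foods":             {"protein_g": 6.0, "fiber_g": 3.0},
    "soups_sauces":            {"protein_g": 2.0, "fiber_g": 1.0},
    "dairy_drinks":            {"protein_g": 3.3, "fiber_g": 0.0},
    "other_beverages":         {"protein_g": 0.1, "fiber_g": 0.1},
    "sodas":                   {"protein_g": 0.0, "fiber_g": 0.0},
    "fruit_juice":             {"protein_g": 0.5, "fiber_g": 0.2},
}

# Plausible base ingredient lists per category (solids get flour/oil bases,
# beverages water bases); used to synthesize ingredient text.
_BASE_INGREDIENTS = {
    "breakfast_cereals": "whole grain oats, sugar, salt",
    "cereals_cereal_products": "wheat flour, water, salt",
    "confectionery_dessert": "sugar, cocoa mass, palm oil, emulsifier",
    "dairy": "milk, cream, salt",
    "fruits_vegetables": "fruit, sugar, water",
    "vegetables": "vegetables, water, salt",
    "legumes": "beans, water, salt",
    "mixed_dishes": "rice, vegetable oil, salt, flavouring",
    "protein": "chicken, salt, preservative",
    "snack_foods": "potato, vegetable oil, salt",
    "soups_sauces": "water, tomato paste, sugar, salt",
    "dairy_drinks": "milk, sugar, stabiliser",
    "other_beverages": "water, sugar, citric acid, flavouring",
    "sodas": "carbonated water, sugar, citric acid, flavouring",
    "fruit_juice": "fruit juice, water",
}


class CategoryParams(BaseModel):
    model_config = ConfigDict(frozen=True)

    n: int = Field(ge=0)
    means: dict[str, float]
    nss_probability: float = Field(ge=0, le=1)


class GeneratorConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    seed: int
    categories: dict[str, CategoryParams]
    cv: float = Field(default=0.6, gt=0)
    basis: str = "as_packaged"


def default_generator_config(seed: int, scale: float = 1.0) -> GeneratorConfig:
    """Generator parameterized to the published category means, counts and
    NSS prevalences of the 2018 survey; ``scale`` shrinks category sizes."""
    stats = supply_stats()["category_stats"]
    categories = {}
    for cat, row in stats.items():
        n = max(1, round(row["n"] * scale)) if scale != 1.0 else row["n"]
        means = dict(row["means"])
        means.update(_ASSUMED_ENCOURAGE_MEANS.get(cat, {}))
        categories[cat] = CategoryParams(
            n=n, means=means,
            nss_probability=row["nss_count"] / row["n"])
    return GeneratorConfig(seed=seed, categories=categories)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, n: int,
               label: str) -> np.ndarray:
    if mean < 0:
        raise ValueError(f"{label}: negative target mean")
    if mean == 0:
        if cv > 0:
            warnings.warn(f"{label}: mean 0 with cv {cv} degenerates to a "
                          "point mass at 0", stacklevel=3)
        return np.zeros(n)
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), n)


def generate_supply(
    config: GeneratorConfig,
    taxonomy: CategoryTaxonomy | None = None,
) -> list[ProductRecord]:
    """Draw a synthetic supply: per category, ``n`` products with log-normal
    nutrient amounts at the target means, NSS flags at the configured
    probability (matching tokens synthesized into the ingredient text), and
    sat fat <= total fat, trans fat <= total fat, free sugar <= total sugar
    by construction."""
    taxonomy = taxonomy or default_taxonomy()
    rng = np.random.default_rng(config.seed)
    products: list[ProductRecord] = []
    for cat in sorted(config.categories):
        params = config.categories[cat]
        if params.n == 0:
            continue
        m = params.means
        n = params.n
        energy = _lognormal(rng, m.get("energy_kJ", 0.0), config.cv, n, f"{cat}.energy")
        sugar = _lognormal(rng, m.get("total_sugar_g", 0.0), config.cv, n, f"{cat}.sugar")
        fat = _lognormal(rng, m.get("total_fat_g", 0.0), config.cv, n, f"{cat}.fat")
        sodium = _lognormal(rng, m.get("sodium_mg", 0.0), config.cv, n, f"{cat}.sodium")
        protein = (_lognormal(rng, m["protein_g"], config.cv, n, f"{cat}.protein")
                   if "protein_g" in m else None)
        fiber = (_lognormal(rng, m["fiber_g"], config.cv, n, f"{cat}.fiber")
                 if "fiber_g" in m else None)
        sugar_mean = m.get("total_sugar_g", 0.0)
        fat_mean = m.get("total_fat_g", 0.0)
        free_ratio = min(m.get("free_sugar_g", 0.0) / sugar_mean, 1.0) if sugar_mean else 0.0
        sat_ratio = min(m.get("sat_fat_g", 0.0) / fat_mean, 1.0) if fat_mean else 0.0
        trans_ratio = min(m.get("trans_fat_g", 0.0) / fat_mean, 1.0) if fat_mean else 0.0
        nss_flags = rng.random(n) < params.nss_probability
        nss_pick = rng.integers(0, len(_NSS_TOKENS), n)

        is_bev = taxonomy.is_beverage.get(cat, False)
        base = _BASE_INGREDIENTS.get(cat, "water, salt")
        for i in range(n):
            ingredients = base
            if nss_flags[i]:
                ingredients = f"{base}, {_NSS_TOKENS[nss_pick[i]]}"
            products.append(ProductRecord(
                product_id=f"{cat}-{i:05d}",
                category=cat,
                form="liquid" if is_bev else "solid",
                basis=config.basis,
                panel=NutrientPanel(
                    energy_kJ=float(energy[i]),
                    total_sugar_g=float(sugar[i]),
                    free_sugar_g=float(sugar[i] * free_ratio),
                    total_fat_g=float(fat[i]),
                    sat_fat_g=float(fat[i] * sat_ratio),
                    trans_fat_g=float(fat[i] * trans_ratio),
                    sodium_mg=float(sodium[i]),
                    protein_g=None if protein is None else float(protein[i]),
                    fiber_g=None if fiber is None else float(fiber[i]),
                ),
                ingredients_text=ingredients,
            ))
    return products


# ---------------------------------------------------------------------------
# Hand-authored fixtures with frozen expected classifications

class FixtureSupply(NamedTuple):
    products: list[ProductRecord]
    expected: dict[str, dict]


FIXTURE_NAMES = ("table5_boundaries", "leniency_demo", "energy_only_demo")


def _boundary_product(pid: str, form: str, **panel) -> ProductRecord:
    defaults = dict(energy_kJ=0.0, total_sugar_g=0.0, sat_fat_g=0.0,
                    total_fat_g=panel.get("sat_fat_g", 0.0), sodium_mg=0.0)
    defaults.update(panel)
    defaults["total_fat_g"] = max(defaults["total_fat_g"], defaults["sat_fat_g"])
    category = "sodas" if form == "liquid" else "snack_foods"
    return ProductRecord(product_id=pid, category=category, form=form,
                         panel=NutrientPanel(**defaults))


def _table5_boundaries() -> FixtureSupply:
    # At-limit, just-above and just-below products for each cut-point and
    # form.  Expected flags assume all qualifying criteria hold and no NSS.
    cuts = {"solid": {"sodium": 400.0, "sugar": 10.0, "sat_fat": 4.0},
            "liquid": {"sodium": 100.0, "sugar": 5.0, "sat_fat": 3.0}}
    field = {"sodium": "sodium_mg", "sugar": "total_sugar_g", "sat_fat": "sat_fat_g"}
    products, expected = [], {}
    for form, table in cuts.items():
        for nut, cut in table.items():
            for suffix, value, flagged in (("at", cut, False),
                                           ("above", cut + 0.1, True),
                                           ("below", cut - 0.1, False)):
                pid = f"{form}-{nut}-{suffix}"
                products.append(_boundary_product(pid, form, **{field[nut]: value}))
                flags = frozenset({nut}) if flagged else frozenset()
                expected[pid] = {"sa_flags": flags, "cwo_flags": flags}
    products.append(_boundary_product("solid-allzero", "solid"))
    expected["solid-allzero"] = {"sa_flags": frozenset(), "cwo_flags": frozenset()}
    # An NSS-containing product is flagged by the proposed model only.
    nss = ProductRecord(product_id="liquid-nss", category="sodas", form="liquid",
                        panel=NutrientPanel(energy_kJ=1.0, total_sugar_g=0.0,
                                            sat_fat_g=0.0, total_fat_g=0.0,
                                            sodium_mg=0.0),
                        ingredients_text="carbonated water, aspartame")
    products.append(nss)
    expected["liquid-nss"] = {"sa_flags": frozenset({"nss"}),
                              "cwo_flags": frozenset()}
    return FixtureSupply(products, expected)


def _energy_only_demo() -> FixtureSupply:
    # Chilean solid energy limit is 1150.6 kJ/100 g; the first product
    # exceeds it and nothing else, the second also breaches sugar, the third
    # is compliant throughout.
    mk = _boundary_product
    products = [
        mk("energy-only", "solid", energy_kJ=1200.0, total_sugar_g=5.0,
           sodium_mg=200.0, sat_fat_g=2.0),
        mk("energy-plus-sugar", "solid", energy_kJ=1200.0, total_sugar_g=12.0,
           sodium_mg=200.0, sat_fat_g=2.0),
        mk("fully-compliant", "solid", energy_kJ=900.0, total_sugar_g=5.0,
           sodium_mg=200.0, sat_fat_g=2.0),
    ]
    expected = {
        "energy-only": {"cwo_flags": frozenset({"energy"})},
        "energy-plus-sugar": {"cwo_flags": frozenset({"energy", "sugar"})},
        "fully-compliant": {"cwo_flags": frozenset()},
    }
    return FixtureSupply(products, expected)


def _leniency_demo() -> FixtureSupply:
    # "lenient-winner": baseline 5 points (energy 1500 kJ -> 4, sugar 6 g ->
    # 1) minus 5 protein points -> final 0, compliant only under the final
    # variant.  "cap-bound": baseline 20 (sugar 50 -> 10, sodium 1000 -> 10)
    # triggers the protein cap with no FVNL, non-compliant either way.
    products = [
        ProductRecord(product_id="lenient-winner", category="mixed_dishes",
                      form="solid",
                      panel=NutrientPanel(energy_kJ=1500.0, total_sugar_g=6.0,
                                          sat_fat_g=0.0, total_fat_g=0.0,
                                          sodium_mg=0.0, protein_g=9.0)),
        ProductRecord(product_id="cap-bound", category="mixed_dishes",
                      form="solid",
                      panel=NutrientPanel(energy_kJ=0.0, total_sugar_g=50.0,
                                          sat_fat_g=0.0, total_fat_g=0.0,
                                          sodium_mg=1000.0, protein_g=9.0)),
        ProductRecord(product_id="plain", category="mixed_dishes", form="solid",
                      panel=NutrientPanel(energy_kJ=0.0, total_sugar_g=0.0,
                                          sat_fat_g=0.0, total_fat_g=0.0,
                                          sodium_mg=0.0)),
    ]
    expected = {
        "lenient-winner": {"sahnc_final_compliant": True,
                           "sahnc_baseline_compliant": False,
                           "sahnc_final_score": 0, "sahnc_baseline_score": 5},
        "cap-bound": {"sahnc_final_compliant": False,
                      "sahnc_baseline_compliant": False,
                      "sahnc_final_score": 20, "sahnc_baseline_score": 20},
        "plain": {"sahnc_final_compliant": True,
                  "sahnc_baseline_compliant": True,
                  "sahnc_final_score": 0, "sahnc_baseline_score": 0},
    }
    return FixtureSupply(products, expected)


def fixture_supply(name: str) -> FixtureSupply:
    """Return a named hand-authored fixture (products + expected results)."""
    builders = {"table5_boundaries": _table5_boundaries,
                "leniency_demo": _leniency_demo,
                "energy_only_demo": _energy_only_demo}
    if name not in builders:
        raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    return builders[name]()
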