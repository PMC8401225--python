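import pytest

from nutriprofile import NutrientPanel, ProductRecord, QualifyingCriteria


@pytest.fixture
def all_qualified():
    """Every qualifying criterion holds, no NSS: pure threshold behaviour."""
    return QualifyingCriteria(
        contains_free_sugar_source=True, contains_added_sugar=True,
        contains_added_sodium=True, contains_added_sat_fat=True,
        contains_nss=False)


@pytest.fixture
def none_qualified():
    return QualifyingCriteria(
        contains_free_sugar_source=False, contains_added_sugar=False,
        contains_added_sodium=False, contains_added_sat_fat=False,
        contains_nss=False)


def make_product(pid="p1", category="snack_foods", form="solid",
                 ingredients=None, **panel):
    defaults = dict(energy_kJ=0.0, total_sugar_g=0.0, total_fat_g=0.0,
                    sat_fat_g=0.0, sodium_mg=0.0)
    defaults.update(panel)
    if defaults.get("sat_fat_g") and defaults["sat_fat_g"] > defaults.get("total_fat_g", 0):
        defaults["total_fat_g"] = defaults["sat_fat_g"]
    return ProductRecord(product_id=pid, category=category, form=form,
                         panel=NutrientPanel(**defaults),
                         ingredients_text=ingredients)


@pytest.fixture
def product_factory():
    return make_product
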