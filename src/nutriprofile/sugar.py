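"""Free-sugar estimation and WHO-guideline-aligned per-energy computations.

WHO dietary guidelines cap total sugar at 10% and free sugar at 5% of daily
energy.  At the 8400 kJ (2000 kcal) reference intake that is 1 g of total
sugar per 168 kJ and 1 g of free sugar per 336 kJ, which converts a mean
energy density into an aligned sugar limit per 100 g/100 mL.

Percent-of-energy arithmetic uses a sugar energy density of 17 kJ/g.  Note a
deliberate inconsistency kept for fidelity with the published worked figures:
the 168 kJ/g anchor implies 16.8 kJ/g (8400/500), but the published
percent-of-energy values reproduce only with 17 kJ/g, the conventional
carbohydrate Atwater factor.  Each constant is used exactly where the source
computation used it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, NamedTuple

from ._util import compile_term_pattern, normalize_text, round_half_up
from .config import load_packaged, load_yaml
from .core import ProductRecord

__all__ = [
    "SugarGuidelineConstants", "FreeSugarRuleSet", "FreeSugarEstimate",
    "estimate_free_sugar", "who_aligned_limit", "pct_energy_from_sugar",
]


@dataclass(frozen=True)
class SugarGuidelineConstants:
    reference_energy_kJ_per_day: float = 8400.0
    total_sugar_energy_share: float = 0.10
    free_sugar_energy_share: float = 0.05
    kJ_per_g_total_anchor: float = 168.0   # 1 g total sugar per 168 kJ
    kJ_per_g_free_anchor: float = 336.0    # 1 g free sugar per 336 kJ
    sugar_energy_density_kJ_per_g: float = 17.0  # %-energy arithmetic

    def __post_init__(self) -> None:
        if abs(self.kJ_per_g_free_anchor - 2 * self.kJ_per_g_total_anchor) > 1e-9:
            raise ValueError("free anchor must be twice the total anchor")
        for share in (self.total_sugar_energy_share, self.free_sugar_energy_share):
            if not 0 < share < 1:
                raise ValueError("energy shares must lie in (0, 1)")


DEFAULT_CONSTANTS = SugarGuidelineConstants()


class FreeSugarEstimate(NamedTuple):
    value: float
    source: Literal["declared", "estimated"]


class FreeSugarRuleSet:
    """Per-category rules mapping total sugar to an estimated free sugar.

    Rule kinds: ``all_free``, ``none_free``, ``fraction`` (fixed share) and
    ``ingredient_driven`` (all-free when a free-sugar-source token appears in
    the ingredient list, else none-free).
    """

    def __init__(self, rules: Mapping[str, Mapping], free_sugar_sources: list[str]):
        for cat, rule in rules.items():
            kind = rule.get("kind")
            if kind not in {"all_free", "none_free", "fraction", "ingredient_driven"}:
                raise ValueError(f"category {cat!r}: unknown rule kind {kind!r}")
            if kind == "fraction" and not 0 <= float(rule.get("value", -1)) <= 1:
                raise ValueError(f"category {cat!r}: fraction must be in [0, 1]")
        self.rules = dict(rules)
        self.source_pattern = compile_term_pattern(free_sugar_sources)

    @classmethod
    def packaged_default(cls) -> "FreeSugarRuleSet":
        return cls.from_config(load_packaged("free_sugar_rules.yaml"))

    @classmethod
    def from_yaml(cls, path) -> "FreeSugarRuleSet":
        return cls.from_config(load_yaml(path))

    @classmethod
    def from_config(cls, cfg: Mapping) -> "FreeSugarRuleSet":
        sources = list(cfg.get("added_sugar_sources", [])) + list(
            cfg.get("free_sugar_only_sources", []))
        return cls(cfg["rules"], sources)


def estimate_free_sugar(product: ProductRecord,
                        rules: FreeSugarRuleSet | None = None) -> FreeSugarEstimate:
    """Free sugar per 100 g/mL: the declared value when present, otherwise a
    deterministic category-rule estimate, never exceeding total sugar."""
    rules = rules or FreeSugarRuleSet.packaged_default()
    panel = product.panel
    if panel.free_sugar_g is not None:
        return FreeSugarEstimate(panel.free_sugar_g, "declared")
    if panel.total_sugar_g is None:
        raise ValueError(f"{product.product_id}: total sugar missing, cannot estimate")
    rule = rules.rules.get(product.category)
    if rule is None:
        raise ValueError(
            f"no free-sugar rule for category {product.category!r}; "
            f"covered: {sorted(rules.rules)}")
    total = panel.total_sugar_g
    kind = rule["kind"]
    if kind == "all_free":
        value = total
    elif kind == "none_free":
        value = 0.0
    elif kind == "fraction":
        value = float(rule["value"]) * total
    else:  # ingredient_driven
        text = normalize_text(product.ingredients_text or "")
        value = total if rules.source_pattern.search(text) else 0.0
    return FreeSugarEstimate(value, "estimated")


def who_aligned_limit(mean_energy: float,
                      sugar_kind: Literal["total", "free"] = "total",
                      constants: SugarGuidelineConstants = DEFAULT_CONSTANTS,
                      ndigits: int = 1) -> float:
    """Sugar limit (g per 100 g/mL) aligning a mean energy density with the
    WHO shares: mean energy divided by the 168 (total) or 336 (free) kJ/g
    anchor, rounded half-up."""
    if mean_energy <= 0:
        raise ValueError("mean energy must be positive")
    anchor = (constants.kJ_per_g_total_anchor if sugar_kind == "total"
              else constants.kJ_per_g_free_anchor)
    return round_half_up(mean_energy / anchor, ndigits)


def pct_energy_from_sugar(sugar_g: float, energy_kJ: float,
                          constants: SugarGuidelineConstants = DEFAULT_CONSTANTS,
                          ndigits: int = 1) -> float:
    """Percent of energy attributable to sugar at 17 kJ/g, rounded half-up.

    A sugar energy above the declared total energy indicates inconsistent
    data; a warning is raised and the value still returned.
    """
    if energy_kJ <= 0:
        raise ValueError("energy must be positive")
    if sugar_g < 0:
        raise ValueError("sugar must be non-negative")
    pct = 100.0 * sugar_g * constants.sugar_energy_density_kJ_per_g / energy_kJ
    if pct > 100.0:
        warnings.warn("sugar energy exceeds total energy (inconsistent data)",
                      stacklevel=2)
    return round_half_up(pct, ndigits)
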