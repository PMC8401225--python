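"""The nutrient profiling models.

Three model families share the threshold semantics here:

* **CWO 2019** — the Chilean warning-octagon thresholds for energy, total
  sugar, sodium and saturated fat per 100 g/100 mL, with Chile's added-sugar
  qualifier on the sugar criterion.
* **SA proposed restrictive model** — the Chilean sugar/sodium/saturated-fat
  cut-points plus an NSS criterion, gated by ingredient-based qualifying
  criteria (free-sugar source, added sodium, added saturated fat, NSS) and a
  default-excessive rule for missing values.
* **SA HNC scored model** — the FSANZ-style points model of draft R429, in a
  final variant (baseline minus protein/fibre/FVNL modifying points) and a
  baseline-only variant.

"Exceed" means strictly greater than the cut-point throughout: a product
sitting exactly at a limit is compliant.  The comparison dialect is a single
config field (``comparison: gt``) should a >= regime ever be needed.
"""

from __future__ import annotations

from typing import Literal, Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field, model_validator

from ._util import compile_term_pattern, normalize_text
from .config import ConfigError, load_packaged, load_yaml
from .core import CategoryTaxonomy, NutrientPanel, ProductRecord, default_taxonomy

__all__ = [
    "CutPoints", "ThresholdSet", "QualifyingCriteria", "NPMResult",
    "SAHNCScore", "SAHNCBands",
    "classify_cwo", "classify_sa_proposed", "score_sahnc", "sahnc_compliant",
    "estimate_fvnl_percent", "derive_qualifying_criteria",
    "table5_thresholds", "cwo2019_thresholds", "MissingValueError",
]


class MissingValueError(ValueError):
    """An evaluated nutrient is missing and no resolution policy was chosen."""


class CutPoints(BaseModel):
    model_config = ConfigDict(frozen=True)

    sodium_mg: float = Field(gt=0)
    total_sugar_g: float = Field(gt=0)
    sat_fat_g: float = Field(gt=0)
    energy_kJ: Optional[float] = Field(default=None, gt=0)


class ThresholdSet(BaseModel):
    """A named model's per-form cut-points and comparison semantics."""

    model_config = ConfigDict(frozen=True)

    name: str
    solids: CutPoints
    liquids: CutPoints
    includes_energy: bool = False
    includes_nss: bool = False
    comparison: Literal["gt", "ge"] = "gt"

    @model_validator(mode="after")
    def _liquids_not_laxer(self) -> "ThresholdSet":
        for f in ("sodium_mg", "total_sugar_g", "sat_fat_g"):
            if getattr(self.liquids, f) > getattr(self.solids, f):
                raise ValueError(f"liquid {f} cut-point exceeds solid cut-point")
        return self

    def for_form(self, form: str) -> CutPoints:
        return self.solids if form == "solid" else self.liquids

    def exceeds(self, value: float, cutpoint: float) -> bool:
        return value > cutpoint if self.comparison == "gt" else value >= cutpoint

    @classmethod
    def from_yaml(cls, path) -> "ThresholdSet":
        return cls(**load_yaml(path))


def table5_thresholds() -> ThresholdSet:
    """The proposed SA restrictive-model cut-points (no energy, with NSS)."""
    return ThresholdSet(**load_packaged("table5.yaml"))


def cwo2019_thresholds() -> ThresholdSet:
    """Chile Warning Octagon 2019 cut-points (energy included, no NSS)."""
    return ThresholdSet(**load_packaged("cwo2019.yaml"))


class QualifyingCriteria(BaseModel):
    """Ingredient-based conditions gating whether a threshold applies.

    ``None`` means unknown; unknown resolves to *qualified* (conservative
    toward flagging), consistent with the default-excessive stance.
    ``contains_added_sugar`` is the Chilean qualifier; the SA proposal uses
    ``contains_free_sugar_source`` instead, so fruit-juice sugar qualifies.
    """

    model_config = ConfigDict(frozen=True)

    contains_free_sugar_source: Optional[bool] = None
    contains_added_sugar: Optional[bool] = None
    contains_added_sodium: Optional[bool] = None
    contains_added_sat_fat: Optional[bool] = None
    contains_nss: Optional[bool] = None


def _resolve(flag: Optional[bool]) -> tuple[bool, bool]:
    """(qualified, was_unknown): unknown counts as qualified."""
    return (True, True) if flag is None else (flag, False)


class NPMResult(BaseModel):
    """Per-product classification under one model."""

    model_config = ConfigDict(frozen=True)

    model: str
    flags: frozenset[str]
    compliant: bool
    score: Optional[float] = None
    detail: dict[str, dict] = {}

    @model_validator(mode="after")
    def _consistent(self) -> "NPMResult":
        if self.score is None and self.compliant != (not self.flags):
            raise ValueError("threshold model: compliant iff no flags")
        return self


_EVALUATED = {  # flag name -> panel field
    "sugar": "total_sugar_g",
    "sodium": "sodium_mg",
    "sat_fat": "sat_fat_g",
    "energy": "energy_kJ",
}


def classify_cwo(
    product: ProductRecord,
    thresholds: ThresholdSet | None = None,
    qual: QualifyingCriteria | None = None,
    missing: Literal["error", "excessive", "lenient"] = "error",
) -> NPMResult:
    """Classify under the Chile Warning Octagon 2019 thresholds.

    A nutrient is flagged when its value is strictly above the form-specific
    cut-point.  The total-sugar cut-point applies only to products with added
    sugar (Chile's qualifier), so intrinsic-sugar foods are not accidentally
    restricted.  Compliant iff nothing is flagged.

    ``missing`` selects the policy for absent evaluated values: ``"error"``
    (default) raises, ``"excessive"`` flags, ``"lenient"`` passes.
    """
    thresholds = thresholds or cwo2019_thresholds()
    qual = qual or QualifyingCriteria()
    cuts = thresholds.for_form(product.form)
    panel = product.effective_panel

    flags: set[str] = set()
    detail: dict[str, dict] = {}
    for flag_name, field in _EVALUATED.items():
        if flag_name == "energy" and not thresholds.includes_energy:
            continue
        cutpoint = getattr(cuts, field)
        if cutpoint is None:
            continue
        qualified, unknown = (True, False)
        if flag_name == "sugar":
            qualified, unknown = _resolve(qual.contains_added_sugar)
        value = panel.get(field)
        flagged = False
        if qualified:
            if value is None:
                if missing == "error":
                    raise MissingValueError(
                        f"{product.product_id}: {field} missing; pass "
                        "missing='excessive' or missing='lenient'")
                flagged = missing == "excessive"
            else:
                flagged = thresholds.exceeds(value, cutpoint)
        if flagged:
            flags.add(flag_name)
        detail[flag_name] = {"value": value, "cutpoint": cutpoint,
                             "qualified": qualified, "qualifier_unknown": unknown,
                             "missing": value is None, "flagged": flagged}
    return NPMResult(model=thresholds.name, flags=frozenset(flags),
                     compliant=not flags, detail=detail)


def classify_sa_proposed(
    product: ProductRecord,
    thresholds: ThresholdSet | None = None,
    qual: QualifyingCriteria | None = None,
) -> NPMResult:
    """Classify under the proposed SA restrictive model.

    Each nutrient cut-point applies only when the matching qualifying
    criterion holds (free-sugar source / added sodium / added saturated fat);
    NSS is flagged on any presence.  A missing value for a qualified nutrient
    is assessed as excessive by default, and the as-consumed panel is used
    when declared, falling back to as-packaged.
    """
    thresholds = thresholds or table5_thresholds()
    qual = qual or QualifyingCriteria()
    cuts = thresholds.for_form(product.form)
    panel = product.effective_panel

    gates = {
        "sugar": qual.contains_free_sugar_source,
        "sodium": qual.contains_added_sodium,
        "sat_fat": qual.contains_added_sat_fat,
    }
    flags: set[str] = set()
    detail: dict[str, dict] = {}
    for flag_name, field in _EVALUATED.items():
        if flag_name == "energy":
            continue  # the proposal drops the energy criterion
        cutpoint = getattr(cuts, field)
        qualified, unknown = _resolve(gates[flag_name])
        value = panel.get(field)
        flagged = qualified and (value is None or thresholds.exceeds(value, cutpoint))
        if flagged:
            flags.add(flag_name)
        detail[flag_name] = {"value": value, "cutpoint": cutpoint,
                             "qualified": qualified, "qualifier_unknown": unknown,
                             "missing": value is None, "flagged": flagged}
    if thresholds.includes_nss:
        contains_nss, unknown = _resolve(qual.contains_nss)
        if contains_nss:
            flags.add("nss")
        detail["nss"] = {"value": contains_nss, "cutpoint": "contains any",
                         "qualified": True, "qualifier_unknown": unknown,
                         "missing": qual.contains_nss is None,
                         "flagged": contains_nss}
    return NPMResult(model=thresholds.name, flags=frozenset(flags),
                     compliant=not flags, detail=detail)


# ---------------------------------------------------------------------------
# SA HNC scored model (FSANZ-style)

class SAHNCBands(BaseModel):
    """Opaque points-band tables for the scored model (editable config)."""

    baseline: dict[str, list[float]]
    baseline_cheese_or_fat: dict[str, list[float]] = {}
    modifying: dict[str, list[float]]
    protein_cap: dict[str, int]
    compliance_thresholds: dict[str, float]

    @classmethod
    def packaged_default(cls) -> "SAHNCBands":
        return cls(**load_packaged("sahnc_bands.yaml"))

    @classmethod
    def from_yaml(cls, path) -> "SAHNCBands":
        cfg = load_yaml(path)
        for key in ("baseline", "modifying", "compliance_thresholds"):
            if key not in cfg:
                raise ConfigError(f"points-band config missing {key!r} table")
        return cls(**cfg)


class SAHNCScore(BaseModel):
    """Score breakdown: final score = baseline - modifying points."""

    model_config = ConfigDict(frozen=True)

    baseline_points: int
    modifying_points: int
    final_score: int
    scoring_category: Literal["beverage", "cheese_or_fat", "other"]
    variant: Literal["final", "baseline"]
    breakdown: dict[str, int] = {}

    @model_validator(mode="after")
    def _consistent(self) -> "SAHNCScore":
        if self.modifying_points < 0 or self.final_score != self.baseline_points - self.modifying_points:
            raise ValueError("inconsistent score breakdown")
        return self


def _band_points(value: Optional[float], bands: Sequence[float]) -> int:
    """Points = number of ascending band thresholds strictly exceeded."""
    if value is None:
        return 0
    return sum(value > b for b in bands)


def score_sahnc(
    product: ProductRecord,
    bands: SAHNCBands | None = None,
    variant: Literal["final", "baseline"] = "final",
    scoring_category: Literal["beverage", "cheese_or_fat", "other"] | None = None,
    taxonomy: CategoryTaxonomy | None = None,
) -> SAHNCScore:
    """Score a product under the SA HNC points model.

    Baseline points accrue from energy, saturated fat, total sugar and sodium
    bands; the ``final`` variant subtracts protein, fibre and FVNL modifying
    points (subject to the protein-cap rule), while ``baseline`` sets
    modifying points to zero.  Missing nutrient values contribute no points.
    """
    bands = bands or SAHNCBands.packaged_default()
    if scoring_category is None:
        taxonomy = taxonomy or default_taxonomy()
        scoring_category = ("beverage"
                            if taxonomy.is_beverage.get(product.category, product.form == "liquid")
                            else "other")
    panel = product.effective_panel

    breakdown: dict[str, int] = {}
    baseline_points = 0
    for field, table in bands.baseline.items():
        if scoring_category == "cheese_or_fat" and field in bands.baseline_cheese_or_fat:
            table = bands.baseline_cheese_or_fat[field]
        pts = _band_points(panel.get(field), table)
        breakdown[field] = pts
        baseline_points += pts

    modifying_points = 0
    if variant == "final":
        fvnl_bands = bands.modifying.get("fvnl_percent", [])
        fvnl_award = bands.modifying.get("fvnl_points", [])
        fvnl_idx = _band_points(panel.get("fvnl_percent"), fvnl_bands)
        fvnl_pts = int(fvnl_award[fvnl_idx - 1]) if fvnl_idx else 0
        fiber_pts = _band_points(panel.get("fiber_g"), bands.modifying.get("fiber_g", []))
        protein_pts = _band_points(panel.get("protein_g"), bands.modifying.get("protein_g", []))
        cap = bands.protein_cap
        if (baseline_points >= cap["baseline_at_or_above"]
                and fvnl_pts < cap["unless_fvnl_points_at_least"]):
            protein_pts = 0
        breakdown.update(fvnl_points=fvnl_pts, fiber_points=fiber_pts,
                         protein_points=protein_pts)
        modifying_points = fvnl_pts + fiber_pts + protein_pts
    return SAHNCScore(baseline_points=baseline_points,
                      modifying_points=modifying_points,
                      final_score=baseline_points - modifying_points,
                      scoring_category=scoring_category,
                      variant=variant, breakdown=breakdown)


def sahnc_compliant(score: SAHNCScore, bands: SAHNCBands | None = None) -> bool:
    """Compliant iff the final score is strictly below the category threshold
    (beverages < 1, processed cheese and fats < 28, other foods < 4)."""
    bands = bands or SAHNCBands.packaged_default()
    return score.final_score < bands.compliance_thresholds[score.scoring_category]


# ---------------------------------------------------------------------------
# FVNL estimation and qualifying-criteria derivation

def estimate_fvnl_percent(
    product: ProductRecord,
    taxonomy: CategoryTaxonomy | None = None,
    rules: Mapping | None = None,
) -> Optional[float]:
    """Estimate a banded FVNL percentage from the ingredient list.

    Emulates the manual dietitian banding: sub-categories without FVNLs score
    0; otherwise the FVNL share of non-negligible ingredients (water, salt and
    similar carriers excluded), weighted up for concentrated forms and
    penalized when the first substantive ingredient is not an FVNL, is snapped
    to the nearest configured band.  Returns ``None`` (unknown) for an
    eligible category with no ingredient text.
    """
    taxonomy = taxonomy or default_taxonomy()
    rules = rules or load_packaged("fvnl_rules.yaml")
    if not taxonomy.fvnl_eligible.get(product.category, True):
        return 0.0
    if not product.ingredients_text:
        return None

    fvnl_pat = compile_term_pattern(list(rules["fvnl_terms"]))
    negligible = {normalize_text(t) for t in rules["negligible_ingredients"]}
    conc_pat = compile_term_pattern(list(rules["concentrated_markers"]))
    conc_weight = float(rules.get("concentrated_weight", 1.0))

    ingredients = [normalize_text(tok)
                   for tok in product.ingredients_text.split(",") if tok.strip()]
    substantive = [ing for ing in ingredients if ing not in negligible]
    if not substantive:
        return 0.0
    num = den = 0.0
    for ing in substantive:
        w = conc_weight if conc_pat.search(ing) else 1.0
        den += w
        if fvnl_pat.search(ing):
            num += w
    if num == 0:
        return 0.0
    share = num / den
    if not fvnl_pat.search(substantive[0]):
        share *= float(rules.get("order_penalty", 1.0))
    bands = sorted(float(b) for b in rules["bands"])
    target = 100.0 * share
    return min(bands, key=lambda b: (abs(b - target), -b))


def derive_qualifying_criteria(
    product: ProductRecord,
    free_sugar_sources: Sequence[str] | None = None,
    nss_detector=None,
) -> QualifyingCriteria:
    """Derive qualifying criteria from ingredient text by keyword rules.

    Added sodium is inferred from salt/sodium tokens, added saturated fat from
    fat/oil/butter/cream tokens, and NSS from the supplied detector
    (``detect_nss`` by default).  The sugar qualifiers differ by dialect:
    ``contains_added_sugar`` (Chile) matches only added-sugar tokens, while
    ``contains_free_sugar_source`` (the SA proposal) additionally matches
    juice, pulp and concentrate tokens, whose sugars are free but not added.
    Absent ingredient text leaves every criterion unknown.
    """
    if product.ingredients_text is None:
        return QualifyingCriteria()
    from .nss import NSSTermList, detect_nss  # local import to avoid cycle

    if free_sugar_sources is None:
        cfg = load_packaged("free_sugar_rules.yaml")
        added_sources = list(cfg["added_sugar_sources"])
        free_sugar_sources = added_sources + list(cfg["free_sugar_only_sources"])
    else:
        added_sources = list(free_sugar_sources)
    text = normalize_text(product.ingredients_text)
    free_sugar = bool(compile_term_pattern(list(free_sugar_sources)).search(text))
    added_sugar = bool(compile_term_pattern(added_sources).search(text))
    sodium = bool(compile_term_pattern(
        ["salt", "iodised salt", "sea salt", "sodium chloride", "sodium",
         "monosodium glutamate", "brine"]).search(text))
    sat_fat = bool(compile_term_pattern(
        ["palm oil", "coconut oil", "butter", "cream", "ghee", "lard",
         "hydrogenated", "shortening", "vegetable fat", "animal fat",
         "palm kernel oil"]).search(text))
    if nss_detector is None:
        nss = detect_nss(product.ingredients_text, NSSTermList.packaged_default())
        contains_nss = nss.contains_nss
    else:
        contains_nss = nss_detector(product.ingredients_text)
    return QualifyingCriteria(
        contains_free_sugar_source=free_sugar,
        contains_added_sugar=added_sugar,
        contains_added_sodium=sodium,
        contains_added_sat_fat=sat_fat,
        contains_nss=contains_nss,
    )
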