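"""Food-supply compliance analysis: category summaries, regulated counts,
energy-only share, per-nutrient compliance and model comparison tables."""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import pandas as pd

from ._util import round_half_up
from .core import CategoryTaxonomy, ProductRecord, default_taxonomy
from .npm import NPMResult
from .nss import NSSTermList, detect_nss, prevalence_percent

__all__ = [
    "summarize_categories", "count_regulated", "energy_only_share",
    "sugar_compliance_share", "compliance_share", "compare_models",
    "plot_compliance",
]

_SUMMARY_NUTRIENTS = ["energy_kJ", "total_sugar_g", "free_sugar_g",
                      "total_fat_g", "sat_fat_g", "trans_fat_g", "sodium_mg"]
_FLAG_NUTRIENTS = ["sugar", "sodium", "sat_fat", "energy"]


def _category_order(taxonomy: CategoryTaxonomy) -> list[str]:
    foods = [c for c, b in taxonomy.is_beverage.items() if not b]
    bevs = [c for c, b in taxonomy.is_beverage.items() if b]
    return foods + bevs


def summarize_categories(
    products: Sequence[ProductRecord],
    taxonomy: CategoryTaxonomy | None = None,
    nss_terms: NSSTermList | None = None,
    include_totals: bool = True,
) -> pd.DataFrame:
    """Category-level summary: n, nutrient means, NSS count and percent.

    Means are computed over non-missing values, with the divisor recorded in
    a ``<nutrient>_n`` column (a category whose products all lack a nutrient
    reports a missing mean with divisor 0).  Grand rows (food / beverage /
    overall totals) are pooled means over products, not means of means.
    """
    taxonomy = taxonomy or default_taxonomy()
    nss_terms = nss_terms or NSSTermList.packaged_default()

    rows = []
    for p in products:
        row = {"category": p.category,
               "is_beverage": taxonomy.is_beverage[p.category]}
        for nut in _SUMMARY_NUTRIENTS:
            row[nut] = p.panel.get(nut)
        det = detect_nss(p.ingredients_text, nss_terms)
        row["contains_nss"] = bool(det.contains_nss)
        rows.append(row)
    df = pd.DataFrame(rows)

    def _summary(sub: pd.DataFrame, label: str) -> dict:
        out: dict = {"category": label, "n": len(sub)}
        for nut in _SUMMARY_NUTRIENTS:
            values = sub[nut].dropna()
            out[nut] = values.mean() if len(values) else None
            out[f"{nut}_n"] = int(len(values))
        count = int(sub["contains_nss"].sum())
        out["nss_count"] = count
        out["nss_percent"] = prevalence_percent(count, len(sub)) if len(sub) else None
        return out

    summaries = [_summary(df[df["category"] == cat], cat)
                 for cat in _category_order(taxonomy)
                 if (df["category"] == cat).any()]
    if include_totals:
        food = df[~df["is_beverage"]]
        bev = df[df["is_beverage"]]
        if len(food):
            summaries.append(_summary(food, "food_total"))
        if len(bev):
            summaries.append(_summary(bev, "beverage_total"))
        summaries.append(_summary(df, "all_total"))
    return pd.DataFrame(summaries).set_index("category")


def count_regulated(
    products: Sequence[ProductRecord],
    results: Mapping[str, NPMResult],
    taxonomy: CategoryTaxonomy | None = None,
    merge_parents: bool = True,
) -> pd.DataFrame:
    """Regulated counts per category: overall (union of any flag), per
    nutrient, and energy-only (flagged for energy and nothing else).

    A product may count toward several nutrients; ``overall`` is the union.
    With ``merge_parents`` the taxonomy's merged groups (e.g. the combined
    fruits & vegetables rollup) replace their members in the table.
    """
    taxonomy = taxonomy or default_taxonomy()
    rows = []
    for p in products:
        res = results[p.product_id]
        cat = taxonomy.rollup(p.category) if merge_parents else p.category
        row = {"category": cat,
               "is_beverage": taxonomy.is_beverage[p.category],
               "overall": bool(res.flags),
               "energy_only": res.flags == frozenset({"energy"})}
        for nut in _FLAG_NUTRIENTS:
            row[nut] = nut in res.flags
        rows.append(row)
    df = pd.DataFrame(rows)

    def _agg(sub: pd.DataFrame, label: str) -> dict:
        out = {"category": label, "n": len(sub),
               "overall": int(sub["overall"].sum()),
               "energy_only": int(sub["energy_only"].sum())}
        for nut in _FLAG_NUTRIENTS:
            out[nut] = int(sub[nut].sum())
        return out

    order = []
    for cat in _category_order(taxonomy):
        rolled = taxonomy.rollup(cat) if merge_parents else cat
        if rolled not in order:
            order.append(rolled)
    aggregates = [_agg(df[df["category"] == cat], cat)
                  for cat in order if (df["category"] == cat).any()]
    food = df[~df["is_beverage"]]
    bev = df[df["is_beverage"]]
    if len(food):
        aggregates.append(_agg(food, "food_total"))
    if len(bev):
        aggregates.append(_agg(bev, "beverage_total"))
    aggregates.append(_agg(df, "all_total"))
    return pd.DataFrame(aggregates).set_index("category")


def energy_only_share(energy_only: int, regulated_overall: int,
                      ndigits: int = 1) -> float:
    """Share (%) of regulated products exceeding only the energy cut-point."""
    if regulated_overall <= 0:
        raise ValueError("no regulated products")
    return round_half_up(100.0 * energy_only / regulated_overall, ndigits)


def compliance_share(n: int, regulated: int, ndigits: int = 0) -> float:
    """Percent of a category compliant with one criterion: 100*(n-regulated)/n."""
    if n <= 0:
        raise ValueError("category n must be positive")
    return round_half_up(100.0 * (n - regulated) / n, ndigits)


def sugar_compliance_share(n: int, sugar_regulated: int, ndigits: int = 0) -> float:
    """Percent compliant with the sugar criterion (integer by default, the
    precision used in the published juice figure)."""
    return compliance_share(n, sugar_regulated, ndigits)


def compare_models(
    products: Sequence[ProductRecord],
    models: Mapping[str, Callable[[ProductRecord], bool]],
    taxonomy: CategoryTaxonomy | None = None,
) -> pd.DataFrame:
    """Per-category and overall compliance under each model.

    ``models`` maps a model name to a predicate returning compliance for one
    product.  Output rows are categories (plus ``all_total``); columns are
    ``<model>_compliant_n`` and ``<model>_compliant_pct``.  Totals are
    permutation-invariant in the product order.
    """
    taxonomy = taxonomy or default_taxonomy()
    records = []
    for p in products:
        row = {"category": p.category}
        for name, predicate in models.items():
            row[name] = bool(predicate(p))
        records.append(row)
    df = pd.DataFrame(records)

    def _agg(sub: pd.DataFrame, label: str) -> dict:
        out = {"category": label, "n": len(sub)}
        for name in models:
            k = int(sub[name].sum())
            out[f"{name}_compliant_n"] = k
            out[f"{name}_compliant_pct"] = prevalence_percent(k, len(sub))
        return out

    aggregates = [_agg(df[df["category"] == cat], cat)
                  for cat in _category_order(taxonomy)
                  if (df["category"] == cat).any()]
    aggregates.append(_agg(df, "all_total"))
    return pd.DataFrame(aggregates).set_index("category")


def plot_compliance(comparison: pd.DataFrame, path) -> None:
    """Bar chart of per-category compliance percentages by model (optional,
    requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pct_cols = [c for c in comparison.columns if c.endswith("_compliant_pct")]
    ax = comparison[pct_cols].rename(
        columns=lambda c: c.removesuffix("_compliant_pct")).plot.bar(
        figsize=(10, 5), width=0.8)
    ax.set_ylabel("% compliant")
    ax.set_ylim(0, 100)
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)
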