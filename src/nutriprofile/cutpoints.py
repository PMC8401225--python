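"""Cut-point context against a whole-foods food-composition-table extract.

Candidate cut-points are sanity-checked against the distribution of nutrients
in whole, unprocessed foods: a well-placed cut-point spares natural foods.
This module evaluates and reports (order statistics and exceedance rates);
it does not derive cut-points.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from .core import NutrientPanel, SchemaError, _parse_float
from .npm import ThresholdSet

__all__ = ["FCTEntry", "read_fct", "distribution_summary",
           "flag_rate_under_cutpoints"]

_FCT_NUTRIENTS = ["energy_kJ", "total_sugar_g", "free_sugar_g", "total_fat_g",
                  "sat_fat_g", "trans_fat_g", "sodium_mg", "protein_g",
                  "fiber_g"]


class FCTEntry(BaseModel):
    """One whole-food entry: name, group, per-100 g as-consumed panel and the
    upstream inclusion flag (dietitian-reviewed, an input not a computation)."""

    model_config = ConfigDict(frozen=True)

    name: str
    group: str = ""
    panel: NutrientPanel
    included: bool = True


def read_fct(path, delimiter: str | None = None) -> list[FCTEntry]:
    """Read a food-composition extract: columns ``name``, optional ``group``
    and ``included``, plus the product-table nutrient columns."""
    sep = delimiter
    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            sep = "\t" if "\t" in fh.readline() else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if "name" not in df.columns:
        raise SchemaError("FCT extract missing required column 'name'")
    entries = []
    for row in df.to_dict(orient="records"):
        panel = NutrientPanel(**{
            col: _parse_float(row.get(col), col, row["name"])
            for col in _FCT_NUTRIENTS if col in df.columns})
        entries.append(FCTEntry(
            name=row["name"], group=row.get("group", ""),
            panel=panel,
            included=str(row.get("included", "true")).strip().lower()
            not in {"false", "0", "no"}))
    return entries


def distribution_summary(
    entries: Sequence[FCTEntry],
    nutrient: str,
    percentiles: Sequence[float] = (50, 90, 95, 99),
) -> dict[str, float]:
    """Order statistics (min, configurable percentiles, max) of one nutrient
    over the included whole foods."""
    values = np.array([e.panel.get(nutrient) for e in entries
                       if e.included and e.panel.get(nutrient) is not None],
                      dtype=float)
    if values.size == 0:
        raise ValueError(f"no included entries carry {nutrient!r}")
    out = {"n": int(values.size), "min": float(values.min())}
    for p in percentiles:
        out[f"p{p:g}"] = float(np.percentile(values, p))
    out["max"] = float(values.max())
    return out


def flag_rate_under_cutpoints(
    entries: Sequence[FCTEntry],
    thresholds: ThresholdSet,
    form: str = "solid",
) -> dict[str, float]:
    """Fraction of included whole foods that would exceed each cut-point.

    High rates signal a cut-point that would restrict natural foods.  Entries
    missing a nutrient are excluded from that nutrient's denominator.
    Non-increasing as any cut-point increases.
    """
    cuts = thresholds.for_form(form)
    fields = {"sugar": "total_sugar_g", "sodium": "sodium_mg",
              "sat_fat": "sat_fat_g"}
    if thresholds.includes_energy and cuts.energy_kJ is not None:
        fields["energy"] = "energy_kJ"
    rates: dict[str, float] = {}
    for flag, field in fields.items():
        values = [e.panel.get(field) for e in entries if e.included]
        values = [v for v in values if v is not None]
        if not values:
            continue
        cutpoint = getattr(cuts, field)
        rates[flag] = sum(thresholds.exceeds(v, cutpoint) for v in values) / len(values)
    return rates
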