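"""Data model, category taxonomy, delimited-text I/O, unit normalization and
the NOVA marker heuristic for packaged-food-supply records.

A product record is one packaged food or beverage with its nutrition
information panel (NIP) declared per 100 g (solids) or per 100 mL (liquids).
Missing nutrient values are first-class (``None``), never silent zeros: the
proposed restrictive model's default-excessive rule depends on knowing that a
value is absent.
"""

from __future__ import annotations

import csv
import math
import re
import warnings
from typing import Iterable, Literal, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from ._util import compile_term_pattern, normalize_text
from .config import ConfigError, load_packaged, load_yaml

__all__ = [
    "NutrientPanel", "ProductRecord", "CategoryTaxonomy", "NovaMarkerConfig",
    "SchemaError", "CategoryError", "UnitError",
    "read_products", "write_products", "normalize_units", "assign_nova",
    "UNCLASSIFIABLE", "KJ_PER_KCAL", "default_taxonomy",
]

KJ_PER_KCAL = 4.184

#: Sentinel returned by :func:`assign_nova` when neither ingredient text nor a
#: category default is available; excluded from NOVA summaries.
UNCLASSIFIABLE = "unclassifiable"

NUTRIENT_COLUMNS = [
    "energy_kJ", "total_sugar_g", "free_sugar_g", "total_fat_g", "sat_fat_g",
    "trans_fat_g", "sodium_mg", "protein_g", "fiber_g", "fvnl_percent",
]
REQUIRED_COLUMNS = [
    "product_id", "category", "form",
    "energy_kJ", "total_sugar_g", "total_fat_g", "sat_fat_g", "sodium_mg",
]


class SchemaError(ValueError):
    """A product table is missing a required column."""


class CategoryError(ValueError):
    """A record names a category outside the configured taxonomy."""


class UnitError(ValueError):
    """A unit specification uses an unknown unit token."""


class NutrientPanel(BaseModel):
    """Declared nutrient amounts per 100 g (solids) or per 100 mL (liquids).

    All fields are optional; ``None`` means not declared.  Amounts are grams
    except sodium (mg) and energy (kJ).
    """

    model_config = ConfigDict(frozen=True)

    energy_kJ: Optional[float] = Field(default=None, ge=0)
    total_sugar_g: Optional[float] = Field(default=None, ge=0)
    free_sugar_g: Optional[float] = Field(default=None, ge=0)
    total_fat_g: Optional[float] = Field(default=None, ge=0)
    sat_fat_g: Optional[float] = Field(default=None, ge=0)
    trans_fat_g: Optional[float] = Field(default=None, ge=0)
    sodium_mg: Optional[float] = Field(default=None, ge=0)
    protein_g: Optional[float] = Field(default=None, ge=0)
    fiber_g: Optional[float] = Field(default=None, ge=0)
    fvnl_percent: Optional[float] = Field(default=None, ge=0, le=100)

    @model_validator(mode="after")
    def _check_consistency(self) -> "NutrientPanel":
        if self.total_fat_g is not None:
            if self.sat_fat_g is not None and self.sat_fat_g > self.total_fat_g + 1e-9:
                raise ValueError("saturated fat exceeds total fat")
            if self.trans_fat_g is not None and self.trans_fat_g > self.total_fat_g + 1e-9:
                raise ValueError("trans fat exceeds total fat")
        if (self.total_sugar_g is not None and self.free_sugar_g is not None
                and self.free_sugar_g > self.total_sugar_g + 1e-9):
            raise ValueError("free sugar exceeds total sugar")
        return self

    def get(self, field: str) -> Optional[float]:
        return getattr(self, field)


class ProductRecord(BaseModel):
    """One packaged product: category, physical form, panel, ingredient text.

    ``panel`` carries the per-100 g/mL declaration on the basis given by
    ``basis`` (as-packaged by default).  When a separate as-consumed panel is
    declared (e.g. concentrates requiring reconstitution) it is carried in
    ``as_consumed_panel`` and preferred by the proposed restrictive model.
    """

    model_config = ConfigDict(frozen=True)

    product_id: str
    category: str
    form: Literal["solid", "liquid"]
    panel: NutrientPanel = NutrientPanel()
    basis: Literal["as_packaged", "as_consumed"] = "as_packaged"
    as_consumed_panel: Optional[NutrientPanel] = None
    ingredients_text: Optional[str] = None
    nip_present: bool = True

    @property
    def effective_panel(self) -> NutrientPanel:
        """As-consumed values when declared, otherwise the packaged panel."""
        if self.basis == "as_consumed":
            return self.panel
        return self.as_consumed_panel if self.as_consumed_panel is not None else self.panel


class CategoryTaxonomy(BaseModel):
    """Category metadata: beverage membership, FVNL eligibility, parents."""

    is_beverage: dict[str, bool]
    fvnl_eligible: dict[str, bool]
    parent: dict[str, str] = {}
    display: dict[str, str] = {}
    aliases: dict[str, str] = {}

    @property
    def categories(self) -> list[str]:
        return list(self.is_beverage)

    def canonical(self, raw: str) -> str:
        """Resolve a category label (display name, slug or alias) to its slug."""
        slug = _slugify(raw)
        if slug in self.is_beverage:
            return slug
        alias = self.aliases.get(_slugify_key(raw))
        if alias is not None:
            return alias
        raise CategoryError(
            f"unknown category {raw!r}; allowed: {sorted(self.is_beverage)}")

    def rollup(self, category: str) -> str:
        """Parent group used for merged-category reporting, else identity."""
        return self.parent.get(category, category)

    @classmethod
    def from_mapping(cls, cfg: Mapping) -> "CategoryTaxonomy":
        cats = cfg["categories"]
        return cls(
            is_beverage={k: bool(v["is_beverage"]) for k, v in cats.items()},
            fvnl_eligible={k: bool(v.get("fvnl_eligible", True)) for k, v in cats.items()},
            parent={k: v["parent"] for k, v in cats.items() if "parent" in v},
            display={k: v.get("display", k) for k, v in cats.items()},
            aliases={_slugify_key(k): v for k, v in cfg.get("aliases", {}).items()},
        )


def _slugify(raw: str) -> str:
    s = raw.strip().lower().replace("&", " ")
    s = re.sub(r"100\s*%", "", s)
    s = re.sub(r"[^a-z0-9]+", "_", s).strip("_")
    return s


def _slugify_key(raw: str) -> str:
    return re.sub(r"[^a-z0-9]+", " ", raw.lower()).strip()


def default_taxonomy() -> CategoryTaxonomy:
    """The 15-sub-category taxonomy of the 2018 SA supply survey."""
    return CategoryTaxonomy.from_mapping(load_packaged("taxonomy.yaml"))


class NovaMarkerConfig(BaseModel):
    """Ingredient-marker lists for the transparent NOVA heuristic."""

    group4_markers: list[str]
    group3_markers: list[str]
    default_group: int = 1
    category_defaults: dict[str, int] = {}

    @model_validator(mode="after")
    def _check(self) -> "NovaMarkerConfig":
        if not self.group4_markers or not self.group3_markers:
            raise ValueError("marker lists must be non-empty")
        for g in [self.default_group, *self.category_defaults.values()]:
            if g not in (1, 3, 4):
                raise ValueError("NOVA groups limited to {1, 3, 4}")
        return self

    @classmethod
    def packaged_default(cls) -> "NovaMarkerConfig":
        return cls(**load_packaged("nova_markers.yaml"))


# ---------------------------------------------------------------------------
# Delimited-text I/O

def _sniff_delimiter(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _parse_float(cell, column: str, product_id: str) -> Optional[float]:
    if cell is None:
        return None
    text = str(cell).strip()
    if text == "" or text.lower() in {"na", "n/a", "nan", "none", "missing"}:
        if text and text.lower() != "nan":
            warnings.warn(
                f"product {product_id!r}: non-numeric {column} cell {cell!r} "
                "treated as missing", stacklevel=3)
        return None
    try:
        value = float(text)
    except ValueError:
        warnings.warn(
            f"product {product_id!r}: malformed {column} cell {cell!r} "
            "treated as missing", stacklevel=3)
        return None
    return value if not math.isnan(value) else None


def read_products(
    path,
    taxonomy: CategoryTaxonomy | None = None,
    delimiter: str | None = None,
) -> list[ProductRecord]:
    """Read a UTF-8 delimited product table (comma default, tab accepted).

    Raises :class:`SchemaError` when a required column is absent and
    :class:`CategoryError` for categories outside the taxonomy.  Malformed
    numeric cells become missing values with a warning, never silent zeros.
    """
    taxonomy = taxonomy or default_taxonomy()
    sep = delimiter or _sniff_delimiter(path)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"product table missing required column {col!r}")

    records: list[ProductRecord] = []
    for row in df.to_dict(orient="records"):
        pid = str(row["product_id"]).strip()
        category = taxonomy.canonical(str(row["category"]))
        panel_kwargs = {
            col: _parse_float(row.get(col), col, pid)
            for col in NUTRIENT_COLUMNS if col in df.columns
        }
        nip_raw = str(row.get("nip_present", "true")).strip().lower()
        records.append(ProductRecord(
            product_id=pid,
            category=category,
            form=str(row["form"]).strip().lower(),
            basis=str(row.get("basis") or "as_packaged").strip() or "as_packaged",
            panel=NutrientPanel(**panel_kwargs),
            ingredients_text=(str(row["ingredients_text"]).strip() or None)
            if "ingredients_text" in df.columns else None,
            nip_present=nip_raw not in {"false", "0", "no", "f"},
        ))
    return records


def write_products(records: Iterable[ProductRecord], path, delimiter: str = ",") -> None:
    """Write records as a delimited product table readable by ``read_products``."""
    rows = []
    for rec in records:
        row = {
            "product_id": rec.product_id,
            "category": rec.category,
            "form": rec.form,
            "basis": rec.basis,
            "nip_present": str(rec.nip_present).lower(),
            "ingredients_text": rec.ingredients_text or "",
        }
        for col in NUTRIENT_COLUMNS:
            value = rec.panel.get(col)
            row[col] = "" if value is None else repr(value)
        rows.append(row)
    columns = ["product_id", "category", "form", "basis", *NUTRIENT_COLUMNS,
               "ingredients_text", "nip_present"]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter=delimiter)
        writer.writeheader()
        writer.writerows(rows)


# ---------------------------------------------------------------------------
# Unit normalization

_CANONICAL_UNITS = {col: ("mg" if col == "sodium_mg" else "kJ" if col == "energy_kJ"
                          else "percent" if col == "fvnl_percent" else "g")
                    for col in NUTRIENT_COLUMNS}

_CONVERSIONS = {
    ("g", "g"): 1.0, ("mg", "g"): 1e-3,
    ("mg", "mg"): 1.0, ("g", "mg"): 1e3,
    ("kJ", "kJ"): 1.0, ("kcal", "kJ"): KJ_PER_KCAL,
    ("percent", "percent"): 1.0,
}


def normalize_units(raw: Mapping[str, Optional[float]],
                    unit_spec: Mapping[str, str]) -> NutrientPanel:
    """Convert a raw column->value mapping into a canonical panel.

    Canonical units are grams, sodium in mg and energy in kJ (kcal converted
    at 4.184 kJ/kcal).  Idempotent on already-canonical panels.
    """
    out: dict[str, float] = {}
    for col, value in raw.items():
        if col not in _CANONICAL_UNITS:
            raise UnitError(f"unknown nutrient column {col!r}")
        if value is None:
            continue
        unit = unit_spec.get(col, _CANONICAL_UNITS[col])
        factor = _CONVERSIONS.get((unit, _CANONICAL_UNITS[col]))
        if factor is None:
            raise UnitError(
                f"cannot convert {col} from {unit!r} to {_CANONICAL_UNITS[col]!r}")
        out[col] = value * factor
    return NutrientPanel(**out)


# ---------------------------------------------------------------------------
# NOVA marker heuristic

def assign_nova(product: ProductRecord, markers: NovaMarkerConfig) -> int | str:
    """Assign a NOVA processing group from ingredient markers.

    Any group-4 marker (additive, flavourant, NSS token, ...) assigns
    ultra-processed; otherwise any group-3 marker assigns processed; otherwise
    group 1.  Without ingredient text, the category default applies; with
    neither, the ``unclassifiable`` sentinel is returned.  Pure function of
    its inputs and configuration.
    """
    if product.ingredients_text is None:
        if product.category in markers.category_defaults:
            return markers.category_defaults[product.category]
        return UNCLASSIFIABLE
    text = normalize_text(product.ingredients_text)
    if compile_term_pattern(markers.group4_markers).search(text):
        return 4
    if compile_term_pattern(markers.group3_markers).search(text):
        return 3
    return markers.default_group
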