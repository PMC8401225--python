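"""Non-sugar sweetener (NSS) detection from ingredient lists.

Intense sweeteners (aspartame, sucralose, ...) and polyols (sorbitol,
xylitol, ...) are matched against a standardized term list with synonyms and
INS/E additive codes.  Matching is case-folded with word-boundary guards so
``polysaccharide`` never matches ``saccharin``.
"""

from __future__ import annotations

import re
from typing import Iterable, NamedTuple, Optional, Sequence

from pydantic import BaseModel, model_validator

from ._util import compile_term_pattern, normalize_text, round_half_up
from .config import load_packaged, load_yaml
from .core import ProductRecord

__all__ = ["NSSTermList", "NSSDetection", "detect_nss", "nss_prevalence",
           "prevalence_percent"]


class NSSTermList(BaseModel):
    """Canonical sweeteners with per-term class and lower-cased synonyms."""

    version: str = "unversioned"
    terms: dict[str, dict]

    @model_validator(mode="after")
    def _check(self) -> "NSSTermList":
        seen: dict[str, str] = {}
        for canonical, entry in self.terms.items():
            if entry.get("class") not in {"intense", "polyol"}:
                raise ValueError(f"{canonical}: class must be intense or polyol")
            for syn in entry["synonyms"]:
                low = syn.lower().strip()
                if low in seen and seen[low] != canonical:
                    raise ValueError(f"synonym {low!r} maps to both "
                                     f"{seen[low]} and {canonical}")
                seen[low] = canonical
        return self

    @classmethod
    def packaged_default(cls) -> "NSSTermList":
        return cls(**load_packaged("nss_terms.yaml"))

    @classmethod
    def from_yaml(cls, path) -> "NSSTermList":
        return cls(**load_yaml(path))

    def compiled(self) -> list[tuple[str, re.Pattern[str]]]:
        return [(canonical, compile_term_pattern(list(entry["synonyms"])))
                for canonical, entry in self.terms.items()]


class NSSDetection(NamedTuple):
    matches: frozenset[str]
    contains_nss: Optional[bool]  # None = unknown (no ingredient text)

    @property
    def n_distinct(self) -> int:
        return len(self.matches)


def detect_nss(ingredients_text: Optional[str],
               terms: NSSTermList | None = None) -> NSSDetection:
    """Detect canonical NSS in free ingredient text.

    Empty or absent text yields ``contains_nss = None`` (unknown, not false):
    absence of evidence about the ingredient list is not evidence of absence.
    """
    terms = terms or NSSTermList.packaged_default()
    if ingredients_text is None or not ingredients_text.strip():
        return NSSDetection(frozenset(), None)
    text = normalize_text(ingredients_text)
    matched = frozenset(canonical for canonical, pat in terms.compiled()
                        if pat.search(text))
    return NSSDetection(matched, bool(matched))


def prevalence_percent(count: int, n: int, ndigits: int = 1) -> float:
    """100 * count / n, rounded half-up (the 'Contains NSS n (%)' column)."""
    if n <= 0:
        raise ValueError("empty scope: n must be positive")
    return round_half_up(100.0 * count / n, ndigits)


def nss_prevalence(
    products: Sequence[ProductRecord],
    categories: Iterable[str] | None = None,
    terms: NSSTermList | None = None,
) -> tuple[int, float]:
    """Count and percent of in-scope products containing any NSS.

    Scope is an optional category filter.  Detection runs on each product's
    ingredient text; a product with no text (unknown status) is an error since
    prevalence needs a definite flag for every in-scope product.
    """
    scope = set(categories) if categories is not None else None
    in_scope = [p for p in products if scope is None or p.category in scope]
    if not in_scope:
        raise ValueError("empty scope: no products selected")
    terms = terms or NSSTermList.packaged_default()
    count = 0
    for product in in_scope:
        det = detect_nss(product.ingredients_text, terms)
        if det.contains_nss is None:
            raise ValueError(
                f"{product.product_id}: no ingredient text, NSS status unknown")
        count += det.contains_nss
    return count, prevalence_percent(count, len(in_scope))
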