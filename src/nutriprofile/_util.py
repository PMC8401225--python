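"""Small shared helpers: half-up rounding and token matching."""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention used on the reports).

    Python's built-in ``round`` is banker's rounding, which would turn a
    printed 54.0% into 53.9% on some inputs; reports here use half-up.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def compile_term_pattern(terms: list[str]) -> re.Pattern[str]:
    """Compile a word-boundary alternation over lower-cased terms.

    Boundaries guard against substring artefacts (``polysaccharide`` must not
    match ``saccharin``).  Longer terms are tried first so multi-word synonyms
    win over their prefixes.
    """
    ordered = sorted({t.lower().strip() for t in terms if t.strip()},
                     key=len, reverse=True)
    if not ordered:
        raise ValueError("empty term list")
    body = "|".join(re.escape(t) for t in ordered)
    return re.compile(rf"(?<![a-z0-9])(?:{body})(?![a-z0-9])")


def normalize_text(text: str) -> str:
    """Lower-case and collapse punctuation/whitespace for ingredient matching."""
    text = text.lower()
    text = re.sub(r"[()\[\]{}:;.*]", " ", text)
    return re.sub(r"\s+", " ", text).strip()
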