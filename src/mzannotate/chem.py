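"""Elemental-formula arithmetic.

A formula is represented as a plain mapping ``{element symbol: count}``
with strictly positive integer counts (the empty dict is the empty
formula).  All mass arithmetic in the package goes through
:func:`monoisotopic_mass`, which sums the pinned monoisotopic element
masses, so theoretical m/z values are reproducible to the precision of
the embedded element table.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Mapping

from ._elements import ELECTRON_MASS, ELEMENT_TABLE_VERSION, ELEMENTS

__all__ = [
    "ELECTRON_MASS",
    "ELEMENT_TABLE_VERSION",
    "ELEMENTS",
    "PROTON_MZ",
    "Formula",
    "FormulaError",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "rdbe",
    "formula_add",
    "formula_sub",
]

Formula = dict[str, int]

#: m/z of a bare proton: monoisotopic H minus one electron.
PROTON_MZ = ELEMENTS["H"].monoisotopic_mass - ELECTRON_MASS


class FormulaError(ValueError):
    """Raised for unparseable formula strings or unknown elements."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Formula:
    """Parse a formula string such as ``"C9H17N3O6"`` into element counts.

    The dialect is a concatenation of element symbols with optional
    positive integer counts, in any order; no parentheses, hydrates,
    isotope labels or charge suffixes.  Repeated symbols accumulate
    (``"CHC"`` is C2H1).  The empty string parses to the empty formula.

    Raises :class:`FormulaError` naming the offending token for unknown
    element symbols or malformed input.
    """
    text = text.strip()
    counts: Counter[str] = Counter()
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"malformed formula {text!r} at position {pos}: {text[pos:pos + 3]!r}"
            )
        symbol, digits = m.groups()
        if symbol not in ELEMENTS:
            raise FormulaError(f"unknown element symbol {symbol!r} in {text!r}")
        n = int(digits) if digits else 1
        if n > 0:
            counts[symbol] += n
        pos = m.end()
    return dict(counts)


def format_formula(f: Mapping[str, int]) -> str:
    """Format element counts in Hill order (C, H, then alphabetical).

    Elements absent from the formula are omitted; a count of 1 is written
    without a digit.  ``parse_formula(format_formula(f)) == f``.
    """
    items = {k: v for k, v in f.items() if v}
    parts: list[str] = []
    if "C" in items:
        order = ["C"] + (["H"] if "H" in items else [])
        order += sorted(k for k in items if k not in ("C", "H"))
    else:
        order = sorted(items)
    for sym in order:
        n = items[sym]
        parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


def monoisotopic_mass(f: Mapping[str, int]) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a formula, in u."""
    try:
        return sum(ELEMENTS[sym].monoisotopic_mass * n for sym, n in f.items())
    except KeyError as exc:  # pragma: no cover - guarded by parse_formula
        raise FormulaError(f"unknown element symbol {exc.args[0]!r}") from None


def rdbe(f: Mapping[str, int]) -> float:
    """Rings-plus-double-bond equivalents under fixed common valences.

    RDBE = C + Si - (H + F + Cl + Br + I)/2 + (N + P)/2 + 1.  Half-integer
    or negative values indicate a chemically invalid neutral even-electron
    molecule; they are returned as-is so callers can flag them.
    """
    g = lambda s: f.get(s, 0)
    tetravalent = g("C") + g("Si")
    monovalent = g("H") + g("F") + g("Cl") + g("Br") + g("I")
    trivalent = g("N") + g("P")
    return tetravalent - monovalent / 2.0 + trivalent / 2.0 + 1.0


def formula_add(a: Mapping[str, int], b: Mapping[str, int]) -> Formula:
    """Element-wise sum of two formulas."""
    out = Counter(a)
    out.update(b)
    return {k: v for k, v in out.items() if v}


def formula_sub(a: Mapping[str, int], b: Mapping[str, int]) -> Formula:
    """Element-wise difference ``a - b``; raises if any count goes negative."""
    out = Counter(a)
    out.subtract(b)
    if any(v < 0 for v in out.values()):
        raise FormulaError(
            f"cannot remove {format_formula(b)} from {format_formula(a)}"
        )
    return {k: v for k, v in out.items() if v}
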