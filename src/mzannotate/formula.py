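"""Molecular-formula prediction from accurate mass.

For an m/z value with no database hit, the neutral mass is recovered by
inverting the assumed adduct rule and candidate elemental formulas are
enumerated within per-element bounds, keeping those whose monoisotopic
mass falls inside the ppm window and which pass heuristic plausibility
filters in the Golden Rules tradition:

1. element counts inside mass-scaled ranges,
2. ring-plus-double-bond equivalents (RDBE) non-negative and integral
   for a neutral even-electron molecule,
3. element ratios to carbon inside common-range bounds
   (H/C in [0.2, 3.1]; N/C <= 1.3; O/C <= 1.2; P/C <= 0.3; S/C <= 0.8).

Ratio checks apply only to carbon-containing formulas, so inorganic hits
such as H2O are not discarded.  Filters relying on measured isotope
patterns or MS/MS are out of scope here.

Enumeration is depth-first over elements in decreasing mass order with
residual-mass pruning, which is complete within the bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .adducts import AdductRule
from .chem import ELEMENTS, Formula, format_formula, monoisotopic_mass, rdbe

__all__ = [
    "PredictionConstraints",
    "FormulaCandidate",
    "CandidateOverflow",
    "DEFAULT_RATIO_BOUNDS",
    "neutral_mass_from_mz",
    "element_bounds",
    "apply_golden_rules",
    "enumerate_formulas",
]

#: Common-range element-ratio bounds, keyed by element; each value is
#: (lower, upper) for element/C.  Only H has a meaningful lower bound.
DEFAULT_RATIO_BOUNDS: dict[str, tuple[float, float]] = {
    "H": (0.2, 3.1),
    "N": (0.0, 1.3),
    "O": (0.0, 1.2),
    "P": (0.0, 0.3),
    "S": (0.0, 0.8),
}

#: Fixed caps for elements rarely present in numbers (applied after the
#: mass-scaled bound).
_FIXED_CAPS = {"P": 6, "S": 8}


@dataclass(frozen=True)
class PredictionConstraints:
    """Search space and rule toggles for formula enumeration."""

    elements: tuple[str, ...] = ("C", "H", "N", "O", "P", "S")
    ppm: float = 5.0
    max_counts: Mapping[str, int] | None = None  # overrides mass-scaled bounds
    check_element_counts: bool = True
    check_rdbe: bool = True
    check_ratios: bool = True
    ratio_bounds: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RATIO_BOUNDS)
    )
    even_electron: bool = True  # require integral RDBE
    max_candidates: int = 10_000
    max_mass: float = 2000.0


@dataclass(frozen=True)
class FormulaCandidate:
    """One candidate formula with its mass error and rule verdicts."""

    formula: Formula
    mass: float
    ppm_error: float
    rdbe: float
    rules: dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.rules.values())

    def __str__(self) -> str:
        return format_formula(self.formula)


class CandidateOverflow(RuntimeError):
    """Raised when enumeration would exceed the candidate cap."""


def neutral_mass_from_mz(mz: float, rule: AdductRule) -> float:
    """Neutral monoisotopic mass implied by an ionic m/z and adduct rule.

    Exact algebraic inverse of the adduct m/z equation:
    ``M = (z * mz - mass_offset) / x``.  Raises if the implied mass is
    negative (the adduct is inconsistent with so small an m/z).
    """
    if not mz > 0:
        raise ValueError("m/z must be positive")
    mass = (rule.z * mz - rule.mass_offset) / rule.x
    if mass < -1e-9:
        raise ValueError(
            f"adduct {rule.name} implies negative neutral mass for m/z {mz}"
        )
    return max(mass, 0.0)


def element_bounds(
    mass: float, constraints: PredictionConstraints
) -> dict[str, int]:
    """Per-element maximum counts for a target neutral mass.

    Mass-scaled: floor(mass / element mass) + 1, clipped by the fixed
    caps for P and S; explicit ``max_counts`` entries override both.
    """
    bounds: dict[str, int] = {}
    for sym in constraints.elements:
        cap = int(mass / ELEMENTS[sym].monoisotopic_mass) + 1
        if sym in _FIXED_CAPS:
            cap = min(cap, _FIXED_CAPS[sym])
        if constraints.max_counts and sym in constraints.max_counts:
            cap = constraints.max_counts[sym]
        bounds[sym] = cap
    return bounds


def apply_golden_rules(
    f: Mapping[str, int],
    constraints: PredictionConstraints,
    bounds: Mapping[str, int] | None = None,
    target_mass: float | None = None,
) -> dict[str, bool]:
    """Per-rule verdicts for one formula.

    Keys: ``element_counts``, ``rdbe``, ``ratios``.  Disabled rules
    report True.  ``bounds`` defaults to the mass-scaled bounds at the
    formula's own mass.
    """
    verdicts = {"element_counts": True, "rdbe": True, "ratios": True}
    if constraints.check_element_counts:
        if bounds is None:
            m = target_mass if target_mass is not None else monoisotopic_mass(f)
            bounds = element_bounds(m, constraints)
        verdicts["element_counts"] = all(
            f.get(sym, 0) <= bounds.get(sym, f.get(sym, 0)) for sym in f
        )
    if constraints.check_rdbe:
        r = rdbe(f)
        ok = r >= 0
        if constraints.even_electron:
            ok = ok and float(r).is_integer()
        verdicts["rdbe"] = ok
    if constraints.check_ratios:
        c = f.get("C", 0)
        if c > 0:
            for sym, (lo, hi) in constraints.ratio_bounds.items():
                ratio = f.get(sym, 0) / c
                if not (lo <= ratio <= hi):
                    verdicts["ratios"] = False
                    break
    return verdicts


def enumerate_formulas(
    neutral_mass: float,
    constraints: PredictionConstraints = PredictionConstraints(),
    verbose: bool = False,
) -> list[FormulaCandidate]:
    """All formulas within tolerance of a neutral mass, rules applied.

    Complete within the element bounds: depth-first assignment of counts
    in decreasing element-mass order, pruning branches whose residual
    mass cannot be reached by the remaining elements.  Candidates are
    sorted by absolute ppm error (ties by Hill-formula string).  By
    default only candidates passing all enabled rules are returned;
    ``verbose=True`` keeps failures, with their per-rule flags.

    Raises :class:`CandidateOverflow` once more than ``max_candidates``
    in-window formulas accumulate — the tolerance or bounds are too wide
    to be useful.
    """
    if not 0 < neutral_mass <= constraints.max_mass:
        raise ValueError(
            f"neutral mass must lie in (0, {constraints.max_mass}] u"
        )
    tol = neutral_mass * constraints.ppm * 1e-6
    bounds = element_bounds(neutral_mass, constraints)
    order = sorted(
        constraints.elements,
        key=lambda s: ELEMENTS[s].monoisotopic_mass,
        reverse=True,
    )
    masses = [ELEMENTS[s].monoisotopic_mass for s in order]
    # max mass the elements from position i onward can still contribute
    suffix_max = [0.0] * (len(order) + 1)
    for i in range(len(order) - 1, -1, -1):
        suffix_max[i] = suffix_max[i + 1] + masses[i] * bounds[order[i]]

    found: list[FormulaCandidate] = []
    counts: dict[str, int] = {}

    def descend(i: int, residual: float) -> None:
        if residual < -tol or residual - tol > suffix_max[i]:
            return
        if i == len(order):
            if abs(residual) <= tol:
                _emit(residual)
            return
        sym, m = order[i], masses[i]
        if i == len(order) - 1:
            # closed form for the last (lightest) element
            k_lo = max(0, math.ceil((residual - tol) / m))
            k_hi = min(bounds[sym], math.floor((residual + tol) / m))
            for k in range(k_lo, k_hi + 1):
                if abs(residual - k * m) <= tol:
                    if k:
                        counts[sym] = k
                    _emit(residual - k * m)
                    counts.pop(sym, None)
            return
        for k in range(0, min(bounds[sym], int((residual + tol) / m)) + 1):
            if k:
                counts[sym] = k
            descend(i + 1, residual - k * m)
        counts.pop(sym, None)

    def _emit(residual: float) -> None:
        f = dict(counts)
        mass = neutral_mass - residual
        cand = FormulaCandidate(
            formula=f,
            mass=mass,
            ppm_error=1e6 * (neutral_mass - mass) / mass if mass else 0.0,
            rdbe=rdbe(f),
            rules=apply_golden_rules(f, constraints, bounds=bounds),
        )
        if len(found) >= constraints.max_candidates:
            raise CandidateOverflow(
                f"more than {constraints.max_candidates} candidate formulas "
                f"within {constraints.ppm} ppm of {neutral_mass:.4f} u; "
                "narrow the tolerance or element bounds"
            )
        found.append(cand)

    descend(0, neutral_mass)
    if not verbose:
        found = [c for c in found if c.passed]
    found.sort(key=lambda c: (abs(c.ppm_error), format_formula(c.formula)))
    return found
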