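"""Adduct and isotopologue variant generation.

Every compound in a searchable database is expanded into the ionic m/z
values of its adducts ([M+H]+, [M+Na]+, dimers, multiply charged forms,
...) and of the low-order heavy-isotope substitutions of each adduct
(13C1..3, 2H1, 15N1, 18O1, 34S1, 37Cl1).  The adduct m/z is

    m/z = (x*M + mass(added) - mass(removed) - q*m_e) / z

with ``x`` the molecular multiplier (2 for dimers), ``z`` the charge
magnitude, ``q = +z`` for positive and ``-z`` for negative ions, and
``m_e`` the electron mass — charge-corrected masses, since ppm-level
matching is sensitive to half a millidalton.

Isotopologue relative abundances use a per-element binomial model: for a
formula with ``n = x * count(element)`` substitutable atoms and heavy
fraction ``p``, the abundance of the k-substituted peak relative to the
main peak is ``C(n, k) * (p / (1 - p))**k``.  Cross-element doubly-heavy
species are not generated.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .chem import ELECTRON_MASS, Formula, monoisotopic_mass, parse_formula

__all__ = [
    "AdductRule",
    "IsotopeSpec",
    "VariantRecord",
    "DEFAULT_ADDUCTS",
    "DEFAULT_ISOTOPES",
    "adduct_mz",
    "isotope_variants",
    "enumerate_variants",
    "load_adduct_rules",
    "load_isotope_specs",
    "rules_by_name",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class AdductRule:
    """Symbolic ionization rule mapping a neutral mass to an ionic m/z."""

    name: str
    polarity: str  # "+" or "-"
    x: int = 1  # molecular multiplier (2M dimers)
    z: int = 1  # charge magnitude
    added: Mapping[str, int] = field(default_factory=dict)
    removed: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.polarity not in ("+", "-"):
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")
        if self.x < 1 or self.z < 1:
            raise ValueError("multiplier and charge must be positive integers")

    @property
    def charge(self) -> int:
        """Signed charge of the ion."""
        return self.z if self.polarity == "+" else -self.z

    @property
    def mass_offset(self) -> float:
        """mass(added) - mass(removed) - q*m_e, in u (before division by z)."""
        q = self.charge
        return (
            monoisotopic_mass(self.added)
            - monoisotopic_mass(self.removed)
            - q * ELECTRON_MASS
        )


@dataclass(frozen=True)
class IsotopeSpec:
    """One heavy-isotope substitution channel (e.g. 13C up to 3 copies)."""

    label: str
    element: str
    mass_shift: float  # u per substitution, > 0
    abundance: float  # heavy-isotope natural fraction, in (0, 1)
    n_max: int = 1

    def __post_init__(self) -> None:
        if not self.mass_shift > 0:
            raise ValueError("mass_shift must be positive")
        if not 0 < self.abundance < 1:
            raise ValueError("abundance must lie in (0, 1)")


@dataclass(frozen=True)
class VariantRecord:
    """One searchable (compound, adduct, isotopologue) row."""

    compound_id: str
    adduct: str
    isotope: str  # "M0" for the main peak, else e.g. "13C2"
    polarity: str
    mz: float
    charge: int
    abundance: float  # relative to the main peak; 1.0 for M0


def _r(name, polarity, x=1, z=1, added="", removed=""):
    return AdductRule(
        name, polarity, x, z,
        parse_formula(added) if added else {},
        parse_formula(removed) if removed else {},
    )


# Canonical adduct set (Fiehn-lab style), both polarities, |z| <= 2.
DEFAULT_ADDUCTS: tuple[AdductRule, ...] = (
    _r("[M+H]+", "+", added="H"),
    _r("[M+Na]+", "+", added="Na"),
    _r("[M+K]+", "+", added="K"),
    _r("[M+NH4]+", "+", added="NH4"),
    _r("[M+H-H2O]+", "+", added="H", removed="H2O"),
    _r("[M+2Na-H]+", "+", added="Na2", removed="H"),
    _r("[M+2H]2+", "+", z=2, added="H2"),
    _r("[M+H+Na]2+", "+", z=2, added="HNa"),
    _r("[2M+H]+", "+", x=2, added="H"),
    _r("[2M+Na]+", "+", x=2, added="Na"),
    _r("[M+CH3OH+H]+", "+", added="CH5O"),
    _r("[M+ACN+H]+", "+", added="C2H4N"),
    _r("[M-H]-", "-", removed="H"),
    _r("[M+Cl]-", "-", added="Cl"),
    _r("[M+FA-H]-", "-", added="CH2O2", removed="H"),
    _r("[M+Ac-H]-", "-", added="C2H4O2", removed="H"),
    _r("[M-2H]2-", "-", z=2, removed="H2"),
    _r("[M+Na-2H]-", "-", added="Na", removed="H2"),
    _r("[M+Br]-", "-", added="Br"),
    _r("[2M-H]-", "-", x=2, removed="H"),
)

# Heavy-isotope channels; shifts are heavy-minus-light monoisotopic masses
# from the pinned element table, abundances the heavy natural fractions.
DEFAULT_ISOTOPES: tuple[IsotopeSpec, ...] = (
    IsotopeSpec("13C", "C", 13.00335483780 - 12.0, 0.0107, n_max=3),
    IsotopeSpec("2H", "H", 2.01410177785 - 1.00782503207, 0.000115, n_max=1),
    IsotopeSpec("15N", "N", 15.00010889820 - 14.00307400480, 0.00364, n_max=1),
    IsotopeSpec("18O", "O", 17.99916100000 - 15.99491461956, 0.00205, n_max=1),
    IsotopeSpec("34S", "S", 33.96786690000 - 31.97207100000, 0.0425, n_max=1),
    IsotopeSpec("37Cl", "Cl", 36.96590259000 - 34.96885268000, 0.2424, n_max=1),
)


def rules_by_name(rules: Iterable[AdductRule] = DEFAULT_ADDUCTS) -> dict[str, AdductRule]:
    return {r.name: r for r in rules}


def adduct_mz(neutral_mass: float, rule: AdductRule) -> float:
    """Ionic m/z of the ``rule`` adduct of a neutral monoisotopic mass."""
    if neutral_mass < 0:
        raise ValueError("neutral mass must be non-negative")
    return (rule.x * neutral_mass + rule.mass_offset) / rule.z


def isotope_variants(
    formula: Mapping[str, int],
    base_mz: float,
    rule: AdductRule,
    specs: Sequence[IsotopeSpec] = DEFAULT_ISOTOPES,
    compound_id: str = "",
    abundance_floor: float = 1e-4,
) -> list[VariantRecord]:
    """Isotopologue records for one adduct of one neutral formula.

    ``formula`` is the neutral formula; substitutable atom counts are
    multiplied by the rule's ``x`` (a dimer has twice the carbons).
    Variants whose predicted relative abundance falls below
    ``abundance_floor`` are dropped.
    """
    out: list[VariantRecord] = []
    for spec in specs:
        n = rule.x * formula.get(spec.element, 0)
        if n == 0:
            continue
        odds = spec.abundance / (1.0 - spec.abundance)
        for k in range(1, spec.n_max + 1):
            if k > n:
                break
            rel = math.comb(n, k) * odds**k
            if rel < abundance_floor:
                break
            out.append(
                VariantRecord(
                    compound_id=compound_id,
                    adduct=rule.name,
                    isotope=f"{spec.label}{k}",
                    polarity=rule.polarity,
                    mz=base_mz + k * spec.mass_shift / rule.z,
                    charge=rule.charge,
                    abundance=min(rel, 1.0),
                )
            )
    return out


def enumerate_variants(
    compound_id: str,
    formula: Formula | str,
    rules: Sequence[AdductRule] = DEFAULT_ADDUCTS,
    specs: Sequence[IsotopeSpec] = DEFAULT_ISOTOPES,
    abundance_floor: float = 1e-4,
) -> list[VariantRecord]:
    """All adduct + isotopologue records for one compound.

    Order is deterministic: rule order, then isotope spec order, then
    substitution count.  Variants with non-positive m/z (possible for
    removal rules on very small molecules) are discarded with a warning.
    """
    if isinstance(formula, str):
        formula = parse_formula(formula)
    mass = monoisotopic_mass(formula)
    out: list[VariantRecord] = []
    for rule in rules:
        mz = adduct_mz(mass, rule)
        if mz <= 0:
            log.warning(
                "discarding %s variant of %s: non-positive m/z %.6f",
                rule.name, compound_id, mz,
            )
            continue
        out.append(
            VariantRecord(compound_id, rule.name, "M0", rule.polarity, mz,
                          rule.charge, 1.0)
        )
        out.extend(
            isotope_variants(formula, mz, rule, specs, compound_id,
                             abundance_floor)
        )
    return out


def load_adduct_rules(path) -> list[AdductRule]:
    """Read adduct rules from a delimited text file.

    Columns (header required, comma or tab separated): name, polarity, x,
    z, added, removed.  ``added``/``removed`` are formula strings and may
    be empty.
    """
    rules = []
    with open(path, newline="", encoding="utf-8") as fh:
        dialect = csv.Sniffer().sniff(fh.read(2048), delimiters=",\t")
        fh.seek(0)
        for row in csv.DictReader(fh, dialect=dialect):
            rules.append(
                AdductRule(
                    name=row["name"].strip(),
                    polarity=row["polarity"].strip(),
                    x=int(row.get("x") or 1),
                    z=int(row.get("z") or 1),
                    added=parse_formula(row.get("added") or ""),
                    removed=parse_formula(row.get("removed") or ""),
                )
            )
    names = [r.name for r in rules]
    if len(set(names)) != len(names):
        raise ValueError("duplicate adduct rule names in file")
    return rules


def load_isotope_specs(path) -> list[IsotopeSpec]:
    """Read isotope specs from a delimited text file.

    Columns: label, element, mass_shift, abundance, n_max.
    """
    specs = []
    with open(path, newline="", encoding="utf-8") as fh:
        dialect = csv.Sniffer().sniff(fh.read(2048), delimiters=",\t")
        fh.seek(0)
        for row in csv.DictReader(fh, dialect=dialect):
            specs.append(
                IsotopeSpec(
                    label=row["label"].strip(),
                    element=row["element"].strip(),
                    mass_shift=float(row["mass_shift"]),
                    abundance=float(row["abundance"]),
                    n_max=int(row.get("n_max") or 1),
                )
            )
    return specs
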