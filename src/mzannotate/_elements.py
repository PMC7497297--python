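"""Pinned element data.

Monoisotopic masses and isotopic abundances follow the IUPAC/CIAAW 2013
atomic-mass evaluation (rounded at the 1e-8 u level); the table version
string below is recorded in every database build so stored m/z values can
be traced to the constants that produced them.

Valences are the fixed common oxidation-state valences used for
ring-plus-double-bond arithmetic (hypervalent states are deliberately not
modelled there).
"""

from __future__ import annotations

from dataclasses import dataclass

ELEMENT_TABLE_VERSION = "CIAAW-2013/mzannotate-1"

#: Electron rest mass, unified atomic mass units (CODATA).
ELECTRON_MASS = 0.000548579909


@dataclass(frozen=True)
class Element:
    """One chemical element: monoisotopic mass, stable isotopes, valence.

    ``isotopes`` is a list of ``(mass_u, abundance_fraction)`` pairs; the
    monoisotopic mass equals the mass of the most abundant isotope and the
    abundances sum to 1 within 1e-6.
    """

    symbol: str
    monoisotopic_mass: float
    isotopes: tuple[tuple[float, float], ...]
    valence: int


def _e(symbol, mass, isotopes, valence):
    return Element(symbol, mass, tuple(isotopes), valence)


ELEMENTS: dict[str, Element] = {
    "H": _e("H", 1.00782503207,
            [(1.00782503207, 0.999885), (2.01410177785, 0.000115)], 1),
    "C": _e("C", 12.0,
            [(12.0, 0.9893), (13.00335483780, 0.0107)], 4),
    "N": _e("N", 14.00307400480,
            [(14.00307400480, 0.99636), (15.00010889820, 0.00364)], 3),
    "O": _e("O", 15.99491461956,
            [(15.99491461956, 0.99757), (16.99913170000, 0.00038),
             (17.99916100000, 0.00205)], 2),
    "P": _e("P", 30.97376163000,
            [(30.97376163000, 1.0)], 3),
    "S": _e("S", 31.97207100000,
            [(31.97207100000, 0.9499), (32.97145876000, 0.0075),
             (33.96786690000, 0.0425), (35.96708076000, 0.0001)], 2),
    "Na": _e("Na", 22.98976928090,
             [(22.98976928090, 1.0)], 1),
    "K": _e("K", 38.96370668000,
            [(38.96370668000, 0.932581), (39.96399848000, 0.000117),
             (40.96182576000, 0.067302)], 1),
    "Cl": _e("Cl", 34.96885268000,
             [(34.96885268000, 0.7576), (36.96590259000, 0.2424)], 1),
    "Br": _e("Br", 78.91833710000,
             [(78.91833710000, 0.5069), (80.91629060000, 0.4931)], 1),
    "F": _e("F", 18.99840322000,
            [(18.99840322000, 1.0)], 1),
    "I": _e("I", 126.90447300000,
            [(126.90447300000, 1.0)], 1),
    "Si": _e("Si", 27.97692653250,
             [(27.97692653250, 0.92223), (28.97649470000, 0.04685),
              (29.97377017000, 0.03092)], 4),
}
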