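"""ppm-tolerance search against an extended variant database.

The error margin is relative: a query at tolerance ``t`` ppm matches every
stored theoretical m/z inside the closed window
``[mz*(1 - t*1e-6), mz*(1 + t*1e-6)]``.  Hits are sorted by absolute
signed ppm error, with deterministic lexicographic tie-breaking, and can
be re-ranked to put main-peak (M0) and plain (de)protonated adducts first
for follow-up prioritization.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Iterable, Sequence

from .dbbuild import ExtendedDB

__all__ = [
    "SearchQuery",
    "SearchHit",
    "ppm_window",
    "ppm_error",
    "search",
    "batch_search",
    "prioritize",
]

#: Adducts that rank first during prioritization: plain protonation and
#: deprotonation, ahead of salts, dimers and losses.
PRIMARY_ADDUCTS = frozenset({"[M+H]+", "[M-H]-"})


@dataclass(frozen=True)
class SearchQuery:
    """One measured m/z value plus search options."""

    mz: float
    ppm: float = 2.0
    polarity: str = "both"  # "+", "-" or "both"
    sources: tuple[str, ...] | None = None  # None = all source databases
    main_peak_only: bool = False

    def __post_init__(self):
        if not self.mz > 0:
            raise ValueError("query m/z must be positive")
        if not self.ppm > 0:
            raise ValueError("ppm tolerance must be positive")
        if self.polarity not in ("+", "-", "both"):
            raise ValueError(f"polarity must be '+', '-' or 'both', got {self.polarity!r}")


@dataclass(frozen=True)
class SearchHit:
    """One annotation candidate for a query m/z."""

    query_mz: float
    source: str
    compound_id: str
    name: str
    formula: str
    adduct: str
    isotope: str
    theoretical_mz: float
    ppm_error: float  # signed: 1e6 * (query - theoretical) / theoretical


def ppm_window(mz: float, ppm: float) -> tuple[float, float]:
    """Closed search interval around ``mz`` at relative tolerance ``ppm``."""
    if not (mz > 0 and ppm > 0):
        raise ValueError("mz and ppm must be positive")
    half = mz * ppm * 1e-6
    return mz - half, mz + half


def ppm_error(query_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    return 1e6 * (query_mz - theoretical_mz) / theoretical_mz


def _hit_sort_key(h: SearchHit):
    return (abs(h.ppm_error), h.source, h.compound_id, h.adduct)


def search(db: ExtendedDB, q: SearchQuery) -> list[SearchHit]:
    """All variant rows matching the query, best mass accuracy first.

    The (polarity, m/z) index turns the ppm window into a range scan;
    both window boundaries are included.  With ``main_peak_only`` set,
    isotopologue rows (isotope label != "M0") are removed before ranking.
    Raises if the requested source selection matches no database.
    """
    lo, hi = ppm_window(q.mz, q.ppm)
    sql = (
        "SELECT v.source, v.compound_id, c.name, c.formula, v.adduct,"
        " v.isotope, v.mz FROM variants v"
        " JOIN compounds c ON c.source = v.source AND c.id = v.compound_id"
        " WHERE v.mz BETWEEN ? AND ?"
    )
    params: list = [lo, hi]
    if q.polarity != "both":
        sql += " AND v.polarity = ?"
        params.append(q.polarity)
    if q.sources is not None:
        if not q.sources:
            raise ValueError("no source databases selected")
        unknown = set(q.sources) - set(db.sources)
        if unknown:
            raise ValueError(f"unknown source database(s): {sorted(unknown)}")
        sql += f" AND v.source IN ({','.join('?' * len(q.sources))})"
        params.extend(q.sources)
    if q.main_peak_only:
        sql += " AND v.isotope = 'M0'"

    with db.connect() as con:
        rows = con.execute(sql, params).fetchall()

    hits = [
        SearchHit(q.mz, source, cid, name, formula, adduct, isotope, mz,
                  ppm_error(q.mz, mz))
        for source, cid, name, formula, adduct, isotope, mz in rows
    ]
    hits.sort(key=_hit_sort_key)
    return hits


def batch_search(
    db: ExtendedDB,
    queries: Sequence[SearchQuery],
    workers: int = 1,
) -> dict[SearchQuery, list[SearchHit] | Exception]:
    """Search many queries, optionally in parallel.

    Results are keyed by query, identical to running :func:`search`
    serially regardless of worker count.  A query that raises stores its
    exception instead of aborting the rest of the batch.
    """
    def one(q: SearchQuery):
        try:
            return search(db, q)
        except Exception as exc:  # propagated per-query
            return exc

    if workers <= 1:
        results = [one(q) for q in queries]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(one, queries))
    return dict(zip(queries, results))


def prioritize(hits: Iterable[SearchHit]) -> list[SearchHit]:
    """Stable re-ranking for follow-up: isotope and adduct status first.

    Main-peak (M0) hits come before isotopologues; within each, plain
    protonated/deprotonated adducts before salts, dimers and losses;
    within that, smallest absolute ppm error first.
    """
    return sorted(
        hits,
        key=lambda h: (
            h.isotope != "M0",
            h.adduct not in PRIMARY_ADDUCTS,
            abs(h.ppm_error),
            h.source,
            h.compound_id,
            h.adduct,
        ),
    )
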