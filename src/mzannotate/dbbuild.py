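"""Compound-table import, deduplication, and extended-database build.

A compound table (CSV/TSV with at least identifier, name and formula
columns) is expanded into a single-file SQLite database of variant m/z
rows, indexed on (polarity, m/z) so ppm-window queries are range scans.

Deduplication semantics: records sharing an identical SMILES string are
collapsed into one row whose synonym list is the union of all names;
records with equal molecular formulas but distinct structures stay
separate; records without a SMILES are never merged.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sqlite3
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import adducts as _ad
from .adducts import AdductRule, IsotopeSpec, enumerate_variants
from .chem import ELEMENT_TABLE_VERSION, FormulaError, parse_formula

__all__ = [
    "CompoundRecord",
    "ExtendedDB",
    "BuildReport",
    "import_user_db",
    "normalize_compounds",
    "build_extended",
]

log = logging.getLogger(__name__)


@dataclass
class CompoundRecord:
    """One neutral compound as imported from a source table."""

    identifier: str
    name: str
    formula: str
    smiles: str = ""
    description: str = ""
    source: str = "user"
    synonyms: list[str] = field(default_factory=list)


def import_user_db(path, source_label: str = "user") -> list[CompoundRecord]:
    """Read a delimited compound table into records.

    The header must name at least ``identifier`` (or ``id``), ``name``
    and ``formula`` columns (case-insensitive); ``smiles``,
    ``description`` and ``synonyms`` (semicolon-separated) are optional.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    cols = {c.lower().strip(): c for c in df.columns}

    def col(*names):
        for n in names:
            if n in cols:
                return cols[n]
        return None

    id_col = col("identifier", "id", "compound_id")
    missing = [label for label, c in
               (("identifier", id_col), ("name", col("name")),
                ("formula", col("formula"))) if c is None]
    if missing:
        raise ValueError(f"compound table {path} missing mandatory column(s): "
                         + ", ".join(missing))

    ids = df[id_col].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate identifiers in {path}: {', '.join(dupes)}")

    records = []
    for _, row in df.iterrows():
        syn_raw = row[col("synonyms")] if col("synonyms") else ""
        records.append(
            CompoundRecord(
                identifier=row[id_col].strip(),
                name=row[col("name")].strip(),
                formula=row[col("formula")].strip(),
                smiles=(row[col("smiles")].strip() if col("smiles") else ""),
                description=(row[col("description")].strip()
                             if col("description") else ""),
                source=source_label,
                synonyms=[s.strip() for s in syn_raw.split(";") if s.strip()],
            )
        )
    return records


def _canonical_smiles(smiles: str) -> str:
    from rdkit import Chem  # optional dependency

    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToSmiles(mol) if mol is not None else smiles


def normalize_compounds(
    records: Iterable[CompoundRecord], canonicalize: bool = False
) -> list[CompoundRecord]:
    """Collapse synonymous records that share an identical SMILES string.

    The first-seen record provides the display name and identifier; the
    merged synonym list is the case-insensitive union of all names and
    synonyms (minus the display name); descriptions are concatenated and
    deduplicated.  SMILES comparison is exact-string by default;
    ``canonicalize=True`` routes through RDKit canonical SMILES first.
    Records lacking a SMILES pass through unmerged.
    """
    out: list[CompoundRecord] = []
    by_smiles: dict[str, CompoundRecord] = {}
    for rec in records:
        key = rec.smiles
        if key and canonicalize:
            key = _canonical_smiles(key)
        if not key:
            out.append(replace(rec, synonyms=list(rec.synonyms)))
            continue
        merged = by_smiles.get(key)
        if merged is None:
            merged = replace(rec, synonyms=list(rec.synonyms))
            by_smiles[key] = merged
            out.append(merged)
            continue
        seen = {merged.name.lower()} | {s.lower() for s in merged.synonyms}
        for candidate in [rec.name, *rec.synonyms]:
            if candidate.lower() not in seen:
                merged.synonyms.append(candidate)
                seen.add(candidate.lower())
        if rec.description and rec.description not in merged.description:
            merged.description = (
                f"{merged.description} | {rec.description}"
                if merged.description else rec.description
            )
    return out


@dataclass
class BuildReport:
    n_compounds: int
    n_variants: int
    skipped: list[tuple[str, str]]  # (identifier, reason)


_SCHEMA = """
CREATE TABLE compounds (
    id TEXT NOT NULL,
    name TEXT,
    synonyms TEXT,
    formula TEXT,
    smiles TEXT,
    description TEXT,
    source TEXT NOT NULL,
    PRIMARY KEY (source, id)
);
CREATE TABLE variants (
    compound_id TEXT NOT NULL,
    source TEXT NOT NULL,
    adduct TEXT NOT NULL,
    isotope TEXT NOT NULL,
    polarity TEXT NOT NULL,
    mz REAL NOT NULL CHECK (mz > 0),
    charge INTEGER NOT NULL,
    abundance REAL NOT NULL,
    FOREIGN KEY (source, compound_id)
        REFERENCES compounds (source, id) ON DELETE CASCADE
);
CREATE INDEX idx_variants_pol_mz ON variants (polarity, mz);
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
"""


class ExtendedDB:
    """Handle to a built single-file variant database."""

    def __init__(self, path):
        self.path = Path(path)
        if not self.path.exists():
            raise FileNotFoundError(f"no database at {self.path}")

    def connect(self) -> sqlite3.Connection:
        con = sqlite3.connect(self.path)
        con.execute("PRAGMA foreign_keys = ON")
        return con

    @property
    def metadata(self) -> dict[str, str]:
        with self.connect() as con:
            return dict(con.execute("SELECT key, value FROM meta"))

    @property
    def sources(self) -> list[str]:
        with self.connect() as con:
            return [r[0] for r in
                    con.execute("SELECT DISTINCT source FROM compounds ORDER BY source")]

    def n_variants(self) -> int:
        with self.connect() as con:
            return con.execute("SELECT COUNT(*) FROM variants").fetchone()[0]

    def delete_compound(self, source: str, identifier: str) -> None:
        """Remove a compound; its variant rows cascade away."""
        with self.connect() as con:
            con.execute("DELETE FROM compounds WHERE source=? AND id=?",
                        (source, identifier))


def _ruleset_hash(rules: Sequence[AdductRule], specs: Sequence[IsotopeSpec]) -> str:
    blob = json.dumps(
        [[r.name, r.polarity, r.x, r.z, sorted(r.added.items()),
          sorted(r.removed.items())] for r in rules]
        + [[s.label, s.element, s.mass_shift, s.abundance, s.n_max]
           for s in specs],
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_extended(
    compounds: Iterable[CompoundRecord],
    rules: Sequence[AdductRule] = _ad.DEFAULT_ADDUCTS,
    specs: Sequence[IsotopeSpec] = _ad.DEFAULT_ISOTOPES,
    store_path="extended.db",
    abundance_floor: float = 1e-4,
) -> tuple[ExtendedDB, BuildReport]:
    """Expand compounds into variant rows and store them in SQLite.

    Rebuilding on an existing path replaces the store (idempotent, never
    appends).  Compounds with unparseable formulas are skipped and listed
    in the report; if more than half fail to parse the build aborts,
    since that signals a malformed input table rather than a few bad rows.
    """
    compounds = list(compounds)
    store_path = Path(store_path)
    if store_path.exists():
        store_path.unlink()

    skipped: list[tuple[str, str]] = []
    parsed = []
    for rec in compounds:
        try:
            parsed.append((rec, parse_formula(rec.formula)))
        except FormulaError as exc:
            skipped.append((rec.identifier, str(exc)))
            log.warning("skipping compound %s: %s", rec.identifier, exc)
    if compounds and len(skipped) > len(compounds) / 2:
        raise ValueError(
            f"{len(skipped)}/{len(compounds)} compounds have unparseable "
            "formulas; refusing to build from a malformed table"
        )

    con = sqlite3.connect(store_path)
    try:
        con.executescript(_SCHEMA)
        n_variants = 0
        for rec, formula in parsed:
            con.execute(
                "INSERT INTO compounds VALUES (?,?,?,?,?,?,?)",
                (rec.identifier, rec.name, ";".join(rec.synonyms), rec.formula,
                 rec.smiles, rec.description, rec.source),
            )
            rows = enumerate_variants(rec.identifier, formula, rules, specs,
                                      abundance_floor)
            con.executemany(
                "INSERT INTO variants VALUES (?,?,?,?,?,?,?,?)",
                [(v.compound_id, rec.source, v.adduct, v.isotope, v.polarity,
                  v.mz, v.charge, v.abundance) for v in rows],
            )
            n_variants += len(rows)
        per_source = dict(con.execute(
            "SELECT source, COUNT(*) FROM compounds GROUP BY source"))
        meta = {
            "element_table_version": ELEMENT_TABLE_VERSION,
            "ruleset_hash": _ruleset_hash(rules, specs),
            "n_compounds": str(len(parsed)),
            "n_variants": str(n_variants),
            "n_skipped": str(len(skipped)),
            "per_source_counts": json.dumps(per_source, sort_keys=True),
        }
        con.executemany("INSERT INTO meta VALUES (?,?)", meta.items())
        con.commit()
    finally:
        con.close()

    return ExtendedDB(store_path), BuildReport(len(parsed), n_variants, skipped)
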