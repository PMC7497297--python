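"""Readers and writers for peak tables, metadata and search results.

Peak tables are delimited text with samples as rows: the first column
holds sample identifiers, the remaining headers are m/z values optionally
suffixed with a polarity sign ("263.1117+").  Empty cells and "NA" are
missing values; literal zeros are data.  Metadata tables carry a sample
identifier column ("sample", MetaboLights-style "Sample Name", or the
first column) plus one or more experimental variables; fully numeric
columns are typed numeric, everything else categorical.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping

import pandas as pd

from .stats import MetadataTable, PeakTable

__all__ = [
    "read_peak_table",
    "read_metadata",
    "read_query_list",
    "write_hits",
]

_NA_VALUES = ["", "NA", "NaN", "nan"]

_ID_HEADERS = ("sample", "sample name", "sample_name", "sample id", "sample_id")


def _read_delimited(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                       na_values=_NA_VALUES)


def read_peak_table(path, transpose: bool = False) -> PeakTable:
    """Read a samples x m/z intensity matrix.

    ``transpose=True`` accepts the features-as-rows orientation.  Raises
    naming the offending column for unparseable feature headers, and for
    duplicate sample identifiers.
    """
    df = _read_delimited(path)
    if df.shape[1] < 2:
        raise ValueError(f"peak table {path} needs an id column plus features")
    df = df.set_index(df.columns[0])
    df.index.name = "sample"
    if transpose:
        df = df.T
    for col in df.columns:
        try:
            PeakTable.feature_mz(col)
        except ValueError as exc:
            raise ValueError(f"bad feature header in {path}: {exc}") from None
    return PeakTable(df.apply(pd.to_numeric))


def read_metadata(path) -> MetadataTable:
    """Read a sample metadata table with typed variable columns."""
    df = _read_delimited(path)
    if df.shape[1] < 2:
        raise ValueError(
            f"metadata table {path} needs a sample column plus >=1 variable"
        )
    id_col = next((c for c in df.columns if c.strip().lower() in _ID_HEADERS),
                  df.columns[0])
    df = df.set_index(id_col)
    df.index.name = "sample"
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.notna().all() and df[col].notna().all():
            df[col] = numeric
    return MetadataTable(df)


def read_query_list(path) -> list[tuple[float, str]]:
    """Read query m/z values: CSV with mz[,polarity] columns, or a bare
    newline-separated list.  Returns (mz, polarity) pairs, polarity
    defaulting to 'both'."""
    path = Path(path)
    text = path.read_text(encoding="utf-8").strip()
    if not text:
        return []
    first = text.splitlines()[0]
    out: list[tuple[float, str]] = []
    if "," in first or first.strip().lower().startswith("mz"):
        df = pd.read_csv(path, dtype=str)
        cols = {c.lower().strip(): c for c in df.columns}
        if "mz" not in cols:
            raise ValueError(f"query file {path} has no 'mz' column")
        for _, row in df.iterrows():
            pol = row.get(cols.get("polarity", ""), "both")
            pol = pol if isinstance(pol, str) and pol in ("+", "-") else "both"
            out.append((float(row[cols["mz"]]), pol))
    else:
        out = [(float(line), "both") for line in text.splitlines() if line.strip()]
    for mz, _ in out:
        if mz <= 0:
            raise ValueError(f"non-positive query m/z {mz} in {path}")
    return out


def write_hits(hits_by_query: Mapping, path_or_file) -> None:
    """Write ranked search hits as TSV, one row per (query, hit).

    ``path_or_file`` is a filesystem path or an open text stream.
    """
    cols = ["query_mz", "source", "compound_id", "name", "formula", "adduct",
            "isotope", "theoretical_mz", "ppm_error", "rank"]
    if hasattr(path_or_file, "write"):
        _write_hit_rows(path_or_file, cols, hits_by_query)
        return
    with open(path_or_file, "w", newline="", encoding="utf-8") as fh:
        _write_hit_rows(fh, cols, hits_by_query)


def _write_hit_rows(fh, cols, hits_by_query) -> None:
    w = csv.writer(fh, delimiter="\t")
    w.writerow(cols)
    for query, hits in hits_by_query.items():
        if isinstance(hits, Exception):
            continue
        for rank, h in enumerate(hits, start=1):
            w.writerow([
                f"{h.query_mz:.6f}", h.source, h.compound_id, h.name,
                h.formula, h.adduct, h.isotope,
                f"{h.theoretical_mz:.6f}", f"{h.ppm_error:.4f}", rank,
            ])
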