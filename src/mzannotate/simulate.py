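"""Synthetic data generators.

Everything in the test surface can be exercised without downloads:
random compound tables (with controllable duplicate injection to stress
deduplication), evenly stratified query pools over the 60-600 m/z range,
two-group case/control peak experiments with planted differential
features, and a database-size scaling harness that reports (but never
asserts on) per-query search timings.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import string
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import adducts as _ad
from .chem import format_formula, monoisotopic_mass
from .dbbuild import CompoundRecord, build_extended
from .formula import PredictionConstraints, apply_golden_rules
from .search import SearchQuery, search
from .stats import MetadataTable, PeakTable

__all__ = [
    "SimSpec",
    "demo_compounds",
    "gen_compound_db",
    "gen_query_pool",
    "gen_peak_experiment",
    "scaling_harness",
]


@dataclass(frozen=True)
class SimSpec:
    """Study design for a synthetic two-group case/control experiment.

    Intensities are log-normal: per-feature log10 means drawn uniformly
    from ``log_mean_range`` and log10 standard deviations from
    ``log_sd_range``.  Planted features have their case-group log-mean
    shifted by ``effect`` standard deviations.  Missing values are
    injected completely at random at ``missing_rate``.
    """

    n_samples_per_group: int = 20
    n_features: int = 200
    n_planted: int = 10
    effect: float = 2.0  # in units of per-feature sd (log scale)
    missing_rate: float = 0.0
    log_mean_range: tuple[float, float] = (4.0, 6.0)
    log_sd_range: tuple[float, float] = (0.2, 0.6)
    mz_range: tuple[float, float] = (60.0, 600.0)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_samples_per_group, self.n_features) < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.n_planted <= self.n_features:
            raise ValueError("n_planted must lie in [0, n_features]")
        if self.effect < 0:
            raise ValueError("effect size must be non-negative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must lie in [0, 1)")


def demo_compounds() -> list[CompoundRecord]:
    """A small curated metabolite table for worked examples and demos.

    Includes creatine riboside (the classic urinary lung-cancer marker
    whose protonated ion is the nominal 264 m/z feature), its relatives,
    and a glucose/fructose pair that exercises the formula-vs-structure
    deduplication semantics.
    """
    rows = [
        ("DEMO001", "Creatine riboside", "C9H17N3O6",
         "CN(CC(=O)O)C(=N)NC1OC(CO)C(O)C1O",
         "Riboside conjugate of creatine; urinary marker."),
        ("DEMO002", "Creatine", "C4H9N3O2", "CN(CC(=O)O)C(=N)N",
         "Energy-buffer metabolite of muscle."),
        ("DEMO003", "D-Glucose", "C6H12O6", "OCC1OC(O)C(O)C(O)C1O",
         "Hexose sugar, blood glucose."),
        ("DEMO004", "D-Fructose", "C6H12O6", "OCC1(O)OCC(O)C(O)C1O",
         "Ketohexose isomer of glucose."),
        ("DEMO005", "Caffeine", "C8H10N4O2", "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
         "Methylxanthine stimulant."),
        ("DEMO006", "L-Alanine", "C3H7NO2", "CC(N)C(=O)O",
         "Proteinogenic amino acid."),
    ]
    return [
        CompoundRecord(identifier=i, name=n, formula=f, smiles=s,
                       description=d, source="demo")
        for i, n, f, s, d in rows
    ]


_SMILES_ALPHABET = "CNOPS" + string.digits[1:4] + "()="


def _fake_smiles(rng: np.random.Generator) -> str:
    """Synthetic structure key in SMILES-like alphabet (not chemistry)."""
    n = int(rng.integers(8, 20))
    return "".join(rng.choice(list(_SMILES_ALPHABET), size=n))


def _random_formula(rng: np.random.Generator, mass_range) -> dict | None:
    c = int(rng.integers(2, 28))
    h = int(round(c * rng.uniform(0.3, 3.0)))
    f = {"C": c, "H": max(h, 1)}
    for sym, hi in (("N", min(4, c)), ("O", min(8, c)), ("P", 2), ("S", 2)):
        k = int(rng.integers(0, hi + 1))
        if sym in ("P", "S") and rng.random() > 0.15:
            k = 0
        if k:
            f[sym] = k
    mass = monoisotopic_mass(f)
    if not mass_range[0] <= mass <= mass_range[1]:
        return None
    if not all(apply_golden_rules(f, PredictionConstraints()).values()):
        return None
    return f


def gen_compound_db(
    n: int = 500,
    seed: int = 0,
    mass_range: tuple[float, float] = (60.0, 600.0),
    dup_smiles_pairs: int = 0,
    dup_formula_pairs: int = 0,
    source: str = "synthetic",
) -> list[CompoundRecord]:
    """Random compound table of ``n`` plausible neutral formulas.

    Formulas are drawn by rejection sampling so every one passes the
    element-ratio and valence rules and has a neutral mass in
    ``mass_range``.  ``dup_smiles_pairs`` appends records duplicating an
    existing structure key under a new name (must merge);
    ``dup_formula_pairs`` appends records sharing a formula but carrying
    a distinct structure key (must stay separate).
    """
    rng = np.random.default_rng(seed)
    records: list[CompoundRecord] = []
    attempts = 0
    while len(records) < n:
        attempts += 1
        if attempts > 200 * n:
            raise RuntimeError(
                "rejection sampling failed to produce valid formulas; "
                "bounds or mass range too restrictive"
            )
        f = _random_formula(rng, mass_range)
        if f is None:
            continue
        i = len(records) + 1
        records.append(
            CompoundRecord(
                identifier=f"SIM{i:06d}",
                name=f"synthetic compound {i}",
                formula=format_formula(f),
                smiles=_fake_smiles(rng),
                description="synthetic test compound",
                source=source,
            )
        )
    for j in range(dup_smiles_pairs):
        base = records[int(rng.integers(0, n))]
        records.append(
            CompoundRecord(
                identifier=f"SIMDUPS{j:04d}",
                name=f"alias of {base.name}",
                formula=base.formula,
                smiles=base.smiles,
                source=source,
            )
        )
    for j in range(dup_formula_pairs):
        base = records[int(rng.integers(0, n))]
        records.append(
            CompoundRecord(
                identifier=f"SIMDUPF{j:04d}",
                name=f"isomer of {base.name}",
                formula=base.formula,
                smiles=_fake_smiles(rng),
                source=source,
            )
        )
    return records


def gen_query_pool(
    n: int = 100, lo: float = 60.0, hi: float = 600.0, seed: int = 0
) -> np.ndarray:
    """``n`` query m/z values evenly distributed over [lo, hi].

    Stratified: one uniform draw inside each of ``n`` equal-width bins,
    so the pool is even across the range but not gridded.
    """
    if n < 1 or not lo < hi:
        raise ValueError("need n >= 1 and lo < hi")
    rng = np.random.default_rng(seed)
    edges = np.linspace(lo, hi, n + 1)
    return edges[:-1] + rng.uniform(0.0, 1.0, size=n) * np.diff(edges)


def gen_peak_experiment(
    spec: SimSpec,
) -> tuple[PeakTable, MetadataTable, pd.DataFrame]:
    """Two-group log-normal peak experiment with planted effects.

    Returns (peak table, metadata with a ``group`` variable taking
    levels 'control'/'case', truth table flagging planted features).
    """
    rng = np.random.default_rng(spec.seed)
    n_per, n_feat = spec.n_samples_per_group, spec.n_features

    mz = np.sort(rng.uniform(*spec.mz_range, size=n_feat))
    features = [f"{v:.4f}+" for v in mz]
    samples = [f"S{i + 1:04d}" for i in range(2 * n_per)]
    groups = ["control"] * n_per + ["case"] * n_per

    mu = rng.uniform(*spec.log_mean_range, size=n_feat)
    sd = rng.uniform(*spec.log_sd_range, size=n_feat)
    planted_idx = rng.choice(n_feat, size=spec.n_planted, replace=False)

    log_int = rng.normal(mu, sd, size=(2 * n_per, n_feat))
    log_int[n_per:, planted_idx] += spec.effect * sd[planted_idx]
    intensities = 10.0 ** log_int

    if spec.missing_rate > 0:
        mask = rng.random(intensities.shape) < spec.missing_rate
        intensities[mask] = np.nan

    pt = PeakTable(pd.DataFrame(intensities, index=samples, columns=features))
    meta = MetadataTable(pd.DataFrame({"group": groups}, index=pd.Index(samples, name="sample")))
    truth = pd.DataFrame(
        {
            "feature": features,
            "planted": [i in set(planted_idx) for i in range(n_feat)],
        }
    )
    return pt, meta, truth


def scaling_harness(
    db_sizes: Sequence[int],
    pool: Sequence[float],
    ppm: float = 2.0,
    store_dir=".",
    seed: int = 0,
    polarity: str = "+",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Query-latency report over nested databases of increasing size.

    Builds one compound pool at the largest size and nested prefix
    databases, then times each query m/z in ``pool`` against each.
    Returns (summary, detail): summary has one row per size with median
    latency and match statistics; detail one row per (size, query).
    Timings are reported, never asserted — they are hardware-bound.
    """
    db_sizes = list(db_sizes)
    if sorted(db_sizes) != db_sizes:
        raise ValueError("db_sizes must be ascending")
    store_dir = Path(store_dir)
    compounds = gen_compound_db(max(db_sizes) if db_sizes else 0, seed=seed)
    detail_rows = []
    for size in db_sizes:
        db, report = build_extended(
            compounds[:size], store_path=store_dir / f"scaling_{size}.db"
        )
        for mz in pool:
            q = SearchQuery(mz=float(mz), ppm=ppm, polarity=polarity)
            t0 = time.perf_counter()
            hits = search(db, q)
            detail_rows.append(
                {
                    "n_compounds": size,
                    "n_rows": report.n_variants,
                    "query_mz": float(mz),
                    "n_matches": len(hits),
                    "latency_s": time.perf_counter() - t0,
                }
            )
    detail = pd.DataFrame(
        detail_rows,
        columns=["n_compounds", "n_rows", "query_mz", "n_matches", "latency_s"],
    )
    if detail.empty:
        return detail.copy(), detail
    summary = (
        detail.groupby(["n_compounds", "n_rows"], as_index=False)
        .agg(
            median_latency_s=("latency_s", "median"),
            mean_matches=("n_matches", "mean"),
            total_matches=("n_matches", "sum"),
        )
    )
    return summary, detail
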