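"""Minimal statistics: from a peak table to ranked significant features.

The pipeline mirrors the standard untargeted-metabolomics sequence:
normalize (sample-wise total-sum or median, optional log10(x+1)
transform, optional pareto/auto scaling), impute missing intensities,
then per-feature two-group testing (Welch or paired t) with
Benjamini-Hochberg FDR control, plus fold changes on the raw intensity
scale for volcano plots and a hypergeometric test for the significance
of overlap between two hit lists.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PeakTable",
    "MetadataTable",
    "normalize",
    "impute_missing",
    "ttest_all",
    "fold_change",
    "volcano_table",
    "hypergeom_overlap",
    "subset_samples",
]

_FEATURE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*([+-]?)\s*$")


@dataclass
class PeakTable:
    """Samples x features intensity matrix.

    ``data`` is indexed by sample identifier; columns are feature
    identifiers, conventionally the measured m/z as a decimal string with
    an optional trailing polarity sign (e.g. ``"263.1117+"``).  Missing
    intensities are NaN, which is distinct from a measured zero.
    """

    data: pd.DataFrame

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate sample identifiers: {list(dupes)}")
        for col in self.data.columns:
            self.feature_mz(col)  # validates

    @staticmethod
    def feature_mz(feature_id: str) -> tuple[float, str]:
        """Parse a feature identifier into (m/z, polarity); polarity may be ''."""
        m = _FEATURE_RE.match(str(feature_id))
        if m is None or float(m.group(1)) <= 0:
            raise ValueError(
                f"feature identifier {feature_id!r} is not a positive m/z "
                "with optional +/- polarity suffix"
            )
        return float(m.group(1)), m.group(2)

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class MetadataTable:
    """Per-sample experimental variables, indexed by sample identifier."""

    data: pd.DataFrame

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate sample identifiers: {list(dupes)}")

    def check_matches(self, pt: PeakTable) -> None:
        """Require exact agreement between peak-table and metadata samples."""
        missing = sorted(set(pt.samples) - set(self.data.index))
        extra = sorted(set(self.data.index) - set(pt.samples))
        if missing or extra:
            raise ValueError(
                "sample mismatch between peak table and metadata; "
                f"missing from metadata: {missing}; extra in metadata: {extra}"
            )

    def levels(self, variable: str) -> list:
        col = self.data[variable]
        if isinstance(col.dtype, pd.CategoricalDtype):
            return [l for l in col.cat.categories if l in set(col)]
        return list(pd.unique(col.dropna()))


def normalize(
    pt: PeakTable,
    method: str = "none",
    transform: str = "none",
    scale: str = "none",
) -> PeakTable:
    """Sample normalization, variance-stabilizing transform, and scaling.

    ``method``: 'total-sum' (each sample divided by its intensity sum, so
    row sums become 1), 'median' (divided by the sample median), 'none'.
    ``transform``: 'log10' applies log10(x + 1), 'none'.
    ``scale`` (feature-wise): 'auto' (mean 0, sd 1), 'pareto' (mean 0,
    divided by sqrt(sd)), 'none'.  Order: method, transform, scale.
    """
    df = pt.data.astype(float).copy()
    if method == "total-sum":
        sums = df.sum(axis=1, skipna=True)
        zero = sums[sums == 0]
        if len(zero):
            raise ValueError(
                f"all-zero sample(s) under total-sum normalization: {list(zero.index)}"
            )
        df = df.div(sums, axis=0)
    elif method == "median":
        med = df.median(axis=1, skipna=True)
        if (med == 0).any():
            raise ValueError(
                "zero-median sample(s) under median normalization: "
                f"{list(med.index[med == 0])}"
            )
        df = df.div(med, axis=0)
    elif method != "none":
        raise ValueError(f"unknown normalization method {method!r}")

    if transform == "log10":
        df = np.log10(df + 1.0)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")

    if scale in ("auto", "pareto"):
        mu = df.mean(axis=0, skipna=True)
        sd = df.std(axis=0, ddof=1, skipna=True)
        denom = sd if scale == "auto" else np.sqrt(sd)
        denom = denom.replace(0.0, np.nan)
        df = (df - mu) / denom
    elif scale != "none":
        raise ValueError(f"unknown scaling {scale!r}")

    return PeakTable(df)


def impute_missing(
    pt: PeakTable, strategy: str = "half-min", seed: int | None = 0
) -> PeakTable:
    """Fill missing intensities; observed entries are never altered.

    'half-min' fills each feature's gaps with half its minimum observed
    intensity; 'knn' uses K-nearest-neighbour sample matching; 'rf' uses
    iterative random-forest regression (capped at 3 rounds, seeded).
    Features with no observed value at all are dropped with a warning.
    """
    df = pt.data.astype(float).copy()
    all_missing = df.columns[df.isna().all(axis=0)]
    if len(all_missing):
        import warnings

        warnings.warn(
            f"dropping feature(s) with no observed values: {list(all_missing)}",
            stacklevel=2,
        )
        df = df.drop(columns=all_missing)
    if not df.isna().any().any():
        return PeakTable(df)

    if strategy == "half-min":
        fill = df.min(axis=0, skipna=True) / 2.0
        df = df.fillna(fill)
    elif strategy == "knn":
        from sklearn.impute import KNNImputer

        imp = KNNImputer(n_neighbors=min(5, len(df) - 1))
        df = pd.DataFrame(imp.fit_transform(df), index=df.index,
                          columns=df.columns)
    elif strategy == "rf":
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.experimental import enable_iterative_imputer  # noqa: F401
        from sklearn.impute import IterativeImputer

        imp = IterativeImputer(
            estimator=RandomForestRegressor(
                n_estimators=20, random_state=seed, n_jobs=1
            ),
            max_iter=3,
            random_state=seed,
            sample_posterior=False,
        )
        df = pd.DataFrame(imp.fit_transform(df), index=df.index,
                          columns=df.columns)
    else:
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    return PeakTable(df)


def _two_groups(pt: PeakTable, meta: MetadataTable, variable: str):
    meta.check_matches(pt)
    labels = meta.data.loc[pt.data.index, variable]
    levels = meta.levels(variable)
    if len(levels) != 2:
        raise ValueError(
            f"variable {variable!r} has {len(levels)} levels; two-group "
            "tests need exactly 2 (multivariate methods are out of scope)"
        )
    a = pt.data.loc[labels == levels[0]]
    b = pt.data.loc[labels == levels[1]]
    return levels, a, b


def ttest_all(
    pt: PeakTable,
    meta: MetadataTable,
    variable: str,
    paired: bool = False,
    alpha: float = 0.05,
    correction: str = "fdr_bh",
) -> pd.DataFrame:
    """Per-feature two-group t-test with multiple-testing correction.

    Welch (unequal-variance) two-sample t by default; a paired t when
    ``paired`` (samples matched by order within each level).  Features
    whose pooled values are constant are flagged (``constant`` column)
    and excluded from testing and from the correction.  Returns a frame
    indexed by feature with columns statistic, pvalue, p_adjusted,
    log2_fc, mean_<level1>, mean_<level2>, constant, significant.
    """
    levels, a, b = _two_groups(pt, meta, variable)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per level")
    av, bv = a.to_numpy(float), b.to_numpy(float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired test needs equal group sizes")
        stat, pval = sps.ttest_rel(av, bv, axis=0, nan_policy="omit")
    else:
        stat, pval = sps.ttest_ind(av, bv, axis=0, equal_var=False,
                                   nan_policy="omit")
    stat, pval = np.asarray(stat, float), np.asarray(pval, float)

    # a feature constant across all samples carries no testable signal
    with np.errstate(invalid="ignore"):
        constant = (np.nanstd(av, axis=0) == 0) & (np.nanstd(bv, axis=0) == 0) \
            & (np.nanmean(av, axis=0) == np.nanmean(bv, axis=0))
    pval[constant] = np.nan
    stat[constant] = np.nan

    padj = np.full_like(pval, np.nan)
    tested = ~np.isnan(pval)
    if tested.any():
        padj[tested] = multipletests(pval[tested], method=correction)[1]

    mean_a = np.nanmean(av, axis=0)
    mean_b = np.nanmean(bv, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(mean_b / mean_a)

    return pd.DataFrame(
        {
            "statistic": stat,
            "pvalue": pval,
            "p_adjusted": padj,
            "log2_fc": log2fc,
            f"mean_{levels[0]}": mean_a,
            f"mean_{levels[1]}": mean_b,
            "constant": constant,
            "significant": padj < alpha,
        },
        index=pt.data.columns,
    )


def fold_change(pt: PeakTable, meta: MetadataTable, variable: str) -> pd.DataFrame:
    """Per-feature log2 ratio of group means on the raw intensity scale.

    Level order follows the metadata factor order; the ratio is
    mean(level2)/mean(level1).  Zero denominators yield +/-inf, flagged
    in the ``infinite`` column so downstream volcano plots can drop them.
    """
    levels, a, b = _two_groups(pt, meta, variable)
    mean_a = a.mean(axis=0, skipna=True)
    mean_b = b.mean(axis=0, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(mean_b / mean_a)
    return pd.DataFrame(
        {"log2_fc": fc, "infinite": ~np.isfinite(fc)}, index=pt.data.columns
    )


def volcano_table(
    pt: PeakTable, meta: MetadataTable, variable: str, alpha: float = 0.05
) -> pd.DataFrame:
    """(log2 fold change, -log10 adjusted p) pairs for a volcano plot.

    Consistent by construction with :func:`ttest_all` and
    :func:`fold_change` on the same table; infinite fold changes are
    excluded.
    """
    tt = ttest_all(pt, meta, variable, alpha=alpha)
    fc = fold_change(pt, meta, variable)
    out = pd.DataFrame(
        {
            "log2_fc": fc["log2_fc"],
            "neg_log10_padj": -np.log10(tt["p_adjusted"]),
            "significant": tt["significant"],
        }
    )
    return out[~fc["infinite"]]


def hypergeom_overlap(list_a, list_b, universe) -> float:
    """Upper-tail significance of the overlap between two hit lists.

    With a universe of ``N`` features, ``|A|`` and ``|B|`` drawn from it
    and ``k`` shared, returns P(X >= k) for
    X ~ Hypergeometric(N, |A|, |B|) — the chance of an overlap at least
    this large if the lists were independent draws.

    ``universe`` is either the universe size (int) or the collection of
    feature identifiers itself, in which case membership is validated.
    """
    a, b = set(list_a), set(list_b)
    if isinstance(universe, int):
        n_universe = universe
    else:
        uni = set(universe)
        stray = (a | b) - uni
        if stray:
            raise ValueError(f"hit-list element(s) outside universe: {sorted(stray)[:5]}")
        n_universe = len(uni)
    if max(len(a), len(b)) > n_universe:
        raise ValueError("list larger than universe")
    k = len(a & b)
    return float(sps.hypergeom.sf(k - 1, n_universe, len(a), len(b)))


def subset_samples(pt: PeakTable, meta: MetadataTable, predicate):
    """Consistent paired subset of samples; the feature set is unchanged.

    ``predicate`` receives the metadata frame and returns a boolean mask
    over samples.  Raises if no sample survives.
    """
    meta.check_matches(pt)
    mask = pd.Series(predicate(meta.data), index=meta.data.index).astype(bool)
    keep = mask.index[mask]
    if len(keep) == 0:
        raise ValueError("sample subset is empty")
    return (
        PeakTable(pt.data.loc[pt.data.index.intersection(keep, sort=False)]),
        MetadataTable(meta.data.loc[keep]),
    )
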