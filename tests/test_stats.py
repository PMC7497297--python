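"""Normalization, imputation, two-group testing, overlap significance."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mzannotate.simulate import SimSpec, gen_peak_experiment
from mzannotate.stats import (
    MetadataTable,
    PeakTable,
    fold_change,
    hypergeom_overlap,
    impute_missing,
    normalize,
    subset_samples,
    ttest_all,
    volcano_table,
)


def make_pt(values, samples=None, features=None):
    values = np.asarray(values, float)
    samples = samples or [f"s{i}" for i in range(values.shape[0])]
    features = features or [f"{100 + j}.0+" for j in range(values.shape[1])]
    return PeakTable(pd.DataFrame(values, index=samples, columns=features))


def make_meta(groups, samples=None):
    samples = samples or [f"s{i}" for i in range(len(groups))]
    return MetadataTable(pd.DataFrame({"group": groups},
                                      index=pd.Index(samples, name="sample")))


class TestPeakTableValidation:
    def test_feature_id_parsing(self):
        assert PeakTable.feature_mz("263.1117+") == (263.1117, "+")
        assert PeakTable.feature_mz("100.5") == (100.5, "")
        with pytest.raises(ValueError):
            PeakTable.feature_mz("not-an-mz")

    def test_duplicate_samples_rejected(self):
        df = pd.DataFrame([[1.0], [2.0]], index=["a", "a"], columns=["100.0+"])
        with pytest.raises(ValueError, match="duplicate"):
            PeakTable(df)


class TestNormalize:
    def test_total_sum_on_ones(self):
        out = normalize(make_pt(np.ones((2, 2))), method="total-sum")
        assert np.allclose(out.data.to_numpy(), 0.5)
        assert np.allclose(out.data.sum(axis=1), 1.0, atol=1e-9)

    def test_identity_when_everything_off(self):
        pt = make_pt([[1.0, 4.0], [2.0, 8.0]])
        out = normalize(pt)
        pd.testing.assert_frame_equal(out.data, pt.data)

    def test_auto_scaling_standardizes_features(self):
        rng = np.random.default_rng(0)
        out = normalize(make_pt(rng.lognormal(size=(30, 5))), scale="auto")
        assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(out.data.std(axis=0, ddof=1), 1.0, atol=1e-9)

    def test_all_zero_sample_named_in_error(self):
        pt = make_pt([[0.0, 0.0], [1.0, 2.0]], samples=["dead", "ok"])
        with pytest.raises(ValueError, match="dead"):
            normalize(pt, method="total-sum")

    def test_log_transform_applied_elementwise(self):
        out = normalize(make_pt([[9.0, 99.0]]), transform="log10")
        assert np.allclose(out.data.to_numpy(), [[1.0, 2.0]])


class TestImpute:
    @pytest.mark.parametrize("strategy", ["half-min", "knn", "rf"])
    def test_complete_table_identity(self, strategy):
        pt = make_pt([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        out = impute_missing(pt, strategy=strategy, seed=0)
        pd.testing.assert_frame_equal(out.data, pt.data)

    def test_half_min_definition(self):
        pt = make_pt([[10.0, 1.0], [np.nan, 2.0], [40.0, 3.0]])
        out = impute_missing(pt, strategy="half-min")
        assert out.data.iloc[1, 0] == pytest.approx(5.0)

    @pytest.mark.parametrize("strategy", ["knn", "rf"])
    def test_seeded_strategies_reproducible_and_preserve_observed(self, strategy):
        rng = np.random.default_rng(1)
        values = rng.lognormal(size=(20, 6))
        mask = rng.random(values.shape) < 0.15
        values[mask] = np.nan
        pt = make_pt(values)
        a = impute_missing(pt, strategy=strategy, seed=42)
        b = impute_missing(pt, strategy=strategy, seed=42)
        pd.testing.assert_frame_equal(a.data, b.data)
        observed = ~np.isnan(values)
        assert np.array_equal(a.data.to_numpy()[observed], values[observed])
        assert not a.data.isna().any().any()

    def test_fully_missing_feature_dropped_with_warning(self):
        pt = make_pt([[1.0, np.nan], [2.0, np.nan]])
        with pytest.warns(UserWarning, match="no observed values"):
            out = impute_missing(pt)
        assert out.data.shape[1] == 1


class TestTTestAll:
    def test_bh_adjustment_matches_step_up_oracle(self):
        """Adjusted p equals the hand-computed Benjamini-Hochberg step-up."""
        rng = np.random.default_rng(4)
        pt = make_pt(rng.lognormal(size=(16, 30)))
        res = ttest_all(pt, make_meta(["a"] * 8 + ["b"] * 8), "group")
        p = res["pvalue"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        expected = np.minimum.accumulate(stepped[::-1])[::-1].clip(max=1.0)
        assert np.allclose(res["p_adjusted"].to_numpy()[order], expected)
        assert (res["p_adjusted"] >= res["pvalue"] - 1e-12).all()

    def test_constant_feature_flagged_not_tested(self):
        values = np.column_stack([np.full(8, 3.0),
                                  np.random.default_rng(0).normal(size=8)])
        res = ttest_all(make_pt(values), make_meta(["a"] * 4 + ["b"] * 4),
                        "group")
        assert bool(res["constant"].iloc[0]) is True
        assert math.isnan(res["pvalue"].iloc[0])
        assert not res["constant"].iloc[1]

    def test_three_levels_rejected(self):
        pt = make_pt(np.ones((6, 2)) + np.arange(6)[:, None])
        meta = make_meta(["a", "a", "b", "b", "c", "c"])
        with pytest.raises(ValueError, match="multivariate"):
            ttest_all(pt, meta, "group")

    def test_paired_needs_matched_sizes(self):
        pt = make_pt(np.random.default_rng(1).normal(size=(7, 3)))
        meta = make_meta(["a"] * 4 + ["b"] * 3)
        with pytest.raises(ValueError, match="equal group sizes"):
            ttest_all(pt, meta, "group", paired=True)

    def test_planted_shift_detected(self):
        """A 2-sd shift in 10/100 features is recovered at FDR 0.05."""
        pt, meta, truth = gen_peak_experiment(
            SimSpec(n_features=100, n_planted=10, effect=2.0, seed=5)
        )
        pt = normalize(pt, transform="log10")
        res = ttest_all(pt, meta, "group")
        hit = res.loc[truth[truth.planted].feature, "significant"]
        assert hit.sum() >= 8


class TestFoldChange:
    def test_equal_means_zero(self):
        pt = make_pt([[2.0], [2.0], [2.0], [2.0]])
        fc = fold_change(pt, make_meta(["a", "a", "b", "b"]), "group")
        assert fc["log2_fc"].iloc[0] == pytest.approx(0.0)

    def test_level_order_and_value(self):
        # level1 mean 1, level2 mean 4 -> log2(4/1) = 2
        pt = make_pt([[1.0], [1.0], [4.0], [4.0]])
        fc = fold_change(pt, make_meta(["a", "a", "b", "b"]), "group")
        assert fc["log2_fc"].iloc[0] == pytest.approx(2.0)

    def test_zero_denominator_flagged_infinite(self):
        pt = make_pt([[0.0], [0.0], [4.0], [4.0]])
        fc = fold_change(pt, make_meta(["a", "a", "b", "b"]), "group")
        assert bool(fc["infinite"].iloc[0])

    def test_volcano_consistent_with_ttest(self):
        pt, meta, _ = gen_peak_experiment(SimSpec(n_features=40, seed=6))
        v = volcano_table(pt, meta, "group")
        tt = ttest_all(pt, meta, "group")
        fc = fold_change(pt, meta, "group")
        keep = ~fc["infinite"]
        assert np.allclose(v["log2_fc"], fc.loc[keep, "log2_fc"])
        assert np.allclose(v["neg_log10_padj"],
                           -np.log10(tt.loc[keep, "p_adjusted"]))


def enumeration_overlap_p(n_universe, size_a, size_b, k):
    """Exact oracle: enumerate every draw of B and count overlaps >= k."""
    a = set(range(size_a))
    total = 0
    at_least = 0
    for b in itertools.combinations(range(n_universe), size_b):
        total += 1
        if len(a & set(b)) >= k:
            at_least += 1
    return at_least / total


class TestHypergeomOverlap:
    def test_degenerate_full_universe(self):
        u = list(range(10))
        assert hypergeom_overlap(u, u, u) == pytest.approx(1.0)

    def test_closed_form_10_10_100_overlap_5(self):
        a = list(range(10))
        b = list(range(5)) + list(range(50, 55))
        expected = sum(
            math.comb(10, k) * math.comb(90, 10 - k) for k in range(5, 11)
        ) / math.comb(100, 10)
        assert hypergeom_overlap(a, b, 100) == pytest.approx(expected, abs=1e-12)

    def test_zero_overlap_probability_in_unit_interval(self):
        p = hypergeom_overlap(list(range(5)), list(range(10, 15)), 100)
        assert 0.0 < p <= 1.0

    @pytest.mark.parametrize("n_universe,size_a,size_b,k",
                             [(8, 3, 4, 2), (10, 5, 5, 3), (12, 6, 4, 1),
                              (12, 2, 10, 2), (7, 3, 3, 0)])
    def test_matches_exhaustive_enumeration(self, n_universe, size_a, size_b, k):
        a = list(range(size_a))
        b = list(range(size_a - k, size_a - k + size_b))
        assert len(set(a) & set(b)) == k
        assert hypergeom_overlap(a, b, n_universe) == pytest.approx(
            enumeration_overlap_p(n_universe, size_a, size_b, k), abs=1e-12
        )

    def test_element_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside universe"):
            hypergeom_overlap(["x"], ["y"], ["y", "z"])


class TestSubsetSamples:
    def setup_method(self):
        self.pt, self.meta, _ = gen_peak_experiment(
            SimSpec(n_samples_per_group=6, n_features=20, seed=7)
        )

    def test_always_true_predicate_is_identity(self):
        sub_pt, sub_meta = subset_samples(self.pt, self.meta,
                                          lambda df: df["group"].notna())
        pd.testing.assert_frame_equal(sub_pt.data, self.pt.data)
        pd.testing.assert_frame_equal(sub_meta.data, self.meta.data)

    def test_two_level_predicate_partitions_samples(self):
        case_pt, _ = subset_samples(self.pt, self.meta,
                                    lambda df: df["group"] == "case")
        ctrl_pt, _ = subset_samples(self.pt, self.meta,
                                    lambda df: df["group"] == "control")
        assert len(case_pt.samples) + len(ctrl_pt.samples) == len(self.pt.samples)
        assert case_pt.features == self.pt.features

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            subset_samples(self.pt, self.meta, lambda df: df["group"] == "nope")

    def test_stats_on_subset_equal_manual_filtering(self):
        meta2 = MetadataTable(self.meta.data.assign(
            batch=["x", "y"] * (len(self.meta.data) // 2)))
        sub_pt, sub_meta = subset_samples(self.pt, meta2,
                                          lambda df: df["batch"] == "x")
        manual = self.pt.data.loc[meta2.data["batch"] == "x"]
        res_sub = ttest_all(sub_pt, sub_meta, "group")
        res_manual = ttest_all(PeakTable(manual),
                               MetadataTable(meta2.data[meta2.data.batch == "x"]),
                               "group")
        pd.testing.assert_frame_equal(res_sub, res_manual)
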