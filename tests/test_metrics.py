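"""QC, normalization, noise summaries, fold changes and rank tests."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from noisebench.metrics import (
    CountMatrix,
    qc_filter_cells,
    gene_coverage_filter,
    raw_normalize,
    noise_summary,
    cell_table_noise_summary,
    fold_change_table,
    replicate_average,
    negative_control_split,
    compare_populations,
    amplified_fraction,
)


class TestQcFilter:
    def test_min_genes_threshold(self, toy_matrix_factory):
        # detected genes per cell: 5, 2, 4
        counts = np.array(
            [[1, 1, 1], [1, 1, 1], [1, 0, 1], [1, 0, 1], [1, 0, 0]]
        )
        m = toy_matrix_factory(counts)
        kept, report = qc_filter_cells(m, min_genes=4)
        assert kept.cell_ids == ["c0", "c2"]
        assert report.removed["min_genes"] == 1

    def test_disabled_thresholds_are_identity(self, toy_matrix_factory):
        m = toy_matrix_factory(np.arange(12).reshape(3, 4))
        kept, _ = qc_filter_cells(m)
        assert kept.cell_ids == m.cell_ids

    def test_mito_boundary_is_strict(self, toy_matrix_factory):
        # cell 0 has exactly 10% mito reads -> removed under "<10%"
        counts = np.array([[1, 0], [9, 10]])
        m = toy_matrix_factory(counts, gene_ids=["mt-Nd1", "Actb"])
        kept, report = qc_filter_cells(m, max_mito_frac=0.10)
        assert kept.cell_ids == ["c1"]
        assert report.removed["max_mito_frac"] == 1

    def test_min_boundary_is_inclusive(self, toy_matrix_factory):
        m = toy_matrix_factory(np.array([[5, 3]]))
        kept, _ = qc_filter_cells(m, min_umi=5)
        assert kept.cell_ids == ["c0"]

    def test_all_removed_raises_with_breakdown(self, toy_matrix_factory):
        m = toy_matrix_factory(np.array([[1, 1]]))
        with pytest.raises(ValueError, match="min_umi"):
            qc_filter_cells(m, min_umi=100)


class TestGeneCoverageFilter:
    def test_low_detection_gene_dropped(self, toy_matrix_factory):
        counts = np.zeros((2, 100), dtype=int)
        counts[0] = 5
        counts[1, 0] = 1  # detected in 1 of 100 cells
        m = toy_matrix_factory(counts)
        kept = gene_coverage_filter(m, min_mean_count=0.0, min_detect_frac=0.1)
        assert kept.gene_ids == ["g0"]

    def test_zero_thresholds_identity(self, toy_matrix_factory):
        m = toy_matrix_factory(np.ones((3, 10), dtype=int))
        kept = gene_coverage_filter(m, 0.0, 0.0)
        assert kept.gene_ids == m.gene_ids

    def test_intersection_rule_across_conditions(self, toy_matrix_factory):
        # gene passes in control, fails in treated -> dropped
        counts = np.block([
            [np.full((1, 10), 5), np.full((1, 10), 5)],
            [np.full((1, 10), 5), np.zeros((1, 10), dtype=int)],
        ]).astype(int)
        m = toy_matrix_factory(
            counts, conditions=["control"] * 10 + ["treated"] * 10
        )
        kept = gene_coverage_filter(m, min_mean_count=0.5, min_detect_frac=0.5)
        assert kept.gene_ids == ["g0"]


class TestRawNormalize:
    def test_hand_example(self, toy_matrix_factory):
        m = toy_matrix_factory(np.array([[1], [3]]))
        normed = raw_normalize(m)
        assert np.allclose(normed.counts[:, 0], [2500.0, 7500.0])

    def test_single_gene_saturates_scale(self, toy_matrix_factory):
        m = toy_matrix_factory(np.array([[3, 17, 250]]))
        assert np.allclose(raw_normalize(m).counts, 1e4)

    def test_column_sums_conserved(self, toy_matrix_factory):
        rng = np.random.default_rng(0)
        m = toy_matrix_factory(rng.poisson(4, size=(20, 30)) + 1)
        normed = raw_normalize(m)
        assert np.allclose(normed.counts.sum(axis=0), 1e4, rtol=1e-9)

    def test_within_cell_ratios_preserved(self, toy_matrix_factory):
        rng = np.random.default_rng(1)
        counts = rng.poisson(10, size=(5, 8)) + 1
        m = toy_matrix_factory(counts)
        normed = raw_normalize(m)
        assert np.allclose(normed.counts[0] / normed.counts[1],
                           counts[0] / counts[1])

    def test_zero_total_cell_named_in_error(self, toy_matrix_factory):
        m = toy_matrix_factory(np.array([[1, 0]]))
        with pytest.raises(ValueError, match="c1"):
            raw_normalize(m)


class TestNoiseSummary:
    def test_hand_oracle(self):
        s = noise_summary(np.array([2, 4, 6, 8]))
        row = s.iloc[0]
        assert row["mean"] == 5.0
        assert row["var"] == pytest.approx(20.0 / 3.0)
        assert row["fano"] == pytest.approx(4.0 / 3.0)
        assert row["cv2"] == pytest.approx(4.0 / 15.0)

    def test_constant_counts_zero_noise(self):
        row = noise_summary(np.array([5, 5, 5])).iloc[0]
        assert row["var"] == 0.0 and row["cv2"] == 0.0 and row["fano"] == 0.0

    def test_poisson_fano_near_one(self):
        x = np.random.default_rng(2).poisson(10, size=100_000)
        assert noise_summary(x).iloc[0]["fano"] == pytest.approx(1.0, abs=0.03)

    def test_zero_mean_gene_flagged_not_dropped(self):
        s = noise_summary(np.array([[0, 0, 0], [1, 2, 3]]))
        assert bool(s.iloc[0]["undefined"]) and math.isnan(s.iloc[0]["fano"])
        assert len(s) == 2

    def test_fewer_than_two_cells_rejected(self):
        with pytest.raises(ValueError, match="2 cells"):
            noise_summary(np.array([[5]]))

    @given(st.lists(st.integers(0, 50), min_size=3, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_fano_equals_cv2_times_mean(self, counts):
        s = noise_summary(np.array(counts)).iloc[0]
        if not s["undefined"]:
            assert s["fano"] == pytest.approx(s["cv2"] * s["mean"], rel=1e-12)

    def test_cell_table_summary_matches_matrix_path(self):
        cells = pd.DataFrame(
            {"cell_id": list("abcd"), "condition": "control", "replicate": 1,
             "area": 1.0, "count_gX": [2, 4, 6, 8]}
        )
        s = cell_table_noise_summary(cells)
        assert s.iloc[0]["gene_id"] == "gX" and s.iloc[0]["mean"] == 5.0


class TestFoldChange:
    def summary(self, **cols):
        n = len(next(iter(cols.values())))
        base = {"gene_id": [f"g{i}" for i in range(n)], "n_cells": 10,
                "undefined": False}
        base.update(cols)
        return pd.DataFrame(base)

    def test_identical_summaries_all_unity(self):
        s = self.summary(mean=[5.0, 2.0], var=[5.0, 4.0],
                         cv2=[0.2, 1.0], fano=[1.0, 2.0])
        fc = fold_change_table(s, s.copy())
        assert np.allclose(fc[["d_mean", "d_cv2", "d_fano"]], 1.0)

    def test_fano_ratio(self):
        t = self.summary(mean=[10.0], var=[110.0], cv2=[1.1], fano=[11.0])
        c = self.summary(mean=[10.0], var=[60.0], cv2=[0.6], fano=[6.0])
        assert fold_change_table(t, c).iloc[0]["d_fano"] == pytest.approx(11 / 6)

    def test_zero_control_metric_excluded_with_reason(self):
        t = self.summary(mean=[10.0], var=[10.0], cv2=[0.1], fano=[1.0])
        c = self.summary(mean=[10.0], var=[0.0], cv2=[0.0], fano=[0.0])
        fc = fold_change_table(t, c)
        assert len(fc) == 0
        assert fc.attrs["excluded"][0][1] == "non-positive control metric"

    def test_empty_intersection_raises(self):
        t = self.summary(mean=[1.0], var=[1.0], cv2=[1.0], fano=[1.0])
        c = t.copy()
        c["gene_id"] = ["other"]
        with pytest.raises(ValueError, match="overlap"):
            fold_change_table(t, c)


class TestReplicateAverage:
    def summary(self, genes, fano):
        return pd.DataFrame(
            {"gene_id": genes, "n_cells": 10, "mean": 1.0, "var": 1.0,
             "cv2": 1.0, "fano": fano, "undefined": False}
        )

    def test_arithmetic_mean_of_metrics(self):
        out = replicate_average([self.summary(["g"], [2.0]),
                                 self.summary(["g"], [4.0])])
        assert out.iloc[0]["fano"] == 3.0
        assert out.iloc[0]["n_cells"] == 20

    def test_single_replicate_identity(self):
        s = self.summary(["g"], [2.0])
        pd.testing.assert_frame_equal(replicate_average([s]), s)

    def test_gene_missing_in_one_replicate_dropped(self):
        out = replicate_average([self.summary(["g", "h"], [2.0, 1.0]),
                                 self.summary(["g"], [4.0])])
        assert list(out["gene_id"]) == ["g"]


class TestNegativeControlSplit:
    def test_halves_disjoint_and_balanced(self, toy_matrix_factory):
        m = toy_matrix_factory(np.random.default_rng(0).poisson(5, (10, 100)))
        a, b, report = negative_control_split(m, seed=3)
        assert a.n_cells == 50 and b.n_cells == 50
        assert not set(a.cell_ids) & set(b.cell_ids)
        assert set(a.cell_ids) | set(b.cell_ids) == set(m.cell_ids)

    def test_same_seed_reproduces_split(self, toy_matrix_factory):
        m = toy_matrix_factory(np.random.default_rng(0).poisson(5, (10, 101)))
        a1, b1, _ = negative_control_split(m, seed=7)
        a2, b2, _ = negative_control_split(m, seed=7)
        assert a1.cell_ids == a2.cell_ids and b1.cell_ids == b2.cell_ids
        assert abs(a1.n_cells - b1.n_cells) <= 1

    def test_type_i_error_controlled_on_null_data(self, toy_matrix_factory):
        rng = np.random.default_rng(42)
        m = toy_matrix_factory(rng.negative_binomial(2, 0.3, size=(30, 200)))
        low = 0
        n_seeds = 200
        for seed in range(n_seeds):
            _, _, report = negative_control_split(m, seed=seed)
            low += report["fano_rank_sum_p"] < 0.05
        # binomial 3-sigma band around 5% of 200
        assert low <= 0.05 * n_seeds + 3 * math.sqrt(n_seeds * 0.05 * 0.95)


def brute_force_signed_rank(d, alternative):
    """Enumerate all sign patterns of the ranked |differences|."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    from scipy.stats import rankdata
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [sum(r for r, s in zip(ranks, signs) if s)
          for signs in itertools.product([False, True], repeat=len(d))]
    ws = np.array(ws)
    p_ge = np.mean(ws >= w_obs - 1e-12)
    p_le = np.mean(ws <= w_obs + 1e-12)
    return {"greater": p_ge, "less": p_le,
            "two_sided": min(1.0, 2 * min(p_ge, p_le))}[alternative]


def brute_force_rank_sum(a, b, alternative):
    pooled = np.concatenate([a, b])
    from scipy.stats import rankdata
    ranks = rankdata(pooled)
    obs = ranks[: len(a)].sum()
    stats_ = [ranks[list(idx)].sum()
              for idx in itertools.combinations(range(len(pooled)), len(a))]
    stats_ = np.array(stats_)
    p_ge = np.mean(stats_ >= obs - 1e-12)
    p_le = np.mean(stats_ <= obs + 1e-12)
    return {"greater": p_ge, "less": p_le,
            "two_sided": min(1.0, 2 * min(p_ge, p_le))}[alternative]


class TestComparePopulations:
    def test_identical_paired_samples_p_one(self):
        a = np.array([1.0, 2.0, 3.0])
        stat, p = compare_populations(a, a, test="signed_rank", paired=True)
        assert p == 1.0

    def test_uniform_shift_one_sided_exact(self):
        b = np.arange(6, dtype=float)
        _, p = compare_populations(b + 1, b, test="signed_rank",
                                   alternative="greater", paired=True)
        assert p == pytest.approx(1.0 / 64.0)

    def test_separated_rank_sum_exact(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([10.0, 11.0, 12.0, 13.0])
        _, p = compare_populations(a, b, test="rank_sum", alternative="less")
        assert p == pytest.approx(1.0 / 70.0)

    @pytest.mark.parametrize("alternative", ["two_sided", "greater", "less"])
    def test_signed_rank_matches_brute_force_enumeration(self, alternative):
        rng = np.random.default_rng(5)
        for _ in range(10):
            d = rng.integers(-5, 6, size=7).astype(float)
            if np.all(d == 0):
                continue
            _, p = compare_populations(d, np.zeros_like(d), test="signed_rank",
                                       alternative=alternative, paired=True)
            assert p == pytest.approx(brute_force_signed_rank(d, alternative))

    @pytest.mark.parametrize("alternative", ["two_sided", "greater", "less"])
    def test_rank_sum_matches_brute_force_enumeration(self, alternative):
        rng = np.random.default_rng(6)
        for _ in range(10):
            pooled = rng.permutation(np.arange(11, dtype=float))
            a, b = pooled[:5], pooled[5:]
            _, p = compare_populations(a, b, test="rank_sum",
                                       alternative=alternative)
            assert p == pytest.approx(brute_force_rank_sum(a, b, alternative))

    def test_paired_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal-length"):
            compare_populations([1.0, 2.0], [1.0], test="signed_rank",
                                paired=True)


class TestAmplifiedFraction:
    def make_fc(self, vals):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(vals))],
                             "d_mean": 1.0, "d_cv2": 1.0, "d_fano": vals})

    def test_all_unity_gives_zero(self):
        assert amplified_fraction(self.make_fc([1.0, 1.0])) == 0.0

    def test_counts_strict_exceedances(self):
        fc = self.make_fc([0.5, 1.5, 2.0])
        assert amplified_fraction(fc) == pytest.approx(2 / 3)
        assert amplified_fraction(fc, threshold=1.5) == pytest.approx(1 / 3)

    def test_invariant_under_normalization_with_equal_totals(self, toy_matrix_factory):
        rng = np.random.default_rng(9)
        counts = rng.poisson(5, size=(20, 40))
        # force equal totals by padding a dummy gene
        totals = counts.sum(axis=0)
        pad = totals.max() - totals + 1
        counts = np.vstack([counts, pad])
        half = 20
        conds = ["treated"] * half + ["control"] * half
        m = toy_matrix_factory(counts, conditions=conds)

        def fc_of(mat):
            t = mat.subset_cells((mat.cell_meta["condition"] == "treated").to_numpy())
            c = mat.subset_cells((mat.cell_meta["condition"] == "control").to_numpy())
            from noisebench.metrics import noise_summary, fold_change_table
            return fold_change_table(noise_summary(t), noise_summary(c))

        raw_frac = amplified_fraction(fc_of(m))
        norm_frac = amplified_fraction(fc_of(raw_normalize(m)))
        assert raw_frac == pytest.approx(norm_frac)
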