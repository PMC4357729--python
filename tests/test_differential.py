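"""Binned trimmed z-test: binning rules, trimming, calibration, determinism."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from nsc_interactome import (DifferentialConfig, assign_bins,
                             differential_test, standardize_ratios,
                             trim_consistency_factor, trimmed_bin_stats)

UNCORRECTED = DifferentialConfig(consistency_correction=False,
                                 normalize_depth=False)


class TestAssignBins:
    def ids(self, n):
        return [f"P{i:04d}" for i in range(n)]

    @pytest.mark.parametrize("n,target,minimum,sizes", [
        (10, 5, 2, (5, 5)),          # exact division
        (160, 150, 50, (160,)),      # trailing 10 < 50 merged
        (40, 150, 50, (40,)),        # fewer than one bin: single bin
        (210, 150, 50, (150, 60)),   # trailing 60 >= 50 kept
    ])
    def test_occupancy_rules(self, n, target, minimum, sizes):
        cfg = DifferentialConfig(bin_target=target, bin_minimum=minimum)
        bins = assign_bins(np.arange(n, dtype=float), self.ids(n), cfg)
        counts = np.bincount(bins)
        assert tuple(counts) == sizes

    def test_bins_contiguous_in_intensity(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        cfg = DifferentialConfig(bin_target=30, bin_minimum=5)
        bins = assign_bins(x, self.ids(100), cfg)
        order = np.argsort(x, kind="stable")
        assert (np.diff(bins[order]) >= 0).all()

    def test_independent_of_input_order(self):
        rng = np.random.default_rng(4)
        x = np.round(rng.normal(size=60), 1)  # generates ties
        ids = self.ids(60)
        cfg = DifferentialConfig(bin_target=20, bin_minimum=5)
        base = dict(zip(ids, assign_bins(x, ids, cfg)))
        perm = rng.permutation(60)
        shuffled = dict(zip([ids[i] for i in perm],
                            assign_bins(x[perm], [ids[i] for i in perm], cfg)))
        assert base == shuffled


class TestTrimmedBinStats:
    def test_small_bin_trims_nothing(self):
        # n=5, 2.5% trim -> k=0; direct arithmetic oracle
        s = trimmed_bin_stats(np.array([0, 0, 0, 0, 1.0]), UNCORRECTED)
        assert s.mean == pytest.approx(0.2)
        assert s.sd == pytest.approx(np.sqrt(0.2), abs=1e-12)

    def test_trim_removes_extremes(self):
        ratios = np.concatenate([np.zeros(98), [100.0, -100.0]])
        cfg = DifferentialConfig(trim_fraction=0.02,
                                 consistency_correction=False)
        s = trimmed_bin_stats(ratios, cfg)
        assert s.n_trimmed == 96  # k=2 removed per side
        assert s.mean == 0.0 and s.sd == 0.0 and s.degenerate

    def test_consistency_constant_value(self):
        # truncated-normal variance at 2.5% per side
        assert trim_consistency_factor(0.025) == pytest.approx(0.8711, abs=2e-4)
        assert trim_consistency_factor(0.0) == 1.0

    def test_corrected_sd_consistent_for_normal_sample(self):
        rng = np.random.default_rng(12)
        cfg = DifferentialConfig(trim_fraction=0.025)
        s = trimmed_bin_stats(rng.normal(size=10_000), cfg)
        assert s.sd == pytest.approx(1.0, abs=0.03)

    def test_requires_three_members(self):
        with pytest.raises(ValueError):
            trimmed_bin_stats(np.array([0.0, 1.0]), UNCORRECTED)


class TestStandardizeRatios:
    def test_z_matches_brute_force_per_bin(self):
        rng = np.random.default_rng(8)
        n = 400
        ids = [f"P{i:04d}" for i in range(n)]
        I = rng.uniform(1, 8, n)
        r = rng.normal(0, 1, n)
        cfg = DifferentialConfig(bin_target=100, bin_minimum=30)
        table, bin_stats = standardize_ratios(ids, I, r, cfg)
        factor = trim_consistency_factor(cfg.trim_fraction)
        for s in bin_stats:
            members = table[table["bin"] == s.index]
            vals = members["log2_ratio"].to_numpy()
            k = int(np.floor(cfg.trim_fraction * len(vals)))
            kept = np.sort(vals)[k:len(vals) - k]
            mu, sd = kept.mean(), kept.std(ddof=1) / factor
            np.testing.assert_allclose(members["z"],
                                       (vals - mu) / sd, atol=1e-12)

    def test_shift_equivariance_within_bin(self):
        rng = np.random.default_rng(9)
        ids = [f"P{i:03d}" for i in range(120)]
        I = np.sort(rng.uniform(0, 5, 120))
        r = rng.normal(size=120)
        cfg = DifferentialConfig(bin_target=200)  # single bin
        z1 = standardize_ratios(ids, I, r, cfg)[0]["z"]
        z2 = standardize_ratios(ids, I, r + 3.7, cfg)[0]["z"]
        np.testing.assert_allclose(z1, z2, atol=1e-9)

    def test_all_constant_ratios_give_p_one(self):
        ids = [f"P{i}" for i in range(10)]
        table, bins = standardize_ratios(ids, np.arange(10.0), np.ones(10))
        assert (table["pvalue"] == 1.0).all()
        assert all(b.degenerate for b in bins)

    def test_degenerate_bin_borrows_pooled_sd(self):
        # bin 1 constant, bin 2 spread: bin-1 members use the pooled SD
        ids = [f"P{i:02d}" for i in range(40)]
        I = np.concatenate([np.zeros(20), np.full(20, 10.0)])
        r = np.concatenate([np.full(20, 0.5), np.linspace(-1, 1, 20)])
        cfg = DifferentialConfig(bin_target=20, bin_minimum=5,
                                 consistency_correction=False)
        table, bins = standardize_ratios(ids, I, r, cfg)
        assert bins[0].degenerate and not bins[1].degenerate
        assert bins[0].sd == pytest.approx(bins[1].sd)
        assert (table.loc[table["bin"] == 0, "z"] == 0).all()

    def test_empty_input(self):
        table, bins = standardize_ratios([], [], [])
        assert len(table) == 0 and bins == []


class TestDifferentialTest:
    def frame(self, d, p):
        return pd.DataFrame({
            "protein_id": [f"P{i}" for i in range(len(d))],
            "differentiating": d, "proliferating": p})

    def test_single_bin_worked_example(self):
        # counts give log2 ratios (0,0,0,0,1); z = 0.8/sqrt(0.2) ~ 1.789
        table, _ = differential_test(
            self.frame([1, 1, 1, 1, 2], [1, 1, 1, 1, 1]), UNCORRECTED)
        row = table.set_index("protein_id").loc["P4"]
        assert row["z"] == pytest.approx(0.8 / np.sqrt(0.2), abs=1e-9)
        assert row["pvalue"] == pytest.approx(
            2 * stats.norm.sf(0.8 / np.sqrt(0.2)), abs=1e-9)
        assert row["differential"] and row["direction"] == "up-in-differentiation"

    def test_center_of_bin_is_null(self):
        table, _ = differential_test(
            self.frame([2, 2, 2, 2, 2], [2, 2, 2, 2, 2]), UNCORRECTED)
        assert (table["z"] == 0).all()
        assert (table["pvalue"] == 1.0).all()
        assert not table["differential"].any()

    def test_depth_normalization_equalizes_totals(self):
        cfg = DifferentialConfig(consistency_correction=False)
        table, _ = differential_test(
            self.frame([10, 20, 30], [1, 2, 3]), cfg)
        # identical composition at 10x depth: all ratios 0 after normalization
        np.testing.assert_allclose(table["log2_ratio"], 0.0, atol=1e-12)

    def test_fc_filter_only_removes_flags(self):
        rng = np.random.default_rng(21)
        d = rng.poisson(30, 300) + 1
        p = rng.poisson(30, 300) + 1
        loose = DifferentialConfig(lfc_threshold=0.0)
        strict = DifferentialConfig(lfc_threshold=0.5)
        calls_loose = differential_test(self.frame(d, p), loose)[0]["differential"]
        calls_strict = differential_test(self.frame(d, p), strict)[0]["differential"]
        assert (calls_strict <= calls_loose).all()

    def test_result_invariant_under_row_order(self):
        rng = np.random.default_rng(22)
        d = rng.poisson(20, 200) + 1
        p = rng.poisson(20, 200) + 1
        base = differential_test(self.frame(d, p))[0]
        perm = rng.permutation(200)
        shuffled = differential_test(
            self.frame(d, p).iloc[perm].reset_index(drop=True))[0]
        merged = base.merge(shuffled, on="protein_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["z_a"], merged["z_b"], atol=1e-12)
        assert (merged["differential_a"] == merged["differential_b"]).all()
        assert (merged["bin_a"] == merged["bin_b"]).all()

    def test_requires_positive_counts(self):
        with pytest.raises(ValueError, match="in-both"):
            differential_test(self.frame([0, 1, 2], [1, 1, 1]))

    def test_empty_input_empty_output(self):
        table, bins = differential_test(self.frame([], []))
        assert len(table) == 0 and bins == []


@given(st.floats(0.005, 0.2))
def test_consistency_factor_below_one_and_monotone(f):
    val = trim_consistency_factor(f)
    assert 0 < val < 1
    assert val <= trim_consistency_factor(f / 2) + 1e-12
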