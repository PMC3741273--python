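import math

import numpy as np
import pytest

from orthoconcord.containers import DesignTable
from orthoconcord.sam import (
    SamParams,
    pairwise_union,
    permutation_fdr,
    run_sam,
    sam_statistic,
    tune_s0,
)
from conftest import make_matrix


class TestStatistic:
    def test_null_identity(self, design_3v3):
        m = make_matrix([[2, 2, 2, 2, 2, 2], [5, 7, 6, 5, 7, 6]], sample_ids=design_3v3.sample_ids)
        res = sam_statistic(m, design_3v3, "A", "B", s0=0.1)
        np.testing.assert_allclose(res.d, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.fc, 1.0, atol=1e-12)

    def test_hand_evaluation(self, design_3v3):
        # a=(1,2,3), b=(3,4,5): diff 2, SS_a = SS_b = 2,
        # s = sqrt((1/3+1/3) * 4 / 4) = sqrt(2/3), d = 2/(s + 0.1), fc = 4
        m = make_matrix([[1, 2, 3, 3, 4, 5]], sample_ids=design_3v3.sample_ids)
        res = sam_statistic(m, design_3v3, "A", "B", s0=0.1)
        s_expected = math.sqrt(2.0 / 3.0)
        assert res.s[0] == pytest.approx(s_expected, abs=1e-12)
        assert res.d[0] == pytest.approx(2.0 / (s_expected + 0.1), abs=1e-12)
        assert res.fc[0] == pytest.approx(4.0, abs=1e-12)

    def test_scatter_homogeneity(self, design_3v3):
        base = np.array([[1.0, 2, 3, 3, 4, 5]])
        scaled = np.array([[2.0, 4, 6, 6, 8, 10]])  # deviations doubled
        ma = make_matrix(base, sample_ids=design_3v3.sample_ids)
        mb = make_matrix(scaled, sample_ids=design_3v3.sample_ids)
        ra = sam_statistic(ma, design_3v3, "A", "B", 0.0)
        rb = sam_statistic(mb, design_3v3, "A", "B", 0.0)
        assert rb.s[0] == pytest.approx(2 * ra.s[0], abs=1e-12)

    def test_antisymmetric_under_group_swap(self, design_3v3):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(8, 1, (30, 6)), sample_ids=design_3v3.sample_ids)
        ab = sam_statistic(m, design_3v3, "A", "B", 0.2)
        ba = sam_statistic(m, design_3v3, "B", "A", 0.2)
        np.testing.assert_allclose(ab.d, -ba.d, atol=1e-12)
        np.testing.assert_allclose(ab.fc, 1.0 / ba.fc, rtol=1e-12)

    def test_small_group_rejected(self):
        d = DesignTable(["a", "b", "c"], ["m"] * 3, ["A", "B", "B"], [1, 1, 2])
        m = make_matrix(np.ones((2, 3)), sample_ids=["a", "b", "c"])
        with pytest.raises(ValueError, match=">=2 samples"):
            sam_statistic(m, d, "A", "B", 0.1)


class TestTuneS0:
    def test_equal_scatter_returns_smallest_candidate(self, design_3v3):
        rng = np.random.default_rng(1)
        # identical within-group deviations for every feature -> identical s
        base = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        shifts = rng.normal(8, 2, 60)
        X = shifts[:, None] + base[None, :]
        m = make_matrix(X, sample_ids=design_3v3.sample_ids)
        s0 = tune_s0(m, design_3v3, "A", "B")
        res = sam_statistic(m, design_3v3, "A", "B", 0.0)
        assert s0 == pytest.approx(np.percentile(res.s, 0))

    def test_few_features_falls_back_to_median(self, design_3v3):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(8, 1, (20, 6)), sample_ids=design_3v3.sample_ids)
        res = sam_statistic(m, design_3v3, "A", "B", 0.0)
        assert tune_s0(m, design_3v3, "A", "B") == pytest.approx(np.median(res.s))

    def test_within_scatter_range_on_null_data(self, design_3v3):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(8, 0.25, (5000, 6)), sample_ids=design_3v3.sample_ids)
        s0 = tune_s0(m, design_3v3, "A", "B")
        res = sam_statistic(m, design_3v3, "A", "B", 0.0)
        assert np.percentile(res.s, 0) <= s0 <= np.percentile(res.s, 95)


class TestPermutationFdr:
    def test_exhaustive_enumeration_3v3(self, design_3v3):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.normal(8, 1, (50, 6)), sample_ids=design_3v3.sample_ids)
        res = run_sam(m, design_3v3, "A", "B", SamParams(n_perm=100, seed=0))
        assert res.n_perm_used == 20  # C(6,3)

    def test_seeded_bit_reproducibility(self, design_3v3):
        rng = np.random.default_rng(5)
        X = rng.normal(8, 0.5, (100, 6))
        X[:5, 3:] += 2.5
        m = make_matrix(X, sample_ids=design_3v3.sample_ids)
        p = SamParams(n_perm=50, seed=9, fc_cutoff=2.0)
        r1 = run_sam(m, design_3v3, "A", "B", p)
        r2 = run_sam(m, design_3v3, "A", "B", p)
        np.testing.assert_array_equal(r1.d, r2.d)
        np.testing.assert_array_equal(r1.significant, r2.significant)
        assert r1.delta == r2.delta

    def test_fc_gate_monotone_in_cutoff(self, design_3v3):
        rng = np.random.default_rng(6)
        X = rng.normal(8, 0.4, (200, 6))
        X[:20, 3:] += rng.uniform(1.2, 3.0, (20, 3))
        m = make_matrix(X, sample_ids=design_3v3.sample_ids)
        sig3 = set(
            run_sam(m, design_3v3, "A", "B", SamParams(seed=1, fc_cutoff=3.0)).significant_ids()
        )
        sig2 = set(
            run_sam(m, design_3v3, "A", "B", SamParams(seed=1, fc_cutoff=2.0)).significant_ids()
        )
        assert sig3 <= sig2

    def test_planted_features_called_with_direction(self, design_3v3):
        rng = np.random.default_rng(7)
        X = rng.normal(8, 0.25, (500, 6))
        X[:30, 3:] += 3.0
        X[30:60, 3:] -= 3.0
        m = make_matrix(X, sample_ids=design_3v3.sample_ids)
        res = run_sam(m, design_3v3, "A", "B", SamParams(seed=2, fc_cutoff=3.0))
        sig = set(res.significant_ids())
        planted = {f"f{i}" for i in range(60)}
        # the feature sitting exactly on delta is excluded by the strict
        # exceedance rule, so require near-complete rather than total recovery
        assert len(planted & sig) >= 0.95 * len(planted)
        assert not (sig - planted)
        dir_of = dict(zip(res.feature_ids, res.direction))
        assert all(dir_of[f] == "up" for f in sig if int(f[1:]) < 30)
        assert all(dir_of[f] == "down" for f in sig if 30 <= int(f[1:]) < 60)


class TestPairwiseUnion:
    def _study(self, rng):
        # KO24-only effect in features 0-9; WT24+KO24 (age) effect in 10-19
        X = rng.normal(8, 0.25, (300, 12))
        X[:10, 9:12] += 3.0
        X[10:20, 6:12] += 3.0
        return X

    def test_union_matches_per_pair_oracle(self, mouse_design_12):
        X = self._study(np.random.default_rng(8))
        m = make_matrix(X, sample_ids=mouse_design_12.sample_ids)
        pairs = [("WT6", "KO6"), ("WT24", "KO24"), ("KO6", "KO24"), ("WT6", "WT24")]
        params = SamParams(seed=3, fc_cutoff=3.0)
        union, provenance, per_pair = pairwise_union(m, mouse_design_12, pairs, params)
        oracle = set()
        for ga, gb in pairs:
            oracle |= set(run_sam(m, mouse_design_12, ga, gb, params).significant_ids())
        assert set(union) == oracle

    def test_duplicate_pair_idempotent(self, mouse_design_12):
        X = self._study(np.random.default_rng(9))
        m = make_matrix(X, sample_ids=mouse_design_12.sample_ids)
        params = SamParams(seed=4, fc_cutoff=3.0)
        u1, _, _ = pairwise_union(m, mouse_design_12, [("WT24", "KO24")], params)
        u2, _, _ = pairwise_union(
            m, mouse_design_12, [("WT24", "KO24"), ("WT24", "KO24")], params
        )
        assert u1 == u2

    def test_empty_pair_list_rejected(self, mouse_design_12):
        m = make_matrix(np.ones((3, 12)), sample_ids=mouse_design_12.sample_ids)
        with pytest.raises(ValueError):
            pairwise_union(m, mouse_design_12, [], SamParams())
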