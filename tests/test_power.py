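"""Power scan, cluster labeling, and cluster power tables."""

import numpy as np
import pandas as pd
import pytest

from jackmap import (
    CohortSpec,
    ThresholdConfig,
    cluster_power_table,
    label_clusters,
    power_scan,
    simulate_cohort,
)
from jackmap.power import NOT_SIGNIFICANT, PowerMap


class TestLabelClusters:
    def test_two_separated_blobs_get_two_labels(self):
        v = np.zeros((10, 6, 6), bool)
        v[1:3, 1:3, 1:3] = True
        v[6:9, 1:4, 1:4] = True
        labels = label_clusters(v)
        assert labels.max() == 2
        # larger cluster gets label 1
        assert (labels == 1).sum() > (labels == 2).sum()

    def test_single_isolated_voxel_is_a_cluster_of_one(self):
        v = np.zeros((5, 5, 5), bool)
        v[2, 2, 2] = True
        labels = label_clusters(v)
        assert labels.max() == 1 and (labels == 1).sum() == 1

    def test_corner_touching_voxels_depend_on_connectivity(self):
        v = np.zeros((4, 4, 4), bool)
        v[1, 1, 1] = True
        v[2, 2, 2] = True  # touch only at a corner
        assert label_clusters(v, connectivity=26).max() == 1
        assert label_clusters(v, connectivity=6).max() == 2

    def test_deterministic_ordering_by_size_then_position(self):
        v = np.zeros((12, 4, 4), bool)
        v[8:10, 1, 1] = True   # size 2, later position
        v[1:3, 1, 1] = True    # size 2, earlier position
        v[5, 1, 1] = True      # size 1
        labels = label_clusters(v, connectivity=6)
        assert labels[1, 1, 1] == 1   # tie broken by lexicographic min voxel
        assert labels[8, 1, 1] == 2
        assert labels[5, 1, 1] == 3

    def test_invalid_connectivity_rejected(self):
        with pytest.raises(ValueError, match="connectivity"):
            label_clusters(np.zeros((2, 2, 2), bool), connectivity=4)


class TestPowerScan:
    def test_noise_free_blob_reaches_floor(self, noise_free_cohort):
        """With zero noise every subset detects the blob, so min_n is the
        floor everywhere on the blob and the sentinel elsewhere."""
        cfg = ThresholdConfig(method="fwe_bonferroni", alpha=0.05)
        with pytest.warns(RuntimeWarning):
            pm = power_scan(noise_free_cohort, config=cfg, floor=4, cap=10,
                            seed=0)
        blob = noise_free_cohort.data[0] > 0
        assert (pm.min_n[blob] == 4).all()
        assert (pm.min_n[~blob] == NOT_SIGNIFICANT).all()

    def test_min_n_defined_only_on_full_group_significant_set(self,
                                                              small_cohort,
                                                              fdr_config):
        pm = power_scan(small_cohort, config=fdr_config, floor=6, cap=20,
                        seed=1)
        sig = pm.full_map.significant
        assert (pm.min_n[~sig] == NOT_SIGNIFICANT).all()
        defined = pm.min_n[sig]
        assert ((defined >= pm.floor) & (defined <= pm.n)).all()

    def test_monotone_closure_leaves_no_detection_gaps(self, small_cohort,
                                                       fdr_config):
        """Wherever min_n = m, the detection fraction meets the safe
        threshold at every evaluated size >= m."""
        pm = power_scan(small_cohort, config=fdr_config, floor=6, cap=20,
                        seed=1)
        safe = pm.detection_pct >= pm.safe_threshold - 1e-9
        for si, m in enumerate(pm.sizes):
            chain_here = (pm.min_n > 0) & (pm.min_n <= m)
            assert safe[si][chain_here].all()

    def test_deterministic_under_seed(self, small_cohort, fdr_config):
        a = power_scan(small_cohort, config=fdr_config, floor=10, cap=15, seed=4)
        b = power_scan(small_cohort, config=fdr_config, floor=10, cap=15, seed=4)
        np.testing.assert_array_equal(a.min_n, b.min_n)
        np.testing.assert_array_equal(a.detection_pct, b.detection_pct)

    def test_floor_below_feasibility_rejected(self, small_cohort, fdr_config):
        with pytest.raises(ValueError, match="floor"):
            power_scan(small_cohort, config=fdr_config, floor=1)

    def test_stride_skips_sizes(self, small_cohort, fdr_config):
        pm = power_scan(small_cohort, config=fdr_config, floor=8, cap=10,
                        seed=0, stride=3)
        assert pm.sizes == [14, 11, 8]

    def test_fwe_needs_at_least_as_many_subjects_as_fdr(self):
        """Stricter control requires more subjects: voxelwise
        min_n(FWE-Bonferroni) >= min_n(FDR) wherever FWE defines it."""
        spec = CohortSpec(grid_shape=(10, 10, 8), n_subjects=19,
                          blobs=[((5, 5, 4), 1.3, 1.8)], noise_sd=1.0, seed=2)
        cohort = simulate_cohort(spec)
        kw = dict(floor=12, cap=50, seed=7)
        pm_fwe = power_scan(cohort, config=ThresholdConfig("fwe_bonferroni", 0.05), **kw)
        pm_fdr = power_scan(cohort, config=ThresholdConfig("fdr_bh", 0.05), **kw)
        both = (pm_fwe.min_n > 0) & (pm_fdr.min_n > 0)
        assert both.any()
        assert (pm_fwe.min_n[both] >= pm_fdr.min_n[both]).all()


class TestClusterTable:
    def _powermap(self, min_n, sizes, pct, full_sig, t):
        from jackmap.glm import ThresholdedMap, TMap

        mask = np.ones(min_n.shape, bool)
        thr = ThresholdedMap(significant=full_sig, method="uncorrected",
                             alpha=0.05, n_tests=min_n.size, mask=mask)
        tm = TMap(t=t, df=10, mask=mask, contrast=np.array([1.0]),
                  zero_variance=np.zeros(min_n.shape, bool), effect=t,
                  n=11)
        return PowerMap(min_n=min_n, sizes=sizes, detection_pct=pct,
                        full_map=thr, full_t=tm, n=11, floor=min(sizes),
                        safe_threshold=100.0, cap=10)

    def test_cluster_min_n_is_minimum_over_members(self):
        shape = (8, 4, 4)
        min_n = np.zeros(shape, np.int32)
        full_sig = np.zeros(shape, bool)
        full_sig[1:4, 1, 1] = True
        min_n[1, 1, 1], min_n[2, 1, 1], min_n[3, 1, 1] = 14, 18, 22
        t = np.zeros(shape)
        t[1:4, 1, 1] = [3.0, 5.0, 4.0]
        sizes = [22, 18, 14]
        pct = np.zeros((3,) + shape)
        pm = self._powermap(min_n, sizes, pct, full_sig, t)
        labels = label_clusters(full_sig, connectivity=6)
        table = cluster_power_table(pm, labels)
        assert len(table) == 1
        assert table.loc[0, "min_n"] == 14
        assert table.loc[0, "peak_t"] == 5.0
        assert (table.loc[0, ["peak_i", "peak_j", "peak_k"]] == [2, 1, 1]).all()

    def test_uniform_cluster_min_n_trivial(self):
        shape = (5, 4, 4)
        min_n = np.zeros(shape, np.int32)
        full_sig = np.zeros(shape, bool)
        full_sig[1:3, 1, 1] = True
        min_n[full_sig] = 12
        pm = self._powermap(min_n, [12], np.zeros((1,) + shape), full_sig,
                            np.ones(shape))
        table = cluster_power_table(pm, label_clusters(full_sig))
        assert table.loc[0, "min_n"] == 12

    def test_min_n_rule_variants(self):
        shape = (8, 4, 4)
        min_n = np.zeros(shape, np.int32)
        full_sig = np.zeros(shape, bool)
        full_sig[1:4, 1, 1] = True
        min_n[1, 1, 1], min_n[2, 1, 1], min_n[3, 1, 1] = 14, 18, 22
        t = np.zeros(shape)
        t[1:4, 1, 1] = [3.0, 5.0, 4.0]
        pm = self._powermap(min_n, [22, 18, 14], np.zeros((3,) + shape),
                            full_sig, t)
        labels = label_clusters(full_sig, connectivity=6)
        assert cluster_power_table(pm, labels, min_n_rule="any").loc[0, "min_n"] == 14
        assert cluster_power_table(pm, labels, min_n_rule="all").loc[0, "min_n"] == 22
        assert cluster_power_table(pm, labels, min_n_rule="peak").loc[0, "min_n"] == 18

    def test_shape_mismatch_rejected(self, small_cohort, fdr_config):
        pm = power_scan(small_cohort, config=fdr_config, floor=10, cap=5, seed=0)
        with pytest.raises(ValueError, match="shape"):
            cluster_power_table(pm, np.zeros((2, 2, 2), np.int32))

    def test_noise_free_per_size_counts_non_decreasing(self, noise_free_cohort):
        cfg = ThresholdConfig(method="fwe_bonferroni", alpha=0.05)
        with pytest.warns(RuntimeWarning):
            pm = power_scan(noise_free_cohort, config=cfg, floor=4, cap=10,
                            seed=0)
        labels = label_clusters(pm.full_map.significant)
        table = cluster_power_table(pm, labels)
        counts = table.loc[0, [f"n_detected_at_{m}" for m in pm.sizes]]
        counts = counts.to_numpy(dtype=int)[::-1]  # ascending size
        assert (np.diff(counts) >= 0).all()


def test_min_n_rank_correlates_with_full_group_t(small_cohort, fdr_config):
    """Stronger full-group t goes with smaller minimum detecting size in
    trend (negative rank correlation), without being one-to-one."""
    from scipy import stats

    pm = power_scan(small_cohort, config=fdr_config, floor=6, cap=30, seed=3)
    sig = pm.full_map.significant & (pm.min_n > 0)
    if sig.sum() < 5:
        pytest.skip("too few significant voxels in fixture")
    rho = stats.spearmanr(pm.full_t.t[sig], pm.min_n[sig]).statistic
    assert rho < 0
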