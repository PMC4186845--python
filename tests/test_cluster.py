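"""Monte-Carlo cluster-extent correction: null simulation, extent threshold,
component extraction against a BFS oracle, and report formatting."""

from collections import deque

import numpy as np
import pytest
from scipy import stats

from restvar import (
    extract_clusters,
    min_cluster_size,
    report_clusters,
    simulate_null_distribution,
)
from restvar.cluster import NullClusterDistribution, connectivity_structure
from restvar.variability import CohortStatMap


def _stat_from_r(r: np.ndarray, n: int = 10, mask=None) -> CohortStatMap:
    mask = np.ones(r.shape, dtype=bool) if mask is None else mask
    t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    return CohortStatMap(r=r, p=p, mask=mask, n_subjects=n, metric_name="test")


class TestSimulateNull:
    def test_fixed_seed_reproducible(self):
        mask = np.ones((12, 12, 10), dtype=bool)
        a = simulate_null_distribution(mask, 3.0, 2.0, 0.05, 50, seed=5)
        b = simulate_null_distribution(mask, 3.0, 2.0, 0.05, 50, seed=5)
        assert np.array_equal(a.max_cluster_sizes, b.max_cluster_sizes)

    def test_everything_survives_at_loose_threshold(self):
        """voxel_p -> 1 keeps every voxel, so the max cluster is the largest
        connected component of the mask itself."""
        mask = np.zeros((10, 10, 4), dtype=bool)
        mask[:4, :4, :2] = True   # 32 voxels
        mask[6:, 6:, 2:] = True   # 32 voxels, disconnected from the first
        mask[:6, :6, 3] = True    # 36 voxels, disconnected from both
        dist = simulate_null_distribution(mask, 0.0, 2.0, 1 - 1e-12, 5, seed=0)
        from scipy import ndimage

        labeled, n = ndimage.label(mask, structure=connectivity_structure("faces"))
        largest = np.bincount(labeled.ravel())[1:].max()
        assert np.all(dist.max_cluster_sizes == largest)

    def test_unsmoothed_suprathreshold_fraction_matches_voxel_p(self):
        """White noise at voxel p = 0.05: ~5% of voxels exceed threshold."""
        mask = np.ones((20, 20, 20), dtype=bool)
        dist = simulate_null_distribution(mask, 0.0, 2.0, 0.05, 50, seed=1)
        assert np.mean(dist.supra_fractions) == pytest.approx(0.05, abs=0.01)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            simulate_null_distribution(np.zeros((4, 4, 4), bool), 3.0, 2.0, 0.05, 10)


def _dist(sizes, n_iter=None) -> NullClusterDistribution:
    sizes = np.asarray(sizes)
    return NullClusterDistribution(
        max_cluster_sizes=sizes,
        n_iter=len(sizes) if n_iter is None else n_iter,
        voxel_p_threshold=0.05,
        fwhm=3.0,
        connectivity_rule="faces",
        mask_size=10_000,
        seed=0,
    )


class TestMinClusterSize:
    def test_degenerate_distribution(self):
        assert min_cluster_size(_dist([10] * 100), alpha=0.05) == 11

    def test_quantile_definition_on_mixed_sizes(self):
        # 100 draws: 90 of size 3, 10 of size 20 -> P(max >= 4) = 0.10,
        # P(max >= 21) = 0 -> smallest k with tail <= 0.05 is 21
        sizes = [3] * 90 + [20] * 10
        assert min_cluster_size(_dist(sizes), alpha=0.05) == 21
        assert min_cluster_size(_dist(sizes), alpha=0.10) == 4

    def test_loose_alpha_keeps_single_voxels(self):
        sizes = [0] * 50 + [5] * 50
        # P(max >= 1) = 0.5 <= alpha -> every nonempty cluster passes
        assert min_cluster_size(_dist(sizes), alpha=0.6) == 1

    def test_alpha_below_resolution_warns(self):
        with pytest.warns(UserWarning):
            min_cluster_size(_dist([2] * 100), alpha=1e-4)

    def test_monotone_in_forming_threshold_and_alpha(self):
        """Stricter voxel threshold -> smaller clusters -> k_min does not
        increase; smaller alpha -> k_min does not decrease."""
        mask = np.ones((16, 16, 12), dtype=bool)
        k_by_p = []
        for voxel_p in (0.05, 0.01, 0.001):
            dist = simulate_null_distribution(mask, 3.0, 2.0, voxel_p, 200, seed=9)
            k_by_p.append(min_cluster_size(dist, 0.05))
        assert k_by_p[0] >= k_by_p[1] >= k_by_p[2]
        dist = simulate_null_distribution(mask, 3.0, 2.0, 0.05, 200, seed=9)
        assert min_cluster_size(dist, 0.01) >= min_cluster_size(dist, 0.05)

    def test_monotone_in_smoothness(self):
        mask = np.ones((16, 16, 12), dtype=bool)
        ks = [
            min_cluster_size(
                simulate_null_distribution(mask, fwhm, 2.0, 0.05, 200, seed=9), 0.05
            )
            for fwhm in (0.0, 3.0, 6.0)
        ]
        assert ks[0] <= ks[1] <= ks[2]


def _bfs_components(mask: np.ndarray, structure: np.ndarray) -> list[set]:
    """Brute-force BFS connected components of a 3D boolean array."""
    offsets = [
        (i - 1, j - 1, k - 1)
        for i in range(3)
        for j in range(3)
        for k in range(3)
        if structure[i, j, k] and (i, j, k) != (1, 1, 1)
    ]
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp, queue = set(), deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for d in offsets:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[a] < mask.shape[a] for a in range(3)):
                    if mask[w] and not seen[w]:
                        seen[w] = True
                        queue.append(w)
        comps.append(comp)
    return comps


class TestExtractClusters:
    def test_extent_threshold_filters_small_blob(self):
        r = np.zeros((20, 20, 10))
        r[:10, :10, :3] = 0.95   # 300 voxels
        r[12:17, 12:17, 5:9] = 0.95  # 100 voxels
        stat = _stat_from_r(r)
        clusters = extract_clusters(stat, voxel_p=0.05, k_min=258)
        assert len(clusters) == 1
        assert clusters[0].size == 300

    def test_no_suprathreshold_voxels(self):
        stat = _stat_from_r(np.zeros((5, 5, 5)))
        assert extract_clusters(stat, 0.05, 1) == []

    def test_sign_split_separates_touching_blobs(self):
        r = np.zeros((6, 2, 2))
        r[:3] = 0.95
        r[3:] = -0.95
        clusters = extract_clusters(_stat_from_r(r), 0.05, 1, split_sign=True)
        assert sorted(c.size for c in clusters) == [12, 12]
        assert sorted(c.sign for c in clusters) == [-1, 1]
        merged = extract_clusters(_stat_from_r(r), 0.05, 1, split_sign=False)
        assert [c.size for c in merged] == [24]

    @pytest.mark.parametrize("rule", ["faces", "edges", "corners"])
    def test_components_match_bfs_oracle(self, rule, rng):
        structure = connectivity_structure(rule)
        for _ in range(20):
            r = np.where(rng.random((12, 12, 12)) > 0.7, 0.95, 0.0)
            stat = _stat_from_r(r)
            clusters = extract_clusters(stat, 0.05, 1, connectivity_rule=rule)
            got = {frozenset(map(tuple, np.argwhere(c.mask))) for c in clusters}
            expected = {frozenset(c) for c in _bfs_components(r > 0, structure)}
            assert len(got) == len(clusters) and got == expected


class TestReportClusters:
    def _one_voxel_setup(self):
        r = np.zeros((8, 8, 6))
        r[6, 2, 3] = 0.87
        stat = _stat_from_r(r)
        clusters = extract_clusters(stat, 0.05, 1)
        # RAS affine with left hemisphere at high i (x flips sign)
        affine = np.diag([-2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [7.0, -7.0, -5.0]
        parc = np.zeros((8, 8, 6), dtype=int)
        parc[6, 2, 3] = 4
        labels = {4: ("putamen", "L")}
        return clusters, stat, parc, labels, affine

    def test_peak_coordinates_lps_and_ras(self):
        clusters, stat, parc, labels, affine = self._one_voxel_setup()
        rep_lps = report_clusters(clusters, stat, parc, labels, affine, "LPS")
        rep_ras = report_clusters(clusters, stat, parc, labels, affine, "RAS")
        row_l, row_r = rep_lps.table.iloc[0], rep_ras.table.iloc[0]
        # i=6 -> RAS x = -2*6 + 7 = -5 -> LPS x = +5 (left hemisphere)
        assert row_r["peak_x"] == pytest.approx(-5.0)
        assert row_l["peak_x"] == pytest.approx(5.0)
        assert row_l["peak_y"] == pytest.approx(-row_r["peak_y"])
        assert row_l["peak_z"] == pytest.approx(row_r["peak_z"])
        assert row_l["side"] == "L" and row_r["side"] == "L"
        assert row_l["region"] == "putamen"

    def test_peak_p_formatting_for_strong_correlation(self):
        """A peak of r = 0.87 with 10 subjects reports p ~ 0.001 (1 sf)."""
        clusters, stat, parc, labels, affine = self._one_voxel_setup()
        rep = report_clusters(clusters, stat, parc, labels, affine)
        p = rep.table.iloc[0]["peak_p"]
        assert float(f"{p:.0e}") == pytest.approx(0.001)
        assert rep.table.iloc[0]["peak_r"] == pytest.approx(0.87)

    def test_tied_peaks_use_smallest_linear_index(self):
        r = np.zeros((4, 4, 4))
        r[1, 1, 1] = 0.9
        r[2, 1, 1] = 0.9  # same |r|, larger linear index, faces-adjacent
        stat = _stat_from_r(r)
        clusters = extract_clusters(stat, 0.05, 1)
        assert len(clusters) == 1
        affine = np.eye(4)
        rep = report_clusters(clusters, stat, np.zeros((4, 4, 4), int), {}, affine, "RAS")
        assert rep.table.iloc[0]["peak_x"] == pytest.approx(1.0)

    def test_parcel_counts_cover_cluster(self):
        clusters, stat, parc, labels, affine = self._one_voxel_setup()
        rep = report_clusters(clusters, stat, parc, labels, affine)
        assert rep.parcel_counts[0] == {"putamen_L": 1}

    def test_unknown_orientation_rejected(self):
        clusters, stat, parc, labels, affine = self._one_voxel_setup()
        with pytest.raises(ValueError):
            report_clusters(clusters, stat, parc, labels, affine, "SPL")
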