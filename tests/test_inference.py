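"""Group-inference tests: voxel statistics, cluster forming against a
flood-fill oracle, sign-flip/label permutation nulls (exhaustive vs
Monte-Carlo), permutation p-values and BH correction, and the cluster
naming rules."""

import numpy as np
import pytest
from scipy import stats as sp_stats

from pupilseed import inference

MASK8 = np.ones((8, 8, 4), bool)


def stat_from_t(t_vol, df=30, mask=None):
    mask = MASK8 if mask is None else mask
    return inference.StatMap(
        t=np.asarray(t_vol, dtype=float), df=df, contrast="one_sample",
        n_subjects=df + 1, mask=mask,
        affine=np.diag([1.5, 1.5, 1.5, 1.0]),
    )


class TestOneSampleT:
    def test_all_zero_maps_give_zero_t(self):
        Z = np.zeros((5, 20))
        stat = inference.one_sample_t(Z, mask=np.ones((4, 5, 1), bool))
        np.testing.assert_array_equal(stat.t[np.ones((4, 5, 1), bool)], 0.0)
        assert stat.df == 4

    def test_null_tail_fraction_matches_t_distribution(self, rng):
        n, V = 40, 10_000
        Z = rng.standard_normal((n, V))
        stat = inference.one_sample_t(Z, mask=np.ones((100, 100, 1), bool))
        t_crit = sp_stats.t.isf(0.0005, n - 1)
        frac = np.mean(np.abs(stat.t[np.ones((100, 100, 1), bool)]) > t_crit)
        assert abs(frac - 0.001) < 0.0005

    def test_two_subjects_rejected(self):
        with pytest.raises(ValueError):
            inference.one_sample_t(np.zeros((2, 10)), mask=np.ones((10, 1, 1), bool))

    def test_zero_variance_sentinel(self):
        Z = np.tile([[1.0, 0.0]], (5, 1))
        stat = inference.one_sample_t(Z, mask=np.ones((2, 1, 1), bool))
        assert np.isposinf(stat.t[0, 0, 0])
        assert stat.t[1, 0, 0] == 0.0
        assert stat.n_zero_variance == 2


class TestGroupGLM:
    def test_null_labels_give_near_zero_mean_t(self, rng):
        n, V = 40, 2000
        Z = rng.standard_normal((n, V))
        group = rng.permutation(np.repeat([0.0, 1.0], n // 2))
        stat = inference.group_glm(Z, group, covariates=rng.standard_normal(n),
                                   mask=np.ones((40, 50, 1), bool))
        assert abs(np.nanmean(stat.t)) < 3.0 / np.sqrt(V)

    def test_planted_attenuation_detected_at_voxel_level(self, rng):
        n = 76
        group = np.repeat([0.0, 1.0], 38)  # 1 = older
        Z = 0.05 * rng.standard_normal((n, 100))
        Z[:, :10] += np.where(group == 1, 0.15, 0.48)[:, None]  # attenuated
        stat = inference.group_glm(Z, group, mask=np.ones((10, 10, 1), bool))
        t_crit = sp_stats.t.isf(0.0005, stat.df)
        flat = stat.t[np.ones((10, 10, 1), bool)]
        assert np.all(flat[:10] < -t_crit)

    def test_covariate_equal_to_group_rejected(self):
        group = np.repeat([0.0, 1.0], 10)
        with pytest.raises(ValueError):
            inference.group_glm(np.zeros((20, 5)), group, covariates=group,
                                mask=np.ones((5, 1, 1), bool))


def flood_fill_components(supra):
    """Face-connected components by BFS; independent of scipy labeling."""
    seen = np.zeros_like(supra, bool)
    comps = []
    for start in map(tuple, np.argwhere(supra)):
        if seen[start]:
            continue
        comp, queue = [], [start]
        seen[start] = True
        while queue:
            v = queue.pop()
            comp.append(v)
            for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                      (0, 0, 1), (0, 0, -1)):
                u = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= u[i] < supra.shape[i] for i in range(3)) \
                        and supra[u] and not seen[u]:
                    seen[u] = True
                    queue.append(u)
        comps.append(sorted(comp))
    return sorted(comps, key=len, reverse=True)


class TestFormClusters:
    def test_flat_map_gives_empty_table(self):
        table = inference.form_clusters(stat_from_t(np.zeros((8, 8, 4))))
        assert len(table) == 0

    def test_two_blobs_with_oracle_sizes(self):
        t = np.zeros((8, 8, 4))
        t[1:3, 1:3, 0] = 10.0       # 4 voxels
        t[5:7, 4:8, 1:2] += 10.0    # disjoint 8-voxel slab
        t[5, 4, 2] = 10.0           # face-connected to the slab -> 9
        table = inference.form_clusters(stat_from_t(t))
        oracle = flood_fill_components(t > inference.sp_stats.t.isf(0.0005, 30))
        assert [c.size for c in table] == [len(c) for c in oracle]
        assert {tuple(sorted(map(tuple, c.voxels))) for c in table} == {
            tuple(c) for c in oracle
        }

    def test_opposite_signs_never_merge(self):
        t = np.zeros((8, 8, 4))
        t[2, 2:4, 1] = 8.0
        t[2, 4:6, 1] = -8.0  # adjacent, opposite sign
        table = inference.form_clusters(stat_from_t(t))
        assert len(table) == 2
        assert {c.sign for c in table} == {"positive", "negative"}

    def test_peak_reported_in_mm(self):
        t = np.zeros((8, 8, 4))
        t[4, 2, 3] = 9.0
        c = inference.form_clusters(stat_from_t(t)).clusters[0]
        assert c.peak_voxel == (4, 2, 3)
        assert c.peak_mm == (6.0, 3.0, 4.5)


class TestPermutationNull:
    def test_exhaustive_matches_monte_carlo(self, rng):
        Z = rng.standard_normal((10, 8 * 8 * 4)) + 0.4
        with pytest.warns(UserWarning, match="exhaustively"):
            exact = inference.cluster_extent_null(
                Z, n_perm=1024, seed=0, mask=MASK8
            )
        assert exact.exhaustive and exact.n_perm == 1024
        mc = inference.cluster_extent_null(Z + 0.0, n_perm=1000, seed=1,
                                           mask=MASK8)
        assert not mc.exhaustive  # 2^10 > 1000
        se = exact.max_extents.std() / np.sqrt(1000) * 4 + 0.5
        assert abs(exact.max_extents.mean() - mc.max_extents.mean()) < se

    def test_exhaustive_null_invariant_to_subject_order(self, rng):
        Z = rng.standard_normal((8, 8 * 8 * 4))
        with pytest.warns(UserWarning):
            a = inference.cluster_extent_null(Z, n_perm=256, seed=0, mask=MASK8)
            b = inference.cluster_extent_null(Z[::-1], n_perm=256, seed=5,
                                              mask=MASK8)
        np.testing.assert_array_equal(np.sort(a.max_extents),
                                      np.sort(b.max_extents))

    def test_planted_effect_leaves_null_unchanged_in_distribution(self, rng):
        noise = rng.standard_normal((12, 8 * 8 * 4))
        planted = noise.copy()
        planted[:, :30] += 1.5  # strong common effect
        a = inference.cluster_extent_null(noise, n_perm=400, seed=3, mask=MASK8)
        b = inference.cluster_extent_null(planted, n_perm=400, seed=3,
                                          mask=MASK8)
        # sign flips break the coupling: same-order mean extents
        assert abs(a.max_extents.mean() - b.max_extents.mean()) < 1.5

    def test_group_null_is_deterministic_given_seed(self, rng):
        Z = rng.standard_normal((20, 8 * 8 * 4))
        group = np.repeat([0.0, 1.0], 10)
        a = inference.cluster_extent_null(Z, design="group", group=group,
                                          n_perm=150, seed=9, mask=MASK8)
        b = inference.cluster_extent_null(Z, design="group", group=group,
                                          n_perm=150, seed=9, mask=MASK8)
        np.testing.assert_array_equal(a.max_extents, b.max_extents)


def bh_oracle(p):
    """Step-up BH from its definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q


class TestClusterFDR:
    def _table(self, sizes):
        clusters = [
            inference.Cluster(
                voxels=np.zeros((s, 3), int), size=s, peak_voxel=(0, 0, 0),
                peak_mm=(0, 0, 0), peak_t=5.0, sign="positive",
            )
            for s in sizes
        ]
        return inference.ClusterTable(clusters=clusters, voxel_p=0.001,
                                      t_threshold=3.3, df=30)

    def _null(self, extents):
        return inference.NullDistribution(
            max_extents=np.asarray(extents), n_perm=len(extents),
            design="one_sample",
        )

    def test_cluster_beyond_null_hits_permutation_floor(self):
        out = inference.cluster_fdr(self._table([50]),
                                    self._null([1] * 999))
        assert out.clusters[0].p_uncorrected == pytest.approx(1 / 1000)

    def test_tied_sizes_share_fdr_p(self):
        out = inference.cluster_fdr(self._table([5, 5, 5]),
                                    self._null([3, 4, 6, 8] * 100))
        qs = {c.p_fdr for c in out.clusters}
        assert len(qs) == 1

    def test_bh_matches_definitional_oracle(self, rng):
        sizes = rng.integers(1, 40, size=12)
        null = rng.integers(1, 30, size=500)
        out = inference.cluster_fdr(self._table(list(sizes)), self._null(null))
        p = np.array([c.p_uncorrected for c in out.clusters])
        q = np.array([c.p_fdr for c in out.clusters])
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
        assert np.all(q >= p - 1e-15)


class TestLabeling:
    def _table_with_peak(self, peak):
        c = inference.Cluster(
            voxels=np.array([peak]), size=1, peak_voxel=tuple(peak),
            peak_mm=(0, 0, 0), peak_t=5.0, sign="positive",
        )
        return inference.ClusterTable(clusters=[c], voxel_p=0.001,
                                      t_threshold=3.3, df=10)

    def test_labeled_peak_gets_region_name(self):
        vol = np.zeros((4, 4, 4), int)
        vol[1, 1, 1] = 3
        out = inference.label_clusters(self._table_with_peak((1, 1, 1)), vol,
                                       {3: "insula"})
        assert out.clusters[0].name == "insula"

    def test_unlabeled_peak_uses_neighbour_majority_with_star(self):
        vol = np.zeros((4, 4, 4), int)
        vol[0:3, 0:3, 0:3] = 7
        vol[1, 1, 1] = 0  # peak itself unlabeled
        out = inference.label_clusters(self._table_with_peak((1, 1, 1)), vol,
                                       {7: "precuneus"})
        assert out.clusters[0].name == "precuneus*"

    def test_fully_unlabeled_neighbourhood(self):
        vol = np.zeros((4, 4, 4), int)
        out = inference.label_clusters(self._table_with_peak((1, 1, 1)), vol, {})
        assert out.clusters[0].name == "unlabeled*"


class TestModelResults:
    def test_summary_reports_counts(self, rng):
        Z = rng.standard_normal((12, 8 * 8 * 4))
        Z[:, :20] += 1.2
        res = inference.ClusterInferenceModel(Z, mask=MASK8).fit(
            n_perm=200, seed=0
        )
        text = res.summary()
        assert "Cluster-extent inference" in text
        assert f"{len(res.clusters)} clusters" in text
        assert len(res.significant_clusters) >= 1
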