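"""Pooling, k-means mode clustering, silhouette k selection and matching."""

import warnings

import numpy as np
import pytest

from slipsynergy import clustering, stats
from slipsynergy.clustering import (
    ClusteredModes,
    cluster_stage,
    compare_mode_weights,
    kmeans,
    match_stages,
    name_and_order,
    pool,
    select_k,
)
from slipsynergy.io_model import CANONICAL_LABELS
from slipsynergy.synergy import SynergySet


def fake_synergy(w, seed=0):
    w = np.asarray(w, dtype=float)
    k = w.shape[1]
    return SynergySet(W=w, C=np.ones((k, 10)), k=k, vaf_global=95.0,
                      vaf_muscle=np.full(8, 95.0), residual=np.zeros((8, 10)),
                      restarts_used=1, seed=seed)


def planted_groups(n_groups, per_group, spread=0.02, seed=0):
    """Well-separated unit-max synergy columns around n_groups prototypes."""
    rng = np.random.default_rng(seed)
    protos = np.zeros((8, n_groups))
    for j in range(n_groups):
        protos[j % 8, j] = 1.0
        protos[(j + 3) % 8, j] = 0.4
    cols, labels = [], []
    for j in range(n_groups):
        for i in range(per_group):
            v = np.clip(protos[:, j] + rng.normal(0, spread, 8), 0, None)
            cols.append(v / v.max())
            labels.append(j)
    return np.column_stack(cols), np.array(labels)


class TestPool:
    def test_column_count_matches_dimensionalities(self):
        # 8 participants with K=3, 9 with K=4, 9 with K=5 -> 105 columns
        rng = np.random.default_rng(5)
        sets = []
        for i, k in enumerate([3] * 8 + [4] * 9 + [5] * 9):
            w = np.clip(rng.random((8, k)), 0.01, None)
            sets.append((f"P{i}", fake_synergy(w / w.max(axis=0))))
        pooled = pool(sets, stage="early")
        assert pooled.n == 8 * 3 + 9 * 4 + 9 * 5 == 105

    def test_provenance_labels(self):
        w = np.eye(8)[:, :3] + 0.01
        pooled = pool([("P1", fake_synergy(w / w.max(axis=0)))])
        assert pooled.labels == [("P1", 0), ("P1", 1), ("P1", 2)]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool([])


class TestKmeans:
    def test_planted_partition_recovered(self):
        x, truth = planted_groups(2, 20, seed=1)
        assignments, _, _ = kmeans(x, 2, seed=0)
        # perfect recovery up to label permutation
        assert len({(t, a) for t, a in zip(truth, assignments)}) == 2

    def test_k_equals_n_gives_zero_inertia(self):
        x, _ = planted_groups(3, 2, seed=2)
        _, _, inertia = kmeans(x, 6, n_init=10, seed=0)
        assert inertia == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        x, _ = planted_groups(4, 10, seed=3)
        a1, c1, _ = kmeans(x, 4, seed=7)
        a2, c2, _ = kmeans(x, 4, seed=7)
        np.testing.assert_array_equal(a1, a2)
        np.testing.assert_array_equal(c1, c2)

    def test_invalid_k_rejected(self):
        x, _ = planted_groups(2, 5)
        with pytest.raises(ValueError):
            kmeans(x, 0, seed=0)


class TestSelectK:
    def test_five_planted_groups(self):
        x, _ = planted_groups(5, 21, seed=4)  # ~105 pooled synergies
        k, sil = select_k(x, seed=0)
        assert k == 5
        assert sil[5] > sil[4] and sil[5] > sil[6]

    def test_monotone_decreasing_silhouette_picks_left_endpoint(self):
        # two clean groups: silhouette peaks at k=2 and decays after
        x, _ = planted_groups(2, 30, seed=5)
        k, sil = select_k(x, seed=0)
        assert k == 2
        assert all(sil[2] > sil[j] for j in sil if j != 2)

    def test_smallest_local_maximum_wins(self):
        # hierarchical structure: 3 super-groups each splitting into 2
        rng = np.random.default_rng(6)
        protos = np.zeros((8, 3))
        protos[[0, 3, 6], [0, 1, 2]] = 1.0
        cols = []
        for j in range(3):
            for sub in range(2):
                sub_proto = protos[:, j].copy()
                sub_proto[(j * 2 + sub + 1) % 8] += 0.35
                for _ in range(15):
                    v = np.clip(sub_proto + rng.normal(0, 0.02, 8), 0.0, None)
                    cols.append(v / v.max())
        x = np.column_stack(cols)
        k, sil = select_k(x, seed=0)
        local_maxima = [kk for kk in sorted(sil)
                        if sil[kk] > sil.get(kk - 1, -np.inf)
                        and sil[kk] > sil.get(kk + 1, -np.inf)]
        assert k == min(local_maxima)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            select_k(np.ones((8, 2)), seed=0)


class TestNameAndOrder:
    def _modes(self, centroids):
        n = centroids.shape[1]
        return ClusteredModes(
            stage="early", centroids=centroids,
            assignments=np.arange(n), labels=[("P1", j) for j in range(n)],
            vectors=centroids, silhouette_by_k={}, chosen_k=n,
        )

    def test_single_side_dominant(self):
        c = np.zeros((8, 1)) + 0.1
        c[CANONICAL_LABELS.index("R_GAS"), 0] = 1.0
        m = name_and_order(self._modes(c), np.ones((1, 100)))
        assert m.mode_names == ["W_R_GAS"]

    def test_bilateral_dominance_drops_side_prefix(self):
        c = np.zeros((8, 1)) + 0.1
        c[CANONICAL_LABELS.index("R_TA"), 0] = 1.0
        c[CANONICAL_LABELS.index("S_TA"), 0] = 0.97
        m = name_and_order(self._modes(c), np.ones((1, 100)))
        assert m.mode_names == ["W_TA"]

    def test_order_by_peak_time(self):
        c = np.zeros((8, 2)) + 0.1
        c[0, 0] = 1.0
        c[5, 1] = 1.0
        acts = np.zeros((2, 100))
        acts[0, 60] = 1.0   # later peak
        acts[1, 40] = 1.0   # earlier peak
        m = name_and_order(self._modes(c), acts)
        assert m.mode_order == [1, 0]


class TestMatchStages:
    def _modes(self, centroids, stage="early"):
        n = centroids.shape[1]
        return ClusteredModes(
            stage=stage, centroids=centroids, assignments=np.arange(n),
            labels=[("P1", j) for j in range(n)], vectors=centroids,
            silhouette_by_k={}, chosen_k=n,
        )

    def test_identical_centroids_match_perfectly(self):
        x, _ = planted_groups(5, 1, spread=0.0, seed=7)
        match = match_stages(self._modes(x), self._modes(x, "late"))
        assert len(match.pairs) == 5
        for i, j, r in match.pairs:
            assert i == j and r == pytest.approx(1.0)
            assert match.similarity_class(r) == "high"

    def test_r_matches_pearson_formula(self):
        rng = np.random.default_rng(8)
        a = rng.random(8)
        b = a.copy()
        b[3] += 0.4
        match = match_stages(self._modes(a[:, None]), self._modes(b[:, None], "late"))
        r_oracle = np.corrcoef(a, b)[0, 1]
        assert match.pairs[0][2] == pytest.approx(r_oracle, abs=1e-12)

    def test_unequal_mode_counts_leave_leftover(self):
        x5, _ = planted_groups(5, 1, spread=0.0, seed=9)
        x6 = np.column_stack([x5, np.clip(np.random.default_rng(0).random(8), 0.1, 1)])
        match = match_stages(self._modes(x5), self._modes(x6, "late"))
        assert len(match.pairs) == 5
        assert len(match.unmatched_late) == 1
        assert match.unmatched_early == []


class TestCompareModeWeights:
    def _stage_modes(self, weights_by_pid, stage):
        """One mode whose members are each participant's weight vector."""
        cols = [w for w in weights_by_pid.values()]
        labels = [(pid, 0) for pid in weights_by_pid]
        vectors = np.column_stack(cols)
        centroid = vectors.mean(axis=1, keepdims=True)
        return ClusteredModes(
            stage=stage, centroids=centroid / centroid.max(),
            assignments=np.zeros(len(cols), dtype=int), labels=labels,
            vectors=vectors, silhouette_by_k={}, chosen_k=1,
        )

    def test_identical_members_give_zero_t(self):
        rng = np.random.default_rng(10)
        weights = {f"P{i}": np.clip(rng.random(8), 0.05, 1) for i in range(6)}
        early = self._stage_modes(weights, "early")
        late = self._stage_modes(weights, "late")
        match = match_stages(early, late)
        res = compare_mode_weights(early, late, match)
        for r in res[(0, 0)]:
            assert r.statistic == 0.0 and r.p == 1.0

    def test_planted_reduction_power(self):
        """0.3 weight drop (sd 0.1), n=20: significant in >= 95/100 cohorts."""
        rng = np.random.default_rng(11)
        mus = 2
        hits = 0
        for _ in range(100):
            early_w, late_w = {}, {}
            for i in range(20):
                base = np.clip(rng.uniform(0.2, 1.0, 8), 0.05, 1)
                e = base + rng.normal(0, 0.02, 8)
                l = base + rng.normal(0, 0.02, 8)
                l[mus] -= rng.normal(0.3, 0.1)
                early_w[f"P{i}"] = np.clip(e, 0.0, None) + 1e-6
                late_w[f"P{i}"] = np.clip(l, 0.0, None) + 1e-6
            early = self._stage_modes(early_w, "early")
            late = self._stage_modes(late_w, "late")
            match = match_stages(early, late, threshold=-1.1)
            res = compare_mode_weights(early, late, match)
            r = res[(0, 0)][mus]
            if r.p < 0.05 and r.statistic > 0:
                hits += 1
        assert hits >= 95

    def test_unmatched_mode_skipped_with_warning(self):
        rng = np.random.default_rng(12)
        weights = {f"P{i}": np.clip(rng.random(8), 0.05, 1) for i in range(6)}
        early = self._stage_modes(weights, "early")
        late = self._stage_modes(weights, "late")
        match = match_stages(early, late)
        match.unmatched_early = [0]
        match.pairs = []
        with pytest.warns(UserWarning, match="no late-stage partner"):
            out = compare_mode_weights(early, late, match)
        assert out == {}


def test_clustering_invariant_to_column_order():
    x, _ = planted_groups(4, 10, seed=13)
    perm = np.random.default_rng(0).permutation(x.shape[1])
    a1, _, inertia1 = kmeans(x, 4, seed=5)
    a2, _, inertia2 = kmeans(x[:, perm], 4, seed=5)
    assert inertia1 == pytest.approx(inertia2, rel=1e-9)
    # same partition up to label names
    part1 = {tuple(sorted(np.where(a1 == j)[0])) for j in range(4)}
    part2 = {tuple(sorted(perm[np.where(a2 == j)[0]].tolist())) for j in range(4)}
    part2 = {tuple(sorted(g)) for g in part2}
    assert part1 == part2
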