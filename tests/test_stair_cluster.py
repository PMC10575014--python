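"""Unit and property tests for DBSCAN clustering and stair identification.

The DBSCAN tests compare against a brute-force density-reachability
oracle: a point is core iff its closed eps-ball holds >= min_points
points (itself included); clusters are connected components of core
points under mutual eps-reachability, with border points attached to the
first core neighbor's component.
"""

import numpy as np
import pytest

from stairclust.embedding import Embedding
from stairclust.stair_cluster import (
    AssignmentStatus,
    ClusterLabels,
    ClusterSummary,
    WalkGaussian,
    assign_clusters,
    centroid_nll,
    fit_walk_gaussian,
    identify_walking_cluster,
    rank_factors,
    run_dbscan,
    stair_scores,
    summarize_cluster,
    NoClusterError,
)


def brute_force_dbscan(Y: np.ndarray, eps: float, min_points: int):
    """Independent density-reachability implementation (BFS over core points)."""
    n = len(Y)
    d = np.linalg.norm(Y[:, None, :] - Y[None, :, :], axis=2)
    neighbors = [np.nonzero(d[i] <= eps)[0] for i in range(n)]
    core = np.array([len(nb) >= min_points for nb in neighbors])
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        cid += 1
        queue = [i]
        labels[i] = cid
        while queue:
            j = queue.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cid
                    if core[k]:
                        queue.append(k)
    return labels  # -1 = outlier, clusters numbered in discovery order


def _emb(Y):
    return Embedding(Y=np.asarray(Y, dtype=float), seed=0, params={})


def _partition(labels):
    """Cluster partition as a set of frozensets (ignores cluster numbering)."""
    out = {}
    for i, lab in enumerate(labels):
        if lab in (-1, 0):
            continue
        out.setdefault(lab, set()).add(i)
    return {frozenset(v) for v in out.values()}


class TestRunDbscan:
    def test_two_distant_blobs(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(-1, 1, size=(30, 2))
        b = rng.uniform(-1, 1, size=(30, 2)) + [20.0, 0.0]
        cl = run_dbscan(_emb(np.vstack([a, b])), eps=3.0, min_points=15)
        assert cl.n_clusters == 2
        assert cl.outlier_flag.sum() == 0

    def test_isolated_points_all_outliers(self):
        Y = np.arange(10)[:, None] * [10.0, 10.0]
        cl = run_dbscan(_emb(Y), eps=3.0, min_points=15)
        assert cl.n_clusters == 0
        assert cl.outlier_flag.all()

    def test_single_blob(self):
        rng = np.random.default_rng(1)
        Y = rng.uniform(-1, 1, size=(100, 2))
        cl = run_dbscan(_emb(Y), eps=3.0, min_points=15)
        assert cl.n_clusters == 1

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(20, 300))
        n_blobs = int(rng.integers(1, 5))
        pts = [
            rng.normal(rng.uniform(-30, 30, size=2), rng.uniform(0.5, 4.0), size=(n // n_blobs, 2))
            for _ in range(n_blobs)
        ]
        Y = np.vstack(pts)
        eps = float(rng.uniform(0.5, 5.0))
        min_points = int(rng.integers(2, 20))
        ours = run_dbscan(_emb(Y), eps=eps, min_points=min_points)
        oracle = brute_force_dbscan(Y, eps, min_points)
        assert _partition(ours.cluster_id) == _partition(oracle)
        np.testing.assert_array_equal(ours.outlier_flag, oracle == -1)


class TestIdentifyWalkingCluster:
    def _labels(self, sizes):
        ids = np.concatenate([[cid] * n for cid, n in sizes.items()])
        return ClusterLabels(
            cluster_id=ids, outlier_flag=np.zeros(len(ids), dtype=bool)
        )

    def test_largest_wins(self):
        assert identify_walking_cluster(self._labels({1: 900, 2: 50})) == 1
        assert identify_walking_cluster(self._labels({1: 50, 2: 900, 3: 30})) == 2

    def test_tie_lower_id(self):
        assert identify_walking_cluster(self._labels({1: 100, 2: 100})) == 1

    def test_zero_clusters_raises(self):
        cl = ClusterLabels(
            cluster_id=np.zeros(5, dtype=int), outlier_flag=np.ones(5, dtype=bool)
        )
        with pytest.raises(NoClusterError):
            identify_walking_cluster(cl)


class TestSummarizeCluster:
    def _cl(self, n):
        return ClusterLabels(
            cluster_id=np.ones(n, dtype=int), outlier_flag=np.zeros(n, dtype=bool)
        )

    def test_three_collinear_points(self):
        s = summarize_cluster(_emb([[0, 0], [0, 1], [0, 2]]), self._cl(3), 1)
        np.testing.assert_allclose(s.centroid, [0.0, 1.0])
        assert s.compactness == 1.0  # median of {1, 1, 2}

    def test_two_points(self):
        s = summarize_cluster(_emb([[0, 0], [3, 4]]), self._cl(2), 1)
        np.testing.assert_allclose(s.centroid, [1.5, 2.0])
        assert s.compactness == 5.0

    def test_isometry_invariance(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(40, 2))
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = Y @ R.T + [5.0, -3.0]
        s1 = summarize_cluster(_emb(Y), self._cl(40), 1)
        s2 = summarize_cluster(_emb(moved), self._cl(40), 1)
        assert s1.compactness == pytest.approx(s2.compactness, abs=1e-9)

    def test_singleton_flagged(self):
        s = summarize_cluster(_emb([[1, 1]]), self._cl(1), 1)
        assert s.singleton and s.compactness == 0.0


class TestFitWalkGaussian:
    def test_mle_consistency_standard_normal(self):
        rng = np.random.default_rng(3)
        Y = rng.standard_normal(size=(10000, 2))
        cl = ClusterLabels(
            cluster_id=np.ones(10000, dtype=int),
            outlier_flag=np.zeros(10000, dtype=bool),
        )
        g = fit_walk_gaussian(_emb(Y), cl, 1)
        np.testing.assert_allclose(g.mean, [0.0, 0.0], atol=0.05)
        np.testing.assert_allclose(g.covariance, np.eye(2), atol=0.05)

    def test_collinear_points_regularized(self):
        Y = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        cl = ClusterLabels(
            cluster_id=np.ones(3, dtype=int), outlier_flag=np.zeros(3, dtype=bool)
        )
        g = fit_walk_gaussian(_emb(Y), cl, 1)
        assert np.linalg.eigvalsh(g.covariance).min() > 0

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(50, 2))
        cl = ClusterLabels(
            cluster_id=np.ones(50, dtype=int), outlier_flag=np.zeros(50, dtype=bool)
        )
        g1 = fit_walk_gaussian(_emb(Y), cl, 1)
        g2 = fit_walk_gaussian(_emb(Y + [10.0, -7.0]), cl, 1)
        np.testing.assert_allclose(g2.mean, g1.mean + [10.0, -7.0], atol=1e-9)

    def test_too_few_members_raises(self):
        cl = ClusterLabels(
            cluster_id=np.ones(2, dtype=int), outlier_flag=np.zeros(2, dtype=bool)
        )
        with pytest.raises(ValueError):
            fit_walk_gaussian(_emb([[0, 0], [1, 1]]), cl, 1)


class TestCentroidNll:
    def test_closed_form_at_mean(self):
        g = WalkGaussian(mean=np.zeros(2), covariance=np.eye(2))
        assert centroid_nll(g, [0.0, 0.0]) == pytest.approx(np.log(2 * np.pi), abs=1e-12)

    def test_closed_form_offset(self):
        g = WalkGaussian(mean=np.zeros(2), covariance=np.eye(2))
        assert centroid_nll(g, [3.0, 4.0]) == pytest.approx(np.log(2 * np.pi) + 12.5, abs=1e-12)

    def test_mean_minimizes_nll(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(2, 2))
        g = WalkGaussian(mean=rng.normal(size=2), covariance=A @ A.T + 0.5 * np.eye(2))
        base = centroid_nll(g, g.mean)
        for _ in range(50):
            assert centroid_nll(g, g.mean + rng.normal(size=2)) >= base


def _summary(cid, compactness, nll=None):
    return ClusterSummary(
        cluster_id=cid,
        size=10,
        centroid=np.zeros(2),
        compactness=compactness,
        nll=nll,
    )


class TestRankFactors:
    def test_least_compact_gets_one(self):
        summaries = [_summary(1, 5.0), _summary(2, 2.0), _summary(3, 1.0)]
        rank_factors(summaries)
        phis = {s.cluster_id: s.phi for s in summaries}
        assert phis == {1: 1.00, 2: 1.05, 3: pytest.approx(1.10)}

    def test_single_candidate(self):
        s = [_summary(1, 3.0)]
        rank_factors(s)
        assert s[0].phi == 1.0

    def test_tie_broken_by_larger_nll_more_compact(self):
        summaries = [_summary(1, 2.0, nll=5.0), _summary(2, 2.0, nll=9.0)]
        rank_factors(summaries)
        phis = {s.cluster_id: s.phi for s in summaries}
        assert phis[2] > phis[1]


class TestStairScores:
    def test_closed_form(self):
        s = _summary(1, 1.0, nll=20.0)
        s.phi = 1.05
        stair_scores([s])
        assert s.score == pytest.approx(1.0 - 1.0 / 21.0, abs=1e-12)

    def test_selection_between_candidates(self):
        a = _summary(1, 1.0, nll=20.0)
        a.phi = 1.05
        b = _summary(2, 2.0, nll=5.0)
        b.phi = 1.00
        stair_scores([a, b])
        assert b.score == pytest.approx(0.8, abs=1e-12)
        assert a.score > b.score

    def test_monotone_in_nll_and_phi(self):
        rng = np.random.default_rng(6)
        nlls = np.sort(rng.uniform(1.1, 50, size=20))
        scores = []
        for nll in nlls:
            s = _summary(1, 1.0, nll=float(nll))
            s.phi = 1.05
            stair_scores([s])
            scores.append(s.score)
        assert np.all(np.diff(scores) > 0)
        phis = 1.0 + 0.05 * np.arange(10)
        scores = []
        for phi in phis:
            s = _summary(1, 1.0, nll=7.0)
            s.phi = float(phi)
            stair_scores([s])
            scores.append(s.score)
        assert np.all(np.diff(scores) > 0)

    def test_nonpositive_nll_floored(self):
        s = _summary(1, 1.0, nll=-3.0)
        s.phi = 1.0
        stair_scores([s])
        assert s.score < -1e6  # effectively disqualified


def _blob(rng, center, spread, n):
    return rng.normal(center, spread, size=(n, 2))


class TestAssignClusters:
    def _run(self, Y, eps=3.0, min_points=15):
        emb = _emb(Y)
        cl = run_dbscan(emb, eps=eps, min_points=min_points)
        return emb, cl, assign_clusters(emb, cl)

    def test_two_clusters_larger_is_walk(self):
        rng = np.random.default_rng(7)
        Y = np.vstack([_blob(rng, (0, 0), 1.0, 900), _blob(rng, (30, 0), 1.0, 50)])
        _, cl, res = self._run(Y)
        assert res.status is AssignmentStatus.OK
        walk_id = identify_walking_cluster(cl)
        assert res.stair_cluster_id != walk_id
        assert walk_id in res.walking_cluster_ids

    def test_single_cluster_error(self):
        rng = np.random.default_rng(8)
        _, _, res = self._run(_blob(rng, (0, 0), 1.0, 200))
        assert res.status is AssignmentStatus.SINGLE_CLUSTER_ERROR

    def test_no_cluster_error(self):
        Y = np.arange(10)[:, None] * [50.0, 50.0]
        _, _, res = self._run(Y)
        assert res.status is AssignmentStatus.NO_CLUSTER_ERROR
        assert res.stair_cluster_id is None

    def test_three_clusters_scored_by_equation(self):
        # walk blob at origin; candidate A far and compact; candidate B
        # nearby and diffuse -> A must win on nll x phi
        rng = np.random.default_rng(9)
        Y = np.vstack(
            [
                _blob(rng, (0, 0), 2.0, 900),
                _blob(rng, (40, 0), 0.5, 40),  # true stair geometry
                _blob(rng, (12, 0), 1.5, 60),
            ]
        )
        emb, cl, res = self._run(Y)
        assert res.status is AssignmentStatus.OK
        stair_members = cl.members(res.stair_cluster_id)
        assert np.all(emb.Y[stair_members, 0] > 30)  # picked the far blob
        # manual recomputation of the winning score
        walk_id = identify_walking_cluster(cl)
        g = fit_walk_gaussian(emb, cl, walk_id)
        cands = [summarize_cluster(emb, cl, c) for c in cl.ids() if c != walk_id]
        for s in cands:
            s.nll = centroid_nll(g, s.centroid)
        rank_factors(cands)
        stair_scores(cands)
        best = max(cands, key=lambda s: (s.score, s.nll))
        assert best.cluster_id == res.stair_cluster_id

    def test_largest_cluster_never_stair(self):
        for trial in range(20):
            rng = np.random.default_rng(200 + trial)
            blobs = [_blob(rng, (0, 0), 2.0, 500)]
            for _ in range(int(rng.integers(1, 4))):
                blobs.append(
                    _blob(
                        rng,
                        rng.uniform(-40, 40, size=2),
                        rng.uniform(0.5, 2.0),
                        int(rng.integers(20, 80)),
                    )
                )
            emb, cl, res = self._run(np.vstack(blobs))
            if res.status is not AssignmentStatus.OK:
                continue
            assert res.stair_cluster_id != identify_walking_cluster(cl)

    def test_scale_consistency(self):
        rng = np.random.default_rng(10)
        Y = np.vstack(
            [
                _blob(rng, (0, 0), 2.0, 600),
                _blob(rng, (35, 5), 0.6, 40),
                _blob(rng, (-15, 10), 1.2, 50),
            ]
        )
        emb1, cl1, res1 = self._run(Y, eps=3.0)
        emb2, cl2, res2 = self._run(2.5 * Y, eps=7.5)
        assert res1.status is AssignmentStatus.OK
        assert res2.status is AssignmentStatus.OK
        np.testing.assert_array_equal(
            cl1.members(res1.stair_cluster_id), cl2.members(res2.stair_cluster_id)
        )

    def test_final_labels_two_identities(self):
        rng = np.random.default_rng(11)
        Y = np.vstack([_blob(rng, (0, 0), 1.5, 400), _blob(rng, (25, 0), 0.8, 40)])
        emb, cl, res = self._run(Y)
        final = set(res.final_labels(cl))
        assert final <= {"Walk", "Stair", "Outlier"}
        assert "Stair" in final and "Walk" in final
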