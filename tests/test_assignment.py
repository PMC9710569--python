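import numpy as np
import pytest
from scipy.stats import multivariate_normal

from sparcle import (
    AssignParams,
    Clustering,
    CountMatrix,
    apply_assignment,
    assign_to_cell,
    build_mock_cell,
    default_mock_radius,
    estimate_moments,
    mle_cluster,
    mock_to_model_space,
    preprocess,
)
from sparcle.assignment import ClusterModel, MockCell

from conftest import make_spot_table


def random_model(rng, K, G):
    means = rng.normal(size=(K, G))
    covs = np.empty((K, G, G))
    for k in range(K):
        A = rng.normal(size=(G, G))
        covs[k] = A @ A.T + G * np.eye(G)
    return ClusterModel(means=means, covs=covs, n_k=np.ones(K, dtype=int), lam=0.0)


class TestEstimateMoments:
    def test_two_point_sample(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        clustering = Clustering(labels=np.zeros(2, dtype=int), K=1, method="graph")
        m = estimate_moments(X, clustering, lambda_frac=1e-2)
        assert np.allclose(m.means[0], [0.5, 0.5])
        lam = m.lam
        assert np.allclose(m.covs[0], np.array([[0.5, -0.5], [-0.5, 0.5]]) + lam * np.eye(2))

    def test_identical_members_pure_ridge(self):
        X = np.tile([2.0, 3.0, 4.0], (5, 1))
        clustering = Clustering(labels=np.zeros(5, dtype=int), K=1, method="graph")
        m = estimate_moments(X, clustering)
        assert np.allclose(m.covs[0], m.lam * np.eye(3))

    def test_matches_bruteforce_recomputation(self, rng):
        X = rng.normal(size=(200, 10))
        labels = (rng.random(200) < 0.4).astype(int)
        m = estimate_moments(X, Clustering(labels=labels, K=2, method="graph"),
                             lambda_frac=1e-2)
        for k in (0, 1):
            member = X[labels == k]
            assert np.allclose(m.means[k], member.mean(axis=0))
            assert np.allclose(m.covs[k] - m.lam * np.eye(10),
                               np.cov(member, rowvar=False, ddof=1))

    def test_empty_cluster_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        bad = Clustering(labels=np.array([0, 0, 1, 1, 1]), K=2, method="graph")
        bad.labels = np.zeros(5, dtype=int)  # claim K=2 but only label 0 present
        with pytest.raises(ValueError, match="no members"):
            estimate_moments(X, bad)

    def test_singleton_cluster_uses_pooled(self, rng):
        X = rng.normal(size=(10, 3))
        labels = np.array([0] * 9 + [1])
        m = estimate_moments(X, Clustering(labels=labels, K=2, method="graph"))
        assert np.all(np.linalg.eigvalsh(m.covs[1]) > 0)


class TestBuildMockCell:
    def test_isolated_spot_only_self(self):
        spots = make_spot_table([(1, "A", 0.0, 0.0), (2, "B", 100.0, 100.0)])
        mock = build_mock_cell((0.0, 0.0), 0, spots, r=5.0)
        assert mock.n_neighbors == 1
        assert np.allclose(mock.weighted_vector, [1.0, 0.0])

    def test_neighbor_at_delta_contributes_half(self):
        spots = make_spot_table([(1, "A", 0.0, 0.0), (2, "B", 1.0, 0.0)])
        mock = build_mock_cell((0.0, 0.0), 0, spots, r=5.0, delta=1.0)
        assert np.isclose(mock.weighted_vector[1], 0.5)  # 1/(1 + d/delta), d = delta
        assert np.isclose(mock.weighted_vector[0], 1.0)

    def test_nonpositive_radius_rejected(self):
        spots = make_spot_table([(1, "A", 0.0, 0.0)])
        with pytest.raises(ValueError):
            build_mock_cell((0.0, 0.0), 0, spots, r=0.0)

    def test_matches_exhaustive_scan(self, rng):
        pts = rng.uniform(0, 100, size=(500, 2))
        genes = rng.choice(["A", "B", "C", "D"], size=500)
        spots = make_spot_table(
            [(i, g, x, y) for i, (g, (x, y)) in enumerate(zip(genes, pts))],
            panel=["A", "B", "C", "D"])
        gi = {g: k for k, g in enumerate(spots.panel)}
        center = pts[17]
        mock = build_mock_cell(tuple(center), gi[genes[17]], spots, r=25.0, delta=2.0)
        expect = np.zeros(4)
        n = 0
        for (x, y), g in zip(pts, genes):
            d = np.hypot(x - center[0], y - center[1])
            if d <= 25.0:
                expect[gi[g]] += 1.0 / (1.0 + d / 2.0)
                n += 1
        assert np.allclose(mock.weighted_vector, expect)
        assert mock.n_neighbors == n


class TestMockToModelSpace:
    def _pre(self, rng):
        counts = rng.integers(1, 80, size=(12, 5))
        return preprocess(CountMatrix(counts.astype(np.int64), np.arange(1, 13),
                                      [f"g{i}" for i in range(5)], np.zeros((12, 2))))

    def test_scale_invariance(self, rng):
        pre = self._pre(rng)
        v = rng.uniform(0.5, 3.0, size=5)
        m1 = MockCell((0, 0), 1.0, v, 3)
        m2 = MockCell((0, 0), 1.0, 7.3 * v, 3)
        assert np.allclose(mock_to_model_space(m1, pre), mock_to_model_space(m2, pre))

    def test_zero_vector_rejected(self, rng):
        pre = self._pre(rng)
        with pytest.raises(ValueError):
            mock_to_model_space(MockCell((0, 0), 1.0, np.zeros(5), 1), pre)

    def test_matches_manual_transform(self, rng):
        pre = self._pre(rng)
        v = rng.uniform(0.1, 4.0, size=5)
        out = mock_to_model_space(MockCell((0, 0), 1.0, v, 2), pre)
        manual = (np.log1p(v * (pre.median_total / v.sum())) - pre.gene_means) / pre.gene_sds
        assert np.allclose(out, manual)


class TestMleCluster:
    def test_nearest_mean_under_identity_cov(self):
        model = ClusterModel(means=np.eye(2), covs=np.stack([np.eye(2)] * 2),
                             n_k=np.array([5, 5]), lam=0.0)
        k, ll, margin = mle_cluster(np.array([1.0, 0.0]), model)
        assert k == 0 and margin > 0

    def test_tie_breaks_to_lower_id(self):
        model = ClusterModel(means=np.zeros((2, 2)), covs=np.stack([np.eye(2)] * 2),
                             n_k=np.array([5, 5]), lam=0.0)
        k, _, margin = mle_cluster(np.array([0.3, -0.3]), model)
        assert k == 0 and margin == 0.0

    def test_single_cluster_infinite_margin(self):
        model = ClusterModel(means=np.zeros((1, 3)), covs=np.eye(3)[None],
                             n_k=np.array([4]), lam=0.0)
        k, _, margin = mle_cluster(np.zeros(3), model)
        assert k == 0 and margin == np.inf

    def test_dimension_mismatch_rejected(self):
        model = ClusterModel(means=np.zeros((1, 3)), covs=np.eye(3)[None],
                             n_k=np.array([4]), lam=0.0)
        with pytest.raises(ValueError):
            mle_cluster(np.zeros(2), model)

    def test_matches_scipy_density_oracle(self, rng):
        model = random_model(rng, K=4, G=6)
        for _ in range(100):
            v = rng.normal(scale=3.0, size=6)
            k, ll, _ = mle_cluster(v, model)
            dens = [multivariate_normal.logpdf(v, model.means[j], model.covs[j])
                    for j in range(4)]
            assert k == int(np.argmax(dens))
            assert np.isclose(ll, max(dens))


class TestAssignToCell:
    def _matrix(self, centroids):
        n = len(centroids)
        return CountMatrix(np.zeros((n, 2), dtype=np.int64), np.arange(1, n + 1),
                           ["A", "B"], np.asarray(centroids, dtype=float))

    def test_nearest_of_label_wins(self):
        m = self._matrix([[5.0, 0.0], [10.0, 0.0]])
        labels = np.array([1, 1])
        assert assign_to_cell((0.0, 0.0), 1, m, labels, D=20.0) == 1

    def test_no_candidate_within_reach(self):
        m = self._matrix([[50.0, 0.0]])
        assert assign_to_cell((0.0, 0.0), 0, m, np.array([0]), D=10.0) is None

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(100):
            cents = rng.uniform(0, 60, size=(20, 2))
            labels = rng.integers(0, 3, size=20)
            m = self._matrix(cents)
            pt = tuple(rng.uniform(0, 60, size=2))
            k = int(rng.integers(0, 3))
            got = assign_to_cell(pt, k, m, labels, D=25.0)
            best = None
            for i in range(20):
                if labels[i] != k:
                    continue
                d = np.hypot(cents[i, 0] - pt[0], cents[i, 1] - pt[1])
                if d <= 25.0 and (best is None or d < best[0]):
                    best = (d, i + 1)
            assert got == (best[1] if best else None)


class TestApplyAssignment:
    def test_single_increment_and_conservation(self):
        spots = make_spot_table([(1, "A", 0.0, 0.0), (2, "B", 1.0, 1.0)])
        m = CountMatrix(np.array([[2, 0], [0, 3]]), np.array([1, 2]),
                        ["A", "B"], np.zeros((2, 2)))
        before = m.counts.sum()
        rec = apply_assignment(1, 2, m, spots, cluster_id=0, iteration=1, loglik=-3.5)
        assert m.counts[1, 0] == 1 and m.counts.sum() == before + 1
        assert rec.cell_id == 2 and rec.iteration == 1
        assert spots.n_assigned == 1

    def test_double_assignment_rejected(self):
        spots = make_spot_table([(1, "A", 0.0, 0.0)])
        m = CountMatrix(np.zeros((1, 1), dtype=np.int64), np.array([1]), ["A"],
                        np.zeros((1, 2)))
        apply_assignment(1, 1, m, spots, 0, 1, 0.0)
        with pytest.raises(ValueError, match="not dangling"):
            apply_assignment(1, 1, m, spots, 0, 1, 0.0)

    def test_n_assignments_n_records(self):
        spots = make_spot_table([(i, "A", float(i), 0.0) for i in range(5)])
        m = CountMatrix(np.zeros((1, 1), dtype=np.int64), np.array([1]), ["A"],
                        np.zeros((1, 2)))
        recs = [apply_assignment(i, 1, m, spots, 0, 1, 0.0) for i in range(5)]
        assert len(recs) == 5 and m.counts.sum() == 5


class TestAssignParams:
    def test_default_radius_from_cell_scale(self):
        # disks of area pi r^2: equivalent radii 2 and 4 -> median 3 -> r = 6
        areas = {1: np.pi * 4.0, 2: np.pi * 16.0}
        r = AssignParams().resolved(areas).radius
        assert np.isclose(r, 2 * 3.0)
        assert np.isclose(default_mock_radius(areas), r)

    def test_max_dist_default_is_4r(self):
        p = AssignParams(radius=5.0).resolved({})
        assert p.max_assign_dist == 20.0

    def test_invalid_combinations_rejected(self):
        with pytest.raises(ValueError):
            AssignParams(radius=5.0, max_assign_dist=2.0).resolved({})
        with pytest.raises(ValueError):
            AssignParams(radius=-1.0).resolved({})
        with pytest.raises(ValueError):
            AssignParams(radius=1.0, max_iterations=0).resolved({})
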