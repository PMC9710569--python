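"""The spot-reassignment core: cluster moments, mock cells, MLE cluster calls
and nearest-cell assignment.

Each dangling transcript gets a circular, distance-weighted "mock cell" built
from its mRNA neighborhood; the mock cell's expression vector is mapped into
the normalised space the clusters were learned in, classified against the
per-cluster multivariate Gaussians by maximum likelihood, and the spot is
handed to the nearest cell carrying the winning cluster label (within a
distance cap).  Absence of a candidate cell is a valid outcome — the spot
stays dangling, keeping the procedure conservative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.spatial import cKDTree

from .core_io import (
    AssignmentRecord,
    CountMatrix,
    SpotTable,
    STATUS_ASSIGNED,
    STATUS_DANGLING,
)
from .clustering import Clustering, Preprocessing

__all__ = ["ClusterModel", "MockCell", "AssignParams", "estimate_moments",
           "build_mock_cell", "mock_to_model_space", "mle_cluster",
           "assign_to_cell", "apply_assignment", "default_mock_radius"]


@dataclass
class ClusterModel:
    """Per-cluster first- and second-order moments in model (normalised) space.

    ``covs[k]`` is the member sample covariance plus ``lam * I``; the ridge
    keeps every covariance positive definite even when a cluster has fewer
    members than genes.  Cholesky factors are cached for likelihood
    evaluation.
    """

    means: np.ndarray            # K x G
    covs: np.ndarray             # K x G x G
    n_k: np.ndarray              # member counts
    lam: float
    chols: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.chols:
            self.chols = [np.linalg.cholesky(S) for S in self.covs]

    @property
    def K(self) -> int:
        return len(self.means)


@dataclass
class MockCell:
    """Distance-weighted pseudo-expression around one dangling spot."""

    center: tuple[float, float]
    radius: float
    weighted_vector: np.ndarray
    n_neighbors: int


@dataclass
class AssignParams:
    """Tunables of the assignment step.

    ``radius`` (mock-cell radius r) defaults to twice the median
    equivalent-disk radius of the segmented cells, tying the neighborhood to
    the observed cell scale; ``max_assign_dist`` caps the centroid distance a
    spot may travel; ``delta`` sets the length scale of the 1/(1 + d/delta)
    neighbor weight; ``min_loglik_margin`` withholds assignment when the best
    and runner-up clusters are closer than the margin (0 disables the gate).
    """

    radius: float | None = None
    max_assign_dist: float | None = None   # default 4 * radius
    delta: float = 1.0
    min_loglik_margin: float = 0.0
    max_iterations: int = 3

    def resolved(self, cell_areas: dict[int, float]) -> "AssignParams":
        r = self.radius
        if r is None:
            r = default_mock_radius(cell_areas)
        D = self.max_assign_dist if self.max_assign_dist is not None else 4.0 * r
        if r <= 0:
            raise ValueError("mock-cell radius must be positive")
        if D < r:
            raise ValueError("max_assign_dist must be >= radius")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        return AssignParams(radius=r, max_assign_dist=D, delta=self.delta,
                            min_loglik_margin=self.min_loglik_margin,
                            max_iterations=self.max_iterations)


def default_mock_radius(cell_areas: dict[int, float]) -> float:
    """Twice the median equivalent-disk radius sqrt(area / pi) of the cells."""
    if not cell_areas:
        raise ValueError("no segmented cells to derive a mock radius from")
    radii = np.sqrt(np.asarray(list(cell_areas.values())) / np.pi)
    return 2.0 * float(np.median(radii))


def estimate_moments(X: np.ndarray, clustering: Clustering,
                     lambda_frac: float = 1e-2) -> ClusterModel:
    """Per-cluster mean and regularised covariance of the preprocessed matrix.

    The covariance denominator is ``n_k - 1``; singleton clusters fall back to
    the pooled within-cluster covariance.  The ridge is
    ``lambda_frac * mean(diag(pooled covariance))``.
    """
    X = np.asarray(X, dtype=float)
    labels = clustering.labels
    if len(labels) != X.shape[0]:
        raise ValueError("clustering labels do not match matrix rows")
    K, G = clustering.K, X.shape[1]
    for k in range(K):
        if not (labels == k).any():
            raise ValueError(f"cluster {k} has no members")

    means = np.vstack([X[labels == k].mean(axis=0) for k in range(K)])
    n_k = np.array([(labels == k).sum() for k in range(K)])
    # pooled within-cluster covariance (for the ridge scale and singleton fallback)
    scatter = np.zeros((G, G))
    for k in range(K):
        R = X[labels == k] - means[k]
        scatter += R.T @ R
    denom = max(len(labels) - K, 1)
    pooled = scatter / denom
    mean_diag = float(np.mean(np.diag(pooled)))
    # unit-scale floor keeps the ridge positive when all members coincide
    lam = lambda_frac * (mean_diag if mean_diag > 0 else 1.0)

    covs = np.empty((K, G, G))
    eye = np.eye(G)
    for k in range(K):
        member = X[labels == k]
        S = np.cov(member, rowvar=False, ddof=1) if n_k[k] >= 2 else pooled
        covs[k] = np.atleast_2d(S) + lam * eye
    return ClusterModel(means=means, covs=covs, n_k=n_k, lam=lam)


def build_mock_cell(spot_xy: tuple[float, float], gene_idx_of_spot: int,
                    spots: SpotTable, r: float, delta: float = 1.0,
                    tree: cKDTree | None = None,
                    coords: np.ndarray | None = None,
                    gene_idx: np.ndarray | None = None) -> MockCell:
    """Circular weighted mock cell of radius ``r`` centered on a dangling spot.

    All spots within ``r`` contribute — inside, assigned and dangling alike —
    each gene weighted by ``1 / (1 + d / delta)`` of its distance ``d`` to the
    center; the centered spot itself contributes weight 1.  A kd-tree makes
    the neighbor search fast, with results identical to an exhaustive scan.
    """
    if r <= 0:
        raise ValueError("mock-cell radius must be positive")
    if coords is None:
        coords = spots.df[["x", "y"]].to_numpy()
    if gene_idx is None:
        gene_idx = spots.gene_indices()
    if tree is None:
        tree = cKDTree(coords)
    center = np.asarray(spot_xy, dtype=float)
    neigh = tree.query_ball_point(center, r)
    neigh = np.asarray(neigh, dtype=np.int64)
    d = np.linalg.norm(coords[neigh] - center, axis=1)
    w = 1.0 / (1.0 + d / delta)
    vec = np.zeros(len(spots.panel))
    np.add.at(vec, gene_idx[neigh], w)
    return MockCell(center=(float(center[0]), float(center[1])), radius=float(r),
                    weighted_vector=vec, n_neighbors=int(len(neigh)))


def mock_to_model_space(mock: MockCell, preprocessing: Preprocessing) -> np.ndarray:
    """Map a mock cell's weighted vector into the clustered (z-scored) space.

    The vector is rescaled to the median raw total of the segmented cells and
    pushed through the identical log1p + per-gene z-score transform fitted
    during preprocessing, so mock cells and real cells are compared on one
    scale.
    """
    return preprocessing.transform_raw_vector(mock.weighted_vector)


def mle_cluster(v: np.ndarray, model: ClusterModel) -> tuple[int, float, float]:
    """Maximum-likelihood cluster call for one vector.

    Pure Gaussian likelihood, no mixing-proportion prior.  Returns
    ``(cluster_id, loglik, margin)`` where margin is best minus second-best
    log density (+inf for a single cluster).  Ties break to the lower id.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (model.means.shape[1],):
        raise ValueError("vector dimension does not match model")
    if not np.isfinite(v).all():
        raise ValueError("non-finite vector")
    G = len(v)
    logliks = np.empty(model.K)
    for k in range(model.K):
        L = model.chols[k]
        sol = solve_triangular(L, v - model.means[k], lower=True)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        logliks[k] = -0.5 * (G * np.log(2 * np.pi) + logdet + sol @ sol)
    best = int(np.argmax(logliks))          # first max = lowest id on ties
    if model.K == 1:
        return best, float(logliks[best]), float("inf")
    second = np.partition(logliks, -2)[-2]
    return best, float(logliks[best]), float(logliks[best] - second)


def batch_loglik(V: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Gaussian log densities for many vectors at once (n x K), identical to
    per-vector :func:`mle_cluster` evaluation."""
    V = np.asarray(V, dtype=float)
    n, G = V.shape
    out = np.empty((n, model.K))
    for k in range(model.K):
        L = model.chols[k]
        sol = solve_triangular(L, (V - model.means[k]).T, lower=True)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        out[:, k] = -0.5 * (G * np.log(2 * np.pi) + logdet + (sol ** 2).sum(axis=0))
    return out


def assign_to_cell(spot_xy: tuple[float, float], cluster_id: int,
                   matrix: CountMatrix, labels: np.ndarray, D: float) -> int | None:
    """Nearest cell (centroid distance <= D) carrying the given cluster label.

    Returns the cell id, ties broken to the lower id, or ``None`` when no
    cell of that label is within reach.
    """
    labels = np.asarray(labels)
    cand = np.flatnonzero(labels == cluster_id)
    if cand.size == 0:
        return None
    center = np.asarray(spot_xy, dtype=float)
    d = np.linalg.norm(matrix.centroids[cand] - center, axis=1)
    ok = d <= D
    if not ok.any():
        return None
    cand, d = cand[ok], d[ok]
    order = np.lexsort((matrix.cell_ids[cand], d))
    return int(matrix.cell_ids[cand[order[0]]])


def apply_assignment(spot_id, cell_id: int, matrix: CountMatrix, spots: SpotTable,
                     cluster_id: int, iteration: int, loglik: float) -> AssignmentRecord:
    """Commit one reassignment: increment the count matrix, flip the spot's
    status, emit the provenance record."""
    row = spots.df.index[spots.df["spot_id"] == spot_id]
    if len(row) != 1:
        raise ValueError(f"unknown spot {spot_id!r}")
    i = row[0]
    if spots.df.at[i, "status"] != STATUS_DANGLING:
        raise ValueError(f"spot {spot_id!r} is not dangling (double assignment?)")
    gene = spots.df.at[i, "gene"]
    ci = matrix.cell_index(cell_id)
    gi = matrix.genes.index(gene)
    matrix.counts[ci, gi] += 1
    spots.df.at[i, "status"] = STATUS_ASSIGNED
    spots.df.at[i, "cell_id"] = cell_id
    spots.df.at[i, "iteration"] = iteration
    return AssignmentRecord(spot_id=spot_id, cell_id=int(cell_id),
                            cluster_id=int(cluster_id), iteration=int(iteration),
                            loglik=float(loglik))
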