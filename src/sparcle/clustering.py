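"""Clustering of the cell-by-gene matrix without a pre-specified cluster count.

Two interchangeable clusterers are provided, mirroring common practice in
single-cell analysis:

* ``cluster_graph`` — a Phenograph-style pipeline: kNN graph on Euclidean
  distances, Jaccard re-weighting of edges, then Leiden modularity
  optimisation.
* ``cluster_dpmm`` — a Dirichlet process mixture of Gaussians with a
  conjugate Normal–Inverse-Wishart base measure, fit by collapsed Gibbs
  sampling; the maximum-a-posteriori sweep's labels are returned.

Both are deterministic given their seed and return labels in 0..K-1 with no
empty label.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .core_io import CountMatrix

logger = logging.getLogger(__name__)

__all__ = ["Preprocessing", "Clustering", "DpmmParams", "preprocess",
           "cluster_graph", "cluster_dpmm", "match_clusters"]


@dataclass
class Preprocessing:
    """Normalised expression matrix plus the fitted transform record.

    The stored parameters let a raw gene vector (e.g. a mock cell) be mapped
    into exactly the space the clusters and moments were learned in:
    rescale to ``median_total``, ``log1p``, then per-gene z-score with
    ``gene_means`` / ``gene_sds``.
    """

    X: np.ndarray
    kept_cells: np.ndarray      # boolean mask over the input cells
    median_total: float
    gene_means: np.ndarray
    gene_sds: np.ndarray

    def transform_raw_vector(self, v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        total = v.sum()
        if total <= 0:
            raise ValueError("cannot transform a zero expression vector")
        scaled = v * (self.median_total / total)
        return (np.log1p(scaled) - self.gene_means) / self.gene_sds


@dataclass
class Clustering:
    labels: np.ndarray
    K: int
    method: str
    preprocessing: Preprocessing | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        present = np.unique(self.labels)
        if self.K != len(present) or not np.array_equal(present, np.arange(self.K)):
            raise ValueError("labels must use every id in 0..K-1")


@dataclass
class DpmmParams:
    """Hyperparameters of the conjugate DP Gaussian mixture.

    The NIW base measure is empirical-Bayes flavoured: prior mean at the data
    mean, weak ``k0``, ``nu0 = d + 2`` (the smallest value giving a finite
    prior covariance mean) and scale matrix from the per-feature variances.
    """

    alpha: float = 1.0
    k0: float = 0.01
    nu0: float | None = None    # default d + 2
    n_sweeps: int = 200
    n_components_pca: int = 50
    seed: int = 0


def preprocess(matrix: CountMatrix | np.ndarray) -> Preprocessing:
    """Median-depth normalise rows, log1p, z-score each gene column.

    Cells with zero total are dropped (with a warning) and flagged in
    ``kept_cells``; callers re-attach them downstream.  Genes constant across
    cells get z-score 0.
    """
    counts = matrix.counts if isinstance(matrix, CountMatrix) else np.asarray(matrix)
    counts = counts.astype(float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("preprocessing needs a 2D matrix with >=2 cells")
    totals = counts.sum(axis=1)
    if (totals <= 0).all():
        raise ValueError("all-zero count matrix")
    kept = totals > 0
    if not kept.all():
        warnings.warn(f"dropping {int((~kept).sum())} zero-total cell(s) before clustering")
    counts = counts[kept]
    totals = totals[kept]
    median_total = float(np.median(totals))
    norm = counts * (median_total / totals)[:, None]
    logged = np.log1p(norm)
    means = logged.mean(axis=0)
    sds = logged.std(axis=0)
    sds = np.where(sds > 0, sds, 1.0)
    X = (logged - means) / sds
    return Preprocessing(X=X, kept_cells=kept, median_total=median_total,
                         gene_means=means, gene_sds=sds)


def _canonical_relabel(labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Relabel to 0..K-1 in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out, len(mapping)


def _merge_cross_linked(labels: np.ndarray, edges: dict, ratio: float = 0.1) -> np.ndarray:
    """Agglomerate communities that stay densely cross-linked.

    Modularity happily splits one dense blob into sub-communities (a kNN
    graph is blind to geometric scale), but such halves remain heavily
    interconnected, whereas genuinely distinct clusters share almost no
    Jaccard edges.  Pairs whose mean cross-pair weight exceeds ``ratio`` of
    their mean within-pair weight are merged, largest ratio first, until no
    pair qualifies.
    """
    labels = labels.copy()
    while True:
        uniq = np.unique(labels)
        K = len(uniq)
        if K < 2:
            return labels
        pos = {c: i for i, c in enumerate(uniq)}
        W = np.zeros((K, K))
        for (a, b), w in edges.items():
            i, j = pos[labels[a]], pos[labels[b]]
            W[i, j] += w
            W[j, i] += w
        sizes = np.array([(labels == c).sum() for c in uniq])
        within = np.array([W[i, i] / 2 / max(sizes[i] * (sizes[i] - 1) / 2, 1)
                           for i in range(K)])
        best = None
        for i in range(K):
            for j in range(i + 1, K):
                denom = (within[i] + within[j]) / 2
                if denom <= 0:
                    continue
                cross = W[i, j] / (sizes[i] * sizes[j])
                r = cross / denom
                if r >= ratio and (best is None or r > best[0]):
                    best = (r, i, j)
        if best is None:
            return labels
        _, i, j = best
        labels[labels == uniq[j]] = uniq[i]


def cluster_graph(X: np.ndarray, k_neighbors: int = 30, resolution: float = 1.0,
                  seed: int = 0, preprocessing: Preprocessing | None = None) -> Clustering:
    """Phenograph-style kNN/Jaccard/Leiden community detection.

    Singleton communities are merged into the community with the nearest
    centroid.  For small inputs ``k_neighbors`` shrinks (with a warning) to
    at most n/5, so a neighborhood cannot span several plausible communities
    of a small FoV — with k fixed at 30 an 80-cell FoV would force every
    neighborhood to mix cell types and merge true clusters.  Densely
    cross-linked communities are agglomerated afterwards (see
    :func:`_merge_cross_linked`).
    """
    import igraph as ig
    import leidenalg

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("graph clustering needs at least 3 cells")
    k = min(k_neighbors, max(2, n // 5))
    if k < k_neighbors:
        warnings.warn(f"k_neighbors shrunk to {k} for {n} cells")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    neigh = [set(row[1:]) for row in idx]  # exclude self

    edges: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in neigh[i]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            if (a, b) in edges:
                continue
            inter = len(neigh[a] & neigh[b])
            union = len(neigh[a] | neigh[b])
            jac = inter / union if union else 0.0
            if jac > 0:
                edges[(a, b)] = jac

    g = ig.Graph(n=n, edges=list(edges.keys()))
    weights = list(edges.values())
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition, weights=weights,
        resolution_parameter=resolution, seed=int(seed), n_iterations=-1)
    labels = np.asarray(part.membership, dtype=np.int64)

    # fold singletons into the nearest (centroid-distance) larger community
    uniq, sizes = np.unique(labels, return_counts=True)
    big = uniq[sizes > 1]
    if len(big) and len(big) < len(uniq):
        cents = {int(c): X[labels == c].mean(axis=0) for c in big}
        for c in uniq[sizes == 1]:
            i = int(np.flatnonzero(labels == c)[0])
            d = {cc: float(np.linalg.norm(X[i] - mu)) for cc, mu in cents.items()}
            labels[i] = min(d, key=lambda cc: (d[cc], cc))
    labels = _merge_cross_linked(labels, edges)
    labels, K = _canonical_relabel(labels)
    return Clustering(labels=labels, K=K, method="graph", preprocessing=preprocessing,
                      params={"k_neighbors": k, "resolution": resolution, "seed": seed})


class _NIW:
    """Sufficient statistics and predictive densities for one NIW component."""

    def __init__(self, d: int, m0: np.ndarray, k0: float, nu0: float, S0: np.ndarray):
        self.d, self.m0, self.k0, self.nu0, self.S0 = d, m0, k0, nu0, S0
        self.n = 0
        self.sum = np.zeros(d)
        self.outer = np.zeros((d, d))
        self._pred = None   # cached (mn, dof, chol, logdet) for the predictive

    def add(self, x: np.ndarray) -> None:
        self.n += 1
        self.sum += x
        self.outer += np.outer(x, x)
        self._pred = None

    def remove(self, x: np.ndarray) -> None:
        self.n -= 1
        self.sum -= x
        self.outer -= np.outer(x, x)
        self._pred = None

    def posterior(self):
        n = self.n
        kn = self.k0 + n
        nun = self.nu0 + n
        xbar = self.sum / n if n else np.zeros(self.d)
        mn = (self.k0 * self.m0 + self.sum) / kn
        S = self.outer - n * np.outer(xbar, xbar) if n else np.zeros((self.d, self.d))
        diff = xbar - self.m0
        Sn = self.S0 + S + (self.k0 * n / kn) * np.outer(diff, diff)
        return mn, kn, nun, Sn

    def log_predictive(self, x: np.ndarray) -> float:
        """Multivariate-t posterior-predictive log density at x."""
        if self._pred is None:
            mn, kn, nun, Sn = self.posterior()
            dof = nun - self.d + 1
            scale = Sn * (kn + 1) / (kn * dof)
            L = np.linalg.cholesky(scale)
            self._pred = (mn, dof, L, 2 * np.log(np.diag(L)).sum())
        mn, dof, L, logdet = self._pred
        d = self.d
        sol = solve_triangular(L, x - mn, lower=True)
        quad = float(sol @ sol)
        return float(gammaln((dof + d) / 2) - gammaln(dof / 2)
                     - d / 2 * np.log(dof * np.pi) - 0.5 * logdet
                     - (dof + d) / 2 * np.log1p(quad / dof))

    def log_marginal(self) -> float:
        """log evidence of the component's members under the NIW prior."""
        n, d = self.n, self.d
        if n == 0:
            return 0.0
        _, kn, nun, Sn = self.posterior()
        s0, sn = np.linalg.slogdet(self.S0), np.linalg.slogdet(Sn)
        lg = lambda nu: sum(gammaln((nu - i) / 2) for i in range(d))
        return float(-n * d / 2 * np.log(np.pi)
                     + lg(nun) - lg(self.nu0)
                     + self.nu0 / 2 * s0[1] - nun / 2 * sn[1]
                     + d / 2 * (np.log(self.k0) - np.log(kn)))


def cluster_dpmm(X: np.ndarray, params: DpmmParams | None = None,
                 preprocessing: Preprocessing | None = None) -> Clustering:
    """DP Gaussian mixture via collapsed Gibbs; returns the MAP sweep's labels.

    For wide matrices (more than ``n_components_pca`` features) the data are
    first reduced by PCA so the NIW posteriors stay well conditioned.
    """
    params = params or DpmmParams()
    X = np.asarray(X, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in clustering input")
    n, d = X.shape
    if n < 3:
        raise ValueError("DPMM needs at least 3 cells")
    if d > params.n_components_pca:
        from sklearn.decomposition import PCA

        ncomp = min(params.n_components_pca, n - 1)
        X = PCA(n_components=ncomp, svd_solver="full", random_state=0).fit_transform(X)
        d = X.shape[1]

    rng = np.random.default_rng(params.seed)
    m0 = X.mean(axis=0)
    nu0 = params.nu0 if params.nu0 is not None else d + 2
    var = X.var(axis=0)
    S0 = np.diag(np.where(var > 0, var, 1.0))
    make = lambda: _NIW(d, m0, params.k0, nu0, S0)
    empty = make()  # reused for the new-cluster (prior) predictive

    # start from the all-singletons partition: collapsed Gibbs merges easily
    # but splits a merged cluster only with difficulty, so this end is the
    # safe one to anneal from
    comps: list[_NIW] = []
    z = np.arange(n, dtype=np.int64)
    for i, x in enumerate(X):
        comp = make()
        comp.add(x)
        comps.append(comp)
    log_alpha = np.log(params.alpha)

    best_score = -np.inf
    best_labels = z.copy()
    for sweep in range(params.n_sweeps):
        for i in range(n):
            x = X[i]
            comps[z[i]].remove(x)
            if comps[z[i]].n == 0:
                dead = z[i]
                comps.pop(dead)
                z[z > dead] -= 1
            logp = np.empty(len(comps) + 1)
            for c, comp in enumerate(comps):
                logp[c] = np.log(comp.n) + comp.log_predictive(x)
            logp[-1] = log_alpha + empty.log_predictive(x)
            logp -= logp.max()
            p = np.exp(logp)
            choice = rng.choice(len(p), p=p / p.sum())
            if choice == len(comps):
                comps.append(make())
            comps[choice].add(x)
            z[i] = choice
        # joint score: CRP partition prior + per-component NIW evidence
        sizes = np.array([c.n for c in comps])
        crp = (len(comps) * np.log(params.alpha) + gammaln(sizes).sum()
               + gammaln(params.alpha) - gammaln(params.alpha + n))
        score = crp + sum(c.log_marginal() for c in comps)
        if score > best_score:
            best_score = score
            best_labels = z.copy()
    labels, K = _canonical_relabel(best_labels)
    return Clustering(labels=labels, K=K, method="dpmm", preprocessing=preprocessing,
                      params={"alpha": params.alpha, "n_sweeps": params.n_sweeps,
                              "seed": params.seed})


def match_clusters(labels_a: np.ndarray, labels_b: np.ndarray) -> tuple[dict[int, int], float]:
    """Hungarian matching of two labelings of the same cells, plus ARI.

    Returns ``(mapping a-label -> b-label, adjusted Rand index)``.  Unmatched
    a-labels (when a has more clusters) map to -1.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must cover the same cell set")
    ua, ub = np.unique(labels_a), np.unique(labels_b)
    cont = np.zeros((len(ua), len(ub)))
    ia = {l: i for i, l in enumerate(ua)}
    ib = {l: i for i, l in enumerate(ub)}
    for a, b in zip(labels_a, labels_b):
        cont[ia[a], ib[b]] += 1
    rows, cols = linear_sum_assignment(-cont)
    mapping = {int(l): -1 for l in ua}
    for r, c in zip(rows, cols):
        mapping[int(ua[r])] = int(ub[c])
    return mapping, float(adjusted_rand_score(labels_a, labels_b))
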