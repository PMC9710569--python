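"""Orchestration of the iterative reassignment loop.

Each iteration re-clusters the current count matrix, re-estimates the
per-cluster Gaussian moments, classifies every remaining dangling spot via
its mock cell and commits all assignments as one synchronous batch — so an
iteration's decisions depend only on the state at its start and are
independent of spot processing order (spot-id order fixes count-tie breaks).
The loop stops after ``max_iterations`` or the first iteration that assigns
nothing.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .core_io import (
    AssignmentRecord,
    CountMatrix,
    Segmentation,
    SpotTable,
    STATUS_DANGLING,
    build_count_matrix,
    read_segmentation,
    read_spots,
    write_outputs,
)
from .clustering import Clustering, DpmmParams, cluster_dpmm, cluster_graph, preprocess
from .assignment import (
    AssignParams,
    apply_assignment,
    assign_to_cell,
    batch_loglik,
    build_mock_cell,
    estimate_moments,
    mock_to_model_space,
)
from .synthetic import SimConfig, simulate_fov

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "IterationReport", "run_sparcle", "iterate_assignments"]


@dataclass
class IterationReport:
    iteration: int
    n_assigned: int
    fraction_of_total: float
    n_remaining_dangling: int
    K: int
    wall_time: float


@dataclass
class RunConfig:
    """One run: either simulate a FoV or load spots + segmentation from files."""

    mode: str = "simulate"                       # "simulate" | "files"
    sim: SimConfig | None = None
    spots_path: str | None = None
    mask_path: str | None = None
    column_map: dict | None = None
    clusterer: str = "graph"                     # "graph" | "dpmm"
    k_neighbors: int = 30
    resolution: float = 1.0
    dpmm: DpmmParams | None = None
    assign: AssignParams = field(default_factory=AssignParams)
    lambda_frac: float = 1e-2
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in {"simulate", "files"}:
            raise ValueError("mode must be 'simulate' or 'files'")
        if self.mode == "files" and not (self.spots_path and self.mask_path):
            raise ValueError("files mode needs spots_path and mask_path")


def _cluster_matrix(matrix: CountMatrix, cfg: RunConfig, prev_labels: np.ndarray | None):
    """Preprocess + cluster, re-attaching zero-total cells dropped upstream."""
    pre = preprocess(matrix)
    if cfg.clusterer == "graph":
        clustering = cluster_graph(pre.X, k_neighbors=cfg.k_neighbors,
                                   resolution=cfg.resolution, seed=cfg.seed,
                                   preprocessing=pre)
    elif cfg.clusterer == "dpmm":
        params = cfg.dpmm or DpmmParams(seed=cfg.seed)
        clustering = cluster_dpmm(pre.X, params, preprocessing=pre)
    else:
        raise ValueError(f"unknown clusterer {cfg.clusterer!r}")
    if pre.kept_cells.all():
        return pre, clustering, clustering.labels
    # zero-total cells keep their previous label (or 0 on the first iteration)
    full = np.zeros(matrix.n_cells, dtype=np.int64)
    full[pre.kept_cells] = clustering.labels
    dropped = np.flatnonzero(~pre.kept_cells)
    if prev_labels is not None:
        full[dropped] = np.minimum(prev_labels[dropped], clustering.K - 1)
    return pre, clustering, full


def iterate_assignments(spots: SpotTable, seg: Segmentation, matrix: CountMatrix,
                        cfg: RunConfig) -> tuple[CountMatrix, Clustering, list[AssignmentRecord], list[IterationReport]]:
    """Run the fixed-iteration reassignment loop on an initialised state."""
    params = cfg.assign.resolved(seg.cell_areas())
    logger.info("assignment params: r=%.2f D=%.2f delta=%.2f margin=%.2f iters=%d",
                params.radius, params.max_assign_dist, params.delta,
                params.min_loglik_margin, params.max_iterations)
    n_total = len(spots)
    coords = spots.df[["x", "y"]].to_numpy()
    gene_idx = spots.gene_indices()
    tree = cKDTree(coords)

    records: list[AssignmentRecord] = []
    reports: list[IterationReport] = []
    clustering: Clustering | None = None
    full_labels: np.ndarray | None = None

    for it in range(1, params.max_iterations + 1):
        t0 = time.perf_counter()
        pre, clustering, full_labels = _cluster_matrix(matrix, cfg, full_labels)
        model = estimate_moments(pre.X, clustering, lambda_frac=cfg.lambda_frac)
        kept_labels = full_labels[pre.kept_cells] if not pre.kept_cells.all() else full_labels

        dangling = spots.df[spots.df["status"] == STATUS_DANGLING].sort_values("spot_id")
        decisions = []  # (spot_id, cell_id, cluster, loglik), batch-committed below
        if len(dangling):
            didx = dangling.index.to_numpy()
            vecs = np.empty((len(didx), len(spots.panel)))
            for row, i in enumerate(didx):
                mock = build_mock_cell((coords[i, 0], coords[i, 1]), gene_idx[i], spots,
                                       params.radius, params.delta,
                                       tree=tree, coords=coords, gene_idx=gene_idx)
                vecs[row] = mock_to_model_space(mock, pre)
            ll = batch_loglik(vecs, model)
            # argmax with lower-id tie-break, then the conservatism gate
            best = np.array([int(np.argmax(ll[r])) for r in range(len(didx))])
            for row, i in enumerate(didx):
                k = best[row]
                if model.K > 1:
                    second = np.partition(ll[row], -2)[-2]
                    margin = ll[row, k] - second
                else:
                    margin = np.inf
                if margin < params.min_loglik_margin:
                    continue
                cell = assign_to_cell((coords[i, 0], coords[i, 1]), k, matrix,
                                      full_labels, params.max_assign_dist)
                if cell is not None:
                    decisions.append((spots.df.at[i, "spot_id"], cell, k, float(ll[row, k])))

        for spot_id, cell, k, loglik in decisions:
            records.append(apply_assignment(spot_id, cell, matrix, spots, k, it, loglik))

        n_assigned = len(decisions)
        reports.append(IterationReport(
            iteration=it, n_assigned=n_assigned,
            fraction_of_total=n_assigned / n_total if n_total else 0.0,
            n_remaining_dangling=spots.n_dangling, K=clustering.K,
            wall_time=time.perf_counter() - t0))
        logger.info("iteration %d: assigned %d spots (%.1f%% of total), "
                    "%d still dangling, K=%d", it, n_assigned,
                    100 * reports[-1].fraction_of_total, spots.n_dangling, clustering.K)
        if n_assigned == 0:
            break

    # final clustering reflects the corrected matrix
    pre, clustering, full_labels = _cluster_matrix(matrix, cfg, full_labels)
    if not pre.kept_cells.all():
        clustering = Clustering(labels=full_labels, K=int(full_labels.max()) + 1,
                                method=clustering.method, preprocessing=pre,
                                params=clustering.params)
    return matrix, clustering, records, reports


def run_sparcle(cfg: RunConfig):
    """End-to-end run from a :class:`RunConfig`.

    Returns ``(matrix, clustering, records, reports)`` and, when
    ``cfg.out_dir`` is set, writes all output files there.
    """
    if cfg.mode == "simulate":
        sim = cfg.sim or SimConfig(seed=cfg.seed)
        spots, seg, _truth = simulate_fov(sim)
    else:
        spots = read_spots(cfg.spots_path, cfg.column_map)
        seg = read_segmentation(cfg.mask_path)
    matrix = build_count_matrix(spots, seg)
    matrix, clustering, records, reports = iterate_assignments(spots, seg, matrix, cfg)
    if cfg.out_dir:
        write_outputs(matrix, records, spots, cfg.out_dir,
                      cluster_labels=clustering.labels)
        _write_reports(reports, Path(cfg.out_dir) / "iterations.csv")
    return matrix, clustering, records, reports


def _write_reports(reports: list[IterationReport], path: Path) -> None:
    import pandas as pd

    pd.DataFrame([{
        "iteration": r.iteration, "n_assigned": r.n_assigned,
        "fraction_of_total": r.fraction_of_total,
        "n_remaining_dangling": r.n_remaining_dangling, "K": r.K,
    } for r in reports]).to_csv(path, index=False)
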