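"""Domain types, coordinate conventions and file I/O for the spot-to-cell pipeline.

Coordinate conventions
----------------------
Spots live in continuous 2D coordinates ``(x, y)`` in a single unit (pixel or
micron) fixed per run.  Label masks are 2D integer arrays indexed ``mask[ix, iy]``
(axis 0 is x), where pixel ``(i, j)`` covers the half-open unit square
``[i, i+1) x [j, j+1)`` and 0 denotes background.  A spot at ``(x, y)`` falls in
pixel ``(floor(x), floor(y))``; containment is decided by that pixel's label,
with no epsilon tolerance.  Cell centroids from a mask are arithmetic means of
member pixel indices.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

logger = logging.getLogger(__name__)

STATUS_INSIDE = "inside"
STATUS_DANGLING = "dangling"
STATUS_ASSIGNED = "assigned"

__all__ = [
    "SpotTable",
    "Segmentation",
    "CountMatrix",
    "AssignmentRecord",
    "read_spots",
    "read_segmentation",
    "dilate_segmentation",
    "build_count_matrix",
    "write_outputs",
    "STATUS_INSIDE",
    "STATUS_DANGLING",
    "STATUS_ASSIGNED",
]


class SpotTableError(ValueError):
    """Malformed or inconsistent spot data."""


@dataclass
class SpotTable:
    """Per-transcript records plus the ordered gene panel.

    ``df`` columns: ``spot_id`` (unique), ``gene``, ``x``, ``y``, ``status``
    (one of inside/dangling/assigned), ``cell_id`` (-1 when unattached) and
    ``iteration`` (0 for inside spots, the assigning iteration otherwise).
    The panel defines count-matrix column order.
    """

    df: pd.DataFrame
    panel: list[str]

    def __post_init__(self) -> None:
        required = {"spot_id", "gene", "x", "y", "status", "cell_id", "iteration"}
        missing = required - set(self.df.columns)
        if missing:
            raise SpotTableError(f"spot table missing columns: {sorted(missing)}")
        if self.df["spot_id"].duplicated().any():
            dup = self.df.loc[self.df["spot_id"].duplicated(), "spot_id"].iloc[0]
            raise SpotTableError(f"duplicate spot_id {dup!r}")
        unknown = set(self.df["gene"]) - set(self.panel)
        if unknown:
            raise SpotTableError(f"genes outside panel: {sorted(unknown)[:5]}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_dangling(self) -> int:
        return int((self.df["status"] == STATUS_DANGLING).sum())

    @property
    def n_inside(self) -> int:
        return int((self.df["status"] == STATUS_INSIDE).sum())

    @property
    def n_assigned(self) -> int:
        return int((self.df["status"] == STATUS_ASSIGNED).sum())

    def gene_indices(self) -> np.ndarray:
        """Panel index of each spot's gene, in table order."""
        lut = {g: i for i, g in enumerate(self.panel)}
        return self.df["gene"].map(lut).to_numpy(dtype=np.int64)

    def copy(self) -> "SpotTable":
        return SpotTable(self.df.copy(), list(self.panel))


@dataclass
class Segmentation:
    """Cell segmentation as a label mask or per-cell polygons, plus centroids.

    ``label_mask[ix, iy]``: 0 = background, k > 0 = cell k.  ``polygons`` maps
    cell id to an (n, 2) array of boundary vertices.  ``centroids`` maps cell
    id to (x, y).
    """

    label_mask: np.ndarray | None = None
    polygons: dict[int, np.ndarray] | None = None
    centroids: dict[int, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.label_mask is None) == (self.polygons is None):
            raise ValueError("exactly one of label_mask or polygons required")
        if any(int(c) <= 0 for c in self.cell_ids):
            raise ValueError("cell ids must be positive")

    @property
    def cell_ids(self) -> list[int]:
        if self.label_mask is not None:
            ids = np.unique(self.label_mask)
            return [int(i) for i in ids if i > 0]
        return sorted(self.polygons)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cell_areas(self) -> dict[int, float]:
        """Pixel area per cell (mask) or shoelace polygon area."""
        if self.label_mask is not None:
            ids, counts = np.unique(self.label_mask, return_counts=True)
            return {int(i): float(c) for i, c in zip(ids, counts) if i > 0}
        areas = {}
        for cid, poly in self.polygons.items():
            x, y = poly[:, 0], poly[:, 1]
            areas[cid] = float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)
        return areas


@dataclass
class CountMatrix:
    """Cells x genes nonnegative integer counts plus centroids.

    Gene order matches the originating :class:`SpotTable` panel.
    """

    counts: np.ndarray
    cell_ids: np.ndarray
    genes: list[str]
    centroids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integer-valued")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.shape != (len(self.cell_ids), len(self.genes)):
            raise ValueError("counts shape does not match cell_ids x genes")
        if self.centroids.shape != (len(self.cell_ids), 2):
            raise ValueError("centroids must be C x 2")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def cell_index(self, cell_id: int) -> int:
        idx = np.flatnonzero(self.cell_ids == cell_id)
        if idx.size == 0:
            raise KeyError(f"unknown cell id {cell_id}")
        return int(idx[0])

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.counts.copy(), self.cell_ids.copy(), list(self.genes), self.centroids.copy())


@dataclass(frozen=True)
class AssignmentRecord:
    """Provenance of one dangling-spot reassignment."""

    spot_id: object
    cell_id: int
    cluster_id: int
    iteration: int
    loglik: float


def read_spots(path: str | Path, column_map: dict[str, str] | None = None,
               panel: list[str] | None = None) -> SpotTable:
    """Read a per-transcript CSV into a :class:`SpotTable`.

    ``column_map`` maps the logical names ``spot_id, gene, x, y`` to the file's
    column headers (defaults: identical names).  All statuses start dangling;
    containment is decided later by :func:`build_count_matrix`.
    """
    cmap = {"spot_id": "spot_id", "gene": "gene", "x": "x", "y": "y"}
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path)
    missing = [v for v in cmap.values() if v not in raw.columns]
    if missing:
        raise SpotTableError(f"spot file {path} missing required column(s): {missing}")
    df = pd.DataFrame({
        "spot_id": raw[cmap["spot_id"]],
        "gene": raw[cmap["gene"]].astype(str),
    })
    for axis in ("x", "y"):
        vals = pd.to_numeric(raw[cmap[axis]], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise SpotTableError(
                f"non-numeric {axis} coordinate at data row {row} of {path}")
        df[axis] = vals.astype(float)
    df["status"] = STATUS_DANGLING
    df["cell_id"] = -1
    df["iteration"] = 0
    if panel is None:
        panel = sorted(df["gene"].unique())
    return SpotTable(df.reset_index(drop=True), list(panel))


def _mask_centroids(mask: np.ndarray) -> dict[int, tuple[float, float]]:
    ids = [int(i) for i in np.unique(mask) if i > 0]
    if not ids:
        return {}
    coms = ndimage.center_of_mass(np.ones_like(mask, dtype=float), labels=mask, index=ids)
    return {cid: (float(cx), float(cy)) for cid, (cx, cy) in zip(ids, coms)}


def read_segmentation(source) -> Segmentation:
    """Build a :class:`Segmentation` from a mask path/array or polygon dict.

    Masks must be integer-valued; centroids are means of member pixel indices.
    Polygon centroids are vertex means; self-intersecting polygons are rejected.
    """
    if isinstance(source, dict):
        from shapely.geometry import Polygon

        polys: dict[int, np.ndarray] = {}
        centroids: dict[int, tuple[float, float]] = {}
        for cid, verts in source.items():
            arr = np.asarray(verts, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
                raise ValueError(f"cell {cid}: polygon needs >=3 (x, y) vertices")
            if np.allclose(arr[0], arr[-1]) and len(arr) > 3:
                arr = arr[:-1]
            if not Polygon(arr).is_valid:
                raise ValueError(f"cell {cid}: polygon is self-intersecting or degenerate")
            polys[int(cid)] = arr
            centroids[int(cid)] = (float(arr[:, 0].mean()), float(arr[:, 1].mean()))
        return Segmentation(polygons=polys, centroids=centroids)

    if isinstance(source, (str, Path)):
        path = Path(source)
        if path.suffix.lower() in {".tif", ".tiff"}:
            import tifffile

            mask = tifffile.imread(path)
        else:
            from PIL import Image

            mask = np.asarray(Image.open(path))
    else:
        mask = np.asarray(source)
    if not np.issubdtype(mask.dtype, np.integer):
        if not np.array_equal(mask, np.round(mask)):
            raise TypeError("label mask must be integer-valued")
        mask = mask.astype(np.int32)
    if mask.ndim != 2:
        raise ValueError("label mask must be 2D")
    return Segmentation(label_mask=mask.copy(), centroids=_mask_centroids(mask))


def dilate_segmentation(seg: Segmentation, pixels: int) -> Segmentation:
    """Grow each label by a disk of the given radius.

    A background pixel acquires the label of the nearest original labelled
    pixel (Euclidean distance between pixel indices), provided that distance is
    at most ``pixels``; distance ties resolve to the lower label id.  Original
    labelled pixels never change, so over-dilation cannot flip one cell into
    another.  Centroids are recomputed on the dilated mask.
    """
    if seg.label_mask is None:
        raise NotImplementedError("dilation requires a label-mask representation")
    if pixels < 0 or int(pixels) != pixels:
        raise ValueError("dilation radius must be a nonnegative integer")
    mask = seg.label_mask
    ids = seg.cell_ids
    if pixels == 0 or not ids:
        return Segmentation(label_mask=mask.copy(), centroids=_mask_centroids(mask))
    # exact per-label EDTs; argmin over ascending ids gives the lower-id tie-break
    best_d = np.full(mask.shape, np.inf)
    best_lab = np.zeros(mask.shape, dtype=mask.dtype)
    for lab in ids:
        d = ndimage.distance_transform_edt(mask != lab)
        take = d < best_d - 1e-12
        best_d[take] = d[take]
        best_lab[take] = lab
    new_mask = np.where(best_d <= pixels + 1e-12, best_lab, 0).astype(mask.dtype)
    return Segmentation(label_mask=new_mask, centroids=_mask_centroids(new_mask))


def build_count_matrix(spots: SpotTable, seg: Segmentation) -> CountMatrix:
    """Count inside spots per (cell, gene); mark everything else dangling.

    Mutates ``spots.df`` statuses.  Spots outside the image extent are marked
    dangling with a warning, never an error.
    """
    if seg.label_mask is None:
        raise NotImplementedError("counting requires a label-mask representation")
    mask = seg.label_mask
    cell_ids = np.asarray(seg.cell_ids, dtype=np.int64)
    cell_pos = {cid: i for i, cid in enumerate(cell_ids)}

    x = spots.df["x"].to_numpy()
    y = spots.df["y"].to_numpy()
    ix = np.floor(x).astype(np.int64)
    iy = np.floor(y).astype(np.int64)
    in_extent = (ix >= 0) & (iy >= 0) & (ix < mask.shape[0]) & (iy < mask.shape[1])
    n_outside = int((~in_extent).sum())
    if n_outside:
        logger.warning("%d spot(s) outside the image extent; marked dangling", n_outside)

    labels = np.zeros(len(spots.df), dtype=np.int64)
    labels[in_extent] = mask[ix[in_extent], iy[in_extent]]

    spots.df["status"] = np.where(labels > 0, STATUS_INSIDE, STATUS_DANGLING)
    spots.df["cell_id"] = np.where(labels > 0, labels, -1)
    spots.df["iteration"] = 0

    counts = np.zeros((len(cell_ids), len(spots.panel)), dtype=np.int64)
    gidx = spots.gene_indices()
    inside = labels > 0
    rows = np.array([cell_pos[l] for l in labels[inside]], dtype=np.int64)
    np.add.at(counts, (rows, gidx[inside]), 1)

    centroids = np.array([seg.centroids[int(c)] for c in cell_ids], dtype=float) \
        if len(cell_ids) else np.zeros((0, 2))
    return CountMatrix(counts, cell_ids, list(spots.panel), centroids)


def _cell_hulls(spots: SpotTable) -> pd.DataFrame:
    rows = []
    attached = spots.df[spots.df["cell_id"] >= 0]
    for cid, grp in attached.groupby("cell_id", sort=True):
        pts = grp[["x", "y"]].to_numpy()
        pts = np.unique(pts, axis=0)
        if len(pts) >= 3:
            try:
                hull = ConvexHull(pts)
                pts = pts[hull.vertices]
            except QhullError:  # collinear points
                pass
        for order, (px, py) in enumerate(pts):
            rows.append((int(cid), order, float(px), float(py)))
    return pd.DataFrame(rows, columns=["cell_id", "vertex", "x", "y"])


def write_outputs(matrix: CountMatrix, records: list[AssignmentRecord],
                  spots: SpotTable, out_dir: str | Path,
                  cluster_labels: np.ndarray | None = None) -> dict[str, Path]:
    """Write the corrected matrix, assignment records, clusters and hulls.

    Produces MatrixMarket ``counts.mtx`` with ``barcodes.tsv``/``genes.tsv``,
    a dense ``counts.csv``, ``assignments.csv`` (one row per reassignment),
    ``clusters.csv`` and ``boundaries.csv`` (per-cell convex hull over member
    spot coordinates).  Integer data round-trips exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    from scipy.sparse import csr_matrix

    paths["mtx"] = out / "counts.mtx"
    spio.mmwrite(paths["mtx"], csr_matrix(matrix.counts), field="integer")
    paths["barcodes"] = out / "barcodes.tsv"
    pd.Series(matrix.cell_ids).to_csv(paths["barcodes"], index=False, header=False, sep="\t")
    paths["genes"] = out / "genes.tsv"
    pd.Series(matrix.genes).to_csv(paths["genes"], index=False, header=False, sep="\t")

    paths["counts_csv"] = out / "counts.csv"
    dense = pd.DataFrame(matrix.counts, index=matrix.cell_ids, columns=matrix.genes)
    dense.index.name = "cell_id"
    dense.to_csv(paths["counts_csv"])

    paths["assignments"] = out / "assignments.csv"
    rec_df = pd.DataFrame(
        [(r.spot_id, r.cell_id, r.cluster_id, r.iteration, r.loglik) for r in records],
        columns=["spot_id", "cell_id", "cluster_id", "iteration", "loglik"])
    rec_df.to_csv(paths["assignments"], index=False)

    paths["clusters"] = out / "clusters.csv"
    if cluster_labels is None:
        cl = pd.DataFrame({"cell_id": matrix.cell_ids})
    else:
        cl = pd.DataFrame({"cell_id": matrix.cell_ids, "cluster_id": np.asarray(cluster_labels)})
    cl.to_csv(paths["clusters"], index=False)

    paths["boundaries"] = out / "boundaries.csv"
    _cell_hulls(spots).to_csv(paths["boundaries"], index=False)

    paths["spots"] = out / "spots_final.csv"
    spots.df.to_csv(paths["spots"], index=False)
    return paths
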