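"""Segmentation of model-labelled points into discrete clusters.

Each clustered point walks its neighbors in increasing-distance order,
pulling every clustered neighbor into its group and stopping at the
first non-clustered neighbor.  Groups sharing a member are merged
(union-find).  A cluster's outline is the union of discs centred on its
members — disc radius proportional to the cluster's mean
nearest-neighbor distance — eroded inward by a second proportion of the
same distance, which closes the shape without fusing neighboring
clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.ops import unary_union

from .models import PointLabels
from .tables import LocalizationTable

__all__ = [
    "ClusterAssignment",
    "ClusterShape",
    "ClusterStats",
    "segment",
    "build_cluster_shape",
    "summarize",
]

DEFAULT_MIN_CLUSTER_SIZE = 3
DEFAULT_DISC_FACTOR = 1.0
DEFAULT_EROSION_FACTOR = 0.5
DEFAULT_SINGLETON_RADIUS_NM = 20.0


@dataclass
class ClusterAssignment:
    """Disjoint clusters over the clustered-labelled points.

    ``cluster_id`` is 0 for points outside any reported cluster;
    ``clusters`` maps id -> sorted member row indices.
    """

    cluster_id: np.ndarray
    clusters: dict[int, np.ndarray]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


@dataclass
class ClusterShape:
    """Eroded disc-union outline of one cluster.

    The outline may comprise several disjoint sub-polygons after
    erosion; ``fragmented`` flags that case and ``area_nm2`` sums the
    parts.  ``eroded`` is False when erosion annihilated the shape and
    the un-eroded union was reported instead.
    """

    polygons: list[np.ndarray]
    area_nm2: float
    mean_nnd_nm: float
    eroded: bool = True
    fragmented: bool = False

    @property
    def polygon(self) -> np.ndarray:
        return self.polygons[0]


@dataclass
class ClusterStats:
    """Per-field clustering summary."""

    clusters_per_um2: float
    pct_points_clustered: float
    points_per_cluster: np.ndarray
    cluster_area_nm2: np.ndarray
    median_points_per_cluster: float = field(init=False)
    iqr_points_per_cluster: tuple = field(init=False)
    median_cluster_area_nm2: float = field(init=False)
    iqr_cluster_area_nm2: tuple = field(init=False)

    def __post_init__(self) -> None:
        def med_iqr(v):
            if len(v) == 0:
                return float("nan"), (float("nan"), float("nan"))
            return float(np.median(v)), tuple(np.percentile(v, [25, 75]))

        self.median_points_per_cluster, self.iqr_points_per_cluster = med_iqr(
            self.points_per_cluster
        )
        self.median_cluster_area_nm2, self.iqr_cluster_area_nm2 = med_iqr(
            self.cluster_area_nm2
        )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def segment(
    table: LocalizationTable,
    labels: PointLabels | np.ndarray,
    min_cluster_size: int = DEFAULT_MIN_CLUSTER_SIZE,
    max_neighbors: int = 100,
) -> ClusterAssignment:
    """Group clustered points into clusters by walk-and-stop chaining.

    For each clustered point, neighbors are visited in increasing
    distance (ties broken by point id); every clustered neighbor joins
    the point's group and the walk stops at the first non-clustered
    neighbor.  Overlapping groups merge.  Clusters smaller than
    ``min_cluster_size`` are demoted to id 0.  ``max_neighbors`` caps
    the walk at the model's input window.
    """
    if isinstance(labels, PointLabels):
        hard = np.asarray(labels.label)
    else:
        hard = np.asarray(labels)
    if len(hard) != table.n:
        raise ValueError(
            f"labels ({len(hard)}) do not align with table rows ({table.n})"
        )
    clustered = np.flatnonzero(hard >= 1)
    cluster_id = np.zeros(table.n, dtype=int)
    if len(clustered) == 0:
        return ClusterAssignment(cluster_id=cluster_id, clusters={})

    k = min(max_neighbors, table.n - 1)
    tree = cKDTree(table.coords)
    dists, nbrs = tree.query(table.coords[clustered], k=k + 1, workers=-1)
    uf = _UnionFind(table.n)
    is_clustered = hard >= 1
    for row, i in enumerate(clustered):
        for col in range(1, k + 1):  # skip self at column 0
            j = int(nbrs[row, col])
            if not is_clustered[j]:
                break
            uf.union(i, j)

    roots = {}
    next_id = 1
    members: dict[int, list[int]] = {}
    for i in clustered:
        r = uf.find(int(i))
        if r not in roots:
            roots[r] = next_id
            members[next_id] = []
            next_id += 1
        members[roots[r]].append(int(i))

    clusters: dict[int, np.ndarray] = {}
    out_id = 1
    for cid in sorted(members):
        m = np.array(sorted(members[cid]), dtype=int)
        if len(m) >= min_cluster_size:
            clusters[out_id] = m
            cluster_id[m] = out_id
            out_id += 1
    return ClusterAssignment(cluster_id=cluster_id, clusters=clusters)


def _mean_nnd(coords: np.ndarray) -> float:
    tree = cKDTree(coords)
    d, _ = tree.query(coords, k=2)
    return float(d[:, 1].mean())


def build_cluster_shape(
    members: np.ndarray,
    disc_factor: float = DEFAULT_DISC_FACTOR,
    erosion_factor: float = DEFAULT_EROSION_FACTOR,
    singleton_radius_nm: float = DEFAULT_SINGLETON_RADIUS_NM,
) -> ClusterShape:
    """Disc-union-then-erode outline of one cluster.

    Discs of radius ``disc_factor x mean NND`` are centred on every
    member (mean NND computed among members only; a singleton falls back
    to ``singleton_radius_nm``), united, then eroded inward by
    ``erosion_factor x mean NND``.  If erosion annihilates the shape the
    un-eroded union is reported with ``eroded=False``.  3D members are
    projected to the xy plane.
    """
    members = np.asarray(members, dtype=float)
    if members.ndim != 2 or len(members) == 0:
        raise ValueError("members must be a non-empty (n, d) coordinate array")
    xy = members[:, :2]
    if len(xy) == 1:
        mean_nnd = singleton_radius_nm
    else:
        mean_nnd = _mean_nnd(xy)
        if mean_nnd <= 0:
            mean_nnd = singleton_radius_nm
    radius = disc_factor * mean_nnd
    union = unary_union([Point(p).buffer(radius, quad_segs=64) for p in xy])
    erosion = erosion_factor * mean_nnd
    shape = union.buffer(-erosion, quad_segs=64) if erosion > 0 else union
    eroded = True
    if shape.is_empty:
        shape = union
        eroded = False
    if isinstance(shape, MultiPolygon):
        polys = list(shape.geoms)
        fragmented = True
    elif isinstance(shape, Polygon):
        polys = [shape]
        fragmented = False
    else:  # pragma: no cover - buffer of points is always polygonal
        raise RuntimeError(f"unexpected geometry {shape.geom_type}")
    return ClusterShape(
        polygons=[np.asarray(p.exterior.coords) for p in polys],
        area_nm2=float(shape.area),
        mean_nnd_nm=float(mean_nnd),
        eroded=eroded,
        fragmented=fragmented,
    )


def build_all_shapes(
    table: LocalizationTable,
    assignment: ClusterAssignment,
    disc_factor: float = DEFAULT_DISC_FACTOR,
    erosion_factor: float = DEFAULT_EROSION_FACTOR,
) -> dict[int, ClusterShape]:
    """Shape for every reported cluster of an assignment."""
    return {
        cid: build_cluster_shape(table.coords[idx], disc_factor, erosion_factor)
        for cid, idx in assignment.clusters.items()
    }


def summarize(
    assignment: ClusterAssignment,
    shapes: dict[int, ClusterShape],
    analysis_area_um2: float,
) -> ClusterStats:
    """Per-field statistics: cluster density, clustered fraction, and
    median/IQR of per-cluster point counts and areas."""
    if analysis_area_um2 <= 0:
        raise ValueError("analysis_area_um2 must be positive")
    missing = set(assignment.clusters) - set(shapes)
    if missing:
        raise ValueError(f"missing shapes for clusters {sorted(missing)}")
    n_total = len(assignment.cluster_id)
    n_in = int((assignment.cluster_id > 0).sum())
    counts = np.array([len(v) for v in assignment.clusters.values()], dtype=int)
    areas = np.array(
        [shapes[cid].area_nm2 for cid in assignment.clusters], dtype=float
    )
    return ClusterStats(
        clusters_per_um2=assignment.n_clusters / analysis_area_um2,
        pct_points_clustered=100.0 * n_in / n_total if n_total else 0.0,
        points_per_cluster=counts,
        cluster_area_nm2=areas,
    )
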