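"""Ground-truth simulation of clustered SMLM fields.

A field is generated inside a cell-like polygon: cluster seeds are placed
uniformly at random inside the cell (rejection sampling), clustered
points are drawn around each seed according to the scenario's cluster
model, and the remaining points are completely spatially random (CSR)
inside the cell.  Every point carries its true class label and cluster
id, so fields double as labelled training data.

Cluster models
--------------
uniform-disc : uniform over the disc of radius ``cluster_radius_nm``.
gaussian     : isotropic normal, sigma = radius/2, truncated at 2 sigma
               so ~95% of the untruncated mass lies within the hard-edge
               radius used by the disc model.
fiber        : points spread uniformly along a random-walk polyline
               (filament) with lateral normal jitter; labelled class 2.
ring         : uniform over an annulus with inner radius a fixed fraction
               of the outer radius.
sphere-3d    : uniform inside a ball of the given radius; all z values
               are confined to ``[0, axial_range_nm]``, mimicking the
               axial capture range of astigmatic 3D SMLM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon

from .geometry import CellShape
from .scenarios import ClusterScenario, round_half_up
from .tables import LocalizationTable

__all__ = ["GroundTruth", "simulate_field", "SimulationError"]

LABEL_NONCLUSTERED = 0
LABEL_CLUSTERED = 1
LABEL_FIBER = 2

# fiber-model defaults: visually filament-like at SMLM scale
FIBER_LENGTH_NM = 2000.0
FIBER_STEP_NM = 100.0
FIBER_MAX_TURN_RAD = np.deg2rad(30.0)
FIBER_JITTER_NM = 20.0

RING_INNER_FRACTION = 0.5

_MAX_SEED_TRIES = 200


class SimulationError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the scenario."""


@dataclass
class GroundTruth:
    """Per-point truth for a simulated field.

    label: 0 = not clustered, 1 = clustered, 2 = clustered (fiber).
    true_cluster_id: 1-based cluster index, 0 for non-clustered points.
    seed_positions: cluster seed coordinates, nm, one row per cluster.
    """

    label: np.ndarray
    true_cluster_id: np.ndarray
    seed_positions: np.ndarray

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=int)
        self.true_cluster_id = np.asarray(self.true_cluster_id, dtype=int)
        if np.any((self.true_cluster_id > 0) & (self.label < 1)):
            raise ValueError("points with a cluster id must be labelled clustered")
        if np.any((self.label == 0) & (self.true_cluster_id != 0)):
            raise ValueError("non-clustered points must have cluster id 0")


def _uniform_in_polygon(rng: np.random.Generator, poly: Polygon, n: int) -> np.ndarray:
    """Rejection-sample n points uniformly inside a polygon."""
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2))
    filled = 0
    # polygon fills a decent fraction of its bbox, so a few rounds suffice
    while filled < n:
        m = max(2 * (n - filled), 64)
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        keep = cand[contains_xy(poly, cand[:, 0], cand[:, 1])]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _disc_offsets(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _gaussian_offsets(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    sigma = radius / 2.0
    out = np.empty((n, 2))
    filled = 0
    while filled < n:
        cand = rng.normal(scale=sigma, size=(2 * (n - filled) + 8, 2))
        keep = cand[np.hypot(cand[:, 0], cand[:, 1]) <= 2.0 * sigma]
        take = min(len(keep), n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _ring_offsets(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r_in = RING_INNER_FRACTION * radius
    # area-uniform over the annulus
    r = np.sqrt(rng.uniform(r_in**2, radius**2, size=n))
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _ball_offsets(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * rng.uniform(size=n) ** (1.0 / 3.0)
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return r[:, None] * v


def _fiber_points(rng: np.random.Generator, seed_xy: np.ndarray, n: int) -> np.ndarray:
    """Points spread uniformly along a bounded-turning random-walk polyline."""
    n_steps = max(int(FIBER_LENGTH_NM / FIBER_STEP_NM), 1)
    heading = rng.uniform(0.0, 2.0 * np.pi)
    turns = rng.uniform(-FIBER_MAX_TURN_RAD, FIBER_MAX_TURN_RAD, size=n_steps)
    headings = heading + np.cumsum(turns)
    steps = FIBER_STEP_NM * np.column_stack([np.cos(headings), np.sin(headings)])
    verts = np.vstack([seed_xy, seed_xy + np.cumsum(steps, axis=0)])
    # arc-length-uniform positions along the polyline
    t = rng.uniform(0.0, n_steps * FIBER_STEP_NM, size=n)
    seg = np.minimum((t // FIBER_STEP_NM).astype(int), n_steps - 1)
    frac = (t - seg * FIBER_STEP_NM) / FIBER_STEP_NM
    base = verts[seg] + frac[:, None] * (verts[seg + 1] - verts[seg])
    normal = np.column_stack([-np.sin(headings[seg]), np.cos(headings[seg])])
    return base + rng.normal(scale=FIBER_JITTER_NM, size=n)[:, None] * normal


def _cluster_points(
    rng: np.random.Generator,
    scenario: ClusterScenario,
    poly: Polygon,
    seed_xyz: np.ndarray,
    n: int,
    axial: float,
) -> np.ndarray | None:
    """Draw n member points for one cluster; None if the seed is hopeless."""
    model = scenario.cluster_model
    radius = scenario.cluster_radius_nm
    dims = 3 if model == "sphere-3d" else 2
    pts = np.empty((n, dims))
    filled = 0
    for _ in range(60):
        need = n - filled
        if need == 0:
            break
        m = 2 * need + 8
        if model == "uniform-disc":
            cand = seed_xyz[:2] + _disc_offsets(rng, m, radius)
        elif model == "gaussian":
            cand = seed_xyz[:2] + _gaussian_offsets(rng, m, radius)
        elif model == "ring":
            cand = seed_xyz[:2] + _ring_offsets(rng, m, radius)
        elif model == "fiber":
            cand = _fiber_points(rng, seed_xyz[:2], m)
        elif model == "sphere-3d":
            cand = seed_xyz + _ball_offsets(rng, m, radius)
        else:  # pragma: no cover - scenario validation forbids this
            raise ValueError(model)
        ok = contains_xy(poly, cand[:, 0], cand[:, 1])
        if dims == 3:
            ok &= (cand[:, 2] >= 0.0) & (cand[:, 2] <= axial)
        keep = cand[ok]
        take = min(len(keep), need)
        pts[filled : filled + take] = keep[:take]
        filled += take
    if filled < n:
        return None
    return pts


def simulate_field(
    scenario: ClusterScenario,
    cell: CellShape,
    seed: int,
    allow_unviable: bool = False,
) -> tuple[LocalizationTable, GroundTruth]:
    """Simulate one labelled field for a clustering scenario.

    Point counts follow the scenario exactly: ``round(density x area)``
    points total, of which ``round(total x pct/100)`` are clustered.
    Clusters hold ``points_per_cluster`` members each, the last cluster
    under-filled to hit the exact clustered total.  Every point lies
    inside the cell polygon; 3D z values lie in ``[0, axial_range_nm]``.
    Deterministic for a fixed seed.

    Set ``allow_unviable=True`` to simulate scenarios that fail the
    viability filter (CSR controls, stress tests); otherwise unviable
    scenarios with clustering raise.
    """
    from .scenarios import assess_viability

    if not allow_unviable and scenario.pct_clustered > 0:
        if not assess_viability(scenario, cell).viable:
            raise ValueError(
                "scenario fails the viability filter; pass allow_unviable=True "
                "to simulate it anyway"
            )

    rng = np.random.default_rng(seed)
    poly = cell.polygon
    is_3d = scenario.cluster_model == "sphere-3d"
    axial = scenario.axial_range_nm
    if is_3d and axial <= 0:
        raise ValueError("sphere-3d scenarios need axial_range_nm > 0")

    n_total = round_half_up(scenario.overall_density * cell.area_um2)
    n_clustered = round_half_up(n_total * scenario.pct_clustered / 100.0)
    ppc = scenario.points_per_cluster
    n_clusters = -(-n_clustered // ppc) if n_clustered else 0  # ceil
    sizes = [ppc] * n_clusters
    if n_clusters:
        sizes[-1] = n_clustered - ppc * (n_clusters - 1)

    dims = 3 if is_3d else 2
    coords = np.empty((n_total, dims))
    label = np.zeros(n_total, dtype=int)
    cluster_id = np.zeros(n_total, dtype=int)
    member_label = LABEL_FIBER if scenario.cluster_model == "fiber" else LABEL_CLUSTERED

    seeds = np.empty((n_clusters, dims))
    pos = 0
    for ci, size in enumerate(sizes):
        pts = None
        for _ in range(_MAX_SEED_TRIES):
            seed_xy = _uniform_in_polygon(rng, poly, 1)[0]
            seed_xyz = seed_xy
            if is_3d:
                seed_xyz = np.append(seed_xy, rng.uniform(0.0, axial))
            pts = _cluster_points(rng, scenario, poly, seed_xyz, size, axial)
            if pts is not None:
                seeds[ci] = seed_xyz
                break
        if pts is None:
            raise SimulationError(
                f"could not place cluster {ci + 1} of scenario {scenario} "
                f"after {_MAX_SEED_TRIES} seed attempts"
            )
        coords[pos : pos + size] = pts
        label[pos : pos + size] = member_label
        cluster_id[pos : pos + size] = ci + 1
        pos += size

    n_bg = n_total - n_clustered
    bg_xy = _uniform_in_polygon(rng, poly, n_bg)
    if is_3d:
        bg = np.column_stack([bg_xy, rng.uniform(0.0, axial, size=n_bg)])
    else:
        bg = bg_xy
    coords[pos:] = bg

    table = LocalizationTable(coords=coords)
    truth = GroundTruth(label=label, true_cluster_id=cluster_id, seed_positions=seeds)
    return table, truth
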