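"""Clustering scenarios and the viability filter.

A clustering scenario is the four-parameter tuple that generates one
simulated condition: overall point density, percentage of points in
clusters, points per cluster, and the maximum distance of a clustered
point from its cluster seed (the cluster "radius").  Scenario grids are
Cartesian products of per-parameter value lists; training uses only the
"viable" scenarios, those yielding 1-5 clusters per µm² and an
inside/outside point-density ratio between 1.5x and 100x (both bounds
inclusive).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

from .geometry import NM_PER_UM, CellShape

__all__ = [
    "CLUSTER_MODELS",
    "ClusterScenario",
    "ViabilityResult",
    "enumerate_scenarios",
    "assess_viability",
    "default_training_grid",
]

CLUSTER_MODELS = ("uniform-disc", "gaussian", "fiber", "ring", "sphere-3d")


def round_half_up(x: float) -> int:
    """Point counts round half-up (2.5 -> 3), not banker's style."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ClusterScenario:
    """One generative clustering condition.

    overall_density:   points per µm² across the whole cell.
    pct_clustered:     percentage of points belonging to clusters, 0-100.
    points_per_cluster: cluster population (the last cluster of a field may
                       be under-filled to hit the exact clustered total).
    cluster_radius_nm: maximum seed-to-point distance, nm.
    cluster_model:     intra-cluster point distribution.
    axial_range_nm:    axial extent for 3D fields (0 for 2D).
    """

    overall_density: float
    pct_clustered: float
    points_per_cluster: int
    cluster_radius_nm: float
    cluster_model: str = "uniform-disc"
    axial_range_nm: float = 0.0

    def __post_init__(self) -> None:
        if self.overall_density <= 0:
            raise ValueError(f"overall_density must be > 0, got {self.overall_density}")
        if not 0.0 <= self.pct_clustered <= 100.0:
            raise ValueError(f"pct_clustered must lie in [0, 100], got {self.pct_clustered}")
        if self.points_per_cluster < 1:
            raise ValueError(f"points_per_cluster must be >= 1, got {self.points_per_cluster}")
        if self.cluster_radius_nm <= 0:
            raise ValueError(f"cluster_radius_nm must be > 0, got {self.cluster_radius_nm}")
        if self.cluster_model not in CLUSTER_MODELS:
            raise ValueError(
                f"unknown cluster_model {self.cluster_model!r}; expected one of {CLUSTER_MODELS}"
            )
        if self.axial_range_nm < 0:
            raise ValueError("axial_range_nm must be >= 0")

    @property
    def is_3d(self) -> bool:
        return self.cluster_model == "sphere-3d" and self.axial_range_nm > 0

    def to_dict(self) -> dict:
        return {
            "overall_density": self.overall_density,
            "pct_clustered": self.pct_clustered,
            "points_per_cluster": self.points_per_cluster,
            "cluster_radius_nm": self.cluster_radius_nm,
            "cluster_model": self.cluster_model,
            "axial_range_nm": self.axial_range_nm,
        }


@dataclass(frozen=True)
class ViabilityResult:
    """Derived quantities behind the scenario filter."""

    clusters_per_um2: float
    density_inside: float
    density_outside: float
    density_ratio: float
    viable: bool


def enumerate_scenarios(
    densities,
    pcts,
    points_per_cluster,
    radii_nm,
    cluster_model: str = "uniform-disc",
    axial_range_nm: float = 0.0,
) -> list[ClusterScenario]:
    """Cartesian product of per-parameter value lists.

    Order is deterministic: lexicographic in the argument order
    (density, pct, points-per-cluster, radius).
    """
    ranges = {
        "densities": list(densities),
        "pcts": list(pcts),
        "points_per_cluster": list(points_per_cluster),
        "radii_nm": list(radii_nm),
    }
    for name, values in ranges.items():
        if not values:
            raise ValueError(f"parameter range {name!r} is empty")
    return [
        ClusterScenario(
            overall_density=d,
            pct_clustered=p,
            points_per_cluster=ppc,
            cluster_radius_nm=r,
            cluster_model=cluster_model,
            axial_range_nm=axial_range_nm,
        )
        for d, p, ppc, r in itertools.product(
            ranges["densities"], ranges["pcts"], ranges["points_per_cluster"], ranges["radii_nm"]
        )
    ]


def assess_viability(scenario: ClusterScenario, cell: CellShape) -> ViabilityResult:
    """Apply the scenario filter.

    A scenario is viable when it yields 1-5 clusters per µm² (inclusive)
    and the point density inside clusters is between 1.5x and 100x the
    density outside (inclusive).  Density inside = points per cluster /
    area of one cluster (π r²); density outside = non-clustered point
    count / (cell area − summed cluster area).
    """
    area_um2 = cell.area_um2
    n_total = round_half_up(scenario.overall_density * area_um2)
    n_clustered = round_half_up(n_total * scenario.pct_clustered / 100.0)
    n_clusters = math.ceil(n_clustered / scenario.points_per_cluster) if n_clustered else 0

    clusters_per_um2 = (
        scenario.overall_density * (scenario.pct_clustered / 100.0) / scenario.points_per_cluster
    )
    r_um = scenario.cluster_radius_nm / NM_PER_UM
    cluster_area_um2 = math.pi * r_um**2
    total_cluster_area = n_clusters * cluster_area_um2
    if total_cluster_area >= area_um2:
        raise ValueError(
            f"degenerate scenario: total cluster area {total_cluster_area:.1f} µm² "
            f">= cell area {area_um2:.1f} µm²"
        )

    density_inside = scenario.points_per_cluster / cluster_area_um2
    n_outside = n_total - n_clustered
    density_outside = n_outside / (area_um2 - total_cluster_area)
    density_ratio = density_inside / density_outside if density_outside > 0 else math.inf

    viable = (1.0 <= clusters_per_um2 <= 5.0) and (1.5 <= density_ratio <= 100.0)
    return ViabilityResult(
        clusters_per_um2=clusters_per_um2,
        density_inside=density_inside,
        density_outside=density_outside,
        density_ratio=density_ratio,
        viable=viable,
    )


# Default training grid.  Points-per-cluster values stay at or below the
# widest model input window (1000); the grid is filtered by
# assess_viability before any field is simulated.
DEFAULT_GRID: dict = {
    "densities": [50, 100, 200, 300, 400, 500],
    "pcts": [10, 20, 30, 40, 50, 60, 70, 80, 90],
    "points_per_cluster": [5, 10, 20, 50, 100],
    "radii_nm": [10, 20, 30, 40, 50, 60, 70, 80, 90, 100],
}


def default_training_grid(
    cell: CellShape,
    cluster_model: str = "uniform-disc",
    axial_range_nm: float = 0.0,
    grid: dict | None = None,
) -> list[ClusterScenario]:
    """Enumerate the default grid and keep only viable scenarios."""
    g = dict(DEFAULT_GRID if grid is None else grid)
    scenarios = enumerate_scenarios(
        g["densities"],
        g["pcts"],
        g["points_per_cluster"],
        g["radii_nm"],
        cluster_model=cluster_model,
        axial_range_nm=axial_range_nm,
    )
    viable = []
    for s in scenarios:
        try:
            if assess_viability(s, cell).viable:
                viable.append(s)
        except ValueError:
            # clusters would not fit the cell at all: not viable
            continue
    return viable
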