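"""Irregular cell-like field boundaries.

Simulated fields confine points inside a "cell" outline reminiscent of a
T-cell immune synapse flattened against a coverslip under TIRF
illumination: roughly circular overall, with uneven, protruding edges.
The outline is a star-shaped polygon obtained by radially perturbing a
circle and lightly smoothing the radii.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

__all__ = ["CellShape", "generate_cell_shape"]

NM_PER_UM = 1000.0


@dataclass(frozen=True)
class CellShape:
    """Closed, simple polygon bounding a simulated field.

    ``vertices`` are in nm, closed (first vertex repeated last);
    ``area_um2`` is the enclosed area in µm².
    """

    vertices: np.ndarray
    area_um2: float

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_nm2(self) -> float:
        return self.area_um2 * NM_PER_UM**2


def generate_cell_shape(
    seed: int,
    mean_diameter_um: float = 10.0,
    irregularity: float = 0.25,
    n_vertices: int = 64,
) -> CellShape:
    """Build a star-shaped cell outline by radial perturbation of a circle.

    Radius multipliers are drawn uniformly in ``[1 - irregularity,
    1 + irregularity]`` at ``n_vertices`` equally spaced angles, then
    smoothed with a circular 3-vertex moving average so neighbouring
    protrusions blend into each other.  Deterministic for a fixed seed.

    Parameters
    ----------
    seed:
        RNG seed; the same seed always yields the same polygon.
    mean_diameter_um:
        Diameter of the unperturbed circle, µm.
    irregularity:
        Fractional radial perturbation amplitude, in ``[0, 1]``.
    n_vertices:
        Number of boundary vertices (>= 8).
    """
    if mean_diameter_um <= 0:
        raise ValueError(f"mean_diameter_um must be positive, got {mean_diameter_um}")
    if not 0.0 <= irregularity <= 1.0:
        raise ValueError(f"irregularity must lie in [0, 1], got {irregularity}")
    if n_vertices < 8:
        raise ValueError(f"need at least 8 vertices, got {n_vertices}")

    rng = np.random.default_rng(seed)
    base_r = 0.5 * mean_diameter_um * NM_PER_UM
    multipliers = rng.uniform(1.0 - irregularity, 1.0 + irregularity, size=n_vertices)
    # circular moving average keeps the outline star-shaped (one radius per
    # angle), so the polygon cannot self-intersect
    smoothed = (np.roll(multipliers, 1) + multipliers + np.roll(multipliers, -1)) / 3.0
    angles = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    radii = base_r * smoothed
    xy = np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    closed = np.vstack([xy, xy[:1]])
    area_um2 = Polygon(closed).area / NM_PER_UM**2
    return CellShape(vertices=closed, area_um2=area_um2)
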