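import numpy as np
import pytest

from smlmclust import CellShape, ClusterScenario, generate_cell_shape


@pytest.fixture(scope="session")
def square_cell_100um2() -> CellShape:
    """A 10 x 10 µm square cell: exact area for arithmetic checks."""
    side = 10_000.0  # nm
    verts = np.array([[0, 0], [side, 0], [side, side], [0, side], [0, 0]], dtype=float)
    return CellShape(vertices=verts, area_um2=100.0)


@pytest.fixture(scope="session")
def default_cell() -> CellShape:
    return generate_cell_shape(seed=11)


@pytest.fixture
def reference_scenario() -> ClusterScenario:
    """100 points/µm², 50% clustered, 10 points per cluster, radius 30 nm."""
    return ClusterScenario(
        overall_density=100, pct_clustered=50, points_per_cluster=10, cluster_radius_nm=30
    )
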