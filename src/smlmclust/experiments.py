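"""Benchmark experiments: train-and-evaluate runs on the simulation grid.

These functions reproduce the package's reference experiments end to
end: enumerate the viable scenario grid, simulate one field per
scenario inside the default cell geometry, featurize a random subset of
points per field, assemble balanced train/validation/test pools, train
a preset classifier and report held-out metrics.  They are also the
backbone of the reproducibility script shipped in ``scripts/``.
"""

from __future__ import annotations

import numpy as np

from .features import FeatureMatrix, apply_representation, build_training_pool, knn_distances
from .geometry import generate_cell_shape
from .models import Metrics, TrainConfig, TrainedModel, evaluate, model_preset, train
from .scenarios import default_training_grid
from .segment import build_all_shapes, segment, summarize
from .simulate import simulate_field

__all__ = ["grid_classification_experiment", "cluster_recovery_experiment"]


def simulate_grid_datasets(
    seed: int,
    k: int,
    cluster_model: str = "uniform-disc",
    axial_range_nm: float = 0.0,
    rows_per_class_per_field: int = 150,
    representation: str = "normalized-distance",
    max_scenarios: int | None = None,
) -> list[tuple[FeatureMatrix, object]]:
    """Simulate one field per viable grid scenario and featurize a
    per-field random subset of points (both classes).

    Features are stored as float32: at k = 1000 the pooled matrices
    would otherwise dominate memory with no effect on the classifier.
    """
    rng = np.random.default_rng(seed)
    cell = generate_cell_shape(seed=seed)
    grid = default_training_grid(cell, cluster_model=cluster_model, axial_range_nm=axial_range_nm)
    if max_scenarios is not None and len(grid) > max_scenarios:
        keep = sorted(rng.choice(len(grid), size=max_scenarios, replace=False))
        grid = [grid[i] for i in keep]
    datasets = []
    for scenario in grid:
        table, truth = simulate_field(scenario, cell, seed=int(rng.integers(2**31)))
        if table.n <= k:
            continue
        picks = []
        for is_clustered in (False, True):
            idx = np.flatnonzero((truth.label >= 1) == is_clustered)
            take = min(len(idx), rows_per_class_per_field)
            if take:
                picks.append(rng.choice(idx, size=take, replace=False))
        fm = knn_distances(table, k, query_index=np.concatenate(picks))
        fm = apply_representation(fm, representation)
        fm.values = fm.values.astype(np.float32)
        datasets.append((fm, truth))
    return datasets


def grid_classification_experiment(
    preset: str,
    seed: int,
    n_train: int,
    n_val: int,
    n_test: int,
    cluster_model: str = "uniform-disc",
    axial_range_nm: float = 0.0,
    rows_per_class_per_field: int = 150,
    max_scenarios: int | None = None,
    config: TrainConfig | None = None,
) -> tuple[TrainedModel, Metrics]:
    """Train a preset on balanced pools drawn from the viable grid and
    return the model plus its held-out test metrics."""
    spec = model_preset(preset)
    datasets = simulate_grid_datasets(
        seed=seed,
        k=spec.input_k,
        cluster_model=cluster_model,
        axial_range_nm=axial_range_nm,
        rows_per_class_per_field=rows_per_class_per_field,
        max_scenarios=max_scenarios,
    )
    pools = build_training_pool(
        datasets, n_train, n_val, n_test, balance=True, seed=seed, binary=True
    )
    model = train(spec, pools[0], pools[1], config or TrainConfig(seed=seed))
    return model, evaluate(model, pools[2])


def cluster_recovery_experiment(
    seed: int,
    n_fields: int = 10,
    overall_density: float = 100.0,
    pct_clustered: float = 50.0,
    points_per_cluster: int = 10,
    cluster_radius_nm: float = 40.0,
    min_cluster_size: int = 3,
) -> dict:
    """Segment simulated fields with ground-truth labels and measure how
    well the reported clusters reproduce the generative scenario.

    Returns the median recovered points-per-cluster and the median
    cluster extent (per-cluster maximum member distance to the cluster
    centroid), pooled over fields.
    """
    from .scenarios import ClusterScenario

    rng = np.random.default_rng(seed)
    cell = generate_cell_shape(seed=seed)
    scenario = ClusterScenario(
        overall_density, pct_clustered, points_per_cluster, cluster_radius_nm
    )
    counts, extents, stats_list = [], [], []
    for _ in range(n_fields):
        table, truth = simulate_field(
            scenario, cell, seed=int(rng.integers(2**31)), allow_unviable=True
        )
        out = segment(
            table, (truth.label >= 1).astype(int), min_cluster_size=min_cluster_size
        )
        shapes = build_all_shapes(table, out)
        stats_list.append(summarize(out, shapes, analysis_area_um2=cell.area_um2))
        for members in out.clusters.values():
            pts = table.coords[members, :2]
            centroid = pts.mean(axis=0)
            counts.append(len(members))
            extents.append(np.linalg.norm(pts - centroid, axis=1).max())
    return {
        "median_points_per_cluster": float(np.median(counts)),
        "median_cluster_extent_nm": float(np.median(extents)),
        "n_clusters_total": len(counts),
        "per_field_stats": stats_list,
    }
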