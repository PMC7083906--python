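# smlmclust

Neural-network cluster analysis for single-molecule localization
microscopy (SMLM) point data.

SMLM techniques (PALM, dSTORM, GSD, PAINT) produce a list of emitter
coordinates rather than a pixel image, and a central question for such
data is which points belong to clusters and what those clusters look
like. Classical spatial statistics (Ripley's K, Getis & Franklin's
local point-pattern analysis, DBSCAN, pair-correlation) need
user-chosen scales or thresholds that rarely transfer between images.
`smlmclust` instead treats per-point cluster membership as a supervised
classification problem:

1. **Simulate** ground-truth fields: points confined to an irregular
   "cell-like" polygon (mimicking a T-cell synapse imaged under TIRF),
   distributed by a *clustering scenario* — overall density ρ (points/µm²),
   percentage of points in clusters p, points per cluster n, and maximum
   distance R of a clustered point from its cluster seed. Scenario grids
   are filtered to "viable" conditions: 1–5 clusters/µm² and an
   inside/outside density ratio between 1.5× and 100×.
2. **Featurize** each point as the monotonic sequence of Euclidean
   distances to its k nearest neighbors, d₁ ≤ d₂ ≤ … ≤ d_k (the model's
   *input window*), by default normalized per point by d_k.
3. **Classify** every point as clustered / not clustered with a small
   sequential neural network trained on balanced pools of labelled
   feature rows. Presets cover a four-layer dense network with k = 100
   (`XPILJZ`), a 12-layer conv/LSTM stack with k = 100 (`07VEJJ`) or
   k = 1000 (`87B144`), the dense arrangement with k = 1000 on 3D
   distances (`GAXJPR`), and a 3-class variant that also recognises
   fiber-like structures (`3TXKFS`).
4. **Segment** clustered points into discrete clusters by walking each
   point's neighbors in increasing distance and chaining through
   clustered ones (union–find merging), then build each cluster's
   outline as a union of discs of radius proportional to the cluster's
   mean nearest-neighbor distance, eroded inward by half that distance.
   Per-field statistics report cluster density, percent of points
   clustered, and median/IQR of per-cluster point counts and areas.

The networks run on a compact numpy engine included in the package
(dense, 1-D convolution, max-pool, dropout and LSTM layers; Adam with
softmax cross-entropy; gradients verified against finite differences in
the test suite). No GPU or deep-learning framework is required.

## Worked example

```python
import smlmclust as sc
from smlmclust.segment import build_all_shapes

# a 10 µm cell-like field: 100 points/µm², half in 10-point clusters of 30 nm radius
cell = sc.generate_cell_shape(seed=1)
scenario = sc.ClusterScenario(
    overall_density=100, pct_clustered=50, points_per_cluster=10, cluster_radius_nm=30
)
print("viable:", sc.assess_viability(scenario, cell).viable)

table, truth = sc.simulate_field(scenario, cell, seed=1)
print(f"simulated {table.n} points in a {cell.area_um2:.1f} um2 cell")

# segment with the known labels and measure the clusters
assignment = sc.segment(table, (truth.label >= 1).astype(int), min_cluster_size=3)
shapes = build_all_shapes(table, assignment)
stats = sc.summarize(assignment, shapes, analysis_area_um2=cell.area_um2)
print(f"{stats.clusters_per_um2:.2f} clusters per um2, "
      f"{stats.pct_points_clustered:.1f}% of points clustered")
print(f"median points per cluster: {stats.median_points_per_cluster:.0f}, "
      f"median cluster area: {stats.median_cluster_area_nm2:.0f} nm2")
```

prints

```
viable: True
simulated 8041 points in a 80.4 um2 cell
4.29 clusters per um2, 49.9% of points clustered
median points per cluster: 10, median cluster area: 814 nm2
```

The scenario asked for 5 clusters/µm² of 10 points each; segmentation
of the truth-labelled field recovers the per-cluster point count
exactly and a slightly lower cluster density because nearby clusters
occasionally touch and merge, and the final under-filled cluster of a
field falls below the 3-point reporting floor.

To train a classifier instead of using ground-truth labels, see
`smlmclust.experiments.grid_classification_experiment`, which runs the
whole simulate → featurize → pool → train → evaluate chain on the
viable scenario grid, or drive the staged pipeline from the shell:

```sh
smlmclust simulate  --config scenarios.yaml --out run/ --seed 1
smlmclust featurize --in run/ --k 100
smlmclust train     --spec XPILJZ --features run/ --out run/model --seed 1
smlmclust classify  --model run/model --in run/
smlmclust segment   --in run/ --min-size 3
smlmclust report    --in run/ --out run/report.csv
```

Every stage writes files the next stage consumes (localization CSVs,
`.knn` feature containers, model directories with JSON sidecars,
annotated CSVs, WKT outlines), so stages can be re-run, swapped or
batch-applied to a directory of fields independently. Experimental
localization tables in the ThunderSTORM CSV dialect (`"x [nm]"`,
`"y [nm]"`, optional `"z [nm]"`; pixel units converted via the dialect's
pixel size) are read directly.

## Layout

- `smlmclust.geometry` / `smlmclust.scenarios` / `smlmclust.simulate` —
  cell shapes, scenario grids and viability, field simulation
- `smlmclust.features` — k-NN distance featurization and pool assembly
- `smlmclust.nn` / `smlmclust.models` — the network engine, presets,
  training, evaluation, cross-validation, classification
- `smlmclust.segment` — cluster chaining, disc-union shapes, statistics
- `smlmclust.io` / `smlmclust.pipeline` / `smlmclust.cli` — formats,
  staged batch pipeline, command line
- `docs/methods.md` — models, defaults and numerical choices in detail
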