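# Methods

## Field simulation

A simulated field confines points to a "cell-like" polygon meant to
reproduce the gross morphology of a T-cell synapse flattened against a
coverslip: roughly circular with uneven, protruding edges. The outline
is a star polygon built by drawing radius multipliers uniformly in
[1 − irregularity, 1 + irregularity] at equally spaced angles and
smoothing them with a circular 3-vertex moving average. Defaults: mean
diameter 10 µm, irregularity 0.25, 64 vertices. Because every angle has
one radius, the polygon is star-shaped and cannot self-intersect; the
smoothing keeps radii inside the raw sampling bounds (averages of
in-range values stay in range).

A clustering scenario is the tuple (overall density ρ in points/µm²,
percent clustered p, points per cluster n, cluster radius R in nm) plus
a cluster model. Counts are exact: round(ρ × cell area) points total
(half-up rounding), round(total × p/100) of them clustered, clusters of
n points each with the final cluster under-filled to hit the exact
clustered total. Cluster seeds are placed uniformly inside the cell by
rejection sampling; seeds may fall arbitrarily close to each other and
to the boundary (no minimum separation), and every generated point must
lie inside the cell polygon (and, in 3D, inside the axial range) —
points falling outside are redrawn, and a seed whose surroundings
cannot accommodate its cluster is re-placed, with a bounded retry
budget before a simulation error is raised.

Intra-cluster point distributions:

- **uniform-disc** — uniform over the disc of radius R (the reference
  model; point-to-seed distances follow the r² law).
- **gaussian** — isotropic normal with σ = R/2 truncated at 2σ, so
  ~95% of the untruncated mass lies within the hard-edge radius used by
  the disc model; chosen for comparability between the two models.
- **ring** — area-uniform over the annulus with inner radius 0.5 R.
- **fiber** — points spread arc-length-uniformly along a random-walk
  polyline (length 2 µm, step 100 nm, turning angle bounded at ±30°)
  with lateral normal jitter of σ = 20 nm; values chosen to look
  filament-like at SMLM scale. Fiber members carry class label 2 so the
  same fields serve the 3-class model.
- **sphere-3d** — uniform inside a ball of radius R; all z values
  (clustered and background) are confined to [0, 500 nm] by default,
  mimicking the axial capture range of astigmatic 3D SMLM.

Background (non-clustered) points are completely spatially random (CSR)
inside the cell. The simulator does **not** emulate fluorophore
photophysics (re-blinking, multiple detections), localization
uncertainty, or drift; the classifier therefore learns geometry only,
and performance numbers on simulated data say nothing about how well
upstream reconstruction artifacts are tolerated in real data.

### Viability filter

A scenario is *viable* when it would yield between 1 and 5 clusters per
µm² (inclusive) and a point density inside clusters between 1.5× and
100× the outside density (inclusive). Density inside = n / (πR²);
density outside = non-clustered points / (cell area − summed cluster
area). Scenarios with p = 100 have no outside points, giving an
infinite ratio, and are not viable. The default training grid is
ρ ∈ {50, 100, 200, 300, 400, 500}/µm², p ∈ {10, …, 90 step 10},
n ∈ {5, 10, 20, 50, 100}, R ∈ {10, …, 100 step 10} nm; under the
default 10 µm cell 683 of the 2700 combinations survive the filter.

## Featurization

The model input for a point is the sorted sequence of Euclidean
distances to its k nearest neighbors, computed with an exact k-d tree
(2D or 3D per the table). Three representations are available: raw
distances (nm), consecutive differences, and the default per-row
normalization by the k-th distance. Normalization was chosen as the
default because it makes the input invariant to the absolute density
scale of a field, leaving only the *shape* of the distance profile,
which is the clustering signature. Points need k neighbors: tables with
n ≤ k are rejected rather than padded, since padding semantics would be
arbitrary.

Training pools draw feature rows from all simulated fields, sampled
without replacement, class-balanced on request (class counts per split
differ by at most 1), disjoint across train/validation/test, and
deterministic per seed. In the reference experiments a random subset of
rows is featurized per field (both classes) rather than every point — a
compute and memory choice that leaves the pool statistics unchanged.

## Classifiers

The classifier presets are expressed on a small numpy sequential-network
engine written for this package (dense, 1-D convolution with valid
padding, non-overlapping max-pooling, dropout, LSTM with forget-gate
bias 1, softmax output). Backward passes are analytic and checked
against central finite differences in the test suite; all randomness
(initialization, shuffling, dropout) derives from one seed, making
training runs reproducible in single-threaded execution.

Layer counts include the input layer. Published topologies fix the
layer *kinds* only, so widths and rates below are this package's
defaults, configurable through `ModelSpec`:

- `XPILJZ` (k = 100, 4 layers): dense(128, relu) → dense(64, relu) →
  2-way softmax.
- `07VEJJ` (k = 100, 12 layers): conv1d(32, width 5) → maxpool(2) →
  dropout(0.25) → conv1d(64, 5) → maxpool(2) → dropout(0.25) →
  lstm(64, sequences) → lstm(32) → dropout(0.25) → dense(32) →
  2-way softmax.
- `87B144`: as `07VEJJ` with k = 1000.
- `GAXJPR` (k = 1000, 4 layers): the `XPILJZ` arrangement, intended for
  3D distance features.
- `3TXKFS` (k = 1000, 3 layers): dense(128, relu) → 3-way softmax
  (not clustered / round cluster / fiber).

Training uses Adam (learning rate 10⁻³), softmax cross-entropy, batch
256, at most 50 epochs with early stopping on validation accuracy
(patience 5) and restoration of the best-epoch weights — standard,
stable defaults at this scale. Binary hard labels threshold the
clustered-class score at 0.5 with ties going to "clustered"; the
threshold is configurable because segmentation quality depends on it.
Evaluation reports accuracy, macro-averaged precision/recall/F1 and the
confusion matrix; cross-validation is stratified k-fold.

## Segmentation and cluster shapes

Each clustered point walks its neighbors in increasing-distance order
(ties broken by point id), pulling every clustered neighbor into its
group and stopping at the first non-clustered neighbor; groups sharing
a member are merged by union–find. The walk is capped at the model's
input window (default 100 neighbors): a point whose entire window is
clustered contributes all of it, mirroring the classifier's own reach.
A consequence worth knowing: two distinct clusters with *no*
non-clustered point anywhere between them chain together; in practice
viable scenarios always have background (p < 100), which stops the
walk. Clusters smaller than `min_cluster_size` (default 3 — singletons
and pairs are geometrically degenerate for shape building) are demoted
to unclustered.

A cluster's outline is the union of discs centred on its members with
radius 1.0 × the cluster's mean nearest-neighbor distance (computed
among members only), eroded inward by 0.5 × that distance. Both factors
are configurable; dilate-then-partially-erode closes the shape without
fusing neighboring clusters. Singletons fall back to a 20 nm disc
radius. If erosion annihilates the shape, the un-eroded union is
reported and flagged; erosion that fragments a shape keeps all parts
under the same cluster with areas summed, also flagged. Discs are
polygonal approximations (64 segments per quarter-circle), so areas are
exact to ~10⁻⁴ relative; an independent rasterization oracle in the
tests bounds the construction error at 2%. 3D fields are segmented on
3D distances, but shapes and areas are reported on the xy projection.

Per-field statistics: clusters/µm² (against a caller-supplied analysis
area — the package does not guess whether the relevant area is the cell
hull or a wider field of view), percent of points in reported clusters,
and median/IQR of per-cluster point counts and areas, following the
convention of reporting per-cell medians.

## Reference experiments and problem sizes

`smlmclust.experiments.grid_classification_experiment` is the canonical
end-to-end run: one simulated field per viable scenario of the default
grid (683 fields), a capped random subset of rows featurized per field,
balanced pools, training, held-out evaluation. The shipped scales are
50k/10k/10k pool rows for the 2D dense model and 100k/20k/20k for the
3D model — sizes chosen so a full run completes in minutes on one CPU
while keeping split proportions of larger-scale practice. Features are
held as float32 (at k = 1000 the pooled matrices would otherwise
dominate memory; the classifier is insensitive to the difference).

`cluster_recovery_experiment` closes the loop on segmentation: fields
with 10-point, 40 nm clusters are segmented under ground-truth labels
and the recovered median points-per-cluster and median cluster extent
(maximum member distance to the cluster centroid) are compared with the
generative parameters.

## Known limitations

- The simulator's clusters are geometric idealizations; none of the
  photophysical artifacts of real SMLM are modelled, so accuracy on
  simulated data is an upper bound for unpre-processed real data.
- The 12-layer conv/LSTM presets train correctly but slowly on pure
  numpy; the shipped experiments use the dense presets, and the LSTM
  stack is exercised at a smaller scale in the tests.
- Exceeding a model's input window hides large clusters: a cluster of
  more than k points is seen by the model as a mixture of smaller ones.
- Scenario grids near the viability boundaries (density ratio ≈ 1.5)
  are intrinsically hard; per-point accuracy there is well below the
  grid-average.
- The normalized-coordinate input variant (feeding neighbor xy offsets
  instead of distances) is deliberately not implemented.
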