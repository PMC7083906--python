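"""Nearest-neighbor distance featurization.

Each point's model input is the monotonic sequence of Euclidean
distances to its k nearest neighbors (the model's "input window").
Alternative representations are the consecutive-distance differences and
the per-row normalized sequence (each row divided by its own k-th
distance), the default fed to the classifiers: normalization makes the
input invariant to the absolute density scale of the field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .simulate import GroundTruth
from .tables import LocalizationTable

__all__ = [
    "FeatureMatrix",
    "LabeledPool",
    "knn_distances",
    "to_differences",
    "normalize",
    "build_training_pool",
]

REPRESENTATIONS = ("distance", "difference", "normalized-distance")


@dataclass
class FeatureMatrix:
    """n x k array of per-point neighbor-distance features (nm).

    ``point_index`` maps each row back to its source-table row, so
    featurizing a subset of a field keeps provenance.
    """

    values: np.ndarray
    representation: str = "distance"
    point_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.dtype.kind != "f":
            self.values = self.values.astype(float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be a 2-D array")
        if self.representation not in REPRESENTATIONS:
            raise ValueError(
                f"unknown representation {self.representation!r}; "
                f"expected one of {REPRESENTATIONS}"
            )
        if self.point_index is None:
            self.point_index = np.arange(self.values.shape[0])
        else:
            self.point_index = np.asarray(self.point_index, dtype=int)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class LabeledPool:
    """Feature rows plus matching class labels for one data split."""

    features: np.ndarray
    labels: np.ndarray
    split: str = "train"

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features)
        if self.features.dtype.kind != "f":
            self.features = self.features.astype(float)
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != len(self.labels):
            raise ValueError("features and labels must align 1:1")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def k(self) -> int:
        return self.features.shape[1]


def knn_distances(
    table: LocalizationTable, k: int, query_index: np.ndarray | None = None
) -> FeatureMatrix:
    """Sorted distances from each point to its k nearest other points.

    Uses an exact spatial index; 2D or 3D per the table.  ``query_index``
    restricts the rows computed (all points still serve as neighbors).
    Requires n >= k + 1 so every point has k neighbors besides itself.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if table.n <= k:
        raise ValueError(
            f"insufficient points: need more than k={k} points, table has n={table.n}"
        )
    tree = cKDTree(table.coords)
    if query_index is None:
        query_index = np.arange(table.n)
    else:
        query_index = np.asarray(query_index, dtype=int)
    dists, _ = tree.query(table.coords[query_index], k=k + 1, workers=-1)
    # column 0 is the point itself at distance 0
    return FeatureMatrix(
        values=dists[:, 1:], representation="distance", point_index=query_index
    )


def to_differences(fm: FeatureMatrix) -> FeatureMatrix:
    """Consecutive-distance differences: [d1, d2-d1, ..., dk-d(k-1)].

    The cumulative sum of a difference row restores the distance row.
    """
    if fm.representation != "distance":
        raise ValueError(
            f"to_differences expects 'distance' input, got {fm.representation!r}"
        )
    out = np.diff(fm.values, axis=1, prepend=0.0)
    return FeatureMatrix(
        values=out, representation="difference", point_index=fm.point_index
    )


def normalize(fm: FeatureMatrix) -> FeatureMatrix:
    """Divide each row by its own k-th (largest) distance.

    Output rows end in exactly 1 and lie in (0, 1]; the transform is
    invariant to global coordinate scaling.
    """
    if fm.representation != "distance":
        raise ValueError(
            f"normalize expects 'distance' input, got {fm.representation!r}"
        )
    last = fm.values[:, -1]
    if np.any(last <= 0):
        bad = int(np.argmax(last <= 0))
        raise ValueError(
            f"degenerate row {bad}: k-th neighbor distance is zero "
            "(all neighbors coincident)"
        )
    return FeatureMatrix(
        values=fm.values / last[:, None],
        representation="normalized-distance",
        point_index=fm.point_index,
    )


def apply_representation(fm: FeatureMatrix, representation: str) -> FeatureMatrix:
    """Convert a raw distance matrix to the requested representation."""
    if representation == "distance":
        return fm
    if representation == "difference":
        return to_differences(fm)
    if representation == "normalized-distance":
        return normalize(fm)
    raise ValueError(f"unknown representation {representation!r}")


def build_training_pool(
    datasets: list[tuple[FeatureMatrix, GroundTruth]],
    n_train: int,
    n_val: int,
    n_test: int,
    balance: bool = True,
    seed: int = 0,
    binary: bool = True,
) -> tuple[LabeledPool, LabeledPool, LabeledPool]:
    """Pool feature rows across fields and split into train/val/test.

    Rows from all datasets are pooled, sampled without replacement and —
    when ``balance`` is set — drawn as an even mix of the classes (class
    counts per split differ by at most 1).  Splits are pairwise disjoint
    and deterministic for a fixed seed.  With ``binary=True`` any
    clustered sub-class (e.g. fiber) collapses to label 1.
    """
    feats, labs = [], []
    for fm, truth in datasets:
        rows_labels = np.asarray(truth.label)[fm.point_index]
        feats.append(fm.values)
        labs.append(rows_labels)
    X = np.concatenate(feats, axis=0)
    y = np.concatenate(labs, axis=0)
    if binary:
        y = (y >= 1).astype(int)

    rng = np.random.default_rng(seed)
    sizes = {"train": n_train, "validation": n_val, "test": n_test}
    classes = np.unique(y)

    if balance:
        n_classes = len(classes)
        per_class_need = {}
        for split, size in sizes.items():
            base, rem = divmod(size, n_classes)
            # distribute the remainder over the lowest class labels
            per_class_need[split] = {
                c: base + (1 if i < rem else 0) for i, c in enumerate(classes)
            }
        # shuffled index pool per class, consumed in order across splits
        class_pools = {}
        for c in classes:
            idx = np.flatnonzero(y == c)
            need = sum(per_class_need[s][c] for s in sizes)
            if len(idx) < need:
                raise ValueError(
                    f"insufficient rows of class {c}: need {need}, have {len(idx)}"
                )
            class_pools[c] = rng.permutation(idx)
        out = []
        cursors = {c: 0 for c in classes}
        for split, size in sizes.items():
            take = []
            for c in classes:
                m = per_class_need[split][c]
                start = cursors[c]
                take.append(class_pools[c][start : start + m])
                cursors[c] = start + m
            sel = rng.permutation(np.concatenate(take))
            out.append(LabeledPool(features=X[sel], labels=y[sel], split=split))
        return tuple(out)  # type: ignore[return-value]

    total = n_train + n_val + n_test
    if len(y) < total:
        raise ValueError(f"insufficient rows: need {total}, have {len(y)}")
    sel = rng.permutation(len(y))[:total]
    bounds = np.cumsum([n_train, n_val])
    parts = np.split(sel, bounds)
    return tuple(
        LabeledPool(features=X[p], labels=y[p], split=s)
        for p, s in zip(parts, sizes)
    )  # type: ignore[return-value]
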