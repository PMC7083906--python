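"""Batch pipeline: discrete stages wired by files.

Each stage reads the previous stage's output from disk and writes its
own, so any stage can be re-run or swapped independently and a directory
of fields can be processed unattended.  Stage compatibility (e.g. a
model's input window versus a feature file's k) is checked from the JSON
sidecars before any heavy compute.
"""

from __future__ import annotations

import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .features import apply_representation, build_training_pool, knn_distances
from .geometry import generate_cell_shape
from .models import TrainConfig, TrainedModel, classify, evaluate, model_preset, train
from .scenarios import DEFAULT_GRID, ClusterScenario, default_training_grid
from .segment import build_all_shapes, segment
from .simulate import simulate_field
from .tables import LocalizationTable

__all__ = ["run_pipeline"]


def _log(msg: str) -> None:
    print(f"[smlmclust] {msg}", file=sys.stderr)


def stage_simulate(
    out_dir: Path,
    seed: int,
    n_fields: int = 1,
    grid: dict | None = None,
    scenario: dict | None = None,
    cell: dict | None = None,
    max_scenarios: int | None = None,
) -> list[Path]:
    """Simulate fields and write CSV + sidecar per field.

    Either a single ``scenario`` dict or a parameter ``grid`` (filtered
    for viability) drives the run; ``n_fields`` fields are drawn per
    scenario with consecutive sub-seeds.
    """
    out_dir.mkdir(parents=True, exist_ok=True)
    cell_cfg = {"mean_diameter_um": 10.0, "irregularity": 0.25, "n_vertices": 64}
    cell_cfg.update(cell or {})
    shape = generate_cell_shape(seed=seed, **cell_cfg)
    if scenario is not None:
        scenarios = [ClusterScenario(**scenario)]
    else:
        scenarios = default_training_grid(shape, grid=grid or DEFAULT_GRID)
        if max_scenarios is not None and len(scenarios) > max_scenarios:
            rng = np.random.default_rng(seed)
            keep = rng.choice(len(scenarios), size=max_scenarios, replace=False)
            scenarios = [scenarios[i] for i in sorted(keep)]
    written = []
    t0 = time.perf_counter()
    for si, sc in enumerate(scenarios):
        for rep in range(n_fields):
            field_seed = seed + 1000 * si + rep + 1
            table, truth = simulate_field(sc, shape, seed=field_seed, allow_unviable=True)
            stem = out_dir / f"field_s{si:04d}_r{rep:02d}"
            csv_path = stem.with_suffix(".csv")
            io.write_localizations(
                csv_path, table, label=truth.label, true_cluster_id=truth.true_cluster_id
            )
            io.write_sidecar(
                stem.with_suffix(".json"),
                {
                    "stage": "simulate",
                    "seed": field_seed,
                    "scenario": sc.to_dict(),
                    "cell_area_um2": shape.area_um2,
                    "cell_vertices_nm": shape.vertices,
                },
            )
            written.append(csv_path)
    _log(f"simulate: {len(written)} field(s) in {time.perf_counter() - t0:.1f}s")
    return written


def stage_featurize(
    inputs: list[Path],
    k: int,
    representation: str = "normalized-distance",
    out_dir: Path | None = None,
) -> list[Path]:
    """Featurize each localization CSV into a .knn container."""
    written = []
    t0 = time.perf_counter()
    for path in inputs:
        table = io.read_localizations(path)
        fm = apply_representation(knn_distances(table, k), representation)
        out = (out_dir or path.parent) / (path.stem + ".knn")
        io.write_features(out, fm, source=path)
        io.write_sidecar(
            out.with_suffix(".knn.json"),
            {
                "stage": "featurize",
                "k": k,
                "representation": representation,
                "source": str(path),
                "source_sha256": io.sha256_file(path),
            },
        )
        written.append(out)
    _log(f"featurize: {len(written)} file(s), k={k}, in {time.perf_counter() - t0:.1f}s")
    return written


def _load_labelled_features(feature_paths: list[Path]):
    """Pair each .knn file with the labels of its source CSV."""
    from .simulate import GroundTruth

    datasets = []
    for fpath in feature_paths:
        fm = io.read_features(fpath)
        csv_path = fpath.with_suffix(".csv")
        df = pd.read_csv(csv_path)
        if "label" not in df.columns:
            raise ValueError(f"{csv_path}: no ground-truth 'label' column")
        truth = GroundTruth(
            label=df["label"].to_numpy(int),
            true_cluster_id=df.get(
                "true_cluster_id", pd.Series(np.zeros(len(df)))
            ).to_numpy(int),
            seed_positions=np.empty((0, 2)),
        )
        datasets.append((fm, truth))
    return datasets


def stage_train(
    feature_paths: list[Path],
    spec_name: str,
    out_dir: Path,
    seed: int,
    n_train: int,
    n_val: int,
    n_test: int,
    train_config: dict | None = None,
) -> Path:
    """Pool labelled features, train a preset, persist model + metrics."""
    spec = model_preset(spec_name)
    datasets = _load_labelled_features(feature_paths)
    ks = {fm.k for fm, _ in datasets}
    if ks != {spec.input_k}:
        raise ValueError(
            f"feature k {sorted(ks)} incompatible with model input_k={spec.input_k}"
        )
    pools = build_training_pool(
        datasets, n_train, n_val, n_test, balance=True, seed=seed,
        binary=spec.n_classes == 2,
    )
    cfg = TrainConfig(seed=seed, **(train_config or {}))
    t0 = time.perf_counter()
    model = train(spec, pools[0], pools[1], cfg)
    metrics = evaluate(model, pools[2])
    _log(
        f"train: {spec_name} acc={metrics.accuracy:.4f} f1={metrics.f1:.4f} "
        f"in {time.perf_counter() - t0:.1f}s"
    )
    out_dir.mkdir(parents=True, exist_ok=True)
    model.save(out_dir)
    (out_dir / "metrics.json").write_text(
        json.dumps({**metrics.to_dict(), "history": model.history}, indent=2)
    )
    return out_dir


def stage_classify(
    feature_paths: list[Path],
    model_dir: Path,
    threshold: float = 0.5,
    out_dir: Path | None = None,
) -> list[Path]:
    """Label every point of each field with a trained model."""
    # pre-flight: compare sidecar k with every feature header before compute
    sidecar = json.loads((model_dir / "model.json").read_text())
    model_k = sidecar["spec"]["input_k"]
    for fpath in feature_paths:
        header = io.read_feature_header(fpath)
        if header["k"] != model_k:
            raise ValueError(
                f"pre-flight: model {model_dir} expects k={model_k} but "
                f"{fpath} holds k={header['k']}"
            )
    model = TrainedModel.load(model_dir)
    written = []
    for fpath in feature_paths:
        fm = io.read_features(fpath)
        labels = classify(model, fm, threshold=threshold)
        csv_path = fpath.with_suffix(".csv")
        df = pd.read_csv(csv_path)
        ann = df.iloc[fm.point_index].copy()
        ann["score"] = labels.scores[:, 1] if model.spec.n_classes == 2 else labels.scores.max(axis=1)
        ann["pred_label"] = labels.label
        out = (out_dir or fpath.parent) / (fpath.stem + ".labels.csv")
        ann.to_csv(out, index=False)
        written.append(out)
    _log(f"classify: {len(written)} field(s)")
    return written


def stage_segment(
    label_paths: list[Path],
    min_cluster_size: int = 3,
    disc_factor: float = 1.0,
    erosion_factor: float = 0.5,
    out_dir: Path | None = None,
) -> list[Path]:
    """Segment labelled fields; write cluster tables and WKT outlines."""
    from shapely.geometry import Polygon

    written = []
    for path in label_paths:
        df = pd.read_csv(path)
        coord_cols = ["x [nm]", "y [nm]"] + (["z [nm]"] if "z [nm]" in df else [])
        table = LocalizationTable(coords=df[coord_cols].to_numpy(float))
        hard = df["pred_label"].to_numpy(int)
        assignment = segment(table, hard, min_cluster_size=min_cluster_size)
        shapes = build_all_shapes(
            table, assignment, disc_factor=disc_factor, erosion_factor=erosion_factor
        )
        df["cluster_id"] = assignment.cluster_id
        base = (out_dir or path.parent) / path.stem.replace(".labels", "")
        df.to_csv(f"{base}.annotated.csv", index=False)
        rows = []
        wkt_rows = []
        for cid, members in assignment.clusters.items():
            shape = shapes[cid]
            centroid = table.coords[members, :2].mean(axis=0)
            rows.append(
                {
                    "cluster_id": cid,
                    "n_points": len(members),
                    "area_nm2": shape.area_nm2,
                    "centroid_x": centroid[0],
                    "centroid_y": centroid[1],
                }
            )
            wkt = " ".join(Polygon(p).wkt for p in shape.polygons)
            wkt_rows.append(f"{cid}\t{wkt}")
        pd.DataFrame(
            rows, columns=["cluster_id", "n_points", "area_nm2", "centroid_x", "centroid_y"]
        ).to_csv(f"{base}.clusters.csv", index=False)
        Path(f"{base}.outlines.wkt").write_text("\n".join(wkt_rows) + "\n")
        written.append(Path(f"{base}.clusters.csv"))
    _log(f"segment: {len(written)} field(s)")
    return written


def stage_report(cluster_tables: list[Path], out_path: Path) -> Path:
    """Aggregate many fields into one per-field median table."""
    rows = []
    for path in cluster_tables:
        df = pd.read_csv(path)
        ann = pd.read_csv(str(path).replace(".clusters.csv", ".annotated.csv"))
        n_total = len(ann)
        n_in = int((ann["cluster_id"] > 0).sum())
        rows.append(
            {
                "field": path.stem.replace(".clusters", ""),
                "n_clusters": len(df),
                "median_points_per_cluster": df["n_points"].median() if len(df) else np.nan,
                "median_area_nm2": df["area_nm2"].median() if len(df) else np.nan,
                "pct_points_clustered": 100.0 * n_in / n_total if n_total else np.nan,
            }
        )
    out = pd.DataFrame(rows)
    out.to_csv(out_path, index=False)
    _log(f"report: {len(rows)} field(s) -> {out_path}")
    return out_path


def run_pipeline(config_path: str | Path) -> int:
    """Execute the stages a YAML/JSON config requests, in order.

    Config keys: ``stages`` (subset of simulate/featurize/train/classify/
    segment/report), ``out_dir``, ``seed``, and one optional section per
    stage with that stage's keyword arguments.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    stages = cfg.get("stages", [])
    out_dir = Path(cfg.get("out_dir", "."))
    seed = int(cfg.get("seed", 0))
    out_dir.mkdir(parents=True, exist_ok=True)

    fields: list[Path] = sorted(out_dir.glob("field_*.csv"))
    fields = [p for p in fields if ".labels" not in p.name and ".annotated" not in p.name]
    features: list[Path] = sorted(out_dir.glob("*.knn"))
    if "simulate" in stages:
        fields = stage_simulate(out_dir, seed=seed, **cfg.get("simulate", {}))
    if "featurize" in stages:
        fcfg = cfg.get("featurize", {"k": 100})
        features = stage_featurize(fields, out_dir=out_dir, **fcfg)
    if "train" in stages:
        tcfg = dict(cfg.get("train", {}))
        spec_name = tcfg.pop("spec", "XPILJZ")
        stage_train(
            features,
            spec_name,
            out_dir / "model",
            seed=seed,
            n_train=tcfg.pop("n_train", 10000),
            n_val=tcfg.pop("n_val", 2000),
            n_test=tcfg.pop("n_test", 2000),
            train_config=tcfg.pop("config", None),
        )
    labelled: list[Path] = sorted(out_dir.glob("*.labels.csv"))
    if "classify" in stages:
        ccfg = dict(cfg.get("classify", {}))
        model_dir = Path(ccfg.pop("model", out_dir / "model"))
        labelled = stage_classify(features, model_dir, out_dir=out_dir, **ccfg)
    cluster_tables: list[Path] = sorted(out_dir.glob("*.clusters.csv"))
    if "segment" in stages:
        cluster_tables = stage_segment(labelled, out_dir=out_dir, **cfg.get("segment", {}))
    if "report" in stages:
        stage_report(cluster_tables, out_dir / "report.csv")
    return 0
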