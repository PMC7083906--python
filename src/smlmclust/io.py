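"""File formats and provenance.

Localization tables are CSV in the ThunderSTORM export dialect
(``"x [nm]"``, ``"y [nm]"``, optional ``"z [nm]"``; an
``"uncertainty [nm]"`` column is tolerated but ignored) with a generic
``x,y[,z]`` fallback; coordinates stored in pixels are converted to nm
via the dialect's pixel size.  Feature matrices persist in a simple
binary container — a JSON header followed by a row-major float32 array —
so the expensive featurization stage is reusable across models.  Every
writer emits a JSON sidecar carrying the tool version, seed and upstream
file hashes.
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .tables import LocalizationTable

__all__ = [
    "TableDialect",
    "THUNDERSTORM",
    "GENERIC",
    "read_localizations",
    "write_localizations",
    "read_features",
    "write_features",
    "write_sidecar",
]

_KNN_MAGIC = b"KNNF"


@dataclass(frozen=True)
class TableDialect:
    """Column-name mapping and unit convention of a localization CSV."""

    x: str = "x [nm]"
    y: str = "y [nm]"
    z: str | None = "z [nm]"
    id: str | None = "id"
    unit: str = "nm"  # "nm" or "px"
    pixel_size_nm: float | None = None
    delimiter: str = ","

    def __post_init__(self) -> None:
        if self.unit not in ("nm", "px"):
            raise ValueError("unit must be 'nm' or 'px'")
        if self.unit == "px" and not (self.pixel_size_nm and self.pixel_size_nm > 0):
            raise ValueError("px-unit dialect needs a positive pixel_size_nm")


THUNDERSTORM = TableDialect()
GENERIC = TableDialect(x="x", y="y", z="z", id=None)


def read_localizations(
    path: str | Path, dialect: TableDialect | None = None
) -> LocalizationTable:
    """Read a localization CSV into a table with nm coordinates.

    Tries the given dialect (default ThunderSTORM), falling back to the
    generic ``x,y[,z]`` header.  Rows with non-finite coordinates are
    dropped.  Row order is preserved; point ids come from the id column
    or, absent one, from file order.
    """
    path = Path(path)
    dialects = [dialect] if dialect is not None else [THUNDERSTORM, GENERIC]
    df = pd.read_csv(path, sep=dialects[0].delimiter, float_precision="round_trip")
    chosen = None
    for d in dialects:
        if d.x in df.columns and d.y in df.columns:
            chosen = d
            break
    if chosen is None:
        raise ValueError(
            f"{path}: none of the expected coordinate columns found; "
            f"headers present: {list(df.columns)}"
        )
    cols = [chosen.x, chosen.y]
    has_z = chosen.z is not None and chosen.z in df.columns
    if has_z:
        cols.append(chosen.z)
    coords = df[cols].to_numpy(dtype=float)
    ok = np.all(np.isfinite(coords), axis=1)
    coords = coords[ok]
    if len(coords) == 0:
        raise ValueError(f"{path}: no valid localization rows")
    if chosen.unit == "px":
        coords = coords * chosen.pixel_size_nm
    if chosen.id is not None and chosen.id in df.columns:
        ids = df.loc[ok, chosen.id].to_numpy(dtype=int)
    else:
        ids = np.arange(len(coords))
    return LocalizationTable(coords=coords, point_id=ids)


def write_localizations(
    path: str | Path,
    table: LocalizationTable,
    label: np.ndarray | None = None,
    true_cluster_id: np.ndarray | None = None,
    extra: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a table as ThunderSTORM-dialect CSV (nm), optionally with
    ground-truth or annotation columns appended."""
    cols = {"id": table.point_id, "x [nm]": table.coords[:, 0], "y [nm]": table.coords[:, 1]}
    if table.dims == 3:
        cols["z [nm]"] = table.coords[:, 2]
    if label is not None:
        cols["label"] = np.asarray(label)
    if true_cluster_id is not None:
        cols["true_cluster_id"] = np.asarray(true_cluster_id)
    for name, values in (extra or {}).items():
        cols[name] = np.asarray(values)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def write_features(path: str | Path, fm: FeatureMatrix, source: str | Path | None = None) -> None:
    """Persist a feature matrix: magic, JSON header, float32 rows."""
    header = {
        "k": fm.k,
        "n": fm.n,
        "representation": fm.representation,
        "point_index": fm.point_index.tolist(),
        "source_sha256": sha256_file(source) if source else None,
    }
    blob = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(_KNN_MAGIC)
        fh.write(struct.pack("<I", len(blob)))
        fh.write(blob)
        fh.write(np.ascontiguousarray(fm.values, dtype=np.float32).tobytes())


def read_features(path: str | Path) -> FeatureMatrix:
    with open(path, "rb") as fh:
        if fh.read(4) != _KNN_MAGIC:
            raise ValueError(f"{path}: not a feature container")
        (hlen,) = struct.unpack("<I", fh.read(4))
        header = json.loads(fh.read(hlen))
        values = np.frombuffer(fh.read(), dtype=np.float32).reshape(
            header["n"], header["k"]
        )
    return FeatureMatrix(
        values=values.astype(float),
        representation=header["representation"],
        point_index=np.asarray(header["point_index"], dtype=int),
    )


def read_feature_header(path: str | Path) -> dict:
    """Header only — used for cheap pre-flight compatibility checks."""
    with open(path, "rb") as fh:
        if fh.read(4) != _KNN_MAGIC:
            raise ValueError(f"{path}: not a feature container")
        (hlen,) = struct.unpack("<I", fh.read(4))
        return json.loads(fh.read(hlen))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_sidecar(path: str | Path, payload: dict) -> None:
    """JSON sidecar next to an output file: provenance for the next stage."""
    from . import __version__

    record = {"tool": "smlmclust", "version": __version__, **payload}
    Path(path).write_text(json.dumps(record, indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
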