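"""Readers and writers for volumes, trees and metric tables.

Single home for format dialects and unit conventions:

* volumes: multi-page TIFF + YAML sidecar (``<file>.yaml``) carrying
  ``voxel_size_mm`` (required) and ``origin_mm``;
* trees: SWC (one point per line: ``id type x y z radius parent``,
  coordinates *and radius* in mm) and a lossless node-link JSON dialect;
* metrics: CSV, one row per cast, stable column order.

Lossy fields, enumerated once: SWC stores no bend/branch labels (the type
column keeps only root=1 vs other=3), so labels are recomputed from
topology on read — for trees whose labels are topology-derived (all trees
this package produces) the round trip is still exact.  JSON keeps labels
verbatim.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import json
import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import GroundTruthTree, VoxelVolume

__all__ = [
    "MetricsRow",
    "read_volume",
    "write_volume",
    "read_tree",
    "write_tree",
    "read_metrics",
    "write_metrics",
    "METRIC_COLUMNS",
]


@dataclass
class MetricsRow:
    """Per-cast morphometry record (the unit row of a cohort table)."""

    cast_id: str
    group: str  # normal | fgr
    compartment: str  # arterial | venous
    tissue_mass_g: float
    length_density_mm_per_cm3: float = np.nan
    segment_density: float = np.nan
    branch_density: float = np.nan
    tortuosity_density: float = np.nan
    tortuosity_nodes: float = np.nan
    tortuosity_segments: float = np.nan
    diameter_summary_um: float = np.nan
    decile_counts: list[int] = field(default_factory=lambda: [0] * 10)

    def __post_init__(self) -> None:
        if len(self.decile_counts) != 10:
            raise ValueError("decile_counts must have exactly 10 entries")


_DECILE_COLS = [f"decile_{i:02d}" for i in range(1, 11)]
METRIC_COLUMNS = [
    "cast_id",
    "group",
    "compartment",
    "tissue_mass_g",
    "length_density_mm_per_cm3",
    "segment_density",
    "branch_density",
    "tortuosity_density",
    "tortuosity_nodes",
    "tortuosity_segments",
    "diameter_summary_um",
    *_DECILE_COLS,
]


# ---------------------------------------------------------------------------
# volumes


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".yaml")


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF plus a YAML metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path, np.asarray(volume.grid, dtype=np.float32), photometric="minisblack"
    )
    meta = {
        "voxel_size_mm": float(volume.voxel_size_mm),
        "origin_mm": [float(x) for x in volume.origin],
    }
    _sidecar(path).write_text(yaml.safe_dump(meta))


def read_volume(path: str | Path) -> VoxelVolume:
    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(
            f"metadata sidecar {side} not found; voxel_size_mm is required "
            "and is never assumed"
        )
    meta = yaml.safe_load(side.read_text()) or {}
    if "voxel_size_mm" not in meta:
        raise ValueError(f"sidecar {side} is missing required field 'voxel_size_mm'")
    vs = meta["voxel_size_mm"]
    if isinstance(vs, (list, tuple)):
        if len(set(float(v) for v in vs)) != 1:
            raise ValueError("anisotropic voxel spacing is not supported")
        vs = vs[0]
    grid = tifffile.imread(path)
    origin = np.asarray(meta.get("origin_mm", [0.0, 0.0, 0.0]), dtype=float)
    return VoxelVolume(grid, float(vs), origin)


# ---------------------------------------------------------------------------
# trees


def write_tree(tree: GroundTruthTree, path: str | Path) -> None:
    """Write a tree as SWC (``.swc``) or node-link JSON (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".swc":
        _write_swc(tree, path)
    else:
        _write_json(tree, path)


def read_tree(path: str | Path) -> GroundTruthTree:
    path = Path(path)
    if path.suffix.lower() == ".swc":
        return _read_swc(path)
    return _read_json(path)


def _write_swc(tree: GroundTruthTree, path: Path) -> None:
    lines = ["# id type x y z radius parent", "# units: mm (radius in mm)"]
    for i in range(tree.n_points):
        t = 1 if tree.parents[i] < 0 else 3
        x, y, z = tree.points[i]
        r_mm = tree.radii_um[i] / 1000.0  # SWC radius shares the coordinate unit
        lines.append(
            f"{i + 1} {t} {x:.6f} {y:.6f} {z:.6f} {r_mm:.6f} "
            f"{tree.parents[i] + 1 if tree.parents[i] >= 0 else -1}"
        )
    path.write_text("\n".join(lines) + "\n")


def _read_swc(path: Path) -> GroundTruthTree:
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"malformed SWC line: {line!r}")
        rows.append(parts)
    if not rows:
        return GroundTruthTree.empty()
    ids = np.array([int(r[0]) for r in rows])
    order = {int(i): k for k, i in enumerate(ids)}
    points = np.array([[float(r[2]), float(r[3]), float(r[4])] for r in rows])
    radii_um = np.array([float(r[5]) * 1000.0 for r in rows])  # mm -> um
    parents = np.array(
        [order[int(r[6])] if int(r[6]) != -1 else -1 for r in rows], dtype=int
    )
    if int(np.sum(parents < 0)) != 1:
        raise ValueError(
            f"SWC file must have exactly one root (parent -1), "
            f"found {int(np.sum(parents < 0))}"
        )
    tree = GroundTruthTree(
        points=points,
        radii_um=radii_um,
        parents=parents,
        labels=np.full(len(rows), "bend", dtype="U8"),
    )
    tree.relabel_from_topology()  # SWC carries no class labels (documented lossy)
    tree.validate(radius_tol_um=np.inf)
    return tree


def _write_json(tree: GroundTruthTree, path: Path) -> None:
    payload = {
        "format": "vasculocast-tree",
        "units": {"coordinates": "mm", "radii": "um"},
        "points": tree.points.tolist(),
        "radii_um": tree.radii_um.tolist(),
        "parents": tree.parents.tolist(),
        "labels": tree.labels.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def _read_json(path: Path) -> GroundTruthTree:
    payload = json.loads(Path(path).read_text())
    parents = np.asarray(payload["parents"], dtype=int)
    if len(parents) and int(np.sum(parents < 0)) != 1:
        raise ValueError("tree JSON must have exactly one root")
    tree = GroundTruthTree(
        points=np.asarray(payload["points"], dtype=float).reshape(-1, 3),
        radii_um=np.asarray(payload["radii_um"], dtype=float),
        parents=parents,
        labels=np.asarray(payload["labels"], dtype="U8"),
    )
    if tree.n_points:
        tree.validate(radius_tol_um=np.inf)
    return tree


# ---------------------------------------------------------------------------
# metrics


def write_metrics(rows: list[MetricsRow], path: str | Path) -> pd.DataFrame:
    """Write per-cast metric rows as CSV with a stable column order."""
    recs = []
    for row in rows:
        rec = asdict(row)
        dec = rec.pop("decile_counts")
        rec.update({c: int(v) for c, v in zip(_DECILE_COLS, dec)})
        recs.append(rec)
    df = pd.DataFrame(recs, columns=METRIC_COLUMNS)
    if df["cast_id"].duplicated().any():
        dupes = sorted(df.loc[df["cast_id"].duplicated(), "cast_id"].unique())
        raise ValueError(f"duplicate cast_id values: {dupes}")
    df.to_csv(path, index=False, float_format="%.10g")
    return df


def read_metrics(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in METRIC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metrics CSV missing columns: {missing}")
    return df


def metrics_to_rows(df: pd.DataFrame) -> list[MetricsRow]:
    out = []
    for _, r in df.iterrows():
        out.append(
            MetricsRow(
                cast_id=str(r["cast_id"]),
                group=str(r["group"]),
                compartment=str(r["compartment"]),
                tissue_mass_g=float(r["tissue_mass_g"]),
                length_density_mm_per_cm3=float(r["length_density_mm_per_cm3"]),
                segment_density=float(r["segment_density"]),
                branch_density=float(r["branch_density"]),
                tortuosity_density=float(r["tortuosity_density"]),
                tortuosity_nodes=float(r["tortuosity_nodes"]),
                tortuosity_segments=float(r["tortuosity_segments"]),
                diameter_summary_um=float(r["diameter_summary_um"]),
                decile_counts=[int(r[c]) for c in _DECILE_COLS],
            )
        )
    return out
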