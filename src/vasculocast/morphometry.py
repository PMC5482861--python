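"""Per-cast vessel biometry from a classified skeleton graph.

The working container is the *segment table*: one row per vessel segment
(the piece of centreline between two consecutive nodes of any class),
with its length, mean diameter and end-node classes.  All cast-level
metrics derive from it:

* length density — total segment length per cm^3 of tissue, with cast
  mass converted at 1 g = 1 cm^3;
* tortuosity — total node number (branch points + bends) minus true
  branch number, i.e. the bend count;
* numerical densities of segments, true branches and tortuosity;
* the segment diameter census over fixed diameter ranges.

Vessels below the 100 um analysis threshold are excluded (inclusive
boundary: a segment at exactly the threshold survives).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GroundTruthTree
from .skeltree import SkeletonGraph
from .volio import MetricsRow

__all__ = [
    "segment_table_from_graph",
    "segment_table_from_tree",
    "filter_by_diameter",
    "segment_counts",
    "length_density",
    "tortuosity",
    "diameter_census",
    "density_metrics",
    "DEFAULT_MIN_DIAMETER_UM",
    "DEFAULT_BIN_EDGES_UM",
]

DEFAULT_MIN_DIAMETER_UM = 100.0
#: Census ranges start at the 100-200 um bin; the last bin is open-ended so
#: counts always sum to the filtered segment count.
DEFAULT_BIN_EDGES_UM = (100, 200, 300, 400, 500, 600, 700, 800, 900, 1000, np.inf)

_COLUMNS = [
    "node1",
    "node2",
    "node1_class",
    "node2_class",
    "length_mm",
    "mean_diameter_um",
]


def _recompute_classes(df: pd.DataFrame) -> pd.DataFrame:
    """Reclassify end nodes by their degree in the (possibly filtered) table."""
    if df.empty:
        return df
    nodes = pd.concat([df["node1"], df["node2"]])
    deg = nodes.value_counts()

    def cls(n: int) -> str:
        d = deg.get(n, 0)
        return "terminal" if d <= 1 else ("bend" if d == 2 else "branch")

    df = df.copy()
    df["node1_class"] = df["node1"].map(cls)
    df["node2_class"] = df["node2"].map(cls)
    return df


def segment_table_from_graph(sg: SkeletonGraph) -> pd.DataFrame:
    """Segment table of a classified skeleton graph (one row per edge)."""
    rows = []
    for u, w, d in sg.g.edges(data=True):
        rows.append(
            {
                "node1": u,
                "node2": w,
                "node1_class": sg.g.nodes[u].get("cls", "bend"),
                "node2_class": sg.g.nodes[w].get("cls", "bend"),
                "length_mm": float(d["length_mm"]),
                "mean_diameter_um": float(d.get("mean_diameter_um", np.nan)),
            }
        )
    return pd.DataFrame(rows, columns=_COLUMNS)


def segment_table_from_tree(tree: GroundTruthTree) -> pd.DataFrame:
    """Ground-truth segment table straight from tree geometry.

    Every stored parent->child link is one segment (ground-truth trees
    keep points only at the root, branch points, bends and terminals);
    its diameter is the mean of the end-point diameters.  This is the
    oracle route: no voxels, no skeletonisation.
    """
    rows = []
    for i in range(tree.n_points):
        p = int(tree.parents[i])
        if p < 0:
            continue
        length = float(np.linalg.norm(tree.points[i] - tree.points[p]))
        rows.append(
            {
                "node1": p,
                "node2": i,
                "node1_class": str(tree.labels[p]),
                "node2_class": str(tree.labels[i]),
                "length_mm": length,
                "mean_diameter_um": float(tree.radii_um[i] + tree.radii_um[p]),
            }
        )
    df = pd.DataFrame(rows, columns=_COLUMNS)
    return _recompute_classes(df)


def filter_by_diameter(
    table: pd.DataFrame, min_diameter_um: float = DEFAULT_MIN_DIAMETER_UM
) -> pd.DataFrame:
    """Keep segments with mean diameter >= threshold (inclusive).

    End-node classes are recomputed on the surviving subgraph: a branch
    point that loses all but two incident segments becomes a bend, one
    left with a single segment becomes a terminal.
    """
    if min_diameter_um < 0:
        raise ValueError("min_diameter_um must be >= 0")
    if min_diameter_um == 0:
        return table
    kept = table[table["mean_diameter_um"] >= min_diameter_um].reset_index(drop=True)
    return _recompute_classes(kept)


def segment_counts(table: pd.DataFrame) -> dict[str, int]:
    """Node bookkeeping of a segment table.

    ``total_nodes`` counts branch points plus bends (terminals excluded),
    matching the convention that total node number is the sum of branch
    points and vessel bends.
    """
    if table.empty:
        return {
            "n_segments": 0,
            "total_nodes": 0,
            "true_branch_count": 0,
            "terminal_count": 0,
        }
    cls = pd.concat(
        [
            table[["node1", "node1_class"]].rename(
                columns={"node1": "node", "node1_class": "cls"}
            ),
            table[["node2", "node2_class"]].rename(
                columns={"node2": "node", "node2_class": "cls"}
            ),
        ]
    ).drop_duplicates("node")
    counts = cls["cls"].value_counts()
    n_branch = int(counts.get("branch", 0))
    n_bend = int(counts.get("bend", 0))
    return {
        "n_segments": int(len(table)),
        "total_nodes": n_branch + n_bend,
        "true_branch_count": n_branch,
        "terminal_count": int(counts.get("terminal", 0)),
    }


def length_density(table: pd.DataFrame, tissue_mass_g: float) -> float:
    """Total centreline length per cm^3 of tissue (1 g = 1 cm^3)."""
    if not tissue_mass_g > 0:
        raise ValueError("tissue mass must be positive")
    return float(table["length_mm"].sum()) / tissue_mass_g


def tortuosity(table: pd.DataFrame) -> int:
    """Total node number minus true branch number (= bend count)."""
    c = segment_counts(table)
    t = c["total_nodes"] - c["true_branch_count"]
    if t < 0:
        raise RuntimeError(
            "negative tortuosity: node class bookkeeping is inconsistent"
        )
    return int(t)


def diameter_census(
    table: pd.DataFrame, bin_edges_um: tuple[float, ...] = DEFAULT_BIN_EDGES_UM
) -> np.ndarray:
    """Segment counts per diameter range, half-open bins [e_i, e_{i+1})."""
    edges = np.asarray(bin_edges_um, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    d = table["mean_diameter_um"].to_numpy()
    d = d[(d >= edges[0])]
    idx = np.searchsorted(edges, d, side="right") - 1
    idx = idx[idx < len(edges) - 1]
    return np.bincount(idx, minlength=len(edges) - 1)


def density_metrics(
    table: pd.DataFrame,
    tissue_mass_g: float,
    cast_id: str = "cast",
    group: str = "normal",
    compartment: str = "arterial",
    decile_counts: list[int] | None = None,
) -> MetricsRow:
    """Assemble the per-cast metrics row from a (filtered) segment table.

    Both published tortuosity phrasings are reported: ``tortuosity_nodes``
    (total node number minus true branch number) and
    ``tortuosity_segments`` (segment count minus true branch number);
    ``tortuosity_density`` normalises the node-based one.
    """
    if not tissue_mass_g > 0:
        raise ValueError("tissue mass must be positive")
    c = segment_counts(table)
    tort_nodes = tortuosity(table)
    tort_segments = c["n_segments"] - c["true_branch_count"]
    diam = table["mean_diameter_um"].to_numpy()
    return MetricsRow(
        cast_id=cast_id,
        group=group,
        compartment=compartment,
        tissue_mass_g=float(tissue_mass_g),
        length_density_mm_per_cm3=length_density(table, tissue_mass_g),
        segment_density=c["n_segments"] / tissue_mass_g,
        branch_density=c["true_branch_count"] / tissue_mass_g,
        tortuosity_density=tort_nodes / tissue_mass_g,
        tortuosity_nodes=float(tort_nodes),
        tortuosity_segments=float(tort_segments),
        diameter_summary_um=float(np.median(diam)) if len(diam) else np.nan,
        decile_counts=list(decile_counts) if decile_counts is not None else [0] * 10,
    )
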