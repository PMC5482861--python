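"""Config-driven end-to-end cast analysis.

One YAML config describes everything: which synthetic cohorts to generate
(or which volumes to load, with their cast masses), every segmentation /
skeleton / morphometry parameter, and which group comparisons to run.
``run`` executes cohort generation or ingestion -> segmentation ->
skeletonisation -> node classification -> diameter filter -> per-cast
metrics -> tree-map deciles -> group statistics, writes ``metrics.csv``
and ``comparisons.json``, and is fully deterministic given config + seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import groupstats, morphometry, skeltree, treemap, vesselseg, volio
from .core import GroundTruthTree, VoxelVolume
from .synth_cast import generate_cohort, get_preset

__all__ = ["CohortResult", "DEFAULT_CONFIG", "run", "measure_cast", "load_config"]

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohorts": [
        {"preset": "normal_arterial", "n_casts": 6},
        {"preset": "normal_venous", "n_casts": 6},
        {"preset": "fgr_arterial", "n_casts": 6},
        {"preset": "fgr_venous", "n_casts": 6},
    ],
    "segmentation": {"method": "otsu", "fixed_value": None, "min_component_voxels": 5},
    "subvolume": {"shape": [800, 500, 300], "max_count": 9},
    "skeleton": {
        "bend_angle_deg": 30.0,
        "min_bend_spacing_voxels": 5,
        "prune_spur_factor": 1.5,
        "tip_extension": True,
    },
    "morphometry": {
        "min_diameter_um": 100.0,
        "bin_edges_um": list(morphometry.DEFAULT_BIN_EDGES_UM[:-1]),
    },
    "comparisons": [
        ["normal_arterial", "fgr_arterial"],
        ["normal_venous", "fgr_venous"],
        ["normal_arterial", "normal_venous"],
        ["fgr_arterial", "fgr_venous"],
    ],
    "alpha": 0.05,
    "save_trees": False,
}


@dataclass
class CohortResult:
    """Product of one pipeline run."""

    metrics: pd.DataFrame
    comparisons: dict[str, list[groupstats.ComparisonResult]]
    outdir: Path | None = None
    config: dict = field(default_factory=dict)

    def comparisons_dict(self) -> dict:
        return {
            key: [r.to_dict() for r in results]
            for key, results in self.comparisons.items()
        }


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML config over the packaged defaults (shallow per section)."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path is None:
        return cfg
    user = yaml.safe_load(Path(path).read_text()) or {}
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def measure_cast(
    volume: VoxelVolume,
    tissue_mass_g: float,
    config: dict | None = None,
    cast_id: str = "cast",
    group: str = "normal",
    compartment: str = "arterial",
) -> tuple[volio.MetricsRow, treemap.RootedTree | None]:
    """Full measurement chain for one cast volume.

    Segmentation -> skeleton -> spatial graph -> radii -> spur pruning ->
    bend classification -> tip-erosion compensation -> >=100 um filter ->
    metrics row with tree-map decile counts.
    """
    cfg = config or json.loads(json.dumps(DEFAULT_CONFIG))
    seg, skl, mor = cfg["segmentation"], cfg["skeleton"], cfg["morphometry"]

    mask = vesselseg.threshold_volume(volume, seg["method"], seg.get("fixed_value"))
    mask = vesselseg.remove_small_components(mask, seg["min_component_voxels"])
    skel = skeltree.skeletonize(mask)
    sg = skeltree.skeleton_to_graph(skel, volume.voxel_size_mm, volume.origin)
    if sg.g.number_of_nodes() == 0:
        raise RuntimeError(f"cast {cast_id}: no skeleton voxels after segmentation")
    rv = skeltree.estimate_radius(mask, skel, volume.voxel_size_mm)
    skeltree.attach_radii(sg, rv, mask=mask, skeleton=skel)
    skeltree.remove_skeleton_loops(sg)
    skeltree.prune_spurs(sg, skl["prune_spur_factor"])
    skeltree.classify_nodes(sg, skl["bend_angle_deg"], skl["min_bend_spacing_voxels"])
    if skl.get("tip_extension", True):
        skeltree.extend_tip_lengths(sg)

    table = morphometry.segment_table_from_graph(sg)
    table = morphometry.filter_by_diameter(table, mor["min_diameter_um"])

    deciles = None
    rooted = None
    if len(table):
        # decile tree map from the surviving graph
        keep_nodes = set(table["node1"]) | set(table["node2"])
        sub = skeltree.SkeletonGraph(
            sg.g.subgraph(keep_nodes).copy(), sg.voxel_size_mm, sg.origin, sg.junction_voxels
        )
        rooted = treemap.root_tree(sub)
        deciles = rooted.decile_counts().tolist()
    row = morphometry.density_metrics(
        table,
        tissue_mass_g,
        cast_id=cast_id,
        group=group,
        compartment=compartment,
        decile_counts=deciles,
    )
    return row, rooted


def run(
    config: str | Path | dict | None = None,
    outdir: str | Path | None = None,
    seed: int | None = None,
) -> CohortResult:
    """Run the whole pipeline described by a config.

    ``seed`` overrides the config seed.  Synthetic cohorts are generated
    from the named presets; alternatively a cohort entry may list real
    ``volumes`` (paths, with required per-cast ``tissue_mass_g``).
    Returns the cohort metric table and all group comparisons; writes
    ``metrics.csv``, ``comparisons.json`` and ``run.log`` when ``outdir``
    is given.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    if not cfg.get("cohorts"):
        raise ValueError("config lists no cohorts; nothing to analyse")
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(out / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        logging.getLogger("vasculocast").addHandler(handler)
        logging.getLogger("vasculocast").setLevel(logging.INFO)
    log.info("pipeline config: %s", json.dumps(cfg, default=str))

    rows: list[volio.MetricsRow] = []
    tables: dict[str, pd.DataFrame] = {}
    for cohort in cfg["cohorts"]:
        name = cohort.get("preset")
        if name is not None:
            preset = get_preset(name)
            if cohort.get("overrides"):
                from dataclasses import replace as _replace

                preset = _replace(preset, **cohort["overrides"])
            n = int(cohort.get("n_casts", 6))
            if n < 1:
                raise ValueError(f"cohort {name}: n_casts must be >= 1")
            t0 = time.time()
            casts = generate_cohort(preset, n, seed=int(cfg["seed"]))
            log.info("cohort %s: generated %d casts in %.1f s", name, n, time.time() - t0)
            mass = preset.tissue_volume_cm3  # 1 g = 1 cm^3
            group, compartment = preset.group, preset.compartment
            volumes: list[tuple[str, VoxelVolume, float]] = [
                (f"{name}_{i + 1:02d}", vol, mass) for i, (vol, _) in enumerate(casts)
            ]
        else:
            name = cohort["name"]
            group = cohort.get("group", "normal")
            compartment = cohort.get("compartment", "arterial")
            volumes = []
            for i, entry in enumerate(cohort.get("volumes", [])):
                if "tissue_mass_g" not in entry:
                    raise ValueError(
                        f"cohort {name}, volume {entry.get('path')}: tissue_mass_g is required"
                    )
                volumes.append(
                    (
                        entry.get("cast_id", f"{name}_{i + 1:02d}"),
                        volio.read_volume(entry["path"]),
                        float(entry["tissue_mass_g"]),
                    )
                )
            if not volumes:
                raise ValueError(f"cohort {name} lists no volumes")
        cohort_rows = []
        for cast_id, vol, mass in volumes:
            t0 = time.time()
            try:
                row, _ = measure_cast(vol, mass, cfg, cast_id, group, compartment)
            except Exception as err:  # annotate the failing cast
                raise RuntimeError(f"cast {cast_id} failed: {err}") from err
            log.info("cast %s analysed in %.1f s", cast_id, time.time() - t0)
            cohort_rows.append(row)
        rows.extend(cohort_rows)
        tables[name] = pd.DataFrame(
            [
                {
                    **{
                        c: getattr(r, c)
                        for c in volio.METRIC_COLUMNS
                        if not c.startswith("decile_")
                    },
                    **{f"decile_{i + 1:02d}": r.decile_counts[i] for i in range(10)},
                }
                for r in cohort_rows
            ]
        )

    metrics_df = volio.write_metrics(rows, out / "metrics.csv") if out else _rows_to_df(rows)

    comparisons: dict[str, list[groupstats.ComparisonResult]] = {}
    for a, b in cfg.get("comparisons", []):
        if a in tables and b in tables:
            comparisons[f"{a}_vs_{b}"] = groupstats.compare_cohorts(
                tables[a], tables[b], decile_comparison=True, alpha=cfg.get("alpha", 0.05)
            )
    result = CohortResult(metrics_df, comparisons, out, cfg)
    if out is not None:
        (out / "comparisons.json").write_text(
            json.dumps(result.comparisons_dict(), indent=2)
        )
    return result


def _rows_to_df(rows: list[volio.MetricsRow]) -> pd.DataFrame:
    import io

    buf = io.StringIO()
    volio.write_metrics(rows, buf)
    buf.seek(0)
    return pd.read_csv(buf)
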