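"""Shared containers for vascular-cast analysis.

Unit conventions (used across the whole package):

* spatial coordinates and lengths are millimetres (mm),
* vessel radii and diameters are micrometres (um),
* tissue volume is cm^3 with the 1 g = 1 cm^3 equivalence for cast mass,
* length density is mm of centreline per cm^3 of tissue.

Conversions happen only at I/O boundaries (:mod:`vasculocast.volio`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GroundTruthTree", "VoxelVolume", "NODE_LABELS"]

#: Valid per-node class labels of a ground-truth tree.
NODE_LABELS = ("root", "branch", "bend", "terminal")


@dataclass
class VoxelVolume:
    """An isotropically sampled 3D image with physical voxel size.

    ``grid`` is indexed ``[i, j, k]``; the world position of a voxel centre
    is ``origin + index * voxel_size_mm`` (voxel-centre convention,
    0-based indices).
    """

    grid: np.ndarray
    voxel_size_mm: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("grid must be a 3D array with positive extents")
        if not self.voxel_size_mm > 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def world(self, index: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel centre(s) ``index``."""
        return self.origin + np.asarray(index, dtype=float) * self.voxel_size_mm

    def index_of(self, position_mm: np.ndarray) -> np.ndarray:
        """Nearest voxel index of world position(s) (mm)."""
        return np.rint((np.asarray(position_mm) - self.origin) / self.voxel_size_mm).astype(int)


@dataclass
class GroundTruthTree:
    """Node-link vessel centreline geometry with per-point radii.

    The tree is stored SWC-style: ``parents[i]`` is the index of the parent
    point (-1 for the root).  Points comprise the umbilical-insertion root,
    true branch points, course-deviation (bend) points and terminals; the
    straight runs between consecutive points are the centreline edges.

    ``radii_um`` taper from the trunk towards the terminals; a point carries
    the radius of the vessel at that point, so radii are non-increasing on
    every root-to-leaf path (up to a small tolerance for jittered taper).
    """

    points: np.ndarray  # (n, 3) float, mm
    radii_um: np.ndarray  # (n,) float
    parents: np.ndarray  # (n,) int, -1 at root
    labels: np.ndarray  # (n,) unicode, subset of NODE_LABELS

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.radii_um = np.asarray(self.radii_um, dtype=float)
        self.parents = np.asarray(self.parents, dtype=int)
        self.labels = np.asarray(self.labels, dtype="U8")
        if self.n_points and self.points.shape != (self.n_points, 3):
            raise ValueError("points must have shape (n, 3)")

    # -- basic structure ---------------------------------------------------
    @property
    def n_points(self) -> int:
        return len(self.parents)

    @property
    def root_id(self) -> int:
        roots = np.flatnonzero(self.parents < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        return int(roots[0])

    def children(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {i: [] for i in range(self.n_points)}
        for i, p in enumerate(self.parents):
            if p >= 0:
                out[int(p)].append(i)
        return out

    def degrees(self) -> np.ndarray:
        """Undirected graph degree of every point."""
        deg = np.zeros(self.n_points, dtype=int)
        for i, p in enumerate(self.parents):
            if p >= 0:
                deg[i] += 1
                deg[p] += 1
        return deg

    # -- geometry ----------------------------------------------------------
    def edge_lengths_mm(self) -> np.ndarray:
        """Length of every parent->child edge, in point order (root entry 0)."""
        lengths = np.zeros(self.n_points)
        has_parent = self.parents >= 0
        idx = np.flatnonzero(has_parent)
        if len(idx):
            diff = self.points[idx] - self.points[self.parents[idx]]
            lengths[idx] = np.linalg.norm(diff, axis=1)
        return lengths

    def total_length_mm(self) -> float:
        return float(self.edge_lengths_mm().sum())

    def length_density(self, tissue_volume_cm3: float) -> float:
        """Centreline length density in mm/cm^3."""
        if not tissue_volume_cm3 > 0:
            raise ValueError("tissue volume must be positive")
        return self.total_length_mm() / tissue_volume_cm3

    # -- validation --------------------------------------------------------
    def validate(self, radius_tol_um: float = 1.0) -> None:
        """Check tree structure, labels and radius taper; raise on violation."""
        n = self.n_points
        if n == 0:
            return
        root = self.root_id  # raises unless exactly one
        # connectivity/acyclicity: every point must reach the root
        for i in range(n):
            seen = 0
            j = i
            while j != root:
                j = int(self.parents[j])
                seen += 1
                if j < 0 or seen > n:
                    raise ValueError("tree is disconnected or contains a cycle")
        if np.any(self.radii_um <= 0):
            raise ValueError("radii must be positive")
        bad = set(np.unique(self.labels)) - set(NODE_LABELS)
        if bad:
            raise ValueError(f"unknown node labels: {sorted(bad)}")
        idx = np.flatnonzero(self.parents >= 0)
        if np.any(self.radii_um[idx] > self.radii_um[self.parents[idx]] + radius_tol_um):
            raise ValueError("radii must be non-increasing from root to leaves")

    def relabel_from_topology(self) -> None:
        """Set node labels from connectivity: root / branch (>=2 children) /
        bend (1 child, has parent) / terminal (leaf)."""
        kids = self.children()
        labels = np.empty(self.n_points, dtype="U8")
        for i in range(self.n_points):
            nc = len(kids[i])
            if self.parents[i] < 0:
                labels[i] = "root"
            elif nc == 0:
                labels[i] = "terminal"
            elif nc == 1:
                labels[i] = "bend"
            else:
                labels[i] = "branch"
        self.labels = labels

    # -- counts ------------------------------------------------------------
    def count(self, label: str) -> int:
        return int(np.sum(self.labels == label))

    @classmethod
    def empty(cls) -> "GroundTruthTree":
        return cls(
            points=np.zeros((0, 3)),
            radii_um=np.zeros(0),
            parents=np.zeros(0, dtype=int),
            labels=np.zeros(0, dtype="U8"),
        )
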