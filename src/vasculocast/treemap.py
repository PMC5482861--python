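"""Rooted branch-level tree maps and decile binning.

Mirrors the tree-map analysis: the vessel graph is rooted at the
umbilical-insertion point, every *branch* — a maximal vessel path between
consecutive true branch points (bends do not interrupt a branch) — gets a
level (trunk = level 1, incremented at each true branch point, root
excluded), and the levels are grouped into ten contiguous deciles whose
branch counts are compared between cohorts.

Anastomotic loops are resolved here: rooting takes a breadth-first
spanning tree, which drops, within each cycle, the edge farthest from the
root in traversal order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .core import GroundTruthTree
from .skeltree import SkeletonGraph

__all__ = ["RootedTree", "root_tree", "rooted_tree_from_ground_truth", "branch_levels", "decile_bins"]

log = logging.getLogger(__name__)


@dataclass
class RootedTree:
    """Branch-level bookkeeping of a rooted vessel tree.

    ``branches`` maps branch id -> (parent branch id or -1, level >= 1).
    ``dropped_edges`` counts loop edges removed during rooting.
    """

    root_id: int
    branches: dict[int, tuple[int, int]] = field(default_factory=dict)
    dropped_edges: int = 0

    @property
    def n_branches(self) -> int:
        return len(self.branches)

    @property
    def n_levels(self) -> int:
        return max((lvl for _, lvl in self.branches.values()), default=0)

    def per_level_counts(self) -> np.ndarray:
        """Branch counts indexed by level-1 (root excluded by construction)."""
        counts = np.zeros(self.n_levels, dtype=int)
        for _, lvl in self.branches.values():
            counts[lvl - 1] += 1
        return counts

    def decile_counts(self) -> np.ndarray:
        return decile_bins(self.per_level_counts())


def root_tree(sg: SkeletonGraph, root_hint: np.ndarray | None = None) -> RootedTree:
    """Root a classified skeleton graph at the umbilical insertion.

    The root is the node nearest ``root_hint`` if given, else the
    largest-radius terminal (the cut umbilical trunk end).  If the graph
    has several connected components the largest (by node count) is
    analysed and the rest are logged.  A breadth-first spanning tree
    breaks anastomotic loops; bends never increment the branch level.
    """
    g = sg.g
    if g.number_of_nodes() == 0:
        raise ValueError("cannot root an empty graph")
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    if len(comps) > 1:
        log.info("graph has %d components; analysing the largest (%d nodes)", len(comps), len(comps[0]))
    gg = g.subgraph(comps[0])

    if root_hint is not None:
        hint = np.asarray(root_hint, dtype=float)
        root = min(gg.nodes, key=lambda n: float(np.sum((gg.nodes[n]["pos"] - hint) ** 2)))
    else:
        terminals = [n for n in gg.nodes if gg.degree(n) == 1]
        pool = terminals if terminals else list(gg.nodes)
        root = max(pool, key=lambda n: gg.nodes[n].get("radius_um", 0.0))

    # BFS spanning tree over the multigraph
    parent: dict[int, int] = {root: -1}
    order = [root]
    for u in order:
        for w in gg.neighbors(u):
            if w not in parent:
                parent[w] = u
                order.append(w)
    n_tree_edges = len(parent) - 1
    dropped = gg.number_of_edges() - n_tree_edges

    # branch levels: walk from the root; crossing a true branch point
    # starts new branches one level deeper, bends pass through
    children: dict[int, list[int]] = {n: [] for n in parent}
    for n, p in parent.items():
        if p != -1:
            children[p].append(n)

    def is_branch_point(n: int) -> bool:
        return gg.nodes[n].get("cls") == "branch" or len(children[n]) + (n != root) >= 3

    branches: dict[int, tuple[int, int]] = {}
    next_branch = 0
    # stack entries: (node, current branch id, level, parent branch id)
    stack: list[tuple[int, int, int]] = []
    for c in children[root]:
        branches[next_branch] = (-1, 1)
        stack.append((c, next_branch, 1))
        next_branch += 1
    while stack:
        node, br, lvl = stack.pop()
        kids = children[node]
        if not kids:
            continue
        if is_branch_point(node):
            for c in kids:
                branches[next_branch] = (br, lvl + 1)
                stack.append((c, next_branch, lvl + 1))
                next_branch += 1
        else:  # bend or pass-through: same branch continues
            for c in kids:
                stack.append((c, br, lvl))
    return RootedTree(root_id=int(root), branches=branches, dropped_edges=int(dropped))


def rooted_tree_from_ground_truth(tree: GroundTruthTree) -> RootedTree:
    """Branch levels straight from ground-truth geometry (oracle route)."""
    kids = tree.children()
    root = tree.root_id
    branches: dict[int, tuple[int, int]] = {}
    next_branch = 0
    stack: list[tuple[int, int, int]] = []
    for c in kids[root]:
        branches[next_branch] = (-1, 1)
        stack.append((c, next_branch, 1))
        next_branch += 1
    while stack:
        node, br, lvl = stack.pop()
        cs = kids[node]
        if not cs:
            continue
        if len(cs) >= 2:  # true branch point
            for c in cs:
                branches[next_branch] = (br, lvl + 1)
                stack.append((c, next_branch, lvl + 1))
                next_branch += 1
        else:
            stack.append((cs[0], br, lvl))
    return RootedTree(root_id=int(root), branches=branches)


def branch_levels(tree: RootedTree) -> np.ndarray:
    """Branch counts per level (level 1 = trunk, root excluded)."""
    return tree.per_level_counts()


def decile_bins(per_level_counts: np.ndarray, n_groups: int = 10) -> np.ndarray:
    """Group branch levels into ten contiguous bins and sum their counts.

    With L levels, each group spans ``L // 10`` levels and the remainder
    ``L % 10`` is distributed one extra level to the first groups (an
    80-level tree gives ten groups of exactly eight levels).  Fewer than
    ten levels leaves trailing groups at zero.  Total branch count is
    conserved for every L >= 1.
    """
    counts = np.asarray(per_level_counts, dtype=int)
    L = len(counts)
    if L < 1:
        raise ValueError("need at least one branch level")
    if L < n_groups:
        log.warning("only %d branch levels for %d groups; trailing groups are zero", L, n_groups)
    base, rem = divmod(L, n_groups)
    out = np.zeros(n_groups, dtype=int)
    start = 0
    for i in range(n_groups):
        span = base + (1 if i < rem else 0)
        out[i] = counts[start : start + span].sum()
        start += span
    return out
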