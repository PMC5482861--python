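"""Skeletonisation, graph extraction, radii and node classification."""

import networkx as nx
import numpy as np
import pytest

from vasculocast import skeltree as sk
from vasculocast.core import GroundTruthTree
from vasculocast.synth_cast import voxelize

from conftest import capsule_oracle


def line_mask(shape, points):
    m = np.zeros(shape, dtype=bool)
    for p in points:
        m[tuple(p)] = True
    return m


def graph_of(mask, voxel_size=1.0):
    skel = sk.skeletonize(mask)
    return sk.skeleton_to_graph(skel, voxel_size)


class TestSkeletonize:
    def test_thin_line_is_fixed_point(self):
        pts = [(5, 5, k) for k in range(2, 13)]
        mask = line_mask((11, 11, 16), pts)
        np.testing.assert_array_equal(sk.skeletonize(mask), mask)

    def test_empty_mask(self):
        assert not sk.skeletonize(np.zeros((5, 5, 5), bool)).any()

    def test_cylinder_axis_recovery(self):
        """Skeleton of a straight cylinder: length within 5% of the axis,
        every interior skeleton voxel within 1 voxel of the axis."""
        a, b, r = np.array([8.0, 15.0, 15.0]), np.array([108.0, 15.0, 15.0]), 5.0
        mask = capsule_oracle((120, 31, 31), a, b, r)
        skel = sk.skeletonize(mask)
        g = sk.skeleton_to_graph(skel, 1.0)
        assert g.total_length_mm() == pytest.approx(100.0, rel=0.05)
        vox = np.argwhere(skel)
        interior = vox[(vox[:, 0] > 15) & (vox[:, 0] < 100)]
        off_axis = np.linalg.norm(interior[:, 1:] - np.array([15, 15]), axis=1)
        assert off_axis.max() <= 1.0

    def test_disjoint_tubes_stay_disjoint(self):
        a = capsule_oracle((60, 30, 30), [5, 8, 8], [55, 8, 8], 3)
        b = capsule_oracle((60, 30, 30), [5, 22, 22], [55, 22, 22], 3)
        g = graph_of(a | b)
        assert nx.number_connected_components(g.g) == 2


class TestSkeletonToGraph:
    def test_straight_path_length(self):
        pts = [(5, 5, k) for k in range(2, 13)]  # 11 voxels
        g = graph_of(line_mask((11, 11, 16), pts), voxel_size=0.1)
        assert g.g.number_of_nodes() == 2
        assert g.g.number_of_edges() == 1
        assert g.total_length_mm() == pytest.approx(1.0)

    def test_y_shape(self):
        pts = (
            [(5, 5, k) for k in range(1, 8)]
            + [(5, 5 + i, 7 + i) for i in range(1, 6)]
            + [(5, 5 - i, 7 + i) for i in range(1, 6)]
        )
        g = graph_of(line_mask((11, 13, 16), pts))
        degs = sorted(d for _, d in g.g.degree())
        assert degs == [1, 1, 1, 3]
        assert g.g.number_of_edges() == 3

    def test_diagonal_length(self):
        """In-plane 45-degree diagonal of 11 voxels measures 10*sqrt(2)*0.1."""
        pts = [(5, 2 + k, 2 + k) for k in range(11)]
        g = graph_of(line_mask((11, 16, 16), pts), voxel_size=0.1)
        assert g.total_length_mm() == pytest.approx(10 * np.sqrt(2) * 0.1)

    def test_edge_length_bounds_endpoint_distance(self):
        tree = GroundTruthTree(
            points=[[0, 0, 0], [4, 0, 0], [4, 3, 2]],
            radii_um=[400, 400, 300],
            parents=[-1, 0, 1],
            labels=["root", "bend", "terminal"],
        )
        vol = voxelize(tree, 0.1)
        skel = sk.skeletonize(vol.grid > 0.5)
        g = sk.skeleton_to_graph(skel, 0.1, vol.origin)
        for u, w, d in g.g.edges(data=True):
            gap = np.linalg.norm(g.g.nodes[u]["pos"] - g.g.nodes[w]["pos"])
            assert d["length_mm"] >= gap - 1e-9


class TestEstimateRadius:
    def test_cylinder_on_axis_radius(self):
        a, b, r = np.array([8.0, 15.0, 15.0]), np.array([108.0, 15.0, 15.0]), 5.0
        mask = capsule_oracle((120, 31, 31), a, b, r)
        skel = sk.skeletonize(mask)
        rv = sk.estimate_radius(mask, skel, 0.1)
        vox = np.argwhere(skel)
        interior = vox[(vox[:, 0] > 15) & (vox[:, 0] < 100)]
        vals = rv[interior[:, 0], interior[:, 1], interior[:, 2]]
        assert np.abs(vals.mean() - 500.0) < 50.0  # within half a voxel

    def test_single_voxel_line_reports_half_voxel(self):
        pts = [(5, 5, k) for k in range(2, 13)]
        mask = line_mask((11, 11, 16), pts)
        rv = sk.estimate_radius(mask, mask, 0.1)
        assert rv[5, 5, 7] == pytest.approx(50.0)  # half of 0.1 mm, in um

    def test_skeleton_outside_mask_rejected(self):
        mask = np.zeros((5, 5, 5), bool)
        skel = np.zeros((5, 5, 5), bool)
        skel[2, 2, 2] = True
        with pytest.raises(ValueError):
            sk.estimate_radius(mask, skel, 0.1)

    def test_tapered_tube_monotone_radii(self):
        """Radius estimates decrease along a linearly tapering tube."""
        tree = GroundTruthTree(
            points=[[0, 1.5, 1.5], [20, 1.5, 1.5]],
            radii_um=[1200.0, 300.0],
            parents=[-1, 0],
            labels=["root", "terminal"],
        )
        vol = voxelize(tree, 0.1)
        mask = vol.grid > 0.5
        skel = sk.skeletonize(mask)
        rv = sk.estimate_radius(mask, skel, 0.1)
        vox = np.argwhere(skel)
        order = np.argsort(vox[:, 0])
        vals = rv[tuple(vox[order].T)]
        x = vox[order][:, 0]
        keep = (x > x.min() + 5) & (x < x.max() - 5)
        slope = np.polyfit(x[keep], vals[keep], 1)[0]
        assert slope < 0
        # monotone within a one-voxel tolerance
        assert np.all(np.diff(vals[keep]) <= 100.0 + 1e-9)


def _path_graph(path, voxel_size=1.0, radius_um=100.0):
    """SkeletonGraph with one edge along an arbitrary float polyline."""
    g = nx.MultiGraph()
    path = np.asarray(path, dtype=float)
    for i, vox in enumerate((path[0], path[-1])):
        g.add_node(i, vox=vox, pos=vox * voxel_size, radius_um=radius_um)
    steps = np.linalg.norm(np.diff(path, axis=0), axis=1) * voxel_size
    g.add_edge(0, 1, path=path, steps_mm=steps, length_mm=float(steps.sum()))
    return sk.SkeletonGraph(g, voxel_size)


def _turn(path, angle_deg, n=12):
    """Extend a polyline with n unit steps after turning by angle_deg."""
    path = list(path)
    d = np.array(path[-1]) - np.array(path[-2])
    d = d / np.linalg.norm(d)
    ang = np.radians(angle_deg)
    rot = np.array(
        [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
    )
    d = rot @ d
    for _ in range(n):
        path.append(np.array(path[-1]) + d)
    return path


class TestClassifyNodes:
    def test_straight_path_has_no_bends(self):
        path = [(0, 0, 0)] + [(k, 0, 0) for k in range(1, 15)]
        sg = _path_graph(path)
        sk.classify_nodes(sg, 30.0, 5)
        assert sg.node_count("bend") == 0
        assert sg.node_count("terminal") == 2

    def test_right_angle_corner_yields_one_bend(self):
        path = [(k, 0, 0) for k in range(13)] + [(12, k, 0) for k in range(1, 13)]
        sg = _path_graph(path)
        sk.classify_nodes(sg, 30.0, 5)
        assert sg.node_count("bend") == 1
        bend = [n for n, d in sg.g.nodes(data=True) if d["cls"] == "bend"][0]
        np.testing.assert_allclose(sg.g.nodes[bend]["pos"], [12.0, 0.0, 0.0], atol=1.5)

    def test_zigzag_counts_only_sharp_corners(self):
        """Corners of 10/40/70 degrees against a 30-degree threshold: 2 bends."""
        path = [np.array([k, 0.0, 0.0]) for k in range(13)]
        for ang in (10.0, 40.0, 70.0):
            path = _turn(path, ang)
        sg = _path_graph(path)
        sk.classify_nodes(sg, 30.0, 5)
        assert sg.node_count("bend") == 2

    def test_bend_insertion_conserves_length(self):
        rng = np.random.default_rng(0)
        path = [np.array([0.0, 0.0, 0.0])]
        d = np.array([1.0, 0.0, 0.0])
        for _ in range(60):
            if rng.random() < 0.15:
                ang = np.radians(rng.uniform(-80, 80))
                rot = np.array(
                    [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
                )
                d = rot @ d
            path.append(path[-1] + d)
        sg = _path_graph(path)
        before = sg.total_length_mm()
        sk.classify_nodes(sg, 30.0, 5)
        assert sg.total_length_mm() == pytest.approx(before, abs=1e-9)

    def test_invalid_threshold_rejected(self):
        sg = _path_graph([(0, 0, 0), (1, 0, 0), (2, 0, 0)])
        with pytest.raises(ValueError):
            sk.classify_nodes(sg, 190.0)

    def test_class_partition_is_exhaustive(self, small_cast_preset):
        from vasculocast.synth_cast import sample_tree

        tree = sample_tree(small_cast_preset, seed=1)
        vol = voxelize(tree, 0.09)
        mask = vol.grid > 0.5
        skel = sk.skeletonize(mask)
        sg = sk.skeleton_to_graph(skel, 0.09, vol.origin)
        rv = sk.estimate_radius(mask, skel, 0.09)
        sk.attach_radii(sg, rv, mask=mask, skeleton=skel)
        sk.classify_nodes(sg)
        classes = [d["cls"] for _, d in sg.g.nodes(data=True)]
        assert set(classes) <= {"branch", "bend", "terminal"}
        n_deg1 = sum(1 for n in sg.g.nodes if sg.g.degree(n) <= 1)
        assert classes.count("terminal") == n_deg1


class TestPruneAndLoops:
    def test_spur_removed_real_branch_kept(self):
        # T shape: long bar with a 2-voxel stub; stub shorter than 1.5 r
        pts = [(5, 5, k) for k in range(1, 30)] + [(5 + i, 5, 15) for i in (1, 2)]
        mask = line_mask((11, 11, 31), pts)
        skel = sk.skeletonize(mask)
        sg = sk.skeleton_to_graph(skel, 1.0)
        for n in sg.g.nodes:
            sg.g.nodes[n]["radius_um"] = 2000.0  # radius 2 voxels
        sk.prune_spurs(sg, 1.5)
        assert sg.g.number_of_edges() == 1  # stub gone, bar contracted back
        assert sg.total_length_mm() == pytest.approx(28.0, abs=1.5)

    def test_small_loop_collapsed_large_loop_kept(self):
        g = nx.MultiGraph()
        # two nodes joined by a short duplicate pair (artefact) and by a
        # long arch (anastomosis-scale)
        p_short1 = np.array([[0, 0, 0], [2, 0.5, 0], [4, 0, 0]], float)
        p_short2 = np.array([[0, 0, 0], [2, -0.5, 0], [4, 0, 0]], float)
        p_arch = np.array([[0, 0, 0], [2, 30, 0], [4, 0, 0]], float)
        g.add_node(0, vox=p_short1[0], pos=p_short1[0], radius_um=1000.0)
        g.add_node(1, vox=p_short1[-1], pos=p_short1[-1], radius_um=1000.0)
        # feeder stubs keep the junctions at degree >= 3, as in real graphs
        for n, stub_end in ((0, [-10.0, 0, 0]), (1, [14.0, 0, 0])):
            e = np.array([g.nodes[n]["vox"], stub_end])
            steps = np.linalg.norm(np.diff(e, axis=0), axis=1)
            g.add_node(2 + n, vox=e[-1], pos=e[-1], radius_um=1000.0)
            g.add_edge(n, 2 + n, path=e, steps_mm=steps, length_mm=float(steps.sum()),
                       mean_diameter_um=2000.0)
        for p in (p_short1, p_short2, p_arch):
            steps = np.linalg.norm(np.diff(p, axis=0), axis=1)
            g.add_edge(0, 1, path=p, steps_mm=steps, length_mm=float(steps.sum()),
                       mean_diameter_um=2000.0)
        sg = sk.SkeletonGraph(g, 1.0)
        sk.remove_skeleton_loops(sg, scale_factor=3.0)
        lengths = sorted(d["length_mm"] for *_, d in sg.g.edges(data=True))
        assert len(lengths) == 4  # one duplicate dropped, stubs + arch kept
        assert lengths[-1] > 50  # the arch survived
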