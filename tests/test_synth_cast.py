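"""Phantom generator: geometry, calibration, determinism, voxelisation."""

from dataclasses import replace

import numpy as np
import pytest

from vasculocast.core import GroundTruthTree
from vasculocast.synth_cast import (
    TargetDensityError,
    TreePreset,
    apply_breakage,
    generate_cohort,
    get_preset,
    load_presets,
    sample_tree,
    voxelize,
)

from conftest import capsule_oracle


class TestSampleTree:
    def test_degenerate_single_segment(self, big_domain_preset):
        """No generations, no bends: one root-to-terminal segment."""
        preset = replace(
            big_domain_preset,
            n_generations=0,
            segment_length_mm=50.0,
            target_length_density_mm_per_cm3=10.0 / 1000.0,
        )
        tree = sample_tree(preset)
        assert tree.count("branch") == 0
        assert tree.count("root") == 1 and tree.count("terminal") == 1
        # endpoints = degree-1 nodes: the root and the terminal
        assert int((tree.degrees() == 1).sum()) == 2
        assert tree.total_length_mm() == pytest.approx(10.0, rel=1e-9)

    def test_full_binary_tree_combinatorics(self, big_domain_preset):
        """3 symmetric generations: 7 true branch points, 8 terminals."""
        # budget exactly covers trunk + 2 + 4 + 8 unit segments
        tree = sample_tree(big_domain_preset)
        tree.validate()
        assert tree.count("branch") == 7
        assert tree.count("terminal") == 8
        assert tree.total_length_mm() == pytest.approx(15.0, rel=1e-9)

    def test_density_exact_and_recomputable(self, big_domain_preset):
        """Reported density equals the value recomputed from the tree."""
        tree = sample_tree(big_domain_preset)
        dens = tree.length_density(big_domain_preset.tissue_volume_cm3)
        assert dens == pytest.approx(
            big_domain_preset.target_length_density_mm_per_cm3, rel=1e-9
        )

    def test_packaged_preset_hits_group_median(self):
        """normal_arterial ground truth lands on the published median."""
        preset = get_preset("normal_arterial")
        tree = sample_tree(preset, seed=0)
        dens = tree.length_density(preset.tissue_volume_cm3)
        assert dens == pytest.approx(27.29, rel=0.05)

    def test_unreachable_target_reports_achieved(self, big_domain_preset):
        preset = replace(
            big_domain_preset, n_generations=0, target_length_density_mm_per_cm3=1.0
        )
        with pytest.raises(TargetDensityError) as err:
            sample_tree(preset)
        assert 0 < err.value.achieved_mm_per_cm3 < 1.0

    def test_seeded_determinism(self, small_cast_preset):
        t1 = sample_tree(small_cast_preset, seed=5)
        t2 = sample_tree(small_cast_preset, seed=5)
        np.testing.assert_array_equal(t1.points, t2.points)
        np.testing.assert_array_equal(t1.parents, t2.parents)

    def test_taper_and_domain_invariants(self, small_cast_preset):
        tree = sample_tree(small_cast_preset, seed=2)
        tree.validate()  # single root, acyclic, radii non-increasing
        r = small_cast_preset.domain_radius_mm
        h = small_cast_preset.domain_height_mm
        assert np.all(tree.points[:, 0] ** 2 + tree.points[:, 1] ** 2 <= r**2 + 1e-6)
        assert np.all((tree.points[:, 2] >= -1e-6) & (tree.points[:, 2] <= h + 1e-6))

    def test_lumens_do_not_interpenetrate(self, small_cast_preset):
        """Distinct vessel segments never cross through each other."""
        tree = sample_tree(small_cast_preset, seed=4)
        pts, radii = tree.points, tree.radii_um / 1000.0
        child = np.flatnonzero(tree.parents >= 0)
        # sample each edge midpoints and check distance to non-adjacent edges
        for i in child[:: max(1, len(child) // 60)]:
            a, b = pts[tree.parents[i]], pts[i]
            mid = (a + b) / 2.0
            r_i = radii[i]
            for j in child:
                if j == i or tree.parents[j] in (i, tree.parents[i]) or j == tree.parents[i]:
                    continue
                c, d = pts[tree.parents[j]], pts[j]
                ab = d - c
                t = np.clip(np.dot(mid - c, ab) / max(np.dot(ab, ab), 1e-12), 0, 1)
                dist = np.linalg.norm(mid - (c + t * ab))
                # allow the documented junction-ball exemption
                anchor_gap = min(
                    np.linalg.norm(mid - pts[tree.parents[j]]), np.linalg.norm(mid - pts[j])
                )
                if anchor_gap < 2.5 * (radii[j] + r_i) + 0.2:
                    continue
                assert dist > 0.5 * (r_i + radii[j])


class TestBreakage:
    def test_zero_probability_is_identity(self, y_tree):
        out = apply_breakage(y_tree, 100.0, 0.0, seed=0)
        assert out is y_tree

    def test_forced_removal_clears_subthreshold_terminals(self, small_cast_preset):
        tree = sample_tree(small_cast_preset, seed=9)
        out = apply_breakage(tree, 100.0, 1.0, seed=0)
        term_d = 2 * out.radii_um[out.labels == "terminal"]
        assert np.all(term_d >= 100.0)
        out.validate()

    def test_above_threshold_segments_untouched(self, small_cast_preset):
        tree = sample_tree(small_cast_preset, seed=9)
        out = apply_breakage(tree, 100.0, 1.0, seed=0)
        thick_before = np.sum(2 * tree.radii_um >= 100.0)
        thick_after = np.sum(2 * out.radii_um >= 100.0)
        assert thick_before == thick_after

    def test_binomial_removal_rate(self):
        """Empirical removal fraction of eligible terminals matches p."""
        # comb tree: 200 um spine with 30 fragile 95 um twigs
        n = 30
        pts, radii, parents, labels = [[0.0, 0.0, 0.0]], [100.0], [-1], ["root"]
        for i in range(n):
            spine = len(pts)
            pts.append([float(i + 1), 0.0, 0.0])
            radii.append(100.0)
            parents.append(spine - 2 if i else 0)
            labels.append("branch")
            pts.append([float(i + 1), 1.0, 0.0])
            radii.append(47.5)
            parents.append(spine)
            labels.append("terminal")
        tree = GroundTruthTree(pts, radii, parents, labels)
        tree.relabel_from_topology()
        eligible = int(
            np.sum((tree.labels == "terminal") & (2 * tree.radii_um < 100.0))
        )
        assert eligible == n
        n_rep, p = 400, 0.3
        removed = 0
        for s in range(n_rep):
            out = apply_breakage(tree, 100.0, p, seed=s)
            removed += eligible - int(
                np.sum((out.labels == "terminal") & (2 * out.radii_um < 100.0))
            )
        frac = removed / (n_rep * eligible)
        sigma = np.sqrt(p * (1 - p) / (n_rep * eligible))
        assert abs(frac - p) < 5 * sigma


class TestVoxelize:
    def test_empty_tree_all_background(self):
        vol = voxelize(GroundTruthTree.empty(), 0.1)
        assert not np.any(vol.grid > 0)

    def test_cylinder_matches_capsule_oracle(self):
        """Voxelised cylinder equals the brute-force capsule voxel set."""
        a, b, r = np.array([10.0, 15.0, 15.0]), np.array([110.0, 15.0, 15.0]), 5.0
        tree = GroundTruthTree(
            points=[a, b], radii_um=[r * 1000] * 2, parents=[-1, 0],
            labels=["root", "terminal"],
        )
        vol = voxelize(tree, 1.0)
        oracle = capsule_oracle(vol.shape, a - vol.origin, b - vol.origin, r)
        np.testing.assert_array_equal(vol.grid > 0.5, oracle)
        count = int((vol.grid > 0.5).sum())
        # capsule = cylinder + two hemispherical caps
        expected = np.pi * r**2 * 100 + 4.0 / 3.0 * np.pi * r**3
        assert count == pytest.approx(expected, rel=0.03)

    def test_subresolution_branch_renders_thin_or_vanishes(self):
        """An 80 um branch at 0.1 mm voxels is at most one voxel thick."""
        tree = GroundTruthTree(
            points=[[0, 0, 0], [3, 0, 0], [3, 0.2, 0], [3, 4, 0]],
            radii_um=[400.0, 400.0, 40.0, 40.0],
            parents=[-1, 0, 1, 2],
            labels=["root", "branch", "bend", "terminal"],
        )
        vol = voxelize(tree, 0.1)
        # voxels belonging to the thin branch: y > 0.6 mm from its axis start
        idx = np.argwhere(vol.grid > 0.5)
        pos = vol.world(idx)
        thin = pos[pos[:, 1] > 0.6]
        if len(thin):
            # every thin-branch voxel centre within half a diagonal of the axis
            d = np.sqrt((thin[:, 0] - 3.0) ** 2 + thin[:, 2] ** 2)
            assert d.max() <= 0.1 * np.sqrt(3) / 2 + 1e-9

    def test_trunk_resolution_guard(self, y_tree):
        with pytest.raises(ValueError, match="voxel size"):
            voxelize(y_tree, 0.5)  # trunk 1 mm -> 2 voxels

    def test_grid_size_guard(self, y_tree):
        with pytest.raises(ValueError, match="grid"):
            voxelize(y_tree, 0.01, max_grid_voxels=1000)


class TestCohorts:
    def test_seeded_cohorts_are_byte_identical(self, small_cast_preset):
        a = generate_cohort(small_cast_preset, 2, seed=11)
        b = generate_cohort(small_cast_preset, 2, seed=11)
        for (va, ta), (vb, tb) in zip(a, b):
            np.testing.assert_array_equal(ta.points, tb.points)
            np.testing.assert_array_equal(va.grid, vb.grid)

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            generate_cohort("normal_capillary", 2, seed=0)

    def test_large_cohort_median_converges(self, small_cast_preset):
        """Sample median of 1000 ground-truth densities within 2% of the
        group median."""
        preset = replace(small_cast_preset, density_sigma_ln=0.57)
        casts = generate_cohort(preset, 1000, seed=1, render=False)
        dens = np.array(
            [t.length_density(preset.tissue_volume_cm3) for _, t in casts]
        )
        assert np.median(dens) == pytest.approx(
            preset.target_length_density_mm_per_cm3, rel=0.02
        )

    def test_packaged_catalog(self):
        presets = load_presets()
        assert set(presets) == {
            "normal_arterial", "normal_venous", "fgr_arterial", "fgr_venous",
        }
        # calibration medians are the published group values
        assert presets["normal_arterial"].target_length_density_mm_per_cm3 == 27.29
        assert presets["normal_venous"].target_length_density_mm_per_cm3 == 13.39
        assert presets["fgr_arterial"].target_length_density_mm_per_cm3 == 14.82
        assert presets["fgr_venous"].target_length_density_mm_per_cm3 == 32.10

    def test_preset_invariants_enforced(self):
        with pytest.raises(ValueError):
            TreePreset(taper_ratio=1.4)
        with pytest.raises(ValueError):
            TreePreset(trunk_diameter_um=80.0)
        with pytest.raises(ValueError):
            TreePreset(tissue_volume_cm3=-1.0)
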