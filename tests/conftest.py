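import numpy as np
import pytest

from vasculocast.core import GroundTruthTree
from vasculocast.synth_cast import TreePreset


@pytest.fixture
def big_domain_preset():
    """Deterministic preset in a huge domain (no boundary interference)."""
    return TreePreset(
        name="unit",
        n_generations=3,
        trunk_diameter_um=1000.0,
        taper_ratio=0.8,
        taper_jitter_sd=0.0,
        segment_length_mm=1.0,
        segment_length_dispersion=0.0,
        length_diameter_ratio=0.0,
        bend_rate=0.0,
        target_length_density_mm_per_cm3=15.0 / 1000.0,
        density_sigma_ln=0.0,
        tissue_volume_cm3=1000.0,
        breakage_prob=0.0,
        rng_seed=7,
    )


@pytest.fixture
def small_cast_preset():
    """Small but realistic preset for fast voxel-pipeline tests."""
    return TreePreset(
        name="small",
        trunk_diameter_um=1500.0,
        target_length_density_mm_per_cm3=25.0,
        density_sigma_ln=0.3,
        tissue_volume_cm3=1.0,
        segment_length_mm=1.0,
        rng_seed=3,
    )


@pytest.fixture
def y_tree():
    """Hand-built Y tree: trunk splits into two terminals."""
    c, s = np.cos(np.radians(35.0)), np.sin(np.radians(35.0))
    pts = np.array(
        [[0, 0, 0], [10, 0, 0], [10 + 8 * c, 8 * s, 0], [10 + 8 * c, -8 * s, 0]],
        dtype=float,
    )
    return GroundTruthTree(
        points=pts,
        radii_um=[500.0, 500.0, 350.0, 350.0],
        parents=[-1, 0, 1, 1],
        labels=["root", "branch", "terminal", "terminal"],
    )


def capsule_oracle(shape, a, b, r):
    """Brute-force point-in-capsule test over every voxel centre."""
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    ab = np.asarray(b, float) - np.asarray(a, float)
    denom = float(ab @ ab)
    t = np.clip((idx - a) @ ab / denom, 0, 1) if denom > 0 else np.zeros(len(idx))
    near = a + t[:, None] * ab
    return (((idx - near) ** 2).sum(1) <= r * r).reshape(shape)
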