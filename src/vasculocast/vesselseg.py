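"""Segmentation of cast volumes into clean binary vessel masks.

Mirrors the pre-analysis steps applied to reconstructed cast scans:
global thresholding (the contrast-to-noise of cast CT is high enough for
automatic segmentation), speckle removal by small-component filtering,
and optional tiling into fixed-size subvolumes.  Tiling here is purely a
memory/bookkeeping device: tiles form a deterministic raster partition,
so additive quantities measured per tile sum exactly to the whole-volume
value, and segments crossing tile borders are measured after global
re-assembly.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import VoxelVolume

__all__ = ["threshold_volume", "remove_small_components", "extract_subvolumes"]

log = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity for thin vessels


def threshold_volume(
    volume: VoxelVolume | np.ndarray,
    method: str = "otsu",
    fixed_value: float | None = None,
) -> np.ndarray:
    """Binarise a grayscale cast volume; foreground = vessel.

    ``otsu`` maximises inter-class variance on the intensity histogram;
    ``fixed`` keeps voxels with intensity >= ``fixed_value``.  Raising a
    fixed threshold never adds foreground (segmentation is monotone).
    """
    grid = volume.grid if isinstance(volume, VoxelVolume) else np.asarray(volume)
    if method == "fixed":
        if fixed_value is None:
            raise ValueError("fixed_value is required for method='fixed'")
        return grid >= fixed_value
    if method == "otsu":
        if np.ptp(grid) == 0:
            raise ValueError("cannot apply Otsu thresholding to a constant volume")
        return grid >= threshold_otsu(grid)
    raise ValueError(f"unknown threshold method {method!r}")


def remove_small_components(mask: np.ndarray, min_voxels: int = 5) -> np.ndarray:
    """Drop 26-connected foreground components smaller than ``min_voxels``."""
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    mask = np.asarray(mask).astype(bool)
    if min_voxels == 1 or not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=_STRUCT26)
    if n == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_voxels
    keep[0] = False
    return keep[labels]


def extract_subvolumes(
    mask: np.ndarray,
    shape: tuple[int, int, int] = (800, 500, 300),
    max_count: int = 9,
) -> list[tuple[np.ndarray, tuple[int, int, int]]]:
    """Tile the mask into non-overlapping subvolumes covering all foreground.

    Tiles are taken in deterministic raster order from the origin and
    clipped at the array boundary; only tiles containing foreground are
    returned, each with its voxel offset.  ``max_count`` is a soft cap:
    if more tiles are needed to cover the foreground they are all
    returned and a warning is logged, because the partition property
    (union of tiles = whole foreground, pairwise disjoint) takes
    precedence.
    """
    if any(s < 1 for s in shape):
        raise ValueError("subvolume shape must be positive")
    mask = np.asarray(mask).astype(bool)
    out: list[tuple[np.ndarray, tuple[int, int, int]]] = []
    for i0 in range(0, mask.shape[0], shape[0]):
        for j0 in range(0, mask.shape[1], shape[1]):
            for k0 in range(0, mask.shape[2], shape[2]):
                sub = mask[i0 : i0 + shape[0], j0 : j0 + shape[1], k0 : k0 + shape[2]]
                if sub.any():
                    out.append((sub.copy(), (i0, j0, k0)))
    if len(out) > max_count:
        log.warning(
            "foreground spans %d subvolumes, exceeding max_count=%d; "
            "returning all to preserve coverage",
            len(out),
            max_count,
        )
    return out
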