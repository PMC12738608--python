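"""Small measurement helpers for voxel volumes.

These mirror the threshold-based segmentations a treatment planning
system would apply to the exported series (external contour first, then
low-density regions enclosed by it), and are used by the verification
phantoms to recover ground-truth displacements.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .voxel_core import VoxelVolume


def segment_enclosed_air(vol: VoxelVolume, threshold: float = -100.0) -> np.ndarray:
    """Low-density regions enclosed by the body.

    Thresholds ``hu < threshold`` and removes every connected component
    touching the volume border — the background air and its
    partial-volume ramp along the body surface — leaving only enclosed
    cavities such as lung volumes.
    """
    mask = vol.hu < threshold
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    border = np.zeros(mask.shape, dtype=bool)
    border[[0, -1], :, :] = True
    border[:, [0, -1], :] = True
    border[:, :, [0, -1]] = True
    touching = np.unique(labels[border & mask])
    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    keep[touching] = False
    return keep[labels]


def mask_centroid_mm(vol: VoxelVolume, mask: np.ndarray) -> np.ndarray:
    """Centroid of the masked voxel centres, in scene millimetres."""
    idx = np.argwhere(mask)
    if len(idx) == 0:
        raise ValueError("empty mask")
    centre_idx = idx.mean(axis=0)
    return np.asarray(vol.grid.bbox_min) + (centre_idx + 0.5) * np.asarray(
        vol.grid.spacing
    )


def voxelised_volume_mm3(
    vol: VoxelVolume, background_hu: float = -1000.0, structure_hu: float = 0.0
) -> float:
    """Occupancy-weighted volume of a single-structure voxelisation.

    Treats each voxel's HU as a linear mix of background and structure
    densities; exact for partial-volume-averaged boundary voxels.
    """
    frac = (vol.hu - background_hu) / (structure_hu - background_hu)
    return float(frac.sum() * vol.grid.voxel_volume_mm3())
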