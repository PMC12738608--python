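"""CT artefact simulators: Gaussian noise, metal streaks, partial volume
blur and ring artefacts, plus the final HU clip.

Each simulator takes and returns a :class:`~meshct.voxel_core.VoxelVolume`
(inputs are never mutated).  The combined pipeline applies, in order,
metal streaks → partial volume → rings → noise → clip: deterministic
detector/reconstruction effects are layered before stochastic noise, and
the clip keeps everything in the encodable HU range.  A single integer
seed drives all stochastic steps through derived substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .hu import HU_MAX, HU_MIN
from .voxel_core import VoxelVolume

#: default pipeline stage order (clip always runs last)
DEFAULT_ORDER = ("metal", "partial_volume", "ring", "noise")


@dataclass
class ArtefactParams:
    """All artefact knobs; zero intensity/sigma disables a stage.

    ``pve_sigma`` is the Gaussian-kernel standard deviation in voxels
    (isotropic in index space); ``streak_attenuation`` is per millimetre;
    ``ring_frequency`` counts rings across the slice radius.
    """

    noise_std_dev: float = 0.0  # HU
    metal_threshold: float = 3000.0  # HU
    num_angles: int = 36
    streak_intensity: float = 0.0  # HU at the source
    streak_attenuation: float = 0.05  # per mm
    streak_max_radius: float = 100.0  # mm
    pve_sigma: float = 0.0  # voxels
    ring_frequency: float = 8.0  # rings per slice radius
    ring_intensity: float = 0.0  # HU
    seed: int = 0
    clip_lo: float = HU_MIN
    clip_hi: float = HU_MAX
    order: tuple = field(default=DEFAULT_ORDER)

    def __post_init__(self):
        if self.noise_std_dev < 0:
            raise ParameterError("noise_std_dev must be >= 0")
        if self.num_angles < 1:
            raise ParameterError("num_angles must be >= 1")
        if self.streak_intensity < 0 or self.streak_attenuation < 0:
            raise ParameterError("streak parameters must be >= 0")
        if self.streak_max_radius <= 0:
            raise ParameterError("streak_max_radius must be > 0")
        if self.pve_sigma < 0:
            raise ParameterError("pve_sigma must be >= 0")
        if self.ring_frequency <= 0:
            raise ParameterError("ring_frequency must be > 0")
        if self.ring_intensity < 0:
            raise ParameterError("ring_intensity must be >= 0")
        if not self.clip_lo < self.clip_hi:
            raise ParameterError("clip_lo must be below clip_hi")
        unknown = set(self.order) - set(DEFAULT_ORDER)
        if unknown:
            raise ParameterError(f"unknown pipeline stages: {sorted(unknown)}")


def add_noise(vol: VoxelVolume, std: float, seed: int = 0) -> VoxelVolume:
    """Add i.i.d. zero-mean Gaussian noise of the given standard deviation
    (HU) to every voxel; ``std = 0`` is the identity."""
    if std < 0:
        raise ParameterError("noise std must be >= 0")
    if std == 0:
        return vol.copy_with(vol.hu.copy())
    rng = np.random.default_rng(seed)
    return vol.copy_with(vol.hu + rng.normal(0.0, std, size=vol.hu.shape))


def simulate_metal_artifacts(
    vol: VoxelVolume,
    threshold: float,
    num_angles: int = 36,
    intensity: float = 300.0,
    attenuation: float = 0.05,
    max_radius: float = 100.0,
    clip_lo: float = HU_MIN,
    clip_hi: float = HU_MAX,
) -> VoxelVolume:
    """Bright radial streaks around supra-threshold voxels, per axial slice.

    Every metal voxel (HU > threshold) emits ``num_angles`` equally spaced
    in-plane rays; sample points stepped along each ray out to
    ``max_radius`` deposit ``intensity * exp(-attenuation * r)`` into the
    nearest voxel.  Deposits from all rays and sources accumulate
    additively, then the slice is clipped to the valid HU range.
    """
    if num_angles < 1:
        raise ParameterError("num_angles must be >= 1")
    hu = vol.hu.copy()
    nx, ny, _ = hu.shape
    spx, spy, _ = vol.grid.spacing
    step = min(spx, spy)
    radii = np.arange(step, max_radius + step, step)
    angles = np.linspace(0.0, 2.0 * np.pi, num_angles, endpoint=False)
    dx = np.cos(angles)[:, None] * radii[None, :]  # (A, R) mm
    dy = np.sin(angles)[:, None] * radii[None, :]
    deposit = intensity * np.exp(-attenuation * radii)  # (R,)
    for k in range(hu.shape[2]):
        metal = np.argwhere(hu[:, :, k] > threshold)
        if len(metal) == 0:
            continue
        delta = np.zeros((nx, ny))
        for i, j in metal:
            ix = i + np.rint(dx / spx).astype(np.int64)
            iy = j + np.rint(dy / spy).astype(np.int64)
            ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
            np.add.at(
                delta, (ix[ok], iy[ok]), np.broadcast_to(deposit, ix.shape)[ok]
            )
        hu[:, :, k] = np.clip(hu[:, :, k] + delta, clip_lo, clip_hi)
    return vol.copy_with(hu)


def apply_partial_volume(vol: VoxelVolume, sigma: float) -> VoxelVolume:
    """Gaussian blur of the whole grid (sigma in voxels, reflect boundary),
    emulating the HU averaging of voxels spanning multiple tissues."""
    if sigma < 0:
        raise ParameterError("sigma must be >= 0")
    if sigma == 0:
        return vol.copy_with(vol.hu.copy())
    return vol.copy_with(ndimage.gaussian_filter(vol.hu, sigma=sigma, mode="reflect"))


def pve_sigma_from_mm(sigma_mm: float, grid) -> float:
    """Convert a physical blur width (mm) to the voxel-space sigma used by
    :func:`apply_partial_volume` (mean of the per-axis conversions)."""
    return float(sigma_mm / np.mean(grid.spacing))


def simulate_ring_artefacts(
    vol: VoxelVolume,
    frequency: float,
    intensity: float,
    centre=None,
) -> VoxelVolume:
    """Concentric sinusoidal rings on every axial slice.

    Adds ``intensity * sin(2 pi * frequency * r / R)`` where r is the
    in-plane distance from the (shared) slice centre and R half the
    smaller in-plane extent, so ``frequency`` rings span the radius.
    """
    if intensity < 0:
        raise ParameterError("intensity must be >= 0")
    if frequency <= 0:
        raise ParameterError("frequency must be > 0")
    if intensity == 0:
        return vol.copy_with(vol.hu.copy())
    grid = vol.grid
    nx, ny, _ = grid.shape
    xc = grid.centres(0)
    yc = grid.centres(1)
    if centre is None:
        centre = (
            0.5 * (grid.bbox_min[0] + grid.bbox_max[0]),
            0.5 * (grid.bbox_min[1] + grid.bbox_max[1]),
        )
    big_r = 0.5 * min(nx * grid.spacing[0], ny * grid.spacing[1])
    r = np.hypot(xc[:, None] - centre[0], yc[None, :] - centre[1])
    pattern = intensity * np.sin(2.0 * np.pi * frequency * r / big_r)
    return vol.copy_with(vol.hu + pattern[:, :, None])


def clip_hu(vol: VoxelVolume, lo: float = HU_MIN, hi: float = HU_MAX) -> VoxelVolume:
    """Limit all values to [lo, hi]."""
    if not lo < hi:
        raise ParameterError("lo must be below hi")
    return vol.copy_with(np.clip(vol.hu, lo, hi))


def apply_pipeline(vol: VoxelVolume, params: ArtefactParams) -> VoxelVolume:
    """Apply the enabled artefact stages in ``params.order`` then clip.

    Stages whose controlling parameter is zero are skipped; the result is
    fully determined by ``params`` (noise uses a substream derived from
    ``params.seed``).
    """
    ss = np.random.SeedSequence(params.seed)
    substreams = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(DEFAULT_ORDER, ss.spawn(len(DEFAULT_ORDER)))
    }
    out = vol
    for stage in params.order:
        if stage == "metal" and params.streak_intensity > 0:
            out = simulate_metal_artifacts(
                out,
                params.metal_threshold,
                params.num_angles,
                params.streak_intensity,
                params.streak_attenuation,
                params.streak_max_radius,
                params.clip_lo,
                params.clip_hi,
            )
        elif stage == "partial_volume" and params.pve_sigma > 0:
            out = apply_partial_volume(out, params.pve_sigma)
        elif stage == "ring" and params.ring_intensity > 0:
            out = simulate_ring_artefacts(
                out, params.ring_frequency, params.ring_intensity
            )
        elif stage == "noise" and params.noise_std_dev > 0:
            out = add_noise(out, params.noise_std_dev, seed=substreams["noise"])
    return clip_hu(out, params.clip_lo, params.clip_hi)
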