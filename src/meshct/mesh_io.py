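"""Triangle-mesh loading, validation and scene assembly.

A :class:`Structure` is one closed triangle surface carrying the two
attributes the voxeliser needs: a uniform Hounsfield density and an
integer overlap priority (higher priority wins wherever structures
overlap).  A :class:`Scene` is an ordered, name-unique collection of
structures sharing one patient-LPS millimetre frame.

STL (binary and ASCII) and Wavefront OBJ files are parsed with trimesh;
polygonal OBJ faces are fan-triangulated and vertices closer than the
merge tolerance are fused.  Materials and normals are ignored — only
geometry is read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import DegenerateMeshError, EmptySceneError, MeshFormatError
from .hu import HU_MAX, HU_MIN
from .ray import SpatialIndex

#: vertices closer than this (mm) are merged on load — far below any
#: clinically relevant voxel size, removes STL facet duplication
MERGE_TOL_MM = 1e-6


@dataclass
class Structure:
    """One watertight triangle mesh with density and priority attributes."""

    name: str
    vertices: np.ndarray  # (V, 3) float64, mm
    triangles: np.ndarray  # (T, 3) int64 vertex indices
    density_hu: float
    priority: int

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise DegenerateMeshError(
                f"structure {self.name!r}: triangle indices out of range"
            )
        if not (HU_MIN <= self.density_hu <= HU_MAX):
            raise ValueError(
                f"density_hu {self.density_hu} outside [{HU_MIN}, {HU_MAX}]"
            )

    def copy(self) -> "Structure":
        return Structure(
            self.name,
            self.vertices.copy(),
            self.triangles.copy(),
            self.density_hu,
            self.priority,
        )


@dataclass
class Scene:
    """Ordered collection of structures in one LPS millimetre frame."""

    structures: list = field(default_factory=list)
    frame: str = "LPS-mm"

    def __post_init__(self):
        if not self.structures:
            raise EmptySceneError("scene contains no structures")
        names = [s.name for s in self.structures]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate structure names in scene: {names}")

    def __iter__(self):
        return iter(self.structures)

    def __len__(self):
        return len(self.structures)


@dataclass
class WatertightReport:
    is_closed: bool
    boundary_edge_count: int


def _merge_vertices(vertices, triangles, tol: float = MERGE_TOL_MM):
    """Fuse vertices that coincide to within ``tol`` (grid-bucket merge)."""
    decimals = max(0, int(round(-np.log10(tol))))
    rounded = np.round(vertices, decimals)
    _, first, inverse = np.unique(
        rounded, axis=0, return_index=True, return_inverse=True
    )
    merged = vertices[first]
    new_tris = inverse[triangles]
    # drop triangles collapsed by the merge
    ok = (
        (new_tris[:, 0] != new_tris[:, 1])
        & (new_tris[:, 1] != new_tris[:, 2])
        & (new_tris[:, 0] != new_tris[:, 2])
    )
    return merged, new_tris[ok]


def load_mesh(path, density_hu: float, priority: int, name: str | None = None) -> Structure:
    """Load an STL or OBJ file as a :class:`Structure`.

    Polygonal faces are triangulated, duplicate vertices within
    :data:`MERGE_TOL_MM` merged, and the given density/priority attached.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        mesh = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:  # noqa: BLE001 - trimesh raises many types
        raise MeshFormatError(f"could not parse {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise MeshFormatError(f"{path} contains no triangle geometry")
    vertices, triangles = _merge_vertices(
        np.asarray(mesh.vertices, dtype=np.float64),
        np.asarray(mesh.faces, dtype=np.int64),
    )
    if len(triangles) == 0:
        raise DegenerateMeshError(f"{path}: only zero-area geometry")
    areas = 0.5 * np.linalg.norm(
        np.cross(
            vertices[triangles[:, 1]] - vertices[triangles[:, 0]],
            vertices[triangles[:, 2]] - vertices[triangles[:, 0]],
        ),
        axis=1,
    )
    if not (areas > 0).any():
        raise DegenerateMeshError(f"{path}: only zero-area geometry")
    return Structure(
        name=name or path.stem,
        vertices=vertices,
        triangles=triangles,
        density_hu=float(density_hu),
        priority=int(priority),
    )


def save_obj(structure: Structure, path) -> Path:
    """Write a structure as a Wavefront OBJ (geometry only)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# meshct structure {structure.name}\n")
        for v in structure.vertices:
            fh.write(f"v {v[0]:.7f} {v[1]:.7f} {v[2]:.7f}\n")
        for t in structure.triangles:
            fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")
    return path


def check_watertight(structure: Structure) -> WatertightReport:
    """Report closedness: closed iff every edge is shared by exactly two
    triangles (edge-incidence tally)."""
    t = structure.triangles
    edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = int((counts == 1).sum())
    closed = bool(np.all(counts == 2))
    return WatertightReport(is_closed=closed, boundary_edge_count=boundary)


def build_index(structure: Structure) -> SpatialIndex:
    """Build the BVH spatial index used for all ray queries."""
    if len(structure.triangles) == 0:
        raise DegenerateMeshError(f"structure {structure.name!r} is empty")
    return SpatialIndex(structure)
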