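import numpy as np
import pytest
import trimesh
from hypothesis import HealthCheck, settings

from meshct.mesh_io import Scene, Structure

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# vertices/faces of the unit cube [0,1]^3 (12 facets, 8 vertices)
CUBE_VERTICES = np.array(
    [
        [0, 0, 0],
        [1, 0, 0],
        [1, 1, 0],
        [0, 1, 0],
        [0, 0, 1],
        [1, 0, 1],
        [1, 1, 1],
        [0, 1, 1],
    ],
    dtype=float,
)
CUBE_FACES = np.array(
    [
        [0, 2, 1],
        [0, 3, 2],
        [4, 5, 6],
        [4, 6, 7],
        [0, 1, 5],
        [0, 5, 4],
        [1, 2, 6],
        [1, 6, 5],
        [2, 3, 7],
        [2, 7, 6],
        [3, 0, 4],
        [3, 4, 7],
    ]
)


def make_cube(scale=1.0, offset=(0.0, 0.0, 0.0), density_hu=0.0, priority=0, name="cube"):
    return Structure(
        name,
        CUBE_VERTICES * scale + np.asarray(offset, dtype=float),
        CUBE_FACES.copy(),
        density_hu,
        priority,
    )


def make_sphere(radius, centre=(0, 0, 0), subdivisions=3, density_hu=0.0, priority=0, name="sphere"):
    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return Structure(
        name,
        np.asarray(tm.vertices, dtype=float) + np.asarray(centre, dtype=float),
        np.asarray(tm.faces),
        density_hu,
        priority,
    )


@pytest.fixture
def unit_cube():
    return make_cube()


@pytest.fixture
def sphere20():
    return make_sphere(20.0, subdivisions=4)


@pytest.fixture
def sphere_scene():
    return Scene([make_sphere(25.0, density_hu=0.0, priority=1)])


def ascii_stl_cube(path):
    """Write the unit cube as ASCII STL (12 facets, duplicated vertices)."""
    lines = ["solid cube"]
    for tri in CUBE_FACES:
        v = CUBE_VERTICES[tri]
        n = np.cross(v[1] - v[0], v[2] - v[0])
        n = n / np.linalg.norm(n)
        lines.append(f"  facet normal {n[0]:.1f} {n[1]:.1f} {n[2]:.1f}")
        lines.append("    outer loop")
        for p in v:
            lines.append(f"      vertex {p[0]:.1f} {p[1]:.1f} {p[2]:.1f}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append("endsolid cube")
    path.write_text("\n".join(lines) + "\n")
    return path
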