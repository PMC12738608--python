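"""Parametric test phantoms and primitive mesh generation.

All test geometry is generated programmatically: watertight primitives
(sphere, cylinder, ellipsoid), a three-cylinder lung phantom with optional
metal insert, a cranial-style lesion phantom exercising priority
overrides, and cyclic breathing-phase deformation for 4D series.

Default dimensions are anatomy-scaled declared values: the body cylinder
is 120 mm radius stretched x1.4 laterally and 200 mm tall; lungs are
40 mm radius, 150 mm tall, centred +-60 mm laterally; the metal insert is
a 5 mm radius sphere; the head is an ellipsoid with (80, 95, 105) mm
semi-axes, a 6 mm skull shell and three 8 mm lesions.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .errors import ParameterError
from .mesh_io import Scene, Structure

# lung phantom construction values (HU per the standard tissue surrogates:
# water body, typical lung, high-density implant)
BODY_HU = 0.0
LUNG_HU = -200.0
METAL_HU = 2000.0
BODY_RADIUS_MM = 120.0
BODY_LATERAL_STRETCH = 1.4
BODY_HEIGHT_MM = 200.0
LUNG_RADIUS_MM = 40.0
LUNG_HEIGHT_MM = 150.0
LUNG_LATERAL_OFFSET_MM = 60.0
METAL_RADIUS_MM = 5.0

# lesion (cranial-style) phantom
HEAD_HU = 0.0
SKULL_HU = 1000.0
BRAIN_HU = 200.0
LESION_HU = 250.0
HEAD_SEMI_AXES_MM = (80.0, 95.0, 105.0)
SKULL_OUTER_SEMI_AXES_MM = (70.0, 85.0, 95.0)
SKULL_THICKNESS_MM = 6.0
LESION_RADIUS_MM = 8.0
LESION_CENTRES_MM = (
    (-25.0, 10.0, 20.0),
    (20.0, -15.0, -10.0),
    (0.0, 30.0, -30.0),
)


def _as_structure(mesh: trimesh.Trimesh, name, density_hu, priority) -> Structure:
    return Structure(
        name=name,
        vertices=np.asarray(mesh.vertices, dtype=np.float64),
        triangles=np.asarray(mesh.faces, dtype=np.int64),
        density_hu=float(density_hu),
        priority=int(priority),
    )


def make_primitive(
    kind: str,
    *,
    radius: float | None = None,
    height: float | None = None,
    semi_axes=None,
    centre=(0.0, 0.0, 0.0),
    subdivisions: int = 3,
    scale_xyz=None,
    density_hu: float = 0.0,
    priority: int = 0,
    name: str | None = None,
) -> Structure:
    """Closed triangle mesh approximating a sphere, capped cylinder
    (axis along z) or ellipsoid.

    ``subdivisions`` controls tessellation (icosphere subdivision level;
    ``8 * 2**subdivisions`` circumferential sections for cylinders).
    """
    if subdivisions < 2:
        raise ParameterError("subdivisions must be >= 2")
    kind = kind.lower()
    if kind == "sphere":
        if radius is None or radius <= 0:
            raise ParameterError("sphere requires a positive radius")
        mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    elif kind == "cylinder":
        if radius is None or radius <= 0 or height is None or height <= 0:
            raise ParameterError("cylinder requires positive radius and height")
        mesh = trimesh.creation.cylinder(
            radius=radius, height=height, sections=8 * 2**subdivisions
        )
    elif kind == "ellipsoid":
        if semi_axes is None or np.any(np.asarray(semi_axes) <= 0):
            raise ParameterError("ellipsoid requires three positive semi-axes")
        mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
        mesh.vertices = mesh.vertices * np.asarray(semi_axes, dtype=np.float64)
    else:
        raise ParameterError(f"unknown primitive kind {kind!r}")
    vertices = np.asarray(mesh.vertices, dtype=np.float64)
    if scale_xyz is not None:
        vertices = vertices * np.asarray(scale_xyz, dtype=np.float64)
    vertices = vertices + np.asarray(centre, dtype=np.float64)
    return Structure(
        name=name or kind,
        vertices=vertices,
        triangles=np.asarray(mesh.faces, dtype=np.int64),
        density_hu=float(density_hu),
        priority=int(priority),
    )


def make_lung_phantom(
    lung_si_offset_mm: float = 0.0, with_metal: bool = False, subdivisions: int = 3
) -> Scene:
    """Three-cylinder lung phantom: water-equivalent body (0 HU, priority
    0) stretched laterally, two lung cylinders (-200 HU, priority 1)
    translated ``lung_si_offset_mm`` along SI (+z superior), optionally a
    2000 HU metal sphere (priority 2) midway between the lungs."""
    body = make_primitive(
        "cylinder",
        radius=BODY_RADIUS_MM,
        height=BODY_HEIGHT_MM,
        scale_xyz=(BODY_LATERAL_STRETCH, 1.0, 1.0),
        subdivisions=subdivisions,
        density_hu=BODY_HU,
        priority=0,
        name="body",
    )
    lungs = [
        make_primitive(
            "cylinder",
            radius=LUNG_RADIUS_MM,
            height=LUNG_HEIGHT_MM,
            centre=(side * LUNG_LATERAL_OFFSET_MM, 0.0, lung_si_offset_mm),
            subdivisions=subdivisions,
            density_hu=LUNG_HU,
            priority=1,
            name=f"lung_{label}",
        )
        for side, label in ((-1.0, "left"), (1.0, "right"))
    ]
    structures = [body, *lungs]
    if with_metal:
        structures.append(
            make_primitive(
                "sphere",
                radius=METAL_RADIUS_MM,
                centre=(0.0, 0.0, lung_si_offset_mm),
                subdivisions=subdivisions,
                density_hu=METAL_HU,
                priority=2,
                name="metal_insert",
            )
        )
    return Scene(structures)


def _shell(outer_axes, inner_axes, subdivisions, name, density_hu, priority):
    """Closed shell bounded by two nested ellipsoid surfaces (one mesh with
    two components; parity classifies the inter-surface region as inside)."""
    outer = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    inner = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    vo = outer.vertices * np.asarray(outer_axes, dtype=np.float64)
    vi = inner.vertices * np.asarray(inner_axes, dtype=np.float64)
    vertices = np.vstack([vo, vi])
    faces = np.vstack([outer.faces, inner.faces + len(vo)])
    return Structure(name, vertices, faces, float(density_hu), int(priority))


def make_lesion_phantom(subdivisions: int = 3) -> Scene:
    """Cranial-style phantom exercising every priority tier.

    Outer head ellipsoid at 0 HU (priority 0), a 6 mm skull shell at
    1000 HU (priority 1), a solid brain ellipsoid at 200 HU (priority 1,
    disjoint from the shell interior), and three 250 HU lesion spheres at
    priority 2 fully inside the brain.
    """
    brain_axes = tuple(a - SKULL_THICKNESS_MM for a in SKULL_OUTER_SEMI_AXES_MM)
    head = make_primitive(
        "ellipsoid",
        semi_axes=HEAD_SEMI_AXES_MM,
        subdivisions=subdivisions,
        density_hu=HEAD_HU,
        priority=0,
        name="head",
    )
    skull = _shell(
        SKULL_OUTER_SEMI_AXES_MM,
        brain_axes,
        subdivisions,
        "skull",
        SKULL_HU,
        1,
    )
    brain = make_primitive(
        "ellipsoid",
        semi_axes=brain_axes,
        subdivisions=subdivisions,
        density_hu=BRAIN_HU,
        priority=1,
        name="brain",
    )
    lesions = [
        make_primitive(
            "sphere",
            radius=LESION_RADIUS_MM,
            centre=c,
            subdivisions=subdivisions,
            density_hu=LESION_HU,
            priority=2,
            name=f"lesion_{i + 1}",
        )
        for i, c in enumerate(LESION_CENTRES_MM)
    ]
    return Scene([head, skull, brain, *lesions])


def make_breathing_phases(
    base: Scene,
    n_phases: int,
    si_amplitude: float = 0.10,
    ap_amplitude: float = 0.03,
    structures=None,
) -> list:
    """Cyclic breathing deformation of designated structures.

    Phase p applies the cyclic profile ``a(p) = amplitude * sin^2(pi p / n)``
    as a non-linear scaling: the local stretch grows linearly from the
    cranial plane (fixed, zero displacement) to the caudal plane, so
    displacement grows quadratically toward the diaphragm end — its
    maximum is ``amplitude * SI extent`` at mid-cycle.  The AP axis is
    scaled the same way about the posterior plane (patient supine, back
    fixed).  Phase 0 is the base scene exactly; phase n wraps to phase 0.
    """
    if n_phases < 1:
        raise ParameterError("n_phases must be >= 1")
    for amp in (si_amplitude, ap_amplitude):
        if not 0.0 <= amp <= 0.5:
            raise ParameterError("amplitudes must lie in [0, 0.5]")
    names = set(structures) if structures is not None else {s.name for s in base}
    allv = np.vstack([s.vertices for s in base])
    z_top, z_bot = allv[:, 2].max(), allv[:, 2].min()
    y_back, y_front = allv[:, 1].max(), allv[:, 1].min()
    hz = z_top - z_bot
    hy = y_back - y_front
    phases = []
    for p in range(n_phases):
        a = float(np.sin(np.pi * p / n_phases) ** 2)
        if a == 0.0:
            phases.append(Scene([s.copy() for s in base]))
            continue
        new_structs = []
        for s in base:
            if s.name not in names:
                new_structs.append(s.copy())
                continue
            v = s.vertices.copy()
            dz = z_top - v[:, 2]
            v[:, 2] = z_top - dz * (1.0 + si_amplitude * a * dz / hz)
            dy = y_back - v[:, 1]
            v[:, 1] = y_back - dy * (1.0 + ap_amplitude * a * dy / hy)
            new_structs.append(
                Structure(s.name, v, s.triangles.copy(), s.density_hu, s.priority)
            )
        phases.append(Scene(new_structs))
    return phases
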