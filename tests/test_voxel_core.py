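"""Voxelisation core: grid geometry, parity classification, priority
resolution, boundary detection and adaptive refinement."""

import numpy as np
import pytest
import trimesh
from hypothesis import given
from hypothesis import strategies as st

from meshct.errors import EmptySceneError, ParameterError
from meshct.mesh_io import Scene, Structure, build_index
from meshct.voxel_core import (
    compute_bounding_box,
    detect_boundaries,
    first_pass,
    make_grid,
    point_inside,
    refine_boundaries,
    resolve_density,
    voxelise_scene,
)

from .conftest import make_cube, make_sphere


class TestBoundingBox:
    def test_unit_cube_no_padding(self, unit_cube):
        lo, hi = compute_bounding_box(Scene([unit_cube]), 0.0)
        assert np.allclose(lo, 0) and np.allclose(hi, 1)

    def test_union_of_two_cubes(self):
        scene = Scene(
            [make_cube(name="a"), make_cube(offset=(2, 2, 2), name="b")]
        )
        lo, hi = compute_bounding_box(scene, 0.0)
        assert np.allclose(lo, 0) and np.allclose(hi, 3)

    def test_random_vertices_against_exhaustive_scan(self):
        rng = np.random.default_rng(7)
        verts = rng.uniform(-50, 80, size=(500, 3))
        tris = rng.integers(0, 500, size=(200, 3))
        s = Structure("blob", verts, tris, 0.0, 0)
        lo, hi = compute_bounding_box(Scene([s]), 5.0)
        expect_lo = np.array([min(v[a] for v in verts) for a in range(3)]) - 5
        expect_hi = np.array([max(v[a] for v in verts) for a in range(3)]) + 5
        assert np.allclose(lo, expect_lo) and np.allclose(hi, expect_hi)

    def test_empty_scene_rejected(self):
        with pytest.raises(EmptySceneError):
            compute_bounding_box(None, 0.0)


class TestMakeGrid:
    @pytest.mark.parametrize(
        "extent,expected", [(10.0, 4), (9.9, 4), (10.1, 5)]
    )
    def test_ceil_dimensions(self, extent, expected):
        grid = make_grid((0, 0, 0), (extent, extent, extent), 2.5)
        assert grid.dims == (expected,) * 3

    def test_voxel_centres(self):
        grid = make_grid((1.0, 0.0, 0.0), (9.0, 4.0, 4.0), 2.0)
        assert np.allclose(grid.centres(0), [2.0, 4.0, 6.0, 8.0])

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ParameterError):
            make_grid((0, 0, 0), (1, 1, 1), 0.0)


class TestPointInside:
    def test_sphere_against_analytic(self, sphere20):
        idx = build_index(sphere20)
        rng = np.random.default_rng(11)
        pts = rng.uniform(-25, 25, size=(10_000, 3))
        r = np.linalg.norm(pts, axis=1)
        # exclude the band where mesh facets deviate from the true sphere
        far = np.abs(r - 20.0) > 0.1
        inside = idx.contains(pts, rng=rng)
        assert np.array_equal(inside[far], (r < 20.0)[far])

    def test_single_point_api(self, sphere20):
        idx = build_index(sphere20)
        assert point_inside(idx, (0.0, 0.0, 0.0))
        assert not point_inside(idx, (25.0, 0.0, 0.0))

    def test_ellipsoid_against_analytic(self):
        """Implicit-function oracle on a non-spherical surface."""
        axes = np.array([18.0, 12.0, 9.0])
        tm = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        s = Structure(
            "ell", np.array(tm.vertices) * axes, np.array(tm.faces), 0.0, 0
        )
        idx = build_index(s)
        rng = np.random.default_rng(3)
        pts = rng.uniform(-20, 20, size=(5000, 3))
        q = np.linalg.norm(pts / axes, axis=1)
        far = np.abs(q - 1.0) > 0.02  # skip the facet-sag band
        ours = idx.contains(pts, rng=rng)
        assert np.array_equal(ours[far], (q < 1.0)[far])


class TestResolveDensity:
    def test_empty_hits_give_background(self):
        assert resolve_density([], -1000.0) == -1000.0

    def test_higher_priority_wins(self):
        assert resolve_density([(200.0, 1), (250.0, 2)]) == 250.0

    def test_equal_priority_higher_hu_wins_order_independent(self):
        assert resolve_density([(100.0, 1), (300.0, 1)]) == 300.0
        assert resolve_density([(300.0, 1), (100.0, 1)]) == 300.0

    @given(
        st.lists(
            st.tuples(
                st.floats(-1000, 3000, allow_nan=False),
                st.integers(0, 5),
            ),
            min_size=1,
            max_size=6,
        ),
        st.randoms(),
    )
    def test_permutation_invariant_and_maximal(self, hits, rnd):
        shuffled = list(hits)
        rnd.shuffle(shuffled)
        out = resolve_density(hits)
        assert out == resolve_density(shuffled)
        assert out == max(hits, key=lambda h: (h[1], h[0]))[0]


class TestFirstPass:
    def test_empty_region_is_background(self):
        scene = Scene([make_cube(scale=2.0, offset=(100, 100, 100))])
        grid = make_grid((0, 0, 0), (10, 10, 10), 2.0)
        hu, prio, label = first_pass(scene, grid)
        assert np.all(hu == -1000.0)
        assert np.all(label == -1)

    def test_box_covering_64_centres(self):
        # centres at odd coordinates 1..11; box [1.9, 10.1] covers exactly
        # the 4 centres {3,5,7,9} per axis
        box = make_cube(scale=8.2, offset=(1.9, 1.9, 1.9), density_hu=0.0)
        grid = make_grid((0, 0, 0), (12, 12, 12), 2.0)
        hu, _, _ = first_pass(Scene([box]), grid)
        assert (hu == 0.0).sum() == 64
        assert np.all(hu[(hu != 0.0)] == -1000.0)

    def test_chunk_invariance(self, sphere_scene):
        grid = make_grid(*compute_bounding_box(sphere_scene, 2.0), 2.0)
        outs = [
            first_pass(sphere_scene, grid, chunk_slices=cs)
            for cs in (1, 7, grid.dims[2])
        ]
        for hu, prio, label in outs[1:]:
            assert np.array_equal(hu, outs[0][0])
            assert np.array_equal(label, outs[0][2])

    def test_matches_analytic_cylinder_at_centres(self):
        """Cross-check the whole first pass against the implicit capped
        cylinder r < R and |z| < h/2 (independent of any ray code)."""
        tm = trimesh.creation.cylinder(radius=12.0, height=30.0, sections=256)
        s = Structure("cyl", np.array(tm.vertices), np.array(tm.faces), 0.0, 1)
        scene = Scene([s])
        grid = make_grid(*compute_bounding_box(scene, 3.0), 3.0)
        hu, _, _ = first_pass(scene, grid)
        centres = np.stack(
            np.meshgrid(*(grid.centres(a) for a in range(3)), indexing="ij"), -1
        ).reshape(-1, 3)
        r = np.linalg.norm(centres[:, :2], axis=1).reshape(grid.shape)
        z = centres[:, 2].reshape(grid.shape)
        expected = (r < 12.0) & (np.abs(z) < 15.0)
        ours = hu == 0.0
        # skip centres within 0.1 mm of the surface (facet chord error)
        near = (np.abs(r - 12.0) < 0.1) | (np.abs(np.abs(z) - 15.0) < 0.1)
        assert np.array_equal(ours[~near], expected[~near])


class TestDetectBoundaries:
    def test_uniform_grid_empty_mask(self):
        hu = np.full((5, 5, 5), -1000.0)
        label = np.full((5, 5, 5), -1)
        assert not detect_boundaries(hu, label).any()

    def test_single_voxel_marks_itself_and_six_neighbours(self):
        hu = np.full((5, 5, 5), -1000.0)
        label = np.full((5, 5, 5), -1)
        hu[2, 2, 2] = 0.0
        label[2, 2, 2] = 0
        mask = detect_boundaries(hu, label)
        expected = {(2, 2, 2), (1, 2, 2), (3, 2, 2), (2, 1, 2), (2, 3, 2), (2, 2, 1), (2, 2, 3)}
        assert set(map(tuple, np.argwhere(mask))) == expected

    def test_grid_aligned_box_marks_two_shells(self):
        hu = np.full((8, 8, 8), -1000.0)
        label = np.full((8, 8, 8), -1)
        hu[2:6, 2:6, 2:6] = 0.0
        label[2:6, 2:6, 2:6] = 0
        mask = detect_boundaries(hu, label)
        inner = np.zeros_like(mask)
        inner[2:6, 2:6, 2:6] = True
        inner[3:5, 3:5, 3:5] = False  # interior not marked
        outer = np.zeros_like(mask)
        outer[1:7, 1:7, 1:7] = True
        outer[2:6, 2:6, 2:6] = False
        # exterior shell voxels touching only by edge/corner are not marked
        expected = inner.copy()
        for sh, ax in [(s, a) for a in range(3) for s in (-1, 1)]:
            expected |= np.roll(inner, sh, axis=ax) & outer
        assert np.array_equal(mask, expected | inner)


class TestRefineBoundaries:
    def test_k1_reproduces_centre_sample(self, sphere_scene):
        grid = make_grid(*compute_bounding_box(sphere_scene, 2.0), 4.0)
        hu, prio, label = first_pass(sphere_scene, grid)
        mask = detect_boundaries(hu, label)
        refined = refine_boundaries(sphere_scene, grid, hu, mask, k=1)
        assert np.array_equal(refined, hu)

    def test_half_covered_voxel_averages_to_minus_500(self):
        # one 2 mm voxel; a wide slab covers exactly its lower half in z
        slab = make_cube(scale=40.0, offset=(-20.0, -20.0, -39.0), density_hu=0.0)
        scene = Scene([slab])
        grid = make_grid((0, 0, 0), (2, 2, 2), 2.0)
        hu = np.full((1, 1, 1), -1000.0)
        mask = np.ones((1, 1, 1), dtype=bool)
        refined = refine_boundaries(scene, grid, hu, mask, k=2)
        assert refined[0, 0, 0] == pytest.approx(-500.0)

    def test_fully_inside_voxel_unchanged_by_masking(self, sphere_scene):
        grid = make_grid(*compute_bounding_box(sphere_scene, 2.0), 4.0)
        hu, prio, label = first_pass(sphere_scene, grid)
        centre_idx = tuple(d // 2 for d in grid.shape)
        mask = np.zeros(grid.shape, dtype=bool)
        mask[centre_idx] = True
        refined = refine_boundaries(sphere_scene, grid, hu, mask, k=3)
        assert refined[centre_idx] == 0.0

    def test_invalid_k(self, sphere_scene):
        grid = make_grid((0, 0, 0), (4, 4, 4), 2.0)
        with pytest.raises(ParameterError):
            refine_boundaries(
                sphere_scene, grid, np.zeros((2, 2, 2)), np.zeros((2, 2, 2), bool), k=0
            )


class TestVoxeliseScene:
    def test_sphere_volume_within_two_percent(self, sphere_scene):
        vol = voxelise_scene(sphere_scene, spacing=2.0, padding=2.0, k=3)
        occupancy = (vol.hu + 1000.0) / 1000.0
        est = occupancy.sum() * vol.grid.voxel_volume_mm3()
        analytic = 4.0 / 3.0 * np.pi * 25.0**3
        assert abs(est - analytic) / analytic < 0.02

    def test_volume_convergence_series(self):
        scene = Scene([make_sphere(25.0, density_hu=0.0, priority=1, subdivisions=4)])
        analytic = 4.0 / 3.0 * np.pi * 25.0**3
        errors = []
        for spacing in (5.0, 2.5, 1.25):
            vol = voxelise_scene(scene, spacing=spacing, padding=spacing, k=3)
            est = ((vol.hu + 1000.0) / 1000.0).sum() * vol.grid.voxel_volume_mm3()
            errors.append(abs(est - analytic) / analytic)
        assert errors[1] < 0.02 and errors[2] < 0.02  # r/spacing >= 10
        assert errors[2] < errors[0]

    def test_adaptive_equals_exhaustive_supersampling(self):
        scene = Scene([make_sphere(10.0, density_hu=200.0, priority=1)])
        vol = voxelise_scene(scene, spacing=2.5, padding=2.5, k=3)
        grid = vol.grid
        hu, prio, label = first_pass(scene, grid)
        everywhere = np.ones(grid.shape, dtype=bool)
        exhaustive = refine_boundaries(scene, grid, hu, everywhere, k=3)
        assert np.array_equal(vol.hu, exhaustive)

    def test_priority_dominance_in_overlap(self):
        outer = make_sphere(20.0, density_hu=100.0, priority=1, name="outer")
        inner = make_sphere(10.0, density_hu=300.0, priority=2, name="inner")
        vol = voxelise_scene(Scene([outer, inner]), spacing=2.0, padding=2.0, k=2)
        grid = vol.grid
        centres = [grid.centres(a) for a in range(3)]
        rr = np.sqrt(
            centres[0][:, None, None] ** 2
            + centres[1][None, :, None] ** 2
            + centres[2][None, None, :] ** 2
        )
        assert np.all(vol.hu[rr < 8.0] == 300.0)  # inner interior
        assert np.all(vol.hu[(rr > 12.0) & (rr < 18.0)] == 100.0)

    def test_order_independence_of_equal_priority_tie(self):
        a = make_sphere(10.0, density_hu=100.0, priority=1, name="a")
        b = make_sphere(10.0, density_hu=300.0, priority=1, name="b")
        v1 = voxelise_scene(Scene([a, b]), spacing=2.5, padding=2.5, k=2)
        v2 = voxelise_scene(Scene([b, a]), spacing=2.5, padding=2.5, k=2)
        assert np.array_equal(v1.hu, v2.hu)
        # interior of the coincident spheres resolves to the higher HU
        grid = v1.grid
        centres = [grid.centres(a) for a in range(3)]
        rr = np.sqrt(
            centres[0][:, None, None] ** 2
            + centres[1][None, :, None] ** 2
            + centres[2][None, None, :] ** 2
        )
        assert np.all(v1.hu[rr < 8.0] == 300.0)

    def test_deterministic(self, sphere_scene):
        v1 = voxelise_scene(sphere_scene, spacing=2.5, padding=1.0, k=3, seed=5)
        v2 = voxelise_scene(sphere_scene, spacing=2.5, padding=1.0, k=3, seed=5)
        assert np.array_equal(v1.hu, v2.hu)
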