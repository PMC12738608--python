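"""Ray–mesh intersection acceleration and robust parity (even–odd) testing.

A :class:`SpatialIndex` wraps one closed triangle mesh and supports three
kinds of query:

* :meth:`SpatialIndex.ray_intersections` — all hit parameters of an
  arbitrary ray, found by traversing a bounding-volume hierarchy (BVH);
* :meth:`SpatialIndex.contains` — inside/outside classification of points
  by counting crossings of a +x ray (odd count → inside), with degenerate
  hits (edge/vertex grazing, on-surface origins) resolved by re-casting
  along a slightly perturbed direction;
* :meth:`SpatialIndex.crossings_x_grid` / :meth:`crossings_x_lines` —
  batched x-crossings of many axis-parallel rays at once, the workhorse of
  the voxeliser.  Rays that pass within a tiny band of a triangle edge or
  hit a ray-parallel facet are flagged so the caller can fall back to the
  robust per-point test.

All coordinates are millimetres.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateMeshError

# Relative half-width of the edge band (fraction of twice the projected
# triangle area) inside which a crossing is treated as numerically
# degenerate and re-cast.
_EDGE_EPS = 1e-9
# Absolute length tolerance (mm): crossings closer than this to a sample
# are ambiguous; also used to inflate candidate search boxes.
_LEN_EPS = 1e-7
# Ray parameter below which a hit is "at the origin" (origin on surface).
_T_EPS = 1e-9
# Maximum direction perturbation (radians) and retry count for degenerate
# parity casts.
_PERTURB_RAD = 1e-3
_MAX_RETRIES = 3


def _triangle_vertices(structure):
    v = np.asarray(structure.vertices, dtype=np.float64)
    f = np.asarray(structure.triangles, dtype=np.int64)
    if f.size == 0:
        raise DegenerateMeshError(f"structure {structure.name!r} has no triangles")
    return v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]


class SpatialIndex:
    """BVH-accelerated ray query structure over one structure's triangles."""

    def __init__(self, structure, leaf_size: int = 8):
        self.a, self.b, self.c = _triangle_vertices(structure)
        self.e1 = self.b - self.a
        self.e2 = self.c - self.a
        # projected (y,z) signed double-areas; zero for ray-parallel facets
        self.area_yz = (
            (self.b[:, 1] - self.a[:, 1]) * (self.c[:, 2] - self.a[:, 2])
            - (self.b[:, 2] - self.a[:, 2]) * (self.c[:, 1] - self.a[:, 1])
        )
        self._edge_scale = np.linalg.norm(self.e1, axis=1) * np.linalg.norm(
            self.e2, axis=1
        )
        self.normal = np.cross(self.e1, self.e2)
        tri = np.stack([self.a, self.b, self.c], axis=1)  # (M, 3, 3)
        self.tri_min = tri.min(axis=1)
        self.tri_max = tri.max(axis=1)
        self.bbox_min = self.tri_min.min(axis=0)
        self.bbox_max = self.tri_max.max(axis=0)
        self.n_triangles = len(self.a)
        self._build_bvh(leaf_size)

    # ------------------------------------------------------------------ BVH
    def _build_bvh(self, leaf_size: int) -> None:
        centroids = (self.a + self.b + self.c) / 3.0
        order = np.arange(self.n_triangles)
        bmin, bmax, left, right, start, count = [], [], [], [], [], []

        def build(lo: int, hi: int) -> int:
            node = len(bmin)
            sub = order[lo:hi]
            bmin.append(self.tri_min[sub].min(axis=0))
            bmax.append(self.tri_max[sub].max(axis=0))
            left.append(-1)
            right.append(-1)
            start.append(lo)
            count.append(hi - lo)
            if hi - lo > leaf_size:
                cent = centroids[sub]
                axis = int(np.argmax(cent.max(axis=0) - cent.min(axis=0)))
                order[lo:hi] = sub[np.argsort(cent[:, axis], kind="stable")]
                mid = (lo + hi) // 2
                left[node] = build(lo, mid)
                right[node] = build(mid, hi)
                count[node] = 0
            return node

        import sys

        limit = sys.getrecursionlimit()
        sys.setrecursionlimit(max(limit, 10000))
        try:
            build(0, self.n_triangles)
        finally:
            sys.setrecursionlimit(limit)
        self._order = order
        self._node_bmin = np.asarray(bmin)
        self._node_bmax = np.asarray(bmax)
        self._node_left = np.asarray(left)
        self._node_right = np.asarray(right)
        self._node_start = np.asarray(start)
        self._node_count = np.asarray(count)

    def _slab_hit(self, node: int, origin, direction) -> bool:
        tmin, tmax = -np.inf, np.inf
        bmin = self._node_bmin[node]
        bmax = self._node_bmax[node]
        for ax in range(3):
            d = direction[ax]
            if d == 0.0:
                if origin[ax] < bmin[ax] - _LEN_EPS or origin[ax] > bmax[ax] + _LEN_EPS:
                    return False
            else:
                t1 = (bmin[ax] - origin[ax]) / d
                t2 = (bmax[ax] - origin[ax]) / d
                if t1 > t2:
                    t1, t2 = t2, t1
                tmin = max(tmin, t1)
                tmax = min(tmax, t2)
        return tmax >= max(tmin, 0.0) - _LEN_EPS

    def ray_intersections(self, origin, direction):
        """Sorted hit parameters t > 0 of the ray origin + t * direction.

        Traverses the BVH; hits exactly at the origin are excluded.  A ray
        grazing an edge shared by adjacent triangles yields one crossing
        (edge-band hits are deduplicated by hit position).
        """
        origin = np.asarray(origin, dtype=np.float64)
        direction = np.asarray(direction, dtype=np.float64)
        norm = np.linalg.norm(direction)
        if norm == 0:
            raise ValueError("zero direction")
        direction = direction / norm
        stack = [0]
        hits = []
        grazes = []
        while stack:
            node = stack.pop()
            if not self._slab_hit(node, origin, direction):
                continue
            if self._node_left[node] < 0:
                lo = self._node_start[node]
                sub = self._order[lo : lo + self._node_count[node]]
                t, _, _, hit, degen = self._moller_trumbore(origin, direction, sub)
                if hit.any():
                    hits.append(t[hit])
                band = degen & (t > _T_EPS)
                if band.any():
                    grazes.append(t[band])
            else:
                stack.append(int(self._node_left[node]))
                stack.append(int(self._node_right[node]))
        strict = np.sort(np.concatenate(hits)) if hits else np.empty(0)
        if not grazes:
            return strict
        graze_t = np.sort(np.concatenate(grazes))
        # one crossing per grazed edge/vertex position, unless a strict hit
        # already accounts for it
        keep = []
        for t in graze_t:
            if keep and abs(t - keep[-1]) < 1e-7 * (1.0 + abs(t)):
                continue
            if strict.size and np.min(np.abs(strict - t)) < 1e-7 * (1.0 + abs(t)):
                continue
            keep.append(t)
        return np.sort(np.concatenate([strict, np.asarray(keep)]))

    # -------------------------------------------------------- intersection
    def _moller_trumbore(self, origin, direction, sub=None):
        """Vectorised Möller–Trumbore over a triangle subset.

        Returns (t, u, v, hit, degenerate_hit) arrays; ``degenerate_hit``
        marks hits inside the edge band or with t near zero.
        """
        if sub is None:
            a, e1, e2, scale = self.a, self.e1, self.e2, self._edge_scale
        else:
            a, e1, e2, scale = self.a[sub], self.e1[sub], self.e2[sub], self._edge_scale[sub]
        p = np.cross(direction[None, :], e2)
        det = np.einsum("ij,ij->i", e1, p)
        parallel = np.abs(det) <= 1e-12 * scale
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = np.where(parallel, 0.0, 1.0 / np.where(parallel, 1.0, det))
        tv = origin[None, :] - a
        u = np.einsum("ij,ij->i", tv, p) * inv
        q = np.cross(tv, e1)
        v = np.einsum("ij,j->i", q, direction) * inv
        t = np.einsum("ij,ij->i", e2, q) * inv
        eps = _EDGE_EPS
        in_band = (
            ~parallel
            & (u >= -eps)
            & (v >= -eps)
            & (u + v <= 1.0 + eps)
            & (t > -_T_EPS)
        )
        strict = (
            ~parallel & (u > eps) & (v > eps) & (u + v < 1.0 - eps) & (t > _T_EPS)
        )
        degenerate = in_band & ~strict
        return t, u, v, strict, degenerate

    # --------------------------------------------------------- parity test
    def contains(self, points, rng=None):
        """Even–odd parity classification of points (inside == odd crossings).

        Points are cast along +x; degenerate casts are retried along a
        randomly perturbed direction (≤ 1e-3 rad, up to 3 retries) using
        the supplied seeded generator.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        n = len(pts)
        out = np.zeros(n, dtype=bool)
        inb = np.all(
            (pts >= self.bbox_min - _LEN_EPS) & (pts <= self.bbox_max + _LEN_EPS),
            axis=1,
        )
        idx = np.flatnonzero(inb)
        if idx.size == 0:
            return out if np.ndim(points) > 1 else bool(out[0])
        if rng is None:
            rng = np.random.default_rng(0)
        direction = np.array([1.0, 0.0, 0.0])
        for chunk in np.array_split(idx, max(1, idx.size // 512)):
            parity, degen = self._parity_chunk(pts[chunk], direction)
            out[chunk] = parity
            # degenerate casts: retry the whole subset along a shared
            # perturbed direction (new draw per retry)
            bad = chunk[degen]
            for _ in range(_MAX_RETRIES):
                if bad.size == 0:
                    break
                tilt = rng.uniform(-_PERTURB_RAD, _PERTURB_RAD, size=2)
                d = np.array([1.0, tilt[0], tilt[1]])
                d /= np.linalg.norm(d)
                parity, degen = self._parity_chunk(pts[bad], d)
                out[bad] = parity
                bad = bad[degen]
        if np.ndim(points) == 1:
            return bool(out[0])
        return out

    def _parity_chunk(self, pts, direction):
        """Parity of crossings along ``direction`` for a chunk of points,
        brute-force over all triangles (component-wise Möller–Trumbore)."""
        p = np.cross(direction, self.e2)  # (M, 3)
        det = np.einsum("ij,ij->i", self.e1, p)  # (M,)
        parallel = np.abs(det) <= 1e-12 * self._edge_scale
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = np.where(parallel, 0.0, 1.0 / np.where(parallel, 1.0, det))
        # tv = point - a, broadcast (N, M); cross products written out
        # component-wise to avoid temporaries on (N, M, 3)
        tvx = pts[:, 0, None] - self.a[None, :, 0]
        tvy = pts[:, 1, None] - self.a[None, :, 1]
        tvz = pts[:, 2, None] - self.a[None, :, 2]
        u = (tvx * p[:, 0] + tvy * p[:, 1] + tvz * p[:, 2]) * inv
        e1 = self.e1
        qx = tvy * e1[:, 2] - tvz * e1[:, 1]
        qy = tvz * e1[:, 0] - tvx * e1[:, 2]
        qz = tvx * e1[:, 1] - tvy * e1[:, 0]
        v = (qx * direction[0] + qy * direction[1] + qz * direction[2]) * inv
        e2 = self.e2
        t = (qx * e2[:, 0] + qy * e2[:, 1] + qz * e2[:, 2]) * inv
        eps = _EDGE_EPS
        strict = (
            ~parallel[None, :]
            & (u > eps)
            & (v > eps)
            & (u + v < 1.0 - eps)
            & (t > _T_EPS)
        )
        in_band = (
            ~parallel[None, :]
            & (u >= -eps)
            & (v >= -eps)
            & (u + v <= 1.0 + eps)
            & (t > -_T_EPS)
        )
        parity = (strict.sum(axis=1) % 2).astype(bool)
        degenerate = (in_band & ~strict).any(axis=1)
        # a ray grazing the plane of a ray-parallel facet (inside its
        # footprint) is also ambiguous
        if parallel.any():
            degenerate |= self._grazes_parallel(pts, np.flatnonzero(parallel))
        return parity, degenerate

    def _grazes_parallel(self, pts, par_idx):
        """True per point if a +x ray through it lies in the plane of a
        ray-parallel facet while crossing that facet's (y,z) footprint."""
        near = np.ones((len(pts), par_idx.size), dtype=bool)
        for ax in (1, 2):
            near &= (
                pts[:, ax, None] >= self.tri_min[par_idx, ax] - _LEN_EPS
            ) & (pts[:, ax, None] <= self.tri_max[par_idx, ax] + _LEN_EPS)
        ny_, nz_ = self.normal[par_idx, 1], self.normal[par_idx, 2]
        nlen = np.where(np.hypot(ny_, nz_) > 0, np.hypot(ny_, nz_), 1.0)
        dist = (
            np.abs(
                (pts[:, 1, None] - self.a[par_idx, 1]) * ny_
                + (pts[:, 2, None] - self.a[par_idx, 2]) * nz_
            )
            / nlen
        )
        return (near & (dist < _LEN_EPS)).any(axis=1)

    # ----------------------------------------------------- batched x-rays
    def crossings_x_grid(self, y_values, z_values):
        """x-crossings of the line grid {(y_j, z_k)} cast along x.

        Parameters are sorted 1-D coordinate arrays.  Returns
        ``(line_ids, x_cross, degenerate_lines)`` where line id =
        ``j * len(z_values) + k`` and ``degenerate_lines`` is a boolean
        array over all lines flagging those that need the robust per-point
        fallback.
        """
        yv = np.asarray(y_values, dtype=np.float64)
        zv = np.asarray(z_values, dtype=np.float64)
        ny, nz = len(yv), len(zv)
        j0 = np.searchsorted(yv, self.tri_min[:, 1] - _LEN_EPS, side="left")
        j1 = np.searchsorted(yv, self.tri_max[:, 1] + _LEN_EPS, side="right")
        k0 = np.searchsorted(zv, self.tri_min[:, 2] - _LEN_EPS, side="left")
        k1 = np.searchsorted(zv, self.tri_max[:, 2] + _LEN_EPS, side="right")
        nj = j1 - j0
        nk = k1 - k0
        ncand = nj * nk
        keep = ncand > 0
        if not keep.any():
            return (
                np.empty(0, dtype=np.int64),
                np.empty(0),
                np.zeros(ny * nz, dtype=bool),
            )
        tri_ids = np.flatnonzero(keep)
        ncand_k = ncand[keep]
        offsets = np.concatenate([[0], np.cumsum(ncand_k)])
        total = offsets[-1]
        tri_rep = np.repeat(tri_ids, ncand_k)
        local = np.arange(total) - np.repeat(offsets[:-1], ncand_k)
        nk_rep = np.repeat(nk[keep], ncand_k)
        jj = np.repeat(j0[keep], ncand_k) + local // nk_rep
        kk = np.repeat(k0[keep], ncand_k) + local % nk_rep
        line = jj * nz + kk
        return self._crossings_from_candidates(
            tri_rep, yv[jj], zv[kk], line, ny * nz
        )

    def crossings_x_lines(self, y, z):
        """x-crossings for an arbitrary list of (y, z) lines cast along x."""
        y = np.asarray(y, dtype=np.float64)
        z = np.asarray(z, dtype=np.float64)
        n_lines = len(y)
        order = np.argsort(y, kind="stable")
        ys = y[order]
        j0 = np.searchsorted(ys, self.tri_min[:, 1] - _LEN_EPS, side="left")
        j1 = np.searchsorted(ys, self.tri_max[:, 1] + _LEN_EPS, side="right")
        ncand = j1 - j0
        keep = ncand > 0
        if not keep.any():
            return (
                np.empty(0, dtype=np.int64),
                np.empty(0),
                np.zeros(n_lines, dtype=bool),
            )
        tri_ids = np.flatnonzero(keep)
        ncand_k = ncand[keep]
        offsets = np.concatenate([[0], np.cumsum(ncand_k)])
        tri_rep = np.repeat(tri_ids, ncand_k)
        local = np.arange(offsets[-1]) - np.repeat(offsets[:-1], ncand_k)
        pos = np.repeat(j0[keep], ncand_k) + local
        line = order[pos]
        pz = z[line]
        zok = (pz >= self.tri_min[tri_rep, 2] - _LEN_EPS) & (
            pz <= self.tri_max[tri_rep, 2] + _LEN_EPS
        )
        tri_rep = tri_rep[zok]
        line = line[zok]
        return self._crossings_from_candidates(
            tri_rep, y[line], z[line], line, n_lines
        )

    def _crossings_from_candidates(self, tri, py, pz, line, n_lines):
        """Edge-function crossing evaluation for candidate (triangle, line)
        pairs; shared by the grid and list variants."""
        degen_lines = np.zeros(n_lines, dtype=bool)
        if tri.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0), degen_lines
        area = self.area_yz[tri]
        # ray-parallel facets: projected area ~ 0; a line is ambiguous only
        # if it lies (nearly) in the facet's plane
        flat = np.abs(area) <= 1e-12 * self._edge_scale[tri]
        if flat.any():
            fi = np.flatnonzero(flat)
            tf = tri[fi]
            ny_, nz_ = self.normal[tf, 1], self.normal[tf, 2]
            nlen = np.hypot(ny_, nz_)
            dist = np.abs(
                (py[fi] - self.a[tf, 1]) * ny_ + (pz[fi] - self.a[tf, 2]) * nz_
            ) / np.where(nlen > 0, nlen, 1.0)
            grazing = dist < _LEN_EPS
            if grazing.any():
                degen_lines[np.unique(line[fi[grazing]])] = True
        ay, az = self.a[tri, 1], self.a[tri, 2]
        by, bz = self.b[tri, 1], self.b[tri, 2]
        cy, cz = self.c[tri, 1], self.c[tri, 2]
        w0 = (by - ay) * (pz - az) - (bz - az) * (py - ay)
        w1 = (cy - by) * (pz - bz) - (cz - bz) * (py - by)
        w2 = (ay - cy) * (pz - cz) - (az - cz) * (py - cy)
        s = np.sign(area)
        band = _EDGE_EPS * np.abs(area)
        sw0, sw1, sw2 = s * w0, s * w1, s * w2
        inside = ~flat & (sw0 > band) & (sw1 > band) & (sw2 > band)
        near = (
            ~flat
            & (sw0 >= -band)
            & (sw1 >= -band)
            & (sw2 >= -band)
            & ((sw0 <= band) | (sw1 <= band) | (sw2 <= band))
        )
        if near.any():
            degen_lines[np.unique(line[near])] = True
        ti = tri[inside]
        ai = self.area_yz[ti]
        lam_a = w1[inside] / ai
        lam_b = w2[inside] / ai
        lam_c = w0[inside] / ai
        x = (
            lam_a * self.a[ti, 0]
            + lam_b * self.b[ti, 0]
            + lam_c * self.c[ti, 0]
        )
        return line[inside].astype(np.int64), x, degen_lines
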