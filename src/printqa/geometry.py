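"""Spatial queries on triangle meshes: closest point on surface and
point-in-solid tests.

Both queries are exact per candidate triangle; acceleration uses a KD-tree
over triangle centroids (closest point) and a uniform 2D grid over the xy
bounding boxes of the triangles (vertical-ray parity for the inside test).
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .errors import NotWatertightError
from .mesh import TriMesh


def closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle to each query point.

    points: (n, 3); tri: (n, 3, 3) -- one triangle per point.
    Returns (n, 3) closest points. Ericson's region-based algorithm,
    vectorised.
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    p = points
    ab = b - a
    ac = c - a
    ap = p - a

    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)

    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)

    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    denom_ab = d1 - d3
    denom_ac = d2 - d6
    denom_bc = (d4 - d3) + (d5 - d6)

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(denom_ab != 0, d1 / denom_ab, 0.0)
        w_ac = np.where(denom_ac != 0, d2 / denom_ac, 0.0)
        w_bc = np.where(denom_bc != 0, (d4 - d3) / denom_bc, 0.0)
        denom = va + vb + vc
        v_in = np.where(denom != 0, vb / denom, 0.0)
        w_in = np.where(denom != 0, vc / denom, 0.0)

    result = a + v_in[:, None] * ab + w_in[:, None] * ac  # interior default

    on_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    result = np.where(
        on_bc[:, None], b + np.clip(w_bc, 0, 1)[:, None] * (c - b), result
    )
    on_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    result = np.where(on_ac[:, None], a + np.clip(w_ac, 0, 1)[:, None] * ac, result)
    on_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    result = np.where(on_ab[:, None], a + np.clip(v_ab, 0, 1)[:, None] * ab, result)
    vert_c = (d6 >= 0) & (d5 <= d6)
    result = np.where(vert_c[:, None], c, result)
    vert_b = (d3 >= 0) & (d4 <= d3)
    result = np.where(vert_b[:, None], b, result)
    vert_a = (d1 <= 0) & (d2 <= 0)
    result = np.where(vert_a[:, None], a, result)
    return result


class SurfaceIndex:
    """Accelerated closest-point and inside/outside queries against one mesh."""

    def __init__(
        self, mesh: TriMesh, n_candidates: int = 16, vertex_incidence: bool = True
    ):
        if mesh.n_triangles == 0:
            raise ValueError("cannot index an empty mesh")
        self.mesh = mesh
        self.tri = mesh.triangles
        self.n_candidates = int(min(n_candidates, mesh.n_triangles))
        self.vertex_incidence = bool(vertex_incidence)
        self._centroid_tree = cKDTree(self.tri.mean(axis=1))
        self._vertex_tree = cKDTree(mesh.vertices)
        # CSR-style vertex -> incident faces map
        flat = mesh.faces.ravel()
        order = np.argsort(flat, kind="stable")
        self._vf_faces = order // 3
        self._vf_ptr = np.searchsorted(
            flat[order], np.arange(len(mesh.vertices) + 1)
        )
        self._grid = None

    # -- closest point -----------------------------------------------------
    def closest_point(self, points: np.ndarray):
        """Closest surface point for each query.

        Returns ``(distances, closest_points)``. Candidate triangles are the
        k centroid-nearest plus the faces incident to the nearest vertex;
        for the near-uniform tessellations that iso-surfacing produces this
        recovers the exact nearest triangle.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        k = self.n_candidates
        _, cidx = self._centroid_tree.query(points, k=k)
        cidx = np.atleast_2d(cidx)
        if self.vertex_incidence:
            _, vidx = self._vertex_tree.query(points, k=1)
            # pad incident-face lists to a fixed width
            starts = self._vf_ptr[vidx]
            ends = self._vf_ptr[vidx + 1]
            width = int((ends - starts).max(initial=0))
            inc = np.empty((n, width), dtype=np.int64)
            for j in range(width):
                take = np.minimum(starts + j, ends - 1)
                inc[:, j] = self._vf_faces[take]
            cand = np.concatenate([cidx, inc], axis=1)  # (n, k+width)
        else:
            cand = cidx

        m = cand.shape[1]
        flat_pts = np.repeat(points, m, axis=0)
        flat_tri = self.tri[cand.ravel()]
        cp = closest_point_on_triangles(flat_pts, flat_tri).reshape(n, m, 3)
        d2 = np.einsum("ijk,ijk->ij", cp - points[:, None, :], cp - points[:, None, :])
        best = np.argmin(d2, axis=1)
        rows = np.arange(n)
        return np.sqrt(d2[rows, best]), cp[rows, best]

    # -- inside test -------------------------------------------------------
    def _build_grid(self, n_cells: int = 128):
        t = self.tri
        xy_min = t[..., :2].reshape(-1, 2).min(axis=0)
        xy_max = t[..., :2].reshape(-1, 2).max(axis=0)
        span = np.maximum(xy_max - xy_min, 1e-9)
        nc = int(min(n_cells, max(8, int(np.sqrt(self.mesh.n_triangles)))))
        cell = span / nc
        tmin = t[..., :2].min(axis=1)
        tmax = t[..., :2].max(axis=1)
        lo = np.floor((tmin - xy_min) / cell).astype(int)
        hi = np.floor((tmax - xy_min) / cell).astype(int)
        lo = np.clip(lo, 0, nc - 1)
        hi = np.clip(hi, 0, nc - 1)
        spans = (hi[:, 0] - lo[:, 0] + 1) * (hi[:, 1] - lo[:, 1] + 1)
        tri_ids = np.repeat(np.arange(len(t)), spans)
        # enumerate covered cells per triangle
        cells = np.empty(spans.sum(), dtype=np.int64)
        pos = 0
        # vectorised expansion: loop over the (small) set of distinct span shapes
        for (wx, wy) in set(zip(hi[:, 0] - lo[:, 0], hi[:, 1] - lo[:, 1])):
            sel = np.flatnonzero((hi[:, 0] - lo[:, 0] == wx) & (hi[:, 1] - lo[:, 1] == wy))
            if len(sel) == 0:
                continue
            ox, oy = np.meshgrid(np.arange(wx + 1), np.arange(wy + 1), indexing="ij")
            cx = lo[sel, 0][:, None] + ox.ravel()[None, :]
            cy = lo[sel, 1][:, None] + oy.ravel()[None, :]
            ids = (cx * nc + cy).ravel()
            # place into the slots reserved for these triangles
            slot_starts = np.concatenate([[0], np.cumsum(spans)])[sel]
            w = (wx + 1) * (wy + 1)
            idx = (slot_starts[:, None] + np.arange(w)[None, :]).ravel()
            cells[idx] = ids
            pos += len(idx)
        order = np.argsort(cells, kind="stable")
        self._grid = {
            "xy_min": xy_min,
            "cell": cell,
            "nc": nc,
            "cells_sorted": cells[order],
            "tris_sorted": tri_ids[order],
        }

    def contains(self, points: np.ndarray, jitter: float = 1e-7) -> np.ndarray:
        """Vertical-ray parity test: True where the point is inside the solid.

        Requires a watertight mesh. Query xy coordinates are deterministically
        jittered by ``jitter`` (mm) to step off edge-on ray/triangle ties.
        """
        if not self.mesh.is_watertight:
            raise NotWatertightError(
                self.mesh.open_edge_count(), context="reference mesh for inside test"
            )
        if self._grid is None:
            self._build_grid()
        g = self._grid
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        xy = points[:, :2] + jitter * np.stack(
            [np.cos(0.7 + np.arange(n)), np.sin(1.3 + np.arange(n))], axis=1
        )
        cell_idx = np.floor((xy - g["xy_min"]) / g["cell"]).astype(int)
        out_of_grid = np.any((cell_idx < 0) | (cell_idx >= g["nc"]), axis=1)
        cell_id = np.clip(cell_idx[:, 0], 0, g["nc"] - 1) * g["nc"] + np.clip(
            cell_idx[:, 1], 0, g["nc"] - 1
        )

        inside = np.zeros(n, dtype=bool)
        todo = np.flatnonzero(~out_of_grid)
        order = np.argsort(cell_id[todo], kind="stable")
        todo = todo[order]
        ids = cell_id[todo]
        boundaries = np.flatnonzero(np.diff(ids)) + 1
        groups = np.split(todo, boundaries)
        t = self.tri
        for grp in groups:
            if len(grp) == 0:
                continue
            cid = cell_id[grp[0]]
            s = np.searchsorted(g["cells_sorted"], cid)
            e = np.searchsorted(g["cells_sorted"], cid, side="right")
            tris = g["tris_sorted"][s:e]
            if len(tris) == 0:
                continue
            tt = t[tris]  # (m, 3, 3)
            px = xy[grp, 0][:, None]
            py = xy[grp, 1][:, None]
            x1, y1 = tt[:, 0, 0][None], tt[:, 0, 1][None]
            x2, y2 = tt[:, 1, 0][None], tt[:, 1, 1][None]
            x3, y3 = tt[:, 2, 0][None], tt[:, 2, 1][None]
            d1 = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
            d2 = (x3 - x2) * (py - y2) - (y3 - y2) * (px - x2)
            d3 = (x1 - x3) * (py - y3) - (y1 - y3) * (px - x3)
            in_tri = ((d1 >= 0) & (d2 >= 0) & (d3 >= 0)) | (
                (d1 <= 0) & (d2 <= 0) & (d3 <= 0)
            )
            area = d1 + d2 + d3
            valid = in_tri & (np.abs(area) > 1e-14)
            with np.errstate(divide="ignore", invalid="ignore"):
                w1 = d2 / area
                w2 = d3 / area
                w3 = d1 / area
                z_hit = (
                    w1 * tt[:, 0, 2][None]
                    + w2 * tt[:, 1, 2][None]
                    + w3 * tt[:, 2, 2][None]
                )
            z_hit = np.where(valid, z_hit, -np.inf)
            crossings = (valid & (z_hit > points[grp, 2][:, None])).sum(axis=1)
            inside[grp] = (crossings % 2) == 1
        return inside
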