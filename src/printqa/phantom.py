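"""Synthetic femur-like test phantom ("benchy").

The phantom mimics a proximal femur: a spherical head, an angled
cylindrical neck, and a rectangular shaft with flat faces and sharp
edges, joined by smooth concave fillets, with a gentle seeded free-form
ripple on the large surfaces. It is built as a smooth implicit solid and
surfaced by marching cubes, so the result is watertight by construction
and deterministic for a fixed ``(complexity, seed)``.

The shape stands on the base plane z = 0 (flat bottom, suitable as the
print bed contact face) and measures roughly 57 x 26 x 82 mm with an
enclosed volume around 5.2e4 mm3, the scale of an adult proximal femur
head-neck-shaft segment.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from .mesh import TriMesh

# -- implicit primitives (signed distance, negative inside) ----------------


def _sd_sphere(p, center, r):
    return np.linalg.norm(p - center, axis=-1) - r


def _sd_capsule(p, a, b, r):
    pa = p - a
    ba = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    h = np.clip((pa @ ba) / (ba @ ba), 0.0, 1.0)
    return np.linalg.norm(pa - h[..., None] * ba, axis=-1) - r


def _sd_box(p, center, half):
    q = np.abs(p - center) - half
    outside = np.linalg.norm(np.maximum(q, 0.0), axis=-1)
    inside = np.minimum(q.max(axis=-1), 0.0)
    return outside + inside


def _smooth_union(a, b, k):
    """Polynomial smooth minimum: blends a concave fillet of radius ~k."""
    h = np.clip(0.5 + 0.5 * (b - a) / k, 0.0, 1.0)
    return b * (1.0 - h) + a * h - k * h * (1.0 - h)


# geometry of the default phantom, mm
_SHAFT_CENTER = np.array([0.0, 0.0, 18.0])
_SHAFT_HALF = np.array([17.0, 12.0, 18.0])
_NECK_A = np.array([0.0, 0.0, 33.0])
_NECK_B = np.array([20.0, 0.0, 54.0])
_NECK_R = 10.0
_HEAD_CENTER = np.array([24.0, 0.0, 66.0])
_HEAD_R = 16.0
_FILLET_K = 4.0
_RIPPLE_AMP = 0.5  # mm, free-form surface modulation
_RIPPLE_FREQ = 2.0 * np.pi / 14.0  # one undulation per ~14 mm


def _phantom_sdf(p: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Signed distance-like field of the phantom at points ``p`` (..., 3)."""
    d = _sd_box(p, _SHAFT_CENTER, _SHAFT_HALF)
    d = _smooth_union(d, _sd_capsule(p, _NECK_A, _NECK_B, _NECK_R), _FILLET_K)
    d = _smooth_union(d, _sd_sphere(p, _HEAD_CENTER, _HEAD_R), _FILLET_K)
    # seeded free-form ripple, faded out near the base so the bottom stays flat
    x, y, z = p[..., 0], p[..., 1], p[..., 2]
    fade = np.clip((z - 2.0) / 4.0, 0.0, 1.0)
    ripple = (
        _RIPPLE_AMP
        * fade
        * np.sin(_RIPPLE_FREQ * x + phases[0])
        * np.sin(_RIPPLE_FREQ * y + phases[1])
        * np.sin(_RIPPLE_FREQ * z + phases[2])
    )
    d = d + ripple
    # intersect with the half-space z >= 0: flat printable base
    return np.maximum(d, -z)


def _grid_pitch(complexity: int) -> float:
    return 1.2 / complexity


def generate_benchy(complexity: int = 2, seed: int = 0) -> TriMesh:
    """Generate the femur-like phantom as a watertight triangle mesh.

    Parameters
    ----------
    complexity:
        >= 1; controls the marching-cubes sampling pitch (1.2 mm / complexity),
        i.e. the tessellation fineness. The enclosed volume converges as the
        pitch shrinks.
    seed:
        Seeds the phases of the free-form surface ripple only; the overall
        anatomy is fixed.
    """
    if complexity < 1:
        raise ValueError("complexity must be >= 1")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)

    pitch = _grid_pitch(int(complexity))
    half_y = max(_SHAFT_HALF[1], _HEAD_R + abs(_HEAD_CENTER[1]), _NECK_R)
    lo = np.array([-_SHAFT_HALF[0], -half_y, 0.0]) - 3.0
    hi = np.array([_HEAD_CENTER[0] + _HEAD_R, half_y, _HEAD_CENTER[2] + _HEAD_R]) + 3.0
    # base plane must be captured exactly: keep z=0 between grid samples
    xs = np.arange(lo[0], hi[0] + pitch, pitch)
    ys = np.arange(lo[1], hi[1] + pitch, pitch)
    zs = np.arange(-1.5 * pitch, hi[2] + pitch, pitch)

    gz, gy, gx = np.meshgrid(zs, ys, xs, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    field = _phantom_sdf(pts, phases)

    verts, faces, _, _ = measure.marching_cubes(
        field, level=0.0, spacing=(float(pitch), float(pitch), float(pitch))
    )
    # marching_cubes indexes (z, y, x); map back to world xyz
    verts_xyz = np.column_stack(
        [verts[:, 2] + xs[0], verts[:, 1] + ys[0], verts[:, 0] + zs[0]]
    )
    mesh = TriMesh(verts_xyz, faces.astype(np.int64))
    from .mesh import signed_volume

    if signed_volume(mesh) < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh
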