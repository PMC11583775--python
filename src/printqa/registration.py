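"""Rigid ICP alignment of a moving mesh onto a reference mesh.

Mimics the "best fit" alignment of surface-inspection software: rigid only
(no scaling), point-to-surface correspondences, initialised from centroid
matching plus principal-axes alignment with all four proper axis-sign
combinations, keeping the candidate with the lowest post-ICP RMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .deviation import sample_surface
from .errors import MisalignmentError
from .geometry import SurfaceIndex
from .mesh import TriMesh


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation 3x3, translation mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-9):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ValueError("reflection is not a rigid motion")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass
class ICPOptions:
    n_samples: int = 2000
    max_iterations: int = 200
    tolerance_mm: float = 1e-6  # stop when RMS improves by less than this
    stage_iterations: int = 15  # per-initialisation trial budget
    stage_samples: int = 500  # coarse sample count for the init trials
    stage_tolerance_mm: float = 1e-4
    seed: int = 0
    max_rms_fraction: float = 0.25  # of reference bbox diagonal -> error
    warn_rms_fraction: float = 0.02  # -> flagged unreliable


@dataclass
class ICPResult:
    transform: RigidTransform
    rms_mm: float
    converged: bool
    reliable: bool
    n_iterations: int


def _kabsch(src: np.ndarray, dst: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform mapping src points onto dst points."""
    cs = src.mean(axis=0)
    cd = dst.mean(axis=0)
    h = (src - cs).T @ (dst - cd)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return RigidTransform(r, cd - r @ cs)


def _principal_axes(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    cov = c.T @ c / len(c)
    w, v = np.linalg.eigh(cov)
    v = v[:, ::-1]  # descending variance
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return v


def _run_icp(
    src: np.ndarray,
    index: SurfaceIndex,
    init: RigidTransform,
    max_iter: int,
    tol: float,
):
    transform = init
    prev_rms = np.inf
    rms = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        moved = transform.apply(src)
        dist, cp = index.closest_point(moved)
        rms = float(np.sqrt(np.mean(dist**2)))
        transform = _kabsch(src, cp)
        if prev_rms - rms < tol:
            break
        prev_rms = rms
    return transform, rms, it


def icp_align(
    moving: TriMesh, reference: TriMesh, opts: ICPOptions | None = None
) -> ICPResult:
    """Rigid transform aligning ``moving`` onto ``reference``.

    Raises :class:`MisalignmentError` when the final RMS exceeds
    ``opts.max_rms_fraction`` of the reference bounding-box diagonal (the
    surfaces are too different for a trustworthy comparison); sets
    ``reliable=False`` above ``opts.warn_rms_fraction``.
    """
    opts = opts or ICPOptions()
    if moving.n_triangles == 0 or reference.n_triangles == 0:
        raise ValueError("cannot align empty meshes")
    index = SurfaceIndex(reference, n_candidates=8, vertex_incidence=False)
    src = (
        moving.vertices
        if len(moving.vertices) <= opts.n_samples
        else sample_surface(moving, opts.n_samples, seed=opts.seed)
    )
    src_stage = src[:: max(1, len(src) // opts.stage_samples)]

    axes_m = _principal_axes(moving.vertices)
    axes_r = _principal_axes(reference.vertices)
    cm = src_stage.mean(axis=0)
    cr = reference.vertices.mean(axis=0)

    candidates = []
    for signs in ([1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]):
        r0 = axes_r @ np.diag(signs) @ axes_m.T
        init = RigidTransform(r0, cr - r0 @ cm)
        tr, rms, _ = _run_icp(
            src_stage, index, init, opts.stage_iterations, opts.stage_tolerance_mm
        )
        candidates.append((rms, tr))
    best_rms, best_tr = min(candidates, key=lambda c: c[0])

    transform, rms, n_iter = _run_icp(
        src, index, best_tr, opts.max_iterations, opts.tolerance_mm
    )
    converged = n_iter < opts.max_iterations
    diag = float(np.linalg.norm(reference.extents))
    if rms > opts.max_rms_fraction * diag:
        raise MisalignmentError(
            f"ICP residual RMS {rms:.3f} mm exceeds "
            f"{opts.max_rms_fraction:.0%} of the reference diagonal "
            f"({diag:.1f} mm); the surfaces differ too much for a reliable "
            f"alignment"
        )
    reliable = rms <= opts.warn_rms_fraction * diag
    return ICPResult(
        transform=transform,
        rms_mm=rms,
        converged=converged,
        reliable=reliable,
        n_iterations=n_iter,
    )
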