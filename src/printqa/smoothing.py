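"""Digital-editing stage: three-level smoothing profiles and the DEE metrics.

Clinical segmentation suites expose smoothing on incompatible scales, so the
profiles here reproduce *parameterisations*, not vendor algorithms:

* ``slicer_like``  -- median filter on the label/HU volume, kernel 1 / 3 / 5 mm
  for low / medium / high, followed by re-extraction of the surface;
* ``brainlab_like`` -- mesh-domain Taubin-style smoothing, factor 0.66 / 1.33 /
  2.00 mapped to ``round(10 * factor)`` iterations;
* ``d2p_like``     -- a single low level only (1 mm median), matching a tool
  whose strongest available smoothing is mild.

Absolute deviation magnitudes between profiles are not comparable -- only
the within-profile level orderings are meaningful.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage, sparse

from .ct import HUVolume
from .deviation import DeviationStats, signed_surface_deviation
from .mesh import TriMesh, file_size_proxy, mesh_volume

log = logging.getLogger(__name__)

PROFILES = ("slicer_like", "brainlab_like", "d2p_like")
LEVELS = ("low", "medium", "high")

_VOLUME_KERNELS_MM = {"slicer_like": {"low": 1.0, "medium": 3.0, "high": 5.0},
                      "d2p_like": {"low": 1.0}}
_MESH_FACTORS = {"brainlab_like": {"low": 0.66, "medium": 1.33, "high": 2.00}}


@dataclass(frozen=True)
class SmoothingSpec:
    """One (profile, level) smoothing setting with its resolved parameter."""

    profile: str
    level: str

    def __post_init__(self):
        if self.profile not in PROFILES:
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.profile == "d2p_like" and self.level != "low":
            raise ValueError("d2p_like supports only level='low'")

    @property
    def method(self) -> str:
        return "mesh" if self.profile in _MESH_FACTORS else "volume"

    @property
    def median_kernel_mm(self) -> Optional[float]:
        return _VOLUME_KERNELS_MM.get(self.profile, {}).get(self.level)

    @property
    def factor(self) -> Optional[float]:
        return _MESH_FACTORS.get(self.profile, {}).get(self.level)


def _odd_window(kernel_mm: float, spacing_mm: float) -> int:
    """mm -> voxel window: round up to the next odd integer, at least 1."""
    w = int(np.ceil(kernel_mm / spacing_mm))
    return max(1, w + (1 - w % 2))


def smooth_volume_median(volume: HUVolume, kernel_mm: float) -> HUVolume:
    """Median-filter an HU (or mask) volume with a physical kernel size.

    The kernel is converted per axis to an odd voxel window of at least one
    voxel. When no axis exceeds one voxel the filter is the identity (a
    warning is logged).
    """
    if kernel_mm <= 0:
        raise ValueError("kernel_mm must be positive")
    dx, dy, dz = volume.spacing
    window = (_odd_window(kernel_mm, dz), _odd_window(kernel_mm, dy),
              _odd_window(kernel_mm, dx))
    if all(w == 1 for w in window):
        log.warning(
            "median kernel %.3g mm is below one voxel on every axis; identity",
            kernel_mm,
        )
        return HUVolume(volume.voxels.copy(), volume.spacing, volume.origin)
    filtered = ndimage.median_filter(volume.voxels, size=window, mode="nearest")
    return HUVolume(filtered, volume.spacing, volume.origin)


def _uniform_laplacian(mesh: TriMesh) -> sparse.csr_matrix:
    n = len(mesh.vertices)
    e = np.vstack([mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    adj = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    return sparse.diags(1.0 / deg) @ adj


def smooth_mesh_factor(mesh: TriMesh, factor: float) -> TriMesh:
    """Taubin-style two-step Laplacian smoothing controlled by a scalar factor.

    ``round(10 * factor)`` shrink/inflate iteration pairs (lambda = 0.5,
    mu = -0.45: the slight under-compensation gives the mild monotone
    shrinkage that clinical smoothing exhibits). Triangle count and
    watertightness are preserved; ``factor -> 0`` is the identity.
    """
    if factor < 0:
        raise ValueError("factor must be >= 0")
    iterations = int(round(10.0 * factor))
    if iterations == 0 or mesh.n_triangles == 0:
        return mesh.copy()
    lam, mu = 0.5, -0.45
    w = _uniform_laplacian(mesh)
    v = mesh.vertices.copy()
    for _ in range(iterations):
        v = v + lam * (w @ v - v)
        v = v + mu * (w @ v - v)
    return TriMesh(v, mesh.faces.copy())


@dataclass
class DEEMetrics:
    """Digital-editing error of one smoothing application."""

    dFi_rel_pct: float  # relative file-size (triangle-count) change, %
    dV_rel_pct: float  # relative volume change, %
    deviation: Optional[DeviationStats]


def dee_metrics(
    before: TriMesh,
    after: TriMesh,
    n_samples: int = 100_000,
    seed: int = 0,
    compute_deviation: bool = True,
) -> DEEMetrics:
    """Compare a print-STL (``after``) against its direct segmentation
    (``before``): relative file-size and volume change plus the signed
    surface deviation with ``after`` as the analyzed mesh.

    Both meshes live in the same (scanner) coordinate frame, so no
    re-alignment is applied before the deviation analysis.
    """
    fi_before = file_size_proxy(before)
    fi_after = file_size_proxy(after)
    v_before = mesh_volume(before)
    v_after = mesh_volume(after)
    deviation = (
        signed_surface_deviation(after, before, n_samples=n_samples, seed=seed)
        if compute_deviation
        else None
    )
    return DEEMetrics(
        dFi_rel_pct=100.0 * (fi_after - fi_before) / fi_before,
        dV_rel_pct=100.0 * (v_after - v_before) / v_before,
        deviation=deviation,
    )
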