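"""Threshold segmentation of HU volumes and the segmentation-error metrics.

A voxel belongs to the object iff its HU value is at or above the chosen
threshold. The surface is extracted either with sub-voxel interpolation on
the continuous HU field (default, matching the smooth threshold response of
clinical segmentation tools) or from the binary mask (staircase-style), and
scaled into millimetres using the acquisition spacing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage import measure

from .ct import HU_MIN, HUVolume
from .errors import EmptySegmentationError
from .mesh import MeshMetrics, TriMesh, signed_volume

DEFAULT_CUTOFF_MM3 = 30_000.0
# Non-uniform seven-step sweep: the endpoints are stated explicitly and the
# intermediate values are the ones the study discusses (-600, 0, 100).
DEFAULT_THRESHOLDS_HU = (-800.0, -600.0, -400.0, -200.0, 0.0, 100.0, 200.0)


@dataclass
class SegmentationResult:
    mesh: TriMesh
    threshold_hu: float
    island_policy: str
    metrics: MeshMetrics
    rel_volume_error_pct: float
    n_components: int


def relative_volume_error(v_seg: float, v_ref: float) -> float:
    """Relative volume error in percent: 100 * (v_seg - v_ref) / v_ref.

    Negative values mean the segmentation is smaller than the reference.
    """
    if v_ref <= 0:
        raise ValueError(f"reference volume must be positive, got {v_ref}")
    return 100.0 * (v_seg - v_ref) / v_ref


def passes_cutoff(v_seg: float, v_min: float = DEFAULT_CUTOFF_MM3) -> bool:
    """True when the segmented volume qualifies for surface-deviation analysis.

    Results with a volume *less than* ``v_min`` are excluded (boundary
    inclusive: exactly ``v_min`` passes).
    """
    if v_seg < 0:
        raise ValueError("volume must be non-negative")
    return v_seg >= v_min


def _split_components(mesh: TriMesh):
    """Connected components of a mesh, with their signed volumes."""
    import trimesh

    parts = mesh.to_trimesh().split(only_watertight=False)
    out = []
    for p in parts:
        part = TriMesh.from_trimesh(p)
        out.append((part, signed_volume(part)))
    return out


def segment_threshold(
    volume: HUVolume,
    threshold_hu: float,
    island_policy: str = "keep_all",
    method: str = "subvoxel",
    reference_volume_mm3: Optional[float] = None,
) -> SegmentationResult:
    """Extract the iso-surface of ``volume`` at ``threshold_hu``.

    ``island_policy='keep_all'`` keeps every closed component (reproducing
    island formation in noisy data); ``'largest_component'`` keeps only the
    largest-volume one. ``method='subvoxel'`` interpolates the continuous HU
    field; ``'binary'`` surfaces the thresholded mask (half-voxel staircase).
    """
    if island_policy not in ("keep_all", "largest_component"):
        raise ValueError(f"unknown island_policy {island_policy!r}")
    if method not in ("subvoxel", "binary"):
        raise ValueError(f"unknown method {method!r}")
    voxels = volume.voxels
    vmax = float(voxels.max())
    if vmax < threshold_hu:
        raise EmptySegmentationError(
            f"no voxel reaches threshold {threshold_hu} HU (max {vmax:.1f} HU)"
        )
    if vmax == threshold_hu:
        raise EmptySegmentationError(
            f"threshold {threshold_hu} HU sits exactly at the volume maximum; "
            f"the iso-surface is degenerate (zero volume)"
        )

    dx, dy, dz = volume.spacing
    if method == "subvoxel":
        field = np.pad(voxels.astype(np.float64), 1, constant_values=HU_MIN)
        level = float(threshold_hu)
    else:
        mask = (voxels >= threshold_hu).astype(np.float64)
        field = np.pad(mask, 1, constant_values=0.0)
        level = 0.5
    verts, faces, _, _ = measure.marching_cubes(
        field, level=level, spacing=(dz, dy, dx)
    )
    ox, oy, oz = volume.origin
    verts_xyz = np.column_stack(
        [verts[:, 2] + ox - dx, verts[:, 1] + oy - dy, verts[:, 0] + oz - dz]
    )
    mesh = TriMesh(verts_xyz, faces.astype(np.int64))
    if signed_volume(mesh) < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])

    components = _split_components(mesh)
    n_components = len(components)
    if island_policy == "largest_component" and n_components > 1:
        mesh, _ = max(components, key=lambda cv: abs(cv[1]))
        if signed_volume(mesh) < 0:
            mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])

    metrics = MeshMetrics(
        volume_mm3=signed_volume(mesh),
        n_triangles=mesh.n_triangles,
        file_size_bytes=84 + 50 * mesh.n_triangles,
    )
    rel_err = (
        relative_volume_error(metrics.volume_mm3, reference_volume_mm3)
        if reference_volume_mm3
        else float("nan")
    )
    return SegmentationResult(
        mesh=mesh,
        threshold_hu=float(threshold_hu),
        island_policy=island_policy,
        metrics=metrics,
        rel_volume_error_pct=rel_err,
        n_components=n_components,
    )
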