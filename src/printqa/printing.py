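"""Simulated fused-filament (FFF) printing of a mesh.

Two deformation mechanisms dominate desktop FFF accuracy and are modelled
here, both as smooth vertex displacements that keep the mesh watertight:

* the *layer staircase*: surface heights are pulled halfway toward the
  floor of their extrusion layer (full snapping would self-intersect);
* *warping*: thermal shrinkage peels the part's base edges off the build
  plate; the lift is strongest at the footprint boundary (corners and
  edges), decays toward the interior with a lateral decay length, and
  fades out vertically over the affected zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .errors import SelfIntersectionError
from .mesh import TriMesh


@dataclass(frozen=True)
class PrintSpec:
    """FFF printer behaviour: layer height and the warping parameters.

    ``warp_amplitude_mm`` ~= 0 models a well-adhering printer; values around
    1.0-1.5 mm reproduce the pronounced lift-off of a poorly adhering one.
    """

    layer_height_mm: float = 0.3
    warp_amplitude_mm: float = 0.0
    warp_decay_mm: float = 10.0  # lateral decay of edge lift-off
    warp_height_mm: float = 5.0  # vertical extent of the affected zone
    seed: int = 0

    def __post_init__(self):
        if self.layer_height_mm <= 0:
            raise ValueError("layer_height_mm must be positive")
        if self.warp_amplitude_mm < 0:
            raise ValueError("warp_amplitude_mm must be >= 0")
        if self.warp_decay_mm <= 0 or self.warp_height_mm <= 0:
            raise ValueError("warp decay and height must be positive")


def _footprint_boundary(mesh: TriMesh, z_section: float):
    """Boundary of the base footprint as a shapely geometry, or None."""
    tm = mesh.to_trimesh()
    section = tm.section_multiplane(
        plane_origin=[0.0, 0.0, 0.0],
        plane_normal=[0.0, 0.0, 1.0],
        heights=[z_section],
    )[0]
    if section is None:
        return None
    rings = [p for p in section.polygons_closed if p is not None]
    if not rings:
        return None
    to_3d = section.metadata["to_3D"]
    boundaries = []
    for ring in rings:
        coords2 = np.asarray(ring.exterior.coords)
        coords3 = coords2 @ to_3d[:2, :2].T + to_3d[:2, 3]
        boundaries.append(shapely.LineString(coords3))
    geom = shapely.union_all(boundaries)
    shapely.prepare(geom)
    return geom


def simulate_print(mesh: TriMesh, spec: PrintSpec) -> TriMesh:
    """Return a deformed copy of ``mesh`` as the printer would produce it.

    The base plane is z = z_min of the input. Raises
    :class:`SelfIntersectionError` when ``warp_amplitude_mm`` exceeds
    ``warp_height_mm`` (the lifted base would fold through the layers above).
    """
    if spec.warp_amplitude_mm > spec.warp_height_mm:
        raise SelfIntersectionError(
            f"warp amplitude {spec.warp_amplitude_mm} mm exceeds the affected "
            f"zone height {spec.warp_height_mm} mm; the deformation would "
            f"self-intersect"
        )
    v = mesh.vertices.copy()
    z_min = v[:, 2].min()
    h = spec.layer_height_mm

    # layer staircase: blend halfway toward the layer floor
    layer_floor = z_min + np.floor((v[:, 2] - z_min) / h) * h
    v[:, 2] = 0.5 * v[:, 2] + 0.5 * layer_floor

    if spec.warp_amplitude_mm > 0:
        boundary = _footprint_boundary(mesh, z_min + 0.5 * h)
        if boundary is not None:
            affected = v[:, 2] < z_min + spec.warp_height_mm
            pts = shapely.points(v[affected, 0], v[affected, 1])
            d_interior = shapely.distance(pts, boundary)
            vertical = np.maximum(
                0.0, 1.0 - (v[affected, 2] - z_min) / spec.warp_height_mm
            )
            lift = (
                spec.warp_amplitude_mm
                * np.exp(-d_interior / spec.warp_decay_mm)
                * vertical
            )
            v[affected, 2] += lift
    return TriMesh(v, mesh.faces.copy())
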