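"""Triangle-mesh data model, STL I/O, and the volume / complexity metrics.

All coordinates are millimetres. Vertices are kept at float64 internally;
the 32-bit quantisation that the STL format mandates happens only at
serialisation time, so multi-stage pipelines do not accumulate rounding.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from .errors import NotWatertightError, STLFormatError

log = logging.getLogger(__name__)

_STL_HEADER_BYTES = 80
_STL_RECORD_BYTES = 50
_STL_COUNT_BYTES = 4

_record_dtype = np.dtype(
    [("normal", "<f4", (3,)), ("vertices", "<f4", (3, 3)), ("attr", "<u2")]
)
assert _record_dtype.itemsize == _STL_RECORD_BYTES


@dataclass
class TriMesh:
    """Triangulated surface: ``vertices`` (n, 3) in mm, ``faces`` (m, 3) indices.

    Faces are wound counter-clockwise seen from outside, so the signed
    enclosed volume of a valid solid is positive.
    """

    vertices: np.ndarray
    faces: np.ndarray
    _tm_cache: object = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")
        if len(self.faces) and self.faces.max(initial=-1) >= len(self.vertices):
            raise ValueError("face index out of range")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_triangles(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """(m, 3, 3) coordinates of each face's corners."""
        return self.vertices[self.faces]

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) min/max corner of the axis-aligned bounding box."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    @property
    def extents(self) -> np.ndarray:
        b = self.bounds
        return b[1] - b[0]

    def copy(self) -> "TriMesh":
        return TriMesh(self.vertices.copy(), self.faces.copy())

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriMesh":
        """Apply a rigid motion ``x -> R x + t`` and return a new mesh."""
        r = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return TriMesh(self.vertices @ r.T + t, self.faces.copy())

    def open_edge_count(self) -> int:
        """Number of edges not shared by exactly two faces."""
        edges = np.sort(
            self.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int(np.count_nonzero(counts != 2))

    @property
    def is_watertight(self) -> bool:
        return self.n_triangles > 0 and self.open_edge_count() == 0

    def to_trimesh(self):
        """Cached conversion to a :class:`trimesh.Trimesh` (no processing)."""
        if self._tm_cache is None:
            import trimesh

            self._tm_cache = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._tm_cache

    @classmethod
    def from_trimesh(cls, tm) -> "TriMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces))


@dataclass(frozen=True)
class MeshMetrics:
    """Size and complexity summary of one mesh.

    ``file_size_bytes`` is the binary-STL size proxy Fi = 84 + 50 * n_triangles,
    proportional to the polygon count that the STL would store on disk.
    """

    volume_mm3: float
    n_triangles: int
    file_size_bytes: int

    @classmethod
    def of(cls, mesh: TriMesh) -> "MeshMetrics":
        return cls(
            volume_mm3=mesh_volume(mesh),
            n_triangles=mesh.n_triangles,
            file_size_bytes=file_size_proxy(mesh),
        )


def signed_volume(mesh: TriMesh) -> float:
    """Signed enclosed volume (divergence theorem); no watertightness check."""
    t = mesh.triangles
    return float(
        np.einsum("ij,ij->i", t[:, 0], np.cross(t[:, 1], t[:, 2])).sum() / 6.0
    )


def mesh_volume(mesh: TriMesh) -> float:
    """Enclosed volume in mm3 of a watertight, outward-wound mesh.

    Raises :class:`NotWatertightError` naming the open-edge count otherwise.
    """
    n_open = mesh.open_edge_count()
    if n_open or mesh.n_triangles == 0:
        raise NotWatertightError(max(n_open, 1), context="mesh for volume")
    return signed_volume(mesh)


def file_size_proxy(mesh: TriMesh) -> int:
    """Binary-STL on-disk size in bytes: 80-byte header + count + 50 per triangle."""
    return _STL_HEADER_BYTES + _STL_COUNT_BYTES + _STL_RECORD_BYTES * mesh.n_triangles


# -- STL serialisation -----------------------------------------------------

def _face_normals(tri: np.ndarray) -> np.ndarray:
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        n = np.where(norm > 0, n / norm, 0.0)
    return n


def save_stl(mesh: TriMesh, path: Union[str, Path], mode: str = "binary") -> None:
    """Write ``mesh`` to ``path`` as binary (default) or ASCII STL."""
    path = Path(path)
    tri = mesh.triangles
    normals = _face_normals(tri)
    if mode == "binary":
        records = np.zeros(len(tri), dtype=_record_dtype)
        records["normal"] = normals.astype(np.float32)
        records["vertices"] = tri.astype(np.float32)
        header = b"printqa binary STL".ljust(_STL_HEADER_BYTES, b" ")
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(struct.pack("<I", len(tri)))
            fh.write(records.tobytes())
    elif mode == "ascii":
        with open(path, "w") as fh:
            fh.write("solid printqa\n")
            for nrm, t in zip(normals, tri):
                fh.write(f"  facet normal {nrm[0]:.9e} {nrm[1]:.9e} {nrm[2]:.9e}\n")
                fh.write("    outer loop\n")
                for v in t:
                    fh.write(f"      vertex {v[0]:.9e} {v[1]:.9e} {v[2]:.9e}\n")
                fh.write("    endloop\n")
                fh.write("  endfacet\n")
            fh.write("endsolid printqa\n")
    else:
        raise ValueError(f"unknown STL mode {mode!r}")


def _mesh_from_triangle_soup(tri: np.ndarray) -> TriMesh:
    """Merge exactly-duplicate vertices and drop degenerate faces."""
    flat = tri.reshape(-1, 3)
    vertices, inverse = np.unique(flat, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    # degenerate: repeated indices or (numerically) zero area
    repeated = (
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 2] == faces[:, 0])
    )
    t = vertices[faces]
    area2 = np.linalg.norm(np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0]), axis=1)
    degenerate = repeated | (area2 <= 0.0)
    n_dropped = int(degenerate.sum())
    if n_dropped:
        log.info("dropped %d degenerate STL triangle(s) on load", n_dropped)
        faces = faces[~degenerate]
    return TriMesh(vertices.astype(np.float64), faces)


def _parse_ascii_stl(text: str) -> TriMesh:
    coords = []
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("vertex"):
            parts = line.split()
            if len(parts) != 4:
                raise STLFormatError(f"malformed ASCII vertex line: {line!r}")
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
    if len(coords) % 3 != 0:
        raise STLFormatError("ASCII STL vertex count is not a multiple of 3")
    tri = np.asarray(coords, dtype=np.float64).reshape(-1, 3, 3)
    return _mesh_from_triangle_soup(tri)


def load_stl(path: Union[str, Path]) -> TriMesh:
    """Load an STL file, auto-detecting the binary and ASCII dialects.

    Exact duplicate vertices are merged and degenerate (zero-area) triangles
    are dropped with a logged count. A binary file whose length disagrees
    with its declared triangle count raises :class:`STLFormatError`.
    """
    data = Path(path).read_bytes()
    if data[:5] == b"solid":
        try:
            text = data.decode("ascii")
        except UnicodeDecodeError:
            text = None
        if text is not None and "facet" in text:
            return _parse_ascii_stl(text)
        if text is not None and "endsolid" in text:
            # header-only ASCII solid: empty mesh
            return TriMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64))
    if len(data) < _STL_HEADER_BYTES + _STL_COUNT_BYTES:
        raise STLFormatError(f"file too short for binary STL ({len(data)} bytes)")
    (count,) = struct.unpack_from("<I", data, _STL_HEADER_BYTES)
    expected = _STL_HEADER_BYTES + _STL_COUNT_BYTES + _STL_RECORD_BYTES * count
    if len(data) != expected:
        raise STLFormatError(
            f"binary STL length {len(data)} does not match 84 + 50 x {count} "
            f"= {expected} bytes (truncated or corrupt)"
        )
    records = np.frombuffer(
        data, dtype=_record_dtype, count=count, offset=_STL_HEADER_BYTES + _STL_COUNT_BYTES
    )
    tri = records["vertices"].astype(np.float64)
    return _mesh_from_triangle_soup(tri)
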