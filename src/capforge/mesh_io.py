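"""Surface-mesh and volume I/O.

Formats: binary/ASCII STL, OFF, OBJ (geometry only), JMesh (plain-array JSON
form with ``MeshVertex3``/``MeshTri3`` keys, 1-based indices) and NIfTI
(.nii/.nii.gz). All coordinates are millimeters internally; OBJ/OFF files are
assumed to be in millimeters.

Reads never silently change topology: STL per-facet vertices are merged only
when bit-identical; tolerance-based welding is an explicit operation in
:mod:`capforge.printable`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import trimesh

from .errors import ParseError, ValidationError
from .geometry import weld_vertices

__all__ = [
    "VolumeImage",
    "PolyMesh",
    "read_mesh",
    "write_mesh",
    "read_volume",
    "write_volume",
    "MESH_FORMATS",
]

MESH_FORMATS = ("stl", "off", "obj", "jmesh")

_EXTENSIONS = {
    ".stl": "stl",
    ".off": "off",
    ".obj": "obj",
    ".jmsh": "jmesh",
    ".jmesh": "jmesh",
    ".json": "jmesh",
}


@dataclass
class PolyMesh:
    """General polygonal mesh: faces are index lists of length >= 3."""

    vertices: np.ndarray
    faces: list[list[int]]

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        nv = len(self.vertices)
        for f in self.faces:
            if len(f) < 3:
                raise ValidationError("polygon face with fewer than 3 vertices")
            if min(f) < 0 or max(f) >= nv:
                raise ValidationError("polygon face index out of range")

    def triangulated(self) -> trimesh.Trimesh:
        """Fan-triangulate every polygon about its centroid (planar within
        tolerance by construction of the dual transform)."""
        verts = [self.vertices]
        tris = []
        next_idx = len(self.vertices)
        for f in self.faces:
            if len(f) == 3:
                tris.append(list(f))
                continue
            centroid = self.vertices[f].mean(axis=0)
            verts.append(centroid[None, :])
            for i in range(len(f)):
                tris.append([f[i], f[(i + 1) % len(f)], next_idx])
            next_idx += 1
        return trimesh.Trimesh(
            vertices=np.vstack(verts), faces=np.asarray(tris), process=False
        )


@dataclass
class VolumeImage:
    """3D scalar or integer-label grid with physical voxel size (mm)."""

    array: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.array = np.asarray(self.array)
        if self.array.ndim != 3 or self.array.size == 0:
            raise ValidationError("volume must be a non-empty 3D array")
        self.voxel_size = np.asarray(self.voxel_size, dtype=float).reshape(3)
        if np.any(self.voxel_size <= 0):
            raise ValidationError("voxel sizes must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def is_label_map(self) -> bool:
        return np.issubdtype(self.array.dtype, np.integer)


def _resolve_format(path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in MESH_FORMATS:
            raise ValidationError(f"unknown mesh format {fmt!r}")
        return fmt
    ext = Path(path).suffix.lower()
    if ext not in _EXTENSIONS:
        raise ValidationError(
            f"cannot infer mesh format from extension {ext!r}; pass format="
        )
    return _EXTENSIONS[ext]


def read_mesh(path, format: str | None = None) -> trimesh.Trimesh:
    """Read a triangle mesh; vertices merged only for per-facet formats (STL,
    bit-identical coordinates)."""
    fmt = _resolve_format(path, format)
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"mesh file not found: {path}")
    try:
        if fmt == "jmesh":
            return _read_jmesh(path)
        mesh = trimesh.load(str(path), file_type=fmt, process=False,
                            force="mesh")
    except (ValidationError, ParseError):
        raise
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise ParseError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise ParseError(f"{path} contains no triangle geometry")
    vertices = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=np.int64)
    if fmt == "stl":
        vertices, faces = weld_vertices(vertices, faces, tolerance=0.0)
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


def _read_jmesh(path: Path) -> trimesh.Trimesh:
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(
            f"failed to parse {path} as JMesh: invalid JSON at line "
            f"{exc.lineno}, column {exc.colno}"
        ) from exc
    if "MeshVertex3" not in data or "MeshTri3" not in data:
        raise ParseError(
            f"{path}: JMesh requires MeshVertex3 and MeshTri3 arrays "
            "(plain-array dialect)"
        )
    verts = np.asarray(data["MeshVertex3"], dtype=float)
    tris = np.asarray(data["MeshTri3"], dtype=np.int64)
    if verts.ndim != 2 or verts.shape[1] != 3:
        raise ParseError(f"{path}: MeshVertex3 must be an n-by-3 array")
    if tris.ndim != 2 or tris.shape[1] != 3:
        raise ParseError(f"{path}: MeshTri3 must be an n-by-3 array")
    if tris.min(initial=1) < 1 or tris.max(initial=1) > len(verts):
        raise ParseError(f"{path}: MeshTri3 indices out of 1-based range")
    return trimesh.Trimesh(vertices=verts, faces=tris - 1, process=False)


def write_mesh(mesh: trimesh.Trimesh, path, format: str | None = None,
               binary: bool = True) -> Path:
    """Write a triangle mesh. STL is binary by default."""
    fmt = _resolve_format(path, format)
    path = Path(path)
    if len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise ValidationError("refusing to write an empty mesh")
    if fmt == "jmesh":
        data = {
            "_DataInfo_": {"JMeshVersion": "0.5", "Dimension": 3},
            "MeshVertex3": np.asarray(mesh.vertices, dtype=float).tolist(),
            "MeshTri3": (np.asarray(mesh.faces, dtype=np.int64) + 1).tolist(),
        }
        path.write_text(json.dumps(data))
        return path
    if fmt == "stl":
        file_type = "stl" if binary else "stl_ascii"
    else:
        file_type = fmt
    data = trimesh.exchange.export.export_mesh(mesh, None, file_type=file_type)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
    return path


def read_volume(path) -> VolumeImage:
    """Read a NIfTI volume; integer dtypes are treated as label maps."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"volume file not found: {path}")
    try:
        img = nib.load(str(path))
        array = np.asanyarray(img.dataobj)
    except Exception as exc:  # noqa: BLE001
        raise ParseError(f"failed to parse {path} as NIfTI: {exc}") from exc
    array = np.squeeze(array) if array.ndim == 4 and array.shape[-1] == 1 else array
    if array.ndim != 3:
        raise ValidationError(
            f"{path}: expected a 3D volume, got {array.ndim}D"
        )
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return VolumeImage(array=array, voxel_size=zooms, origin=origin)


def write_volume(volume: VolumeImage, path) -> Path:
    path = Path(path)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(volume.voxel_size)
    affine[:3, 3] = volume.origin
    arr = volume.array
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, affine), str(path))
    return path
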