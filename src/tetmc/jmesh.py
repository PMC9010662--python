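"""JSON mesh (JMesh) and JSON/NIfTI volume I/O.

JMesh is a set of JSON name/value conventions for mesh data: ``MeshVertex3``
holds an Nn x 3 vertex table, ``MeshTri3`` an Nt x 3 triangle table and
``MeshTet4`` an Ne x 4 tetrahedron table (optionally with a 5th per-element
region-label column).  Node indices are **1-based in files**; this module
converts to the package-wide 0-based convention exactly once, at read/write
time.

Three array dialects are supported and decode to identical ndarrays:

* *plain* — nested JSON lists;
* *annotated* — a JData typed-array object with ``_ArrayType_``,
  ``_ArraySize_`` and a row-major ``_ArrayData_`` payload;
* *compressed* — as annotated, but the row-major payload is zlib-compressed
  and base64-encoded under ``_ArrayZipData_`` (``_ArrayZipType_: "zlib"``).

Labeled volumes are read from NIfTI-1 (via nibabel) or text JNIfTI (.jnii).
"""

from __future__ import annotations

import base64
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MeshDocument",
    "LabeledVolume",
    "JMeshError",
    "read_mesh_document",
    "write_mesh_document",
    "read_volume",
    "write_jnii",
    "write_fluence",
    "read_off",
]

_VERTEX_KEY = "MeshVertex3"
_TRI_KEY = "MeshTri3"
_TET_KEY = "MeshTet4"
_POLYLINE_KEY = "MeshPolyLine"
_NODEVAL_KEY = "MeshNodeVal"
_NODEVAL_LOG10_KEY = "MeshNodeValLog10"
# the log-10 display field rides in metadata verbatim (a derived view of
# node_data, not an independent construct)
_MESH_KEYS = (_VERTEX_KEY, _TRI_KEY, _TET_KEY, _POLYLINE_KEY, _NODEVAL_KEY)

_JTYPE_TO_DTYPE = {
    "double": np.float64, "single": np.float32,
    "int8": np.int8, "int16": np.int16, "int32": np.int32, "int64": np.int64,
    "uint8": np.uint8, "uint16": np.uint16, "uint32": np.uint32,
    "uint64": np.uint64,
}


class JMeshError(ValueError):
    """Raised for malformed, inconsistent, or invalid JMesh content."""


@dataclass
class MeshDocument:
    """In-memory JMesh content; indices 0-based, coordinates in mm."""

    vertices: np.ndarray                      # (Nn, 3) float
    triangles: np.ndarray                     # (Nt, 3) int, 0-based
    tetrahedra: np.ndarray                    # (Ne, 4) int, 0-based
    tet_labels: np.ndarray | None = None      # (Ne,) nonnegative int
    node_data: np.ndarray | None = None       # (Nn,) or (Nn, ngates) float
    polylines: list[np.ndarray] = field(default_factory=list)  # 0-based runs
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        nn = len(self.vertices)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise JMeshError("vertices must be an Nn x 3 array")
        if not np.all(np.isfinite(self.vertices)):
            bad = np.argwhere(~np.isfinite(self.vertices))[0]
            raise JMeshError(
                f"non-finite vertex coordinate at row {bad[0]}, column {bad[1]}")
        for name, arr, width in (("triangles", self.triangles, 3),
                                 ("tetrahedra", self.tetrahedra, 4)):
            if arr.size == 0:
                continue
            if arr.ndim != 2 or arr.shape[1] != width:
                raise JMeshError(f"{name} must have {width} columns")
            if arr.min() < 0 or arr.max() >= nn:
                rows = np.where((arr < 0) | (arr >= nn))[0]
                raise JMeshError(
                    f"{name} rows {rows[:10].tolist()} reference nodes outside "
                    f"[1, {nn}] (file convention)")
        for run in self.polylines:
            if run.min() < 0 or run.max() >= nn:
                raise JMeshError("polyline references nodes out of range")
        if self.tet_labels is not None:
            if len(self.tet_labels) != len(self.tetrahedra):
                raise JMeshError("label column length mismatch")
            if self.tet_labels.min() < 0:
                raise JMeshError("region labels must be nonnegative integers")
        if self.node_data is not None and len(self.node_data) != nn:
            raise JMeshError(
                f"node_data length {len(self.node_data)} != node count {nn}")


@dataclass
class LabeledVolume:
    """Integer-labeled voxel volume; label 0 is background."""

    voxels: np.ndarray          # (nx, ny, nz) int
    voxel_size: float           # mm per voxel edge (isotropic)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")


# ---------------------------------------------------------------------------
# array dialect encode/decode

def _decode_array(obj, key: str) -> np.ndarray:
    """Decode plain / annotated / compressed JData array representations."""
    if isinstance(obj, list):
        return np.asarray(obj)
    if not isinstance(obj, dict):
        raise JMeshError(f"{key}: unsupported array representation "
                         f"({type(obj).__name__})")
    try:
        shape = tuple(int(s) for s in np.atleast_1d(obj["_ArraySize_"]))
        dtype = _JTYPE_TO_DTYPE[obj["_ArrayType_"]]
    except KeyError as exc:
        raise JMeshError(f"{key}: annotated array missing {exc}") from None
    n_expected = int(np.prod(shape))
    if "_ArrayZipData_" in obj:
        ziptype = obj.get("_ArrayZipType_", "zlib")
        if ziptype != "zlib":
            raise JMeshError(f"{key}: unsupported _ArrayZipType_ {ziptype!r}")
        raw = zlib.decompress(base64.b64decode(obj["_ArrayZipData_"]))
        flat = np.frombuffer(raw, dtype=dtype)
    elif "_ArrayData_" in obj:
        flat = np.asarray(obj["_ArrayData_"], dtype=dtype).ravel()
    else:
        raise JMeshError(f"{key}: annotated array carries no payload")
    if flat.size != n_expected:
        raise JMeshError(
            f"{key}: size tag {list(shape)} implies {n_expected} elements "
            f"but payload holds {flat.size}")
    return flat.reshape(shape, order="C")


def _encode_array(arr: np.ndarray, dialect: str):
    arr = np.ascontiguousarray(arr)
    if dialect == "plain":
        return arr.tolist()
    if np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float64)
        jtype = "double"
    else:
        arr = arr.astype(np.int32)
        jtype = "int32"
    out = {"_ArrayType_": jtype, "_ArraySize_": list(arr.shape)}
    if dialect == "annotated":
        out["_ArrayData_"] = arr.ravel(order="C").tolist()
    elif dialect == "compressed":
        payload = zlib.compress(arr.ravel(order="C").tobytes())
        out["_ArrayZipType_"] = "zlib"
        out["_ArrayZipSize_"] = list(arr.shape)
        out["_ArrayZipData_"] = base64.b64encode(payload).decode("ascii")
    else:
        raise ValueError(f"unknown dialect {dialect!r} "
                         "(expected plain|annotated|compressed)")
    return out


# ---------------------------------------------------------------------------
# mesh documents

def _load_json(path_or_text) -> dict:
    text = str(path_or_text)
    if not text.lstrip().startswith(("{", "[")):
        text = Path(path_or_text).read_text()
    try:
        return json.loads(text)
    except json.JSONDecodeError as exc:
        raise JMeshError(
            f"malformed JSON at byte offset {exc.pos}: {exc.msg}") from exc


def read_mesh_document(path_or_text) -> MeshDocument:
    """Read a JMesh document from a file path or raw JSON text.

    All three array dialects decode to identical arrays; node indices are
    converted from the 1-based file convention to 0-based here.
    """
    root = _load_json(path_or_text)
    if not isinstance(root, dict):
        raise JMeshError("top-level JMesh construct must be a JSON object")

    metadata = {k: v for k, v in root.items() if k not in _MESH_KEYS}

    vertices = np.zeros((0, 3), dtype=np.float64)
    if _VERTEX_KEY in root:
        vertices = np.atleast_2d(
            _decode_array(root[_VERTEX_KEY], _VERTEX_KEY)).astype(np.float64)

    def _index_table(key, width):
        if key not in root:
            return np.zeros((0, width), dtype=np.int64), None
        arr = np.atleast_2d(_decode_array(root[key], key))
        if not np.issubdtype(arr.dtype, np.number) or \
                np.any(arr != np.round(arr)):
            raise JMeshError(f"{key}: indices must be integers")
        arr = arr.astype(np.int64)
        labels = None
        if key == _TET_KEY and arr.shape[1] == width + 1:
            labels = arr[:, width].copy()
            arr = arr[:, :width]
        if arr.shape[1] != width:
            raise JMeshError(f"{key} must have {width} (or {width + 1}) columns")
        return arr - 1, labels  # 1-based file -> 0-based memory

    triangles, _ = _index_table(_TRI_KEY, 3)
    tetrahedra, tet_labels = _index_table(_TET_KEY, 4)

    node_data = None
    if _NODEVAL_KEY in root:
        node_data = np.asarray(
            _decode_array(root[_NODEVAL_KEY], _NODEVAL_KEY), dtype=np.float64)

    polylines = []
    if _POLYLINE_KEY in root:
        runs = root[_POLYLINE_KEY]
        if isinstance(runs, dict) or (runs and not isinstance(runs[0], list)):
            runs = [runs]
        for run in runs:
            polylines.append(np.asarray(run, dtype=np.int64) - 1)

    doc = MeshDocument(vertices=vertices, triangles=triangles,
                       tetrahedra=tetrahedra, tet_labels=tet_labels,
                       node_data=node_data, polylines=polylines,
                       metadata=metadata)
    doc.validate()
    return doc


def write_mesh_document(doc: MeshDocument, path, dialect: str = "plain") -> Path:
    """Write *doc* as a JMesh file; indices are written 1-based."""
    doc.validate()
    root: dict = {}
    root.update(doc.metadata)
    if len(doc.vertices):
        root[_VERTEX_KEY] = _encode_array(doc.vertices, dialect)
    if len(doc.triangles):
        root[_TRI_KEY] = _encode_array(doc.triangles + 1, dialect)
    if len(doc.tetrahedra):
        tets = doc.tetrahedra + 1
        if doc.tet_labels is not None:
            tets = np.column_stack([tets, doc.tet_labels])
        root[_TET_KEY] = _encode_array(tets, dialect)
    if doc.node_data is not None:
        root[_NODEVAL_KEY] = _encode_array(
            np.asarray(doc.node_data, dtype=np.float64), dialect)
    if doc.polylines:
        root[_POLYLINE_KEY] = [(run + 1).tolist() for run in doc.polylines]
    path = Path(path)
    path.write_text(json.dumps(root))
    return path


# ---------------------------------------------------------------------------
# labeled volumes (NIfTI / JNIfTI)

def read_volume(path) -> LabeledVolume:
    """Read a labeled volume from .nii/.nii.gz (NIfTI-1) or .jnii (JNIfTI).

    Non-integer voxel data are rejected (labels are never rounded), as are
    anisotropic voxel sizes.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        origin = tuple(float(v) for v in img.affine[:3, 3])
    elif name.endswith(".jnii"):
        root = _load_json(path)
        try:
            hdr = root["NIFTIHeader"]
            data = _decode_array(root["NIFTIData"], "NIFTIData")
        except KeyError as exc:
            raise JMeshError(f"JNIfTI file missing {exc}") from None
        zooms = tuple(float(v) for v in hdr.get("VoxelSize", [1, 1, 1])[:3])
        origin = tuple(float(v) for v in hdr.get("Origin", [0, 0, 0])[:3])
        dim = hdr.get("Dim")
        if dim is not None and tuple(int(d) for d in dim) != data.shape:
            raise JMeshError(
                f"JNIfTI Dim {dim} inconsistent with data shape {data.shape}")
    else:
        raise JMeshError(
            f"unsupported volume format {path.suffix!r}; accepted formats: "
            ".nii, .nii.gz (NIfTI-1), .jnii (text JNIfTI)")

    if data.ndim != 3:
        raise JMeshError(f"expected a 3-D volume, got shape {data.shape}")
    if not np.allclose(zooms, zooms[0], rtol=0, atol=1e-9):
        raise JMeshError(f"anisotropic voxels {zooms} are not supported")
    fdata = np.asarray(data, dtype=np.float64)
    if np.any(fdata != np.round(fdata)):
        raise JMeshError("volume is not integer-valued; refusing to round "
                         "continuous data into labels")
    return LabeledVolume(voxels=np.asarray(np.round(fdata), dtype=np.int32),
                         voxel_size=float(zooms[0]), origin=origin)


def write_jnii(vol: LabeledVolume, path, dialect: str = "plain") -> Path:
    """Write a LabeledVolume as a text JNIfTI (.jnii) file."""
    root = {
        "NIFTIHeader": {
            "Dim": list(vol.voxels.shape),
            "VoxelSize": [vol.voxel_size] * 3,
            "Origin": list(vol.origin),
            "DataType": "int32",
        },
        "NIFTIData": _encode_array(vol.voxels.astype(np.int32), dialect),
    }
    path = Path(path)
    path.write_text(json.dumps(root))
    return path


# ---------------------------------------------------------------------------
# fluence output

def write_fluence(mesh, fluence, path, floor: float = 1e-12,
                  dialect: str = "plain") -> Path:
    """Write a fluence map over a tetrahedral mesh as a JMesh file.

    The raw per-node values are stored as node data and a companion field
    stores the log-10 display transform ``log10(max(value, floor))``.
    """
    from .mcsim import FluenceMap, log10_display

    values = fluence.values if isinstance(fluence, FluenceMap) else \
        np.asarray(fluence, dtype=np.float64)
    if values.ndim == 1:
        values = values[:, None]
    if len(values) != len(mesh.node):
        raise JMeshError(
            f"fluence length {len(values)} != mesh node count {len(mesh.node)}")
    display = log10_display(values, floor)
    doc = MeshDocument(
        vertices=np.asarray(mesh.node, dtype=np.float64),
        triangles=np.asarray(mesh.face, dtype=np.int64),
        tetrahedra=np.asarray(mesh.elem, dtype=np.int64),
        tet_labels=np.asarray(mesh.labels, dtype=np.int64),
        node_data=values[:, 0] if values.shape[1] == 1 else values,
        metadata={_NODEVAL_LOG10_KEY: _encode_array(display, dialect)},
    )
    return write_mesh_document(doc, path, dialect=dialect)


def read_off(path) -> tuple[np.ndarray, np.ndarray]:
    """Import a triangular surface from an OFF file (convenience).

    Returns (vertices, faces) with 0-based faces.
    """
    import trimesh

    tm = trimesh.load(str(path), file_type="off", process=False)
    return (np.asarray(tm.vertices, dtype=np.float64),
            np.asarray(tm.faces, dtype=np.int64))
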