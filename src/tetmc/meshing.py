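"""Labeled tetrahedral meshing of scenes and voxel volumes.

Meshes are produced on a rectilinear body lattice: each grid cell is split
into 6 tetrahedra around the cell's main diagonal (the Freudenthal/Kuhn
subdivision).  Using the same diagonal orientation in every cell makes the
global triangulation face-conforming without Steiner points: the diagonal
induced on any shared cube face is identical from both sides.

Element labels come from the scene's point-membership predicate evaluated at
tetrahedron centroids (scene path) or are inherited from voxels (volume
path).  Curved boundaries are therefore rendered at lattice resolution; the
pitch follows from the maximum-element-volume bound as h = (6 Vmax)^(1/3),
so every lattice tetrahedron has volume h^3/6 <= Vmax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .scene import RegionScene, label_points, scene_interfaces_z

__all__ = [
    "TetMesh", "SurfMesh", "MeshingOptions", "MeshingError",
    "cube_to_tets", "tetrahedralize_scene", "volume_to_tetmesh",
    "extract_region_surface", "boundary_faces", "mesh_metrics",
    "tet_volumes",
]


class MeshingError(ValueError):
    pass


@dataclass
class SurfMesh:
    """Triangular surface shell: vertices (mm) + 0-based face triples."""

    vertices: np.ndarray
    faces: np.ndarray


@dataclass
class TetMesh:
    """Labeled tetrahedral mesh: the node/face/elem triplet.

    ``node`` is (Nn, 3) in mm; ``elem`` is (Ne, 4) 0-based node indices with
    positive orientation; ``labels`` is the per-element region id; ``face``
    is the domain-boundary triangle set (each belonging to exactly one
    element).
    """

    node: np.ndarray
    elem: np.ndarray
    labels: np.ndarray
    face: np.ndarray = field(default=None)  # computed lazily if None

    def __post_init__(self):
        self.node = np.asarray(self.node, dtype=np.float64)
        self.elem = np.asarray(self.elem, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.face is None:
            self.face = boundary_faces(self)
        else:
            self.face = np.asarray(self.face, dtype=np.int64)

    def validate(self) -> None:
        if self.elem.min() < 0 or self.elem.max() >= len(self.node):
            raise MeshingError("element indices out of range")
        vols = tet_volumes(self.node, self.elem)
        if np.any(vols <= 0):
            raise MeshingError(
                f"{np.sum(vols <= 0)} non-positively-oriented tetrahedra")
        referenced = np.zeros(len(self.node), dtype=bool)
        referenced[self.elem.ravel()] = True
        if not referenced.all():
            raise MeshingError(
                f"{np.sum(~referenced)} nodes are referenced by no element")
        if len(self.labels) != len(self.elem):
            raise MeshingError("label column length mismatch")

    @property
    def region_labels(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class MeshingOptions:
    """Element-size control: Vmax bounds every tetrahedron's volume."""

    max_tet_volume: float = 1.0 / 6.0   # cubic mm (or cubic model units)
    pitch_override: float | None = None  # mm; bypasses the Vmax->pitch map

    def __post_init__(self):
        if self.max_tet_volume <= 0:
            raise MeshingError("max_tet_volume must be > 0")

    @property
    def pitch(self) -> float:
        if self.pitch_override is not None:
            return float(self.pitch_override)
        return float((6.0 * self.max_tet_volume) ** (1.0 / 3.0))


def tet_volumes(node: np.ndarray, elem: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for canonical orientation)."""
    a = node[elem[:, 0]]
    d1 = node[elem[:, 1]] - a
    d2 = node[elem[:, 2]] - a
    d3 = node[elem[:, 3]] - a
    return np.einsum("ij,ij->i", np.cross(d1, d2), d3) / 6.0


# Freudenthal/Kuhn split of a cube whose 8 corners are indexed by the bit
# pattern (x<<2)|(y<<1)|z: six tetrahedra along the 0->7 main diagonal, one
# per permutation of the axis traversal order, each already positively
# oriented for an axis-aligned box.
_CUBE_TETS = np.array([
    [0, 4, 6, 7],
    [0, 6, 2, 7],
    [0, 2, 3, 7],
    [0, 3, 1, 7],
    [0, 1, 5, 7],
    [0, 5, 4, 7],
], dtype=np.int64)

# faces of a positively oriented tet (v0,v1,v2,v3) with outward normals
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]],
                      dtype=np.int64)


def cube_to_tets(corners: np.ndarray) -> TetMesh:
    """Split a rectangular box (8 corners, bit-pattern order) into 6 tets.

    The decomposition shares the main diagonal from corner 0 to corner 7 and
    adds no nodes; the induced boundary is 12 triangles (2 per face).
    """
    corners = np.asarray(corners, dtype=np.float64)
    if corners.shape != (8, 3):
        raise MeshingError("expected 8 corner points")
    edges = corners[7] - corners[0]
    if np.any(np.abs(edges) < 1e-12):
        raise MeshingError(f"degenerate box: edge lengths {edges}")
    mesh = TetMesh(node=corners, elem=_CUBE_TETS.copy(),
                   labels=np.ones(6, dtype=np.int32))
    vols = tet_volumes(mesh.node, mesh.elem)
    if np.any(vols <= 0):
        raise MeshingError("corner points do not form a canonical box")
    return mesh


def _lattice_axis(lo: float, hi: float, pitch: float,
                  snap: list[float] | None = None) -> np.ndarray:
    """Grid coordinates from lo to hi with spacing <= pitch, including any
    snap planes exactly."""
    cuts = sorted({lo, hi, *[z for z in (snap or []) if lo < z < hi]})
    coords = [cuts[0]]
    for a, b in zip(cuts[:-1], cuts[1:]):
        nseg = max(1, int(np.ceil((b - a) / pitch - 1e-12)))
        coords.extend(np.linspace(a, b, nseg + 1)[1:])
    return np.asarray(coords)


def _lattice_to_tets(xs, ys, zs) -> tuple[np.ndarray, np.ndarray]:
    """All 6-tet cells of a rectilinear lattice -> (nodes, elems)."""
    nx, ny, nz = len(xs), len(ys), len(zs)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    ci, cj, ck = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1),
                             np.arange(nz - 1), indexing="ij")
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()
    # cell corner ids in (x<<2)|(y<<1)|z bit order
    corner = np.stack([nid(ci + ((b >> 2) & 1), cj + ((b >> 1) & 1),
                           ck + (b & 1)) for b in range(8)], axis=1)
    elems = corner[:, _CUBE_TETS].reshape(-1, 4)
    return nodes, elems


def _compact(nodes: np.ndarray, elems: np.ndarray,
             labels: np.ndarray) -> TetMesh:
    used = np.unique(elems)
    remap = np.full(len(nodes), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TetMesh(node=nodes[used], elem=remap[elems], labels=labels)


def tetrahedralize_scene(scene: RegionScene,
                         opts: MeshingOptions | None = None) -> TetMesh:
    """Mesh a RegionScene on an interface-snapped body lattice.

    z-planes of layer interfaces are included in the grid exactly; each
    tetrahedron takes the label of its centroid; label-0 (outside) elements
    and unreferenced nodes are removed.  If any declared region captures no
    element at the requested pitch, the pitch is halved (up to 6 times) with
    a warning before giving up.
    """
    opts = opts or MeshingOptions()
    lo, hi = scene.bounds.bbox()
    zplanes = scene_interfaces_z(scene)
    pitch = opts.pitch
    declared = set(scene.labels)
    for attempt in range(7):
        xs = _lattice_axis(lo[0], hi[0], pitch)
        ys = _lattice_axis(lo[1], hi[1], pitch)
        zs = _lattice_axis(lo[2], hi[2], pitch, snap=zplanes)
        nodes, elems = _lattice_to_tets(xs, ys, zs)
        centroids = nodes[elems].mean(axis=1)
        labels = label_points(scene, centroids)
        keep = labels > 0
        if declared <= set(np.unique(labels[keep]).tolist()):
            mesh = _compact(nodes, elems[keep], labels[keep])
            mesh.validate()
            return mesh
        missing = sorted(declared - set(np.unique(labels[keep]).tolist()))
        if attempt < 6:
            warnings.warn(
                f"regions {missing} unresolved at pitch {pitch:.6g} mm; "
                "halving pitch", stacklevel=2)
            pitch /= 2.0
    raise MeshingError(
        f"regions {missing} still unresolved after 6 pitch halvings")


def volume_to_tetmesh(vol, opts: MeshingOptions | None = None) -> TetMesh:
    """Split every nonzero voxel of a LabeledVolume into 6 tetrahedra.

    Tetrahedra inherit their voxel's label; shared nodes are merged exactly
    (the lattice is built once, so conformity holds by construction);
    coordinates are voxel index * voxel_size + origin, mm.
    """
    voxels = np.asarray(vol.voxels)
    if not np.any(voxels):
        raise MeshingError("no foreground: volume contains no nonzero voxels")
    nx, ny, nz = voxels.shape
    h = vol.voxel_size
    xs = vol.origin[0] + h * np.arange(nx + 1)
    ys = vol.origin[1] + h * np.arange(ny + 1)
    zs = vol.origin[2] + h * np.arange(nz + 1)
    nodes, elems = _lattice_to_tets(xs, ys, zs)
    cell_labels = voxels.ravel(order="C")  # cell order matches meshgrid 'ij'
    labels = np.repeat(cell_labels, 6).astype(np.int32)
    keep = labels > 0
    mesh = _compact(nodes, elems[keep], labels[keep])
    mesh.validate()
    return mesh


def _face_key(faces: np.ndarray) -> np.ndarray:
    return np.sort(faces, axis=1)


def _unique_once_faces(elem: np.ndarray) -> np.ndarray:
    """Oriented faces that occur exactly once among the given elements."""
    faces = elem[:, _TET_FACES].reshape(-1, 3)
    keys = _face_key(faces)
    _, inverse, counts = np.unique(keys, axis=0, return_inverse=True,
                                   return_counts=True)
    return faces[counts[inverse] == 1]


def boundary_faces(mesh_or_elem) -> np.ndarray:
    """Triangles bounding the whole domain (owned by exactly one element),
    wound with outward normals."""
    elem = mesh_or_elem if isinstance(mesh_or_elem, np.ndarray) \
        else mesh_or_elem.elem
    return _unique_once_faces(elem)


def extract_region_surface(mesh: TetMesh, label: int) -> SurfMesh:
    """Closed triangle shell bounding one region's tetrahedra.

    The shell is watertight: every edge borders exactly two triangles.
    """
    sel = mesh.labels == label
    if not np.any(sel):
        raise MeshingError(
            f"label {label} not in mesh; available labels: "
            f"{mesh.region_labels.tolist()}")
    faces = _unique_once_faces(mesh.elem[sel])
    used = np.unique(faces)
    remap = np.full(len(mesh.node), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfMesh(vertices=mesh.node[used], faces=remap[faces])


def mesh_metrics(mesh: TetMesh) -> dict:
    """Deterministic mesh summary: counts and volumes, total and per label."""
    vols = tet_volumes(mesh.node, mesh.elem)
    per_label = {}
    for lab in mesh.region_labels:
        sel = mesh.labels == lab
        per_label[int(lab)] = {"elems": int(np.sum(sel)),
                               "volume": float(vols[sel].sum())}
    return {
        "nodes": len(mesh.node),
        "elems": len(mesh.elem),
        "boundary_triangles": len(mesh.face),
        "volume": float(vols.sum()),
        "min_tet_volume": float(vols.min()),
        "max_tet_volume": float(vols.max()),
        "per_label": per_label,
    }
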