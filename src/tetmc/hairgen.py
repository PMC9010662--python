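"""Hair-fiber geometry over a mesh surface: roots, tilt, randomness, bending.

Fibers are polylines grown from area-uniform random roots on a host surface.
Each fiber starts along its local surface normal, tilted by a fixed angle
toward a tilt axis, with an optional bounded random cone perturbation
("randomness" r: an extra rotation by an angle uniform in [0, r·90°] about a
uniform azimuth).  A deterministic gravity bend rotates successive segments
toward −z, preserving each segment's length (the bend is isometric and
root-preserving).  Geometry is exported as a JMesh polyline document for
downstream implicit-MC tools; the optical transport through hairs is out of
scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .jmesh import MeshDocument, write_mesh_document
from .meshing import SurfMesh

__all__ = [
    "HairSet", "HairParams", "sample_roots", "grow_hairs",
    "apply_gravity_bend", "export_hairs",
]


@dataclass
class HairParams:
    count: int = 1000
    length: float = 5.0            # mm, total fiber arc length
    segments: int = 8
    tilt_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    tilt_angle: float = 0.0        # degrees from the surface normal
    randomness: float = 0.0        # in [0, 1]; cone half-angle = r * 90 deg
    gravity: float = 0.0           # bend factor, >= 0
    seed: int = 0

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("hair count must be >= 1")
        if self.length <= 0:
            raise ValueError("hair length must be > 0")
        if self.segments < 1:
            raise ValueError("segments must be >= 1")
        if not 0.0 <= self.tilt_angle < 90.0:
            raise ValueError("tilt_angle must lie in [0, 90) degrees")
        if not 0.0 <= self.randomness <= 1.0:
            raise ValueError("randomness must lie in [0, 1]")
        if self.gravity < 0:
            raise ValueError("gravity must be >= 0")


@dataclass
class HairSet:
    fibers: list[np.ndarray]       # each (segments+1, 3), mm
    roots: np.ndarray              # (count, 3), on the host surface
    radius: float = 0.03           # uniform fiber radius, mm (metadata)
    metadata: dict = field(default_factory=dict)


def _triangle_areas(surface: SurfMesh) -> np.ndarray:
    v = surface.vertices[surface.faces]
    return 0.5 * np.linalg.norm(
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1)


def sample_roots(surface: SurfMesh, count: int, seed: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Area-uniform random points on a triangle surface.

    Triangles are chosen proportionally to area and points are uniform in
    barycentric coordinates.  Returns (roots, unit normals at each root).
    """
    if len(surface.faces) == 0:
        raise ValueError("cannot sample roots on an empty surface")
    rng = np.random.default_rng(seed)
    areas = _triangle_areas(surface)
    tri = rng.choice(len(areas), size=count, p=areas / areas.sum())
    u = rng.random(count)
    v = rng.random(count)
    flip = u + v > 1
    u[flip] = 1 - u[flip]
    v[flip] = 1 - v[flip]
    verts = surface.vertices[surface.faces[tri]]
    roots = (verts[:, 0] * (1 - u - v)[:, None] + verts[:, 1] * u[:, None]
             + verts[:, 2] * v[:, None])
    normals = np.cross(verts[:, 1] - verts[:, 0], verts[:, 2] - verts[:, 0])
    normals /= np.linalg.norm(normals, axis=1)[:, None]
    return roots, normals


def _rotate_toward(d: np.ndarray, target: np.ndarray,
                   angle: float) -> np.ndarray:
    """Rotate unit vector d toward unit vector target by *angle* radians,
    capped at the angle between them."""
    c = float(np.clip(d @ target, -1.0, 1.0))
    avail = np.arccos(c)
    if avail < 1e-12 or angle <= 0:
        return d
    ang = min(angle, avail)
    orth = target - c * d
    orth /= np.linalg.norm(orth)
    return np.cos(ang) * d + np.sin(ang) * orth


def _random_cone(d: np.ndarray, max_angle: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Random rotation of d by an angle uniform in [0, max_angle] about a
    uniform azimuth."""
    if max_angle <= 0:
        return d
    ang = rng.uniform(0.0, max_angle)
    az = rng.uniform(0.0, 2 * np.pi)
    # orthonormal frame around d
    a = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else \
        np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return (np.cos(ang) * d
            + np.sin(ang) * (np.cos(az) * e1 + np.sin(az) * e2))


def grow_hairs(roots: np.ndarray, normals: np.ndarray,
               params: HairParams) -> HairSet:
    """Grow straight polyline fibers from roots along tilted normals."""
    rng = np.random.default_rng(params.seed)
    tilt_axis = np.asarray(params.tilt_axis, dtype=np.float64)
    norm = np.linalg.norm(tilt_axis)
    if norm < 1e-12:
        raise ValueError("tilt_axis must be a nonzero vector")
    tilt_axis = tilt_axis / norm
    step = params.length / params.segments
    fibers = []
    for root, nvec in zip(np.atleast_2d(roots), np.atleast_2d(normals)):
        d = nvec / np.linalg.norm(nvec)
        if params.tilt_angle > 0:
            d = _rotate_toward(d, tilt_axis, np.deg2rad(params.tilt_angle))
        if params.randomness > 0:
            d = _random_cone(d, params.randomness * np.pi / 2, rng)
        pts = root[None, :] + step * np.arange(params.segments + 1)[:, None] \
            * d[None, :]
        fibers.append(pts)
    return HairSet(fibers=fibers, roots=np.atleast_2d(roots).copy(),
                   metadata={"params": params})


def apply_gravity_bend(hairs: HairSet, gravity: float) -> HairSet:
    """Deterministic gravity bend: segment k is rotated toward −z by
    gravity·k·Δ with Δ = 90°/segments, capped at the segment's remaining
    angle to −z (so strong gravity drives the fiber tip straight down).
    Segment lengths and the root point are preserved; gravity = 0 is the
    identity."""
    if gravity < 0:
        raise ValueError("gravity must be >= 0")
    if gravity == 0:
        return HairSet(fibers=[f.copy() for f in hairs.fibers],
                       roots=hairs.roots.copy(), radius=hairs.radius,
                       metadata=dict(hairs.metadata))
    down = np.array([0.0, 0.0, -1.0])
    bent_fibers = []
    for fiber in hairs.fibers:
        nseg = len(fiber) - 1
        delta = np.pi / 2 / nseg
        pts = [fiber[0].copy()]
        for k in range(nseg):
            seg = fiber[k + 1] - fiber[k]
            slen = np.linalg.norm(seg)
            d = seg / slen
            d = _rotate_toward(d, down, gravity * k * delta)
            pts.append(pts[-1] + slen * d)
        bent_fibers.append(np.asarray(pts))
    return HairSet(fibers=bent_fibers, roots=hairs.roots.copy(),
                   radius=hairs.radius, metadata=dict(hairs.metadata))


def export_hairs(hairs: HairSet, path, dialect: str = "plain"):
    """Write hair geometry as a JMesh polyline document.

    All fiber points are concatenated into one vertex table; each fiber is
    one polyline index run (the runs partition the vertex list).  The fiber
    radius is carried as metadata.
    """
    vertices = np.concatenate(hairs.fibers, axis=0)
    runs = []
    offset = 0
    for fiber in hairs.fibers:
        runs.append(np.arange(offset, offset + len(fiber), dtype=np.int64))
        offset += len(fiber)
    doc = MeshDocument(
        vertices=vertices,
        triangles=np.zeros((0, 3), dtype=np.int64),
        tetrahedra=np.zeros((0, 4), dtype=np.int64),
        polylines=runs,
        metadata={"_DataInfo_": {"HairRadius_mm": hairs.radius,
                                 "HairCount": len(hairs.fibers)}},
    )
    return write_mesh_document(doc, path, dialect=dialect)
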