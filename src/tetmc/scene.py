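"""Constructive scene description: ordered, labeled geometric regions.

A :class:`RegionScene` is an axis-aligned bounding box plus an ordered list of
labeled shape predicates (boxes, z-cut slabs, cylinders, height-field
interfaces).  Point membership is resolved by precedence: the *last* region
containing a point wins, so an embedded vessel listed after its host layer
overrides it.  Label 0 is reserved for "outside".

All scene geometry is held in mm.  A ``unit_scale`` (mm per model unit, the
benchmark "unitinmm" property) is applied exactly once, at construction, so
every downstream consumer works purely in mm.

Boundary convention: every interval / half-space is closed on the low side
and open on the high side, making membership a total, deterministic function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Box", "ZSlab", "Cylinder", "HeightfieldBelow",
    "Region", "RegionScene", "build_scene", "label_point", "label_points",
    "scene_interfaces_z", "load_scene", "save_scene", "SceneError",
]

_ZTOL = 1e-9  # dedup tolerance for z-plane lists, mm


class SceneError(ValueError):
    """Invalid scene construction."""


@dataclass(frozen=True)
class Box:
    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self):
        if not all(h > l for l, h in zip(self.lo, self.hi)):
            raise SceneError(f"degenerate box: lo={self.lo} hi={self.hi}")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((pts >= lo) & (pts < hi), axis=-1)

    def scaled(self, s: float) -> "Box":
        return Box(tuple(s * v for v in self.lo), tuple(s * v for v in self.hi))

    def bbox(self):
        return np.asarray(self.lo), np.asarray(self.hi)


@dataclass(frozen=True)
class ZSlab:
    """Horizontal layer: zmin <= z < zmax (x, y unbounded within the scene)."""

    zmin: float
    zmax: float

    def __post_init__(self):
        if not self.zmin < self.zmax:
            raise SceneError(f"zslab requires zmin < zmax, got "
                             f"[{self.zmin}, {self.zmax}]")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        z = pts[..., 2]
        return (z >= self.zmin) & (z < self.zmax)

    def scaled(self, s: float) -> "ZSlab":
        return ZSlab(s * self.zmin, s * self.zmax)

    def bbox(self):
        inf = np.inf
        return (np.array([-inf, -inf, self.zmin]),
                np.array([inf, inf, self.zmax]))


@dataclass(frozen=True)
class Cylinder:
    """Finite cylinder: axis point, unit axis direction, radius, length.

    The axis point is the cylinder center; the cylinder extends length/2 both
    ways along the axis.  Radial boundary is open (points at exactly r are
    outside), axial extent is half-open [−L/2, +L/2).
    """

    point: tuple[float, float, float]
    axis: tuple[float, float, float]
    radius: float
    length: float

    def __post_init__(self):
        if self.radius <= 0:
            raise SceneError("cylinder radius must be > 0")
        if self.length <= 0:
            raise SceneError("cylinder length must be > 0")
        a = np.linalg.norm(self.axis)
        if a < 1e-12:
            raise SceneError("cylinder axis must be a nonzero vector")
        object.__setattr__(self, "axis",
                           tuple(float(v) / a for v in self.axis))

    def contains(self, pts: np.ndarray) -> np.ndarray:
        p = pts - np.asarray(self.point)
        a = np.asarray(self.axis)
        t = p @ a
        radial2 = np.sum(p * p, axis=-1) - t * t
        half = self.length / 2.0
        return (radial2 < self.radius ** 2) & (t >= -half) & (t < half)

    def scaled(self, s: float) -> "Cylinder":
        return Cylinder(tuple(s * v for v in self.point), self.axis,
                        s * self.radius, s * self.length)

    def bbox(self):
        c = np.asarray(self.point)
        a = np.asarray(self.axis)
        half = self.length / 2.0
        # extent of a finite cylinder along each coordinate axis
        ext = half * np.abs(a) + self.radius * np.sqrt(
            np.clip(1.0 - a * a, 0.0, 1.0))
        return c - ext, c + ext


@dataclass(frozen=True)
class HeightfieldBelow:
    """Half-space below a bilinearly interpolated interface z = base + Z(x,y).

    ``heights`` is an (ny, nx) grid of out-of-plane offsets sampled on a
    regular grid spanning ``[x0, x0+Lx] x [y0, y0+Ly]``; a point is inside
    iff z < base_z + Z(x, y) (strict: points exactly on the interface are
    outside, matching the half-open convention).
    """

    heights: tuple          # stored as nested tuple for hashability
    x0: float
    y0: float
    extent: tuple[float, float]
    base_z: float

    @staticmethod
    def from_array(heights: np.ndarray, x0: float, y0: float,
                   extent: tuple[float, float],
                   base_z: float) -> "HeightfieldBelow":
        h = np.asarray(heights, dtype=np.float64)
        if h.ndim != 2 or h.shape[0] < 2 or h.shape[1] < 2:
            raise SceneError("heightfield grid must be at least 2 x 2")
        if not np.all(np.isfinite(h)):
            raise SceneError("heightfield contains non-finite heights")
        if extent[0] <= 0 or extent[1] <= 0:
            raise SceneError("heightfield extent must be positive")
        return HeightfieldBelow(tuple(map(tuple, h)), float(x0), float(y0),
                                (float(extent[0]), float(extent[1])),
                                float(base_z))

    def _grid(self) -> np.ndarray:
        return np.asarray(self.heights, dtype=np.float64)

    def interface_z(self, x, y) -> np.ndarray:
        """Bilinear interpolation of the interface height at (x, y), mm."""
        h = self._grid()
        ny, nx = h.shape
        u = np.clip((np.asarray(x) - self.x0) / self.extent[0], 0, 1) * (nx - 1)
        v = np.clip((np.asarray(y) - self.y0) / self.extent[1], 0, 1) * (ny - 1)
        i0 = np.clip(u.astype(int), 0, nx - 2)
        j0 = np.clip(v.astype(int), 0, ny - 2)
        fu = u - i0
        fv = v - j0
        z = (h[j0, i0] * (1 - fu) * (1 - fv) + h[j0, i0 + 1] * fu * (1 - fv)
             + h[j0 + 1, i0] * (1 - fu) * fv + h[j0 + 1, i0 + 1] * fu * fv)
        return self.base_z + z

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return pts[:, 2] < self.interface_z(pts[:, 0], pts[:, 1])

    def scaled(self, s: float) -> "HeightfieldBelow":
        return HeightfieldBelow.from_array(
            self._grid() * s, self.x0 * s, self.y0 * s,
            (self.extent[0] * s, self.extent[1] * s), self.base_z * s)

    def bbox(self):
        h = self._grid()
        inf = np.inf
        return (np.array([self.x0, self.y0, -inf]),
                np.array([self.x0 + self.extent[0], self.y0 + self.extent[1],
                          self.base_z + h.max()]))


ShapeSpec = Box | ZSlab | Cylinder | HeightfieldBelow


@dataclass(frozen=True)
class Region:
    label: int
    shape: ShapeSpec
    name: str = ""


@dataclass
class RegionScene:
    """Ordered labeled regions over an axis-aligned bounding box (mm)."""

    bounds: Box
    regions: list[Region]
    unit_scale: float = 1.0  # applied already; retained as metadata
    metadata: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[int]:
        return [r.label for r in self.regions]


def build_scene(bounds: Box, unit_scale: float,
                region_list: list[Region | tuple]) -> RegionScene:
    """Build a scene from model-unit geometry.

    ``bounds`` and every shape are given in model units and are scaled to mm
    by ``unit_scale`` exactly once here; the returned scene is purely in mm.
    Later regions take precedence at overlapping points.
    """
    if unit_scale <= 0:
        raise SceneError("unit_scale must be > 0")
    if not region_list:
        raise SceneError("region_list must be nonempty")
    regions: list[Region] = []
    for entry in region_list:
        if not isinstance(entry, Region):
            entry = Region(*entry)
        if entry.label <= 0:
            raise SceneError(f"region labels must be positive (got "
                             f"{entry.label}); 0 is reserved for outside")
        regions.append(Region(entry.label, entry.shape.scaled(unit_scale),
                              entry.name))
    labels = [r.label for r in regions]
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise SceneError(f"duplicate region labels {dup}")
    scaled_bounds = bounds.scaled(unit_scale)
    blo, bhi = scaled_bounds.bbox()
    tol = 1e-9 * max(1.0, float(np.max(np.abs([blo, bhi]))))
    for r in regions:
        # unbounded extents (zslab x/y, heightfield z) are clipped by bounds,
        # so only finite shape extents are checked against the box
        olo, ohi = r.shape.bbox()
        finite_lo = np.isfinite(olo)
        finite_hi = np.isfinite(ohi)
        if np.any(olo[finite_lo] < blo[finite_lo] - tol) or \
                np.any(ohi[finite_hi] > bhi[finite_hi] + tol):
            raise SceneError(
                f"shape of region {r.label} ({r.name or type(r.shape).__name__})"
                f" extends outside scene bounds")
    return RegionScene(bounds=scaled_bounds, regions=regions,
                       unit_scale=unit_scale)


def label_points(scene: RegionScene, pts: np.ndarray) -> np.ndarray:
    """Vectorized region labels for an (N, 3) point array (mm); 0 = outside."""
    pts = np.atleast_2d(np.asarray(pts, dtype=np.float64))
    labels = np.zeros(len(pts), dtype=np.int32)
    inside_bounds = scene.bounds.contains(pts)
    for region in scene.regions:  # later regions overwrite earlier
        mask = region.shape.contains(pts) & inside_bounds
        labels[mask] = region.label
    return labels


def label_point(scene: RegionScene, p) -> int:
    """Label of the last region containing point *p* (mm), or 0."""
    return int(label_points(scene, np.asarray(p, dtype=np.float64)[None, :])[0])


def scene_interfaces_z(scene: RegionScene) -> list[float]:
    """Sorted, deduplicated z-cut planes: zslab bounds plus the box faces."""
    zs = [scene.bounds.lo[2], scene.bounds.hi[2]]
    for region in scene.regions:
        if isinstance(region.shape, ZSlab):
            zs.extend([region.shape.zmin, region.shape.zmax])
        elif isinstance(region.shape, Box):
            zs.extend([region.shape.lo[2], region.shape.hi[2]])
        elif isinstance(region.shape, HeightfieldBelow):
            zs.append(region.shape.base_z)
    zs = sorted(zs)
    out = [zs[0]]
    for z in zs[1:]:
        if z - out[-1] > _ZTOL:
            out.append(z)
    return out


# ---------------------------------------------------------------------------
# JSON scene configs

def _shape_to_json(shape: ShapeSpec) -> dict:
    if isinstance(shape, Box):
        return {"kind": "box", "lo": list(shape.lo), "hi": list(shape.hi)}
    if isinstance(shape, ZSlab):
        return {"kind": "zslab", "zmin": shape.zmin, "zmax": shape.zmax}
    if isinstance(shape, Cylinder):
        return {"kind": "cylinder", "point": list(shape.point),
                "axis": list(shape.axis), "radius": shape.radius,
                "length": shape.length}
    if isinstance(shape, HeightfieldBelow):
        return {"kind": "heightfield_below",
                "heights": [list(row) for row in shape.heights],
                "x0": shape.x0, "y0": shape.y0,
                "extent": list(shape.extent), "base_z": shape.base_z}
    raise SceneError(f"unknown shape {type(shape).__name__}")


def _shape_from_json(d: dict) -> ShapeSpec:
    kind = d.get("kind")
    if kind == "box":
        return Box(tuple(d["lo"]), tuple(d["hi"]))
    if kind == "zslab":
        return ZSlab(d["zmin"], d["zmax"])
    if kind == "cylinder":
        return Cylinder(tuple(d["point"]), tuple(d["axis"]),
                        d["radius"], d["length"])
    if kind == "heightfield_below":
        return HeightfieldBelow.from_array(
            np.asarray(d["heights"]), d["x0"], d["y0"],
            tuple(d["extent"]), d["base_z"])
    raise SceneError(f"unknown shape kind {kind!r}")


def save_scene(scene: RegionScene, path) -> Path:
    doc = {
        "bounds": {"lo": list(scene.bounds.lo), "hi": list(scene.bounds.hi)},
        "unit_scale": scene.unit_scale,
        "regions": [{"label": r.label, "name": r.name,
                     **_shape_to_json(r.shape)} for r in scene.regions],
    }
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1))
    return path


def load_scene(path_or_text) -> RegionScene:
    """Load a scene config (JSON).  Geometry in configs is already in mm."""
    text = Path(path_or_text).read_text() \
        if Path(str(path_or_text)).exists() else str(path_or_text)
    doc = json.loads(text)
    bounds = Box(tuple(doc["bounds"]["lo"]), tuple(doc["bounds"]["hi"]))
    regions = [Region(r["label"], _shape_from_json(r), r.get("name", ""))
               for r in doc["regions"]]
    scene = build_scene(bounds, 1.0, regions)
    scene.unit_scale = float(doc.get("unit_scale", 1.0))
    return scene
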