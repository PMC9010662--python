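"""Randomized rough interfaces and the Ra roughness statistic.

A flat plane is subdivided into a regular grid (k cuts per edge give k+1
segments and (k+2)^2 grid vertices) and each vertex receives an independent
uniform normal-direction displacement bounded by ±a.  Surface roughness is
quantified by Ra, the arithmetic mean deviation of the height profile: the
mean absolute deviation of vertex heights from their mean.  For a uniform
±a perturbation E[Ra] = a/2.

The resulting height field plugs into a scene as a ``heightfield_below``
region boundary (bilinear interpolation; a point is inside the region iff it
lies strictly below the local interface height).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .scene import HeightfieldBelow

__all__ = [
    "GridSurface", "make_grid_surface", "randomize_normals", "compute_ra",
    "surface_to_region",
]


@dataclass
class GridSurface:
    """Height-field surface: vertex heights over a regular (Lx, Ly) grid."""

    heights: np.ndarray                 # (n, n) out-of-plane offsets, mm
    extent: tuple[float, float]         # (Lx, Ly), mm
    base_z: float = 0.0                 # nominal interface plane, mm
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=np.float64)
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("surface heights must be finite")
        if self.extent[0] <= 0 or self.extent[1] <= 0:
            raise ValueError("surface extent must be positive")


def make_grid_surface(extent: tuple[float, float], cuts: int,
                      base_z: float = 0.0,
                      origin: tuple[float, float] = (0.0, 0.0)) -> GridSurface:
    """Flat subdivided surface: *cuts* cuts per edge -> (cuts+1)^2 cells."""
    if cuts < 0:
        raise ValueError("number of cuts must be >= 0")
    n = cuts + 2  # grid lines per side
    return GridSurface(heights=np.zeros((n, n)), extent=tuple(extent),
                       base_z=base_z, origin=origin)


def randomize_normals(surface: GridSurface, amplitude: float,
                      seed: int) -> GridSurface:
    """I.i.d. uniform ±amplitude normal-direction vertex displacement."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    rng = np.random.default_rng(seed)
    dz = rng.uniform(-amplitude, amplitude, size=surface.heights.shape)
    return GridSurface(heights=surface.heights + dz, extent=surface.extent,
                       base_z=surface.base_z, origin=surface.origin)


def compute_ra(surface: GridSurface) -> float:
    """Arithmetic mean deviation Ra (mm): mean |Z − mean(Z)| over vertices."""
    z = surface.heights.ravel()
    if z.size < 2:
        raise ValueError("Ra requires at least 2 grid nodes")
    return float(np.mean(np.abs(z - z.mean())))


def surface_to_region(surface: GridSurface,
                      cross_section: tuple[float, float] | None = None
                      ) -> HeightfieldBelow:
    """Convert a GridSurface into a heightfield_below region boundary.

    If *cross_section* (the scene's x/y extent) is given it must match the
    surface extent.
    """
    if cross_section is not None:
        if not np.allclose(cross_section, surface.extent, rtol=1e-9):
            raise ValueError(
                f"surface extent {surface.extent} does not match scene "
                f"cross-section {tuple(cross_section)}")
    return HeightfieldBelow.from_array(
        surface.heights, surface.origin[0], surface.origin[1],
        surface.extent, surface.base_z)


def save_surface(surface: GridSurface, path) -> Path:
    doc = {"extent": list(surface.extent), "base_z": surface.base_z,
           "origin": list(surface.origin),
           "heights": surface.heights.tolist(),
           "Ra_mm": compute_ra(surface)}
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def load_surface(path) -> GridSurface:
    doc = json.loads(Path(path).read_text())
    return GridSurface(heights=np.asarray(doc["heights"]),
                       extent=tuple(doc["extent"]),
                       base_z=doc.get("base_z", 0.0),
                       origin=tuple(doc.get("origin", (0.0, 0.0))))
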