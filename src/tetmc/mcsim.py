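"""Mesh-based Monte Carlo photon transport on labeled tetrahedral meshes.

Weighted photon packets are launched from a pencil or disk source, scattered
with the Henyey–Greenstein phase function, and attenuated continuously along
each path segment (weight loss w(1 − e^{−μa s}) per segment rather than
discrete albedo splitting, for lower variance).  Packets traverse the mesh
tetrahedron-by-tetrahedron via exit-face tests on a precomputed face
adjacency table; deposited energy is split to the four nodes of the host
element by the barycentric coordinates of the segment midpoint.

Fluence estimator
-----------------
Each segment contributes Δφ = w(1 − e^{−μa s})/μa using the host element's
μa; elements with μa below 1e-8/mm use the track-length estimator Δφ = w·s
instead (the two coincide in the μa→0 limit, and the switch avoids 0/0 in
transparent regions).  With ``do_normalize`` the nodal accumulators are
divided by V_node · nphoton · tstep (V_node = ¼ of the volume of the
adjacent tetrahedra), yielding fluence rate per unit source energy.

Boundary physics: at interfaces between regions of different refractive
index (and at the outer surface) with ``do_reflection`` enabled, unpolarized
Fresnel reflection/Snell refraction is applied; beyond the critical angle
packets reflect totally.  The exterior medium is transparent with n = 1.

Runs are single-threaded and bitwise reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .meshing import TetMesh, tet_volumes, _TET_FACES

__all__ = [
    "OpticalProps", "PhotonSource", "SimSettings", "FluenceMap",
    "quaternion_to_direction", "sample_free_path", "sample_hg",
    "fresnel_reflectance", "fresnel_boundary", "run_simulation",
    "log10_display", "SPEED_OF_LIGHT_MM_S",
]

SPEED_OF_LIGHT_MM_S = 2.99792458e11   # vacuum speed of light, mm/s
_MUA_TRACKLEN = 1e-8                  # 1/mm; below this, track-length estimator
_EPS_GEOM = 1e-9                      # mm; exit-face / point-in-tet tolerance
_REFERENCE_DIR = np.array([0.0, 0.0, -1.0])  # downward-pointing default


@dataclass
class OpticalProps:
    """Per-region optical properties: μa, μs (1/mm), anisotropy g, index n."""

    mua: float
    mus: float
    g: float = 0.0
    n: float = 1.0

    def __post_init__(self):
        if self.mua < 0 or self.mus < 0:
            raise ValueError("mua and mus must be >= 0")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError("anisotropy g must lie in [-1, 1]")
        if self.n < 1.0:
            raise ValueError("refractive index n must be >= 1")


@dataclass
class PhotonSource:
    """Photon source: position (mm), orientation, type, and photon count.

    ``direction`` may be given directly as a unit vector, or derived from a
    unit quaternion via :func:`quaternion_to_direction`.  ``srcparam1`` holds
    type-specific parameters in model units; for a disk source its first
    element is the disk radius, scaled to mm by ``unit_scale``.
    """

    position: tuple[float, float, float]
    direction: tuple[float, float, float] | None = None
    quaternion: tuple[float, float, float, float] | None = None
    srctype: str = "pencil"
    srcparam1: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    unit_scale: float = 1.0
    nphoton: int = 100000

    def __post_init__(self):
        if self.direction is None:
            if self.quaternion is None:
                raise ValueError("source needs a direction or a quaternion")
            self.direction = tuple(quaternion_to_direction(self.quaternion))
        d = np.asarray(self.direction, dtype=np.float64)
        norm = np.linalg.norm(d)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"direction norm {norm:.8f} != 1")
        self.direction = tuple(d / norm)
        if self.srctype not in ("pencil", "disk"):
            raise ValueError(f"unknown srctype {self.srctype!r}")
        if self.nphoton < 1:
            raise ValueError("nphoton must be >= 1")

    @property
    def radius_mm(self) -> float:
        return float(self.srcparam1[0]) * self.unit_scale


@dataclass
class SimSettings:
    """Global simulation settings; times in seconds."""

    seed: int = 1
    time_gates: tuple[float, float, float] = (0.0, 5e-9, 5e-9)
    do_reflection: bool = False
    do_normalize: bool = True
    roulette_threshold: float = 1e-4
    roulette_survival: float = 0.1

    def __post_init__(self):
        tstart, tend, tstep = self.time_gates
        if not tend > tstart:
            raise ValueError("time gate requires tend > tstart")
        if tstep <= 0:
            raise ValueError("tstep must be > 0")
        if not 0 < self.roulette_survival <= 1:
            raise ValueError("roulette_survival must lie in (0, 1]")

    @property
    def n_gates(self) -> int:
        tstart, tend, tstep = self.time_gates
        return max(1, int(round((tend - tstart) / tstep)))


@dataclass
class FluenceMap:
    """Nodal fluence-rate values per time gate plus weight accounting."""

    values: np.ndarray            # (Nn, n_gates)
    stats: dict = field(default_factory=dict)

    def gate(self, index: int = 0) -> np.ndarray:
        return self.values[:, index]


# ---------------------------------------------------------------------------
# elementary sampling / optics operations

def quaternion_to_direction(q) -> np.ndarray:
    """Rotate the reference direction (0, 0, −1) by unit quaternion (w,x,y,z)."""
    q = np.asarray(q, dtype=np.float64)
    norm = np.linalg.norm(q)
    if norm < 1e-12:
        raise ValueError("zero quaternion")
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"quaternion norm {norm:.8f} != 1")
    w, x, y, z = q / norm
    # rotation-matrix columns applied to (0, 0, -1)
    return np.array([
        -(2 * (x * z + w * y)),
        -(2 * (y * z - w * x)),
        -(1 - 2 * (x * x + y * y)),
    ])


def sample_free_path(mus: float, u: float) -> float:
    """Exponential free path −ln(u)/μs (mm); +inf for a non-scattering medium."""
    if mus <= 0.0:
        return np.inf
    return -np.log(u) / mus


def _hg_costheta(g: float, u1: float) -> float:
    if abs(g) < 1e-12:
        return 2.0 * u1 - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
    ct = (1.0 + g * g - frac * frac) / (2.0 * g)
    return min(1.0, max(-1.0, ct))


def _rotate_direction(d, ct, phi) -> np.ndarray:
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    cp, sp = np.cos(phi), np.sin(phi)
    dx, dy, dz = d
    if abs(dz) > 1.0 - 1e-12:
        sign = 1.0 if dz > 0 else -1.0
        return np.array([st * cp, sign * st * sp, sign * ct])
    den = np.sqrt(1.0 - dz * dz)
    return np.array([
        st * (dx * dz * cp - dy * sp) / den + dx * ct,
        st * (dy * dz * cp + dx * sp) / den + dy * ct,
        -st * cp * den + dz * ct,
    ])


def sample_hg(g: float, u1: float, u2: float,
              incident=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Henyey–Greenstein scattered direction relative to *incident*."""
    ct = _hg_costheta(g, u1)
    out = _rotate_direction(np.asarray(incident, dtype=np.float64),
                            ct, 2.0 * np.pi * u2)
    return out / np.linalg.norm(out)


def fresnel_reflectance(n1: float, n2: float, cos_i: float) -> float:
    """Unpolarized Fresnel reflectance (s/p average); 1 beyond critical angle."""
    cos_i = abs(cos_i)
    sin_t2 = (n1 / n2) ** 2 * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return 1.0
    cos_t = np.sqrt(1.0 - sin_t2)
    rs = ((n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)) ** 2
    rp = ((n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)) ** 2
    return 0.5 * (rs + rp)


def fresnel_boundary(n1: float, n2: float, direction, normal,
                     u: float) -> tuple[str, np.ndarray]:
    """Reflect (probability R) or refract a packet at an index interface.

    *normal* is the interface normal on the side the packet travels toward
    (normal·direction > 0).  Returns ("reflect"|"refract", new unit direction).
    """
    d = np.asarray(direction, dtype=np.float64)
    m = np.asarray(normal, dtype=np.float64)
    cos_i = float(d @ m)
    R = fresnel_reflectance(n1, n2, cos_i)
    if u < R:
        return "reflect", d - 2.0 * cos_i * m
    if abs(n1 - n2) < 1e-12:
        return "refract", d
    eta = n1 / n2
    cos_t = np.sqrt(max(0.0, 1.0 - eta * eta * (1.0 - cos_i * cos_i)))
    out = eta * d - (eta * cos_i - cos_t) * m
    return "refract", out / np.linalg.norm(out)


def log10_display(values, floor: float = 1e-12) -> np.ndarray:
    """log10(max(value, floor)); monotone display transform for fluence."""
    if floor <= 0:
        raise ValueError("floor must be > 0")
    vals = values.values if isinstance(values, FluenceMap) else \
        np.asarray(values, dtype=np.float64)
    return np.log10(np.maximum(vals, floor))


# ---------------------------------------------------------------------------
# mesh acceleration structures

def _build_adjacency(elem: np.ndarray) -> np.ndarray:
    faces = elem[:, _TET_FACES].reshape(-1, 3)
    keys = np.sort(faces, axis=1)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    sorted_inv = inverse[order]
    neighbor = np.full((len(elem), 4), -1, dtype=np.int64)
    same = sorted_inv[:-1] == sorted_inv[1:]
    a = order[:-1][same]
    b = order[1:][same]
    neighbor[a // 4, a % 4] = b // 4
    neighbor[b // 4, b % 4] = a // 4
    return neighbor


def _build_face_planes(node, elem):
    """Outward face normals, plane offsets and vertex heights per element."""
    v = node[elem]                                     # (Ne, 4, 3)
    fnorm = np.empty((len(elem), 4, 3))
    foff = np.empty((len(elem), 4))
    fh = np.empty((len(elem), 4))
    for j, (a, b, c) in enumerate(_TET_FACES):
        n = np.cross(v[:, b] - v[:, a], v[:, c] - v[:, a])
        n /= np.linalg.norm(n, axis=1)[:, None]
        fnorm[:, j] = n
        foff[:, j] = np.einsum("ij,ij->i", n, v[:, a])
        # signed height of the opposite vertex j below its face plane (< 0)
        fh[:, j] = np.einsum("ij,ij->i", n, v[:, j]) - foff[:, j]
    return fnorm, foff, fh


def _build_location_grid(node, elem):
    """Uniform grid binning tetrahedra by bounding box for point location."""
    v = node[elem]
    tlo = v.min(axis=1)
    thi = v.max(axis=1)
    gmin = node.min(axis=0)
    gmax = node.max(axis=0)
    span = np.maximum(gmax - gmin, 1e-12)
    # aim for O(1) tets per cell
    ncell_target = max(1, len(elem) // 4)
    cell = float((span.prod() / ncell_target) ** (1.0 / 3.0))
    dims = np.maximum(1, np.ceil(span / cell).astype(np.int64))
    h = span / dims
    i0 = np.clip(((tlo - gmin) / h).astype(np.int64), 0, dims - 1)
    i1 = np.clip(((thi - gmin) / h).astype(np.int64), 0, dims - 1)
    spans = i1 - i0 + 1
    reps = spans.prod(axis=1)
    total = int(reps.sum())
    tet_ids = np.repeat(np.arange(len(elem)), reps)
    start = np.concatenate([[0], np.cumsum(reps)[:-1]])
    local = np.arange(total) - np.repeat(start, reps)
    sy = np.repeat(spans[:, 1], reps)
    sz = np.repeat(spans[:, 2], reps)
    oz = local % sz
    oy = (local // sz) % sy
    ox = local // (sz * sy)
    ii = np.repeat(i0[:, 0], reps) + ox
    jj = np.repeat(i0[:, 1], reps) + oy
    kk = np.repeat(i0[:, 2], reps) + oz
    cells = (ii * dims[1] + jj) * dims[2] + kk
    order = np.argsort(cells, kind="stable")
    cells_sorted = cells[order]
    items = tet_ids[order]
    ncells = int(dims.prod())
    counts = np.bincount(cells_sorted, minlength=ncells)
    cell_start = np.concatenate([[0], np.cumsum(counts)])
    return (gmin.astype(np.float64), h.astype(np.float64),
            dims.astype(np.int64), cell_start.astype(np.int64),
            items.astype(np.int64))


# ---------------------------------------------------------------------------
# transport kernel (numba)

@njit(cache=True, inline="always", fastmath=True)
def _locate(p, gmin, gh, gdims, cell_start, items, fnorm, foff):
    if p[0] < gmin[0] - _EPS_GEOM or p[1] < gmin[1] - _EPS_GEOM \
            or p[2] < gmin[2] - _EPS_GEOM \
            or p[0] > gmin[0] + gh[0] * gdims[0] + _EPS_GEOM \
            or p[1] > gmin[1] + gh[1] * gdims[1] + _EPS_GEOM \
            or p[2] > gmin[2] + gh[2] * gdims[2] + _EPS_GEOM:
        return -1
    ix = min(max(int((p[0] - gmin[0]) / gh[0]), 0), gdims[0] - 1)
    iy = min(max(int((p[1] - gmin[1]) / gh[1]), 0), gdims[1] - 1)
    iz = min(max(int((p[2] - gmin[2]) / gh[2]), 0), gdims[2] - 1)
    c = (ix * gdims[1] + iy) * gdims[2] + iz
    for k in range(cell_start[c], cell_start[c + 1]):
        e = items[k]
        inside = True
        for j in range(4):
            d = (fnorm[e, j, 0] * p[0] + fnorm[e, j, 1] * p[1]
                 + fnorm[e, j, 2] * p[2] - foff[e, j])
            if d > _EPS_GEOM:
                inside = False
                break
        if inside:
            return e
    return -1


@njit(cache=True, inline="always", fastmath=True)
def _hg_ct(g, u1):
    if abs(g) < 1e-12:
        return 2.0 * u1 - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u1)
    ct = (1.0 + g * g - frac * frac) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@njit(cache=True, inline="always", fastmath=True)
def _spin(dx, dy, dz, ct, phi):
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(dz) > 1.0 - 1e-12:
        sign = 1.0 if dz > 0.0 else -1.0
        return st * cp, sign * st * sp, sign * ct
    den = np.sqrt(1.0 - dz * dz)
    nx = st * (dx * dz * cp - dy * sp) / den + dx * ct
    ny = st * (dy * dz * cp + dx * sp) / den + dy * ct
    nz = -st * cp * den + dz * ct
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always", fastmath=True)
def _fresnel_R(n1, n2, ci):
    s2 = (n1 / n2) * (n1 / n2) * (1.0 - ci * ci)
    if s2 >= 1.0:
        return 1.0
    ct = np.sqrt(1.0 - s2)
    rs = (n1 * ci - n2 * ct) / (n1 * ci + n2 * ct)
    rp = (n1 * ct - n2 * ci) / (n1 * ct + n2 * ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True)
def _run_kernel(node, elem, eprop, neighbor, fnorm, foff, fh,
                p_mua, p_mus, p_g, p_n,
                src_pos, src_dir, src_is_disk, src_radius,
                nphoton, seed,
                tstart, tend, tstep, ngates,
                do_reflection, n_ext,
                rr_threshold, rr_survival,
                gmin, gh, gdims, cell_start, items,
                phi):
    np.random.seed(seed)
    C = SPEED_OF_LIGHT_MM_S
    launched = float(nphoton)
    absorbed = 0.0
    escaped = 0.0
    truncated = 0.0
    lost = 0.0

    # orthonormal basis for disk sampling
    ux, uy, uz = 0.0, 0.0, 0.0
    vx, vy, vz = 0.0, 0.0, 0.0
    if src_is_disk:
        ax, ay, az = 1.0, 0.0, 0.0
        if abs(src_dir[0]) > 0.9:
            ax, ay, az = 0.0, 1.0, 0.0
        ux = ay * src_dir[2] - az * src_dir[1]
        uy = az * src_dir[0] - ax * src_dir[2]
        uz = ax * src_dir[1] - ay * src_dir[0]
        un = np.sqrt(ux * ux + uy * uy + uz * uz)
        ux, uy, uz = ux / un, uy / un, uz / un
        vx = src_dir[1] * uz - src_dir[2] * uy
        vy = src_dir[2] * ux - src_dir[0] * uz
        vz = src_dir[0] * uy - src_dir[1] * ux

    gdiag = np.sqrt(gh[0] * gh[0] * gdims[0] * gdims[0]
                    + gh[1] * gh[1] * gdims[1] * gdims[1]
                    + gh[2] * gh[2] * gdims[2] * gdims[2])
    march = min(gh[0], min(gh[1], gh[2])) * 0.5

    p = np.empty(3)
    d = np.empty(3)

    for _ in range(nphoton):
        # --- launch
        p[0], p[1], p[2] = src_pos[0], src_pos[1], src_pos[2]
        d[0], d[1], d[2] = src_dir[0], src_dir[1], src_dir[2]
        if src_is_disk and src_radius > 0.0:
            r = src_radius * np.sqrt(np.random.random())
            th = 2.0 * np.pi * np.random.random()
            cr = r * np.cos(th)
            sr = r * np.sin(th)
            p[0] += cr * ux + sr * vx
            p[1] += cr * uy + sr * vy
            p[2] += cr * uz + sr * vz
        w = 1.0
        t = 0.0
        ie = _locate(p, gmin, gh, gdims, cell_start, items, fnorm, foff)
        if ie < 0:
            # march along the ray to the first containing element
            found = False
            tray = 0.0
            while tray < gdiag * 2.0:
                tray += march
                q0 = p[0] + tray * d[0]
                q1 = p[1] + tray * d[1]
                q2 = p[2] + tray * d[2]
                qq = np.empty(3)
                qq[0], qq[1], qq[2] = q0, q1, q2
                ie = _locate(qq, gmin, gh, gdims, cell_start, items,
                             fnorm, foff)
                if ie >= 0:
                    # bisect [tray - march, tray] to the entry point
                    t_out = tray - march
                    t_in = tray
                    for _b in range(60):
                        tm = 0.5 * (t_out + t_in)
                        qq[0] = p[0] + tm * d[0]
                        qq[1] = p[1] + tm * d[1]
                        qq[2] = p[2] + tm * d[2]
                        em = _locate(qq, gmin, gh, gdims, cell_start, items,
                                     fnorm, foff)
                        if em >= 0:
                            t_in = tm
                            ie = em
                        else:
                            t_out = tm
                        if t_in - t_out < _EPS_GEOM:
                            break
                    p[0] += t_in * d[0]
                    p[1] += t_in * d[1]
                    p[2] += t_in * d[2]
                    found = True
                    break
            if not found:
                escaped += w     # never intersects the mesh
                continue

        # --- propagate (element data hoisted to scalars, reloaded on entry)
        p0, p1, p2 = p[0], p[1], p[2]
        d0, d1, d2 = d[0], d[1], d[2]
        tau = -np.log(np.random.random())
        stuck = 0
        alive = True
        newelem = True
        while alive:
            if newelem:
                lab = eprop[ie]
                mua = p_mua[lab]
                mus = p_mus[lab]
                g = p_g[lab]
                n = p_n[lab]
                n_over_c = n / C
                f0x = fnorm[ie, 0, 0]
                f0y = fnorm[ie, 0, 1]
                f0z = fnorm[ie, 0, 2]
                f1x = fnorm[ie, 1, 0]
                f1y = fnorm[ie, 1, 1]
                f1z = fnorm[ie, 1, 2]
                f2x = fnorm[ie, 2, 0]
                f2y = fnorm[ie, 2, 1]
                f2z = fnorm[ie, 2, 2]
                f3x = fnorm[ie, 3, 0]
                f3y = fnorm[ie, 3, 1]
                f3z = fnorm[ie, 3, 2]
                o0 = foff[ie, 0]
                o1 = foff[ie, 1]
                o2 = foff[ie, 2]
                o3 = foff[ie, 3]
                h0 = fh[ie, 0]
                h1 = fh[ie, 1]
                h2 = fh[ie, 2]
                h3 = fh[ie, 3]
                e0 = elem[ie, 0]
                e1 = elem[ie, 1]
                e2 = elem[ie, 2]
                e3 = elem[ie, 3]
                newelem = False

            s_scat = 1e30
            if mus > 0.0:
                s_scat = tau / mus
            s_time = (tend - t) / n_over_c
            # signed plane distances and advance rates for all 4 faces
            q0 = f0x * p0 + f0y * p1 + f0z * p2 - o0
            q1 = f1x * p0 + f1y * p1 + f1z * p2 - o1
            q2 = f2x * p0 + f2y * p1 + f2z * p2 - o2
            q3 = f3x * p0 + f3y * p1 + f3z * p2 - o3
            r0 = f0x * d0 + f0y * d1 + f0z * d2
            r1 = f1x * d0 + f1y * d1 + f1z * d2
            r2 = f2x * d0 + f2y * d1 + f2z * d2
            r3 = f3x * d0 + f3y * d1 + f3z * d2
            s_exit = 1e30
            f_exit = -1
            if r0 > 1e-12:
                tf = -q0 / r0
                if tf < 0.0:
                    tf = 0.0
                if tf < s_exit:
                    s_exit = tf
                    f_exit = 0
            if r1 > 1e-12:
                tf = -q1 / r1
                if tf < 0.0:
                    tf = 0.0
                if tf < s_exit:
                    s_exit = tf
                    f_exit = 1
            if r2 > 1e-12:
                tf = -q2 / r2
                if tf < 0.0:
                    tf = 0.0
                if tf < s_exit:
                    s_exit = tf
                    f_exit = 2
            if r3 > 1e-12:
                tf = -q3 / r3
                if tf < 0.0:
                    tf = 0.0
                if tf < s_exit:
                    s_exit = tf
                    f_exit = 3

            s = s_scat
            event = 0            # 0 scatter, 1 cross, 2 time-out
            if s_exit < s:
                s = s_exit
                event = 1
            if s_time < s:
                s = s_time
                event = 2

            if s > 0.0:
                stuck = 0
                # deposit along [p, p + s d]; barycentric weights at the
                # segment midpoint from the face-plane distances
                att = np.exp(-mua * s)
                dw = w * (1.0 - att)
                if mua > _MUA_TRACKLEN:
                    dphi = dw / mua
                else:
                    dphi = w * s
                half = 0.5 * s
                ig = 0
                if ngates > 1:
                    ig = int((t + half * n_over_c - tstart) / tstep)
                    if ig < 0:
                        ig = 0
                    elif ig >= ngates:
                        ig = ngates - 1
                b0 = (q0 + half * r0) / h0
                b1 = (q1 + half * r1) / h1
                b2 = (q2 + half * r2) / h2
                b3 = (q3 + half * r3) / h3
                if b0 > 0.0:
                    phi[e0, ig] += dphi * b0
                if b1 > 0.0:
                    phi[e1, ig] += dphi * b1
                if b2 > 0.0:
                    phi[e2, ig] += dphi * b2
                if b3 > 0.0:
                    phi[e3, ig] += dphi * b3
                absorbed += dw
                w *= att
                t += s * n_over_c
                p0 += s * d0
                p1 += s * d1
                p2 += s * d2
                tau -= mus * s
                if tau < 0.0:
                    tau = 0.0
            else:
                stuck += 1
                if stuck > 8:
                    lost += w
                    alive = False
                    continue

            if event == 2:
                truncated += w
                alive = False
            elif event == 0:
                # scatter
                ct = _hg_ct(g, np.random.random())
                d0, d1, d2 = _spin(d0, d1, d2, ct,
                                   2.0 * np.pi * np.random.random())
                tau = -np.log(np.random.random())
                if w < rr_threshold:
                    if np.random.random() < rr_survival:
                        wnew = w / rr_survival
                        launched += wnew - w
                        w = wnew
                    else:
                        truncated += w
                        alive = False
            else:
                # face crossing
                if f_exit == 0:
                    fx, fy, fz = f0x, f0y, f0z
                elif f_exit == 1:
                    fx, fy, fz = f1x, f1y, f1z
                elif f_exit == 2:
                    fx, fy, fz = f2x, f2y, f2z
                else:
                    fx, fy, fz = f3x, f3y, f3z
                je = neighbor[ie, f_exit]
                if je < 0:
                    if do_reflection and abs(n - n_ext) > 1e-9:
                        ci = fx * d0 + fy * d1 + fz * d2
                        R = _fresnel_R(n, n_ext, ci)
                        if np.random.random() < R:
                            d0 -= 2.0 * ci * fx
                            d1 -= 2.0 * ci * fy
                            d2 -= 2.0 * ci * fz
                        else:
                            escaped += w
                            alive = False
                    else:
                        escaped += w
                        alive = False
                else:
                    n2 = p_n[eprop[je]]
                    if do_reflection and abs(n2 - n) > 1e-9:
                        ci = fx * d0 + fy * d1 + fz * d2
                        R = _fresnel_R(n, n2, ci)
                        if np.random.random() < R:
                            d0 -= 2.0 * ci * fx
                            d1 -= 2.0 * ci * fy
                            d2 -= 2.0 * ci * fz
                        else:
                            eta = n / n2
                            st2 = eta * eta * (1.0 - ci * ci)
                            ctt = np.sqrt(max(0.0, 1.0 - st2))
                            k = eta * ci - ctt
                            d0 = eta * d0 - k * fx
                            d1 = eta * d1 - k * fy
                            d2 = eta * d2 - k * fz
                            dn = np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)
                            d0 /= dn
                            d1 /= dn
                            d2 /= dn
                            ie = je
                            newelem = True
                    else:
                        ie = je
                        newelem = True

    out = np.empty(5)
    out[0] = launched
    out[1] = absorbed
    out[2] = escaped
    out[3] = truncated
    out[4] = lost
    return out


# ---------------------------------------------------------------------------
# driver

def run_simulation(mesh: TetMesh, props: dict[int, OpticalProps],
                   source: PhotonSource,
                   settings: SimSettings | None = None) -> FluenceMap:
    """Run the photon transport simulation and accumulate nodal fluence.

    ``props`` maps every region label present in the mesh to its optical
    properties.  Deterministic for a fixed seed.
    """
    settings = settings or SimSettings()
    mesh_labels = mesh.region_labels
    missing = [int(l) for l in mesh_labels if int(l) not in props]
    if missing:
        raise ValueError(f"missing optical properties for labels {missing}")

    lab_sorted = np.sort(mesh_labels)
    p_mua = np.array([props[int(l)].mua for l in lab_sorted])
    p_mus = np.array([props[int(l)].mus for l in lab_sorted])
    p_g = np.array([props[int(l)].g for l in lab_sorted])
    p_n = np.array([props[int(l)].n for l in lab_sorted])
    eprop = np.searchsorted(lab_sorted, mesh.labels).astype(np.int64)

    neighbor = _build_adjacency(mesh.elem)
    fnorm, foff, fh = _build_face_planes(mesh.node, mesh.elem)
    gmin, gh, gdims, cell_start, items = _build_location_grid(
        mesh.node, mesh.elem)

    src_pos = np.asarray(source.position, dtype=np.float64)
    src_dir = np.asarray(source.direction, dtype=np.float64)
    if source.srctype == "pencil":
        e0 = _locate(src_pos, gmin, gh, gdims, cell_start, items, fnorm, foff)
        if e0 < 0:
            raise ValueError(
                f"pencil source position {tuple(src_pos)} is outside the mesh")

    tstart, tend, tstep = settings.time_gates
    ngates = settings.n_gates
    phi = np.zeros((len(mesh.node), ngates))
    stats_arr = _run_kernel(
        mesh.node, mesh.elem, eprop, neighbor, fnorm, foff, fh,
        p_mua, p_mus, p_g, p_n,
        src_pos, src_dir, source.srctype == "disk", source.radius_mm,
        int(source.nphoton), int(settings.seed) & 0x7FFFFFFF,
        float(tstart), float(tend), float(tstep), ngates,
        bool(settings.do_reflection), 1.0,
        float(settings.roulette_threshold), float(settings.roulette_survival),
        gmin, gh, gdims, cell_start, items,
        phi)

    launched, absorbed, escaped, truncated, lost = stats_arr
    truncated += lost  # keep the three-way balance exact; `lost` also reported
    if settings.do_normalize:
        vols = tet_volumes(mesh.node, mesh.elem)
        v_node = np.zeros(len(mesh.node))
        np.add.at(v_node, mesh.elem.ravel(), np.repeat(vols / 4.0, 4))
        v_node = np.maximum(v_node, 1e-300)
        phi = phi / (v_node[:, None] * source.nphoton * tstep)

    stats = {
        "launched": float(launched),
        "absorbed": float(absorbed),
        "escaped": float(escaped),
        "truncated": float(truncated),
        "lost": float(lost),
        "absorbed_fraction": float(absorbed / launched),
        "escaped_fraction": float(escaped / launched),
        "truncated_fraction": float(truncated / launched),
    }
    return FluenceMap(values=phi, stats=stats)
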