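# Methods

This note records the models, numerical choices and deliberate
simplifications behind `tetmc`, in the spirit of a methods appendix.

## Scenes as labeled predicates

Simulation domains are ordered lists of labeled geometric regions over an
axis-aligned bounding box: boxes, z-cut slabs, finite cylinders, and
height-field interfaces ("everything below the interpolated surface").
Membership is resolved by precedence — the last region containing a point
wins — so an embedded vessel listed after its host layer carves itself out
of that layer. This replaces boolean surface-mesh operations (the approach
used by GUI modelers) with a total, deterministic predicate that is robust
and directly testable; for layered-slab-plus-inclusion domains the two
approaches produce the same region decomposition.

Two conventions remove ambiguity:

* **Half-open boundaries.** Every interval and half-space is closed on the
  low side and open on the high side, so points exactly on a cut plane have
  a unique label and `label_point` is total.
* **Units.** The scene applies its `unit_scale` (mm per model unit, e.g.
  mm per voxel) exactly once at construction. All downstream code — meshing,
  transport, I/O — works purely in mm, so the scale cannot be applied twice.

## Lattice tetrahedralization

Meshing uses a rectilinear body lattice rather than boundary-conforming
Delaunay refinement. Each cell splits into 6 tetrahedra around its main
diagonal (Freudenthal/Kuhn subdivision). With the *same* diagonal
orientation in every cell the induced diagonal on any shared cube face is
identical from both sides, so the global triangulation is face-conforming
with no Steiner points — no alternation between neighboring cells is
needed.

* The maximum-element-volume control Vmax maps to the lattice pitch as
  h = (6·Vmax)^(1/3), which bounds every element volume by Vmax exactly
  (lattice tets have volume h³/6).
* z-planes of layer interfaces are inserted into the grid exactly, so flat
  layer boundaries are honored to machine precision regardless of pitch.
* Element labels come from the scene predicate evaluated at tetrahedron
  centroids. Curved boundaries (the vessel cylinder) are therefore rendered
  at lattice resolution: per-region volume error is O(h) and decreases
  monotonically under pitch halving (tested). If a declared region captures
  no element at the requested pitch — a feature thinner than the lattice —
  the pitch is halved with a warning, up to six times.
* Lattice meshes fill their box exactly: the sum of element volumes equals
  the domain volume to 1e-9 relative, which the tests assert.

Published mesh sizes for the same benchmarks produced by Delaunay meshers
are not comparable element-for-element; the contract here is the labeled,
conforming, volume-bounded mesh, not a specific tessellation.

## Monte Carlo transport

Weighted-packet MC with continuous absorption:

* **Free paths.** Scattering optical depth τ ~ Exp(1) is consumed across
  segments as τ −= μs·s, which handles regions of different μs along one
  path correctly; μs = 0 propagates ballistically.
* **Scattering.** Henyey–Greenstein inverse-CDF sampling of cos θ, uniform
  azimuth, with the isotropic closed form at g = 0.
* **Absorption.** Weight decays by exp(−μa·s) per segment (continuous
  attenuation rather than discrete albedo splitting — lower variance for
  the same photon count).
* **Deposition / fluence estimator.** Each segment adds
  Δφ = w(1 − e^{−μa s})/μa using the *host element's* μa, split to the
  element's four nodes by the barycentric coordinates of the segment
  midpoint. Elements with μa < 1e-8/mm switch to the track-length estimator
  Δφ = w·s, the μa→0 limit of the same expression, avoiding 0/0 in
  transparent regions (e.g. a clear top layer or CSF-like compartments).
  Applying μa at deposition rather than at normalization also makes the
  estimator well-defined at nodes shared between regions of different μa.
  With normalization on, nodal values divide by V_node·nphoton·tstep
  (V_node = ¼ Σ adjacent element volumes), giving fluence rate per unit
  source energy (1/mm² per second of gate width; multiplying by tstep gives
  CW fluence).
* **Traversal.** Packets walk the mesh element-by-element using a
  precomputed face-adjacency table; the exit face is the minimum positive
  ray-plane distance among the four faces (tolerance 1e-9 mm, negatives
  clamped to zero). A packet that fails to advance 8 consecutive times is
  terminated and its weight booked as "lost"; this bucket is reported and
  asserted below 1e-5 of the launched weight in the tests.
* **Boundaries.** With reflection enabled, interfaces where n changes apply
  unpolarized Fresnel reflectance (s/p average, total internal reflection
  beyond the critical angle); refraction follows Snell's law. The exterior
  medium is transparent air with n = 1. With reflection disabled, boundary
  crossings escape without deflection. Specular reflection at the *launch*
  surface is not applied: the source is treated as index-matched into the
  domain.
* **Sources.** Pencil (position must lie inside or on the mesh, enforced)
  or disk (uniform over a disk perpendicular to the direction; radius =
  srcparam1[0] × unit_scale). Disk launch points outside the mesh are
  advanced along the ray to the entry surface by a march-and-bisect search
  (bisection to 1e-9 mm); packets that never intersect the mesh count as
  escaped. The source orientation can be given as a unit quaternion,
  rotating the reference direction (0, 0, −1) — the downward-pointing
  default of a light placed above the domain.
* **Time gating.** Elapsed time advances by s·n/c per segment
  (c = 299.792458 mm/ns). The default single gate is (0, 5 ns); packets
  exceeding the gate end are truncated at the exact time limit. Deposits
  bin by the segment-midpoint time.
* **Russian roulette.** Below weight 1e-4 packets survive with probability
  0.1 and are reweighted ×10. Bookkeeping keeps the weight balance exact:
  survivors' weight gain is added to the launched total and killed weight
  is booked with the truncated bucket, so
  absorbed + escaped + truncated = launched to float rounding on every run.
* **Determinism.** Single-threaded with a seeded generator: identical
  inputs and seed give bitwise-identical fluence maps and byte-identical
  output files.

The transport kernel is JIT-compiled (numba, cached); point location uses a
uniform grid binning elements by bounding box.

### Validation oracles

The test suite checks the physics against independent closed forms rather
than against another simulator: exact Beer–Lambert transmission through a
non-scattering slab; the HG first moment E[cos θ] = g; Fresnel normal-
incidence and critical-angle values; and, end-to-end, the diffusion
Green's function Φ(r) = exp(−μeff·r)/(4πDr) with D = 1/(3(μa+μs′)),
μeff = √(3μa(μa+μs′)). The diffusion check uses a homogeneous 40 mm cube at
2 mm pitch (boundary-image error < 1% at the largest compared radius),
μa = 0.01/mm, μs′ = 1/mm, 10⁶ photons, comparing shell-averaged nodal
fluence at 3–10 mm from the isotropic-equivalent point one transport mean
free path downstream of the pencil source; agreement is required within
10%. These problem sizes keep the full suite at desk scale while leaving
the statistical error well below the asserted tolerances.

## Rough surfaces

A flat interface is subdivided (k cuts per edge → k+1 segments and
(k+2)² grid vertices; k = 39 gives the 40×40-cell grid used throughout)
and every vertex receives an i.i.d. uniform ±a normal displacement. The
roughness statistic Ra — the arithmetic mean deviation of the depth
profile — is computed discretely as mean |Z − mean(Z)| over all grid
vertices: one Ra per surface, the 2-D analogue of the 1-D profile integral.
For the uniform perturbation E|U(−a,a)| = a/2, so a = 0.5 μm yields
E[Ra] = 0.25 μm; a is exposed as a free parameter (a = 3 μm would give
E[Ra] = 1.5 μm for rougher skin, but no specific amplitude is canonical for
that case). Measuring Z from the surface mean makes Ra translation-
invariant and consistent with the draw without recentring bias at large n.

The height field plugs into scenes as a `heightfield_below` region boundary
with bilinear interpolation; at zero amplitude it reproduces the flat-slab
labeling exactly (tested), so roughness is a strict generalization.

## Hair geometry

Hair fibers are polylines grown from area-uniform random roots (triangle
chosen proportional to area, uniform barycentric point). The base direction
is the surface normal rotated by the tilt angle toward a tilt axis;
"randomness" r adds a bounded random cone — an extra rotation by an angle
uniform in [0, r·90°] about a uniform azimuth. Gravity bending is a
deterministic progressive rotation: segment k rotates toward −z by
gravity·k·(90°/segments), capped at its remaining angle to −z, so the bend
is isometric (arc length preserved), root-preserving, the identity at
gravity 0, and drives the tip straight down in the strong-gravity limit.
This replaces physical mass-spring hair dynamics, whose only role here is
to produce plausible curved geometry; a parametric bend is reproducible and
testable. Fiber geometry (vertices + per-fiber polyline index runs +
radius metadata) exports as a JMesh document for downstream implicit-MC
tools; optical transport through hair shafts is out of scope.

## JMesh / JNIfTI I/O

Mesh constructs use `MeshVertex3` / `MeshTri3` / `MeshTet4`; indices are
1-based in files and 0-based in memory, converted exactly once at the I/O
boundary. Three array dialects decode to identical arrays: plain nested
lists; typed annotations (`_ArrayType_`/`_ArraySize_` with a row-major
`_ArrayData_` payload); and compressed annotations (zlib + base64 payload
under `_ArrayZipData_`). Row-major order makes the size tag unambiguous.
Per-element region labels are stored as a 5th `MeshTet4` column (flagged:
other tools may expect a separate construct). Nodal fluence is stored under
`MeshNodeVal` with a companion `MeshNodeValLog10` display field
(log10(max(value, floor)), default floor 1e-12). Unknown JSON keys are
preserved verbatim for forward compatibility. Volumes read from NIfTI-1
(via nibabel) or text JNIfTI; non-integer voxel data are rejected rather
than rounded, and anisotropic voxels are unsupported. Binary
UBJSON-based dialects and `.mat` containers are out of scope.

## Benchmarks

`skinvessel`, `skinvessel_rough` and `slab_hair` are self-contained (no
external files, no network). The slab-with-hair head model reuses the
brain-atlas optical table per layer (scalp/skull → scalp values, CSF →
CSF, brain → gray matter), since no dedicated table exists for it. The
`colin27` (surface-mesh input) and `digimouse` (volume input) benchmarks
package the full 4- and 21-region optical tables and source settings but
require a user-supplied atlas file; without one they fail with an
actionable message. Default photon counts are 10⁵ for desk-scale runs;
production counts are a flag away. The first slab layer of the skin-vessel
table has μa = 0, μs = 1, g = 1 — an effectively non-interacting layer —
and is reproduced verbatim rather than "corrected".

## Known limitations

* Lattice meshing voxelizes curved boundaries at pitch resolution (O(h)
  volume error); no boundary-conforming Delaunay, surface simplification or
  smoothing.
* Single-threaded execution only; determinism is per seed.
* No wide-field/pattern sources, detectors, polarization or fluorescence.
* The synthetic scenes exercise flat layers, one curved inclusion, random
  height fields and hair polylines; they do not capture anatomical surface
  curvature or heterogeneity within a region, so passing tests demonstrate
  correctness of the transport and meshing contracts, not anatomical
  fidelity of any particular tissue model.
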