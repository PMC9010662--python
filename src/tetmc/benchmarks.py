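"""Packaged benchmark scenes and end-to-end pipeline orchestration.

Benchmarks
----------
* ``skinvessel`` — multilayered skin slab with an embedded blood vessel:
  a 200-voxel cube (unit scale 0.005 mm/voxel → 1 mm³ domain) cut into
  Low/Mid/High slabs at z = 0.10 and 0.16 mm, with a 0.1 mm radius cylinder
  along y at z = 0.5 mm; a disk source of radius 50 voxels at
  (100, 100, −10) voxels pointing +z.
* ``skinvessel_rough`` — the same geometry shrunk 10× (unit scale
  0.0005 mm/voxel) with the first layer interface replaced by a randomized
  rough height field, and a 25 μm disk source tilted 30° toward +x.
* ``slab_hair`` — a three-layer head slab (scalp/skull 12.44 mm, CSF
  2.07 mm, brain 20 mm; 20 × 50 mm² cross-section) with 1000 hair fibers
  grown on the top surface and exported as polylines.
* ``colin27`` / ``digimouse`` — optical property tables and source settings
  for the brain-atlas and mouse-atlas benchmarks; both require a
  user-supplied surface-mesh / volume file and fail with an actionable
  message without one.

``run_pipeline`` executes scene → mesh → simulate → write, logging stage
timings, mesh metrics and the weight-conservation summary; every
intermediate artifact is written to the output directory and reruns with the
same seed are reproducible.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import jmesh, roughsurf
from .hairgen import HairParams, apply_gravity_bend, export_hairs, \
    grow_hairs, sample_roots
from .mcsim import OpticalProps, PhotonSource, SimSettings, run_simulation
from .meshing import MeshingOptions, SurfMesh, TetMesh, extract_region_surface, \
    mesh_metrics, tetrahedralize_scene, volume_to_tetmesh
from .scene import Box, Cylinder, Region, RegionScene, ZSlab, build_scene, \
    save_scene

__all__ = ["BenchmarkSpec", "build_benchmark", "run_pipeline",
           "BENCHMARK_NAMES"]

log = logging.getLogger("tetmc")

BENCHMARK_NAMES = ("skinvessel", "skinvessel_rough", "slab_hair",
                   "colin27", "digimouse")


@dataclass
class BenchmarkSpec:
    name: str
    scene: RegionScene | None
    props: dict[int, OpticalProps]
    source: PhotonSource
    settings: SimSettings
    meshing: MeshingOptions
    region_names: dict[int, str] = field(default_factory=dict)
    external_input: Path | None = None    # colin27 surface / digimouse volume
    hair_params: HairParams | None = None
    hair_surface_label: int | None = None


def _skinvessel_regions():
    # geometry in voxel units: 200-voxel cube, plane cuts at z=20 and 32,
    # cylinder radius 20 along y through (100, 100, 100)
    return [
        Region(1, ZSlab(0.0, 20.0), "Low-slab"),
        Region(2, ZSlab(20.0, 32.0), "Mid-slab"),
        Region(3, ZSlab(32.0, 200.0), "High-slab"),
        Region(4, Cylinder((100.0, 100.0, 100.0), (0.0, 1.0, 0.0),
                           20.0, 200.0), "Cylinder"),
    ]


_SKINVESSEL_PROPS = {
    1: OpticalProps(mua=0.0, mus=1.0, g=1.0, n=1.37),       # Low-slab
    2: OpticalProps(mua=1.657, mus=37.594, g=0.9, n=1.37),  # Mid-slab
    3: OpticalProps(mua=0.046, mus=35.654, g=0.9, n=1.37),  # High-slab
    4: OpticalProps(mua=23.054, mus=9.398, g=0.9, n=1.37),  # Cylinder
}

_COLIN27_PROPS = {
    1: OpticalProps(mua=0.019, mus=7.818, g=0.89, n=1.37),  # Scalp
    2: OpticalProps(mua=0.004, mus=0.009, g=0.89, n=1.37),  # CSF
    3: OpticalProps(mua=0.02, mus=9.0, g=0.89, n=1.37),     # Gray matter
    4: OpticalProps(mua=0.08, mus=40.9, g=0.89, n=1.37),    # White matter
}

_COLIN27_NAMES = {1: "Scalp", 2: "CSF", 3: "GM", 4: "WM"}

_DIGIMOUSE_PROPS = {
    1: OpticalProps(0.0191, 6.6, 0.9, 1.37),    # Skin
    2: OpticalProps(0.0136, 8.6, 0.9, 1.37),    # Skeleton
    3: OpticalProps(0.0026, 0.01, 0.9, 1.37),   # Eye
    4: OpticalProps(0.0186, 11.1, 0.9, 1.37),   # Medulla
    5: OpticalProps(0.0186, 11.1, 0.9, 1.37),   # Cerebellum
    6: OpticalProps(0.0186, 11.1, 0.9, 1.37),   # Olfactory bulbs
    7: OpticalProps(0.0186, 11.1, 0.9, 1.37),   # External cerebrum
    8: OpticalProps(0.0186, 11.1, 0.9, 1.37),   # Striatum
    9: OpticalProps(0.024, 8.9, 0.9, 1.37),     # Heart
    10: OpticalProps(0.0026, 0.01, 0.9, 1.37),  # Rest of the brain
    11: OpticalProps(0.024, 8.9, 0.9, 1.37),    # Masseter muscles
    12: OpticalProps(0.024, 8.9, 0.9, 1.37),    # Lachrymal glands
    13: OpticalProps(0.024, 8.9, 0.9, 1.37),    # Bladder
    14: OpticalProps(0.024, 8.9, 0.9, 1.37),    # Testis
    15: OpticalProps(0.024, 8.9, 0.9, 1.37),    # Stomach
    16: OpticalProps(0.072, 5.6, 0.9, 1.37),    # Spleen
    17: OpticalProps(0.072, 5.6, 0.9, 1.37),    # Pancreas
    18: OpticalProps(0.072, 5.6, 0.9, 1.37),    # Liver
    19: OpticalProps(0.05, 5.4, 0.9, 1.37),     # Kidneys
    20: OpticalProps(0.024, 8.9, 0.9, 1.37),    # Adrenal glands
    21: OpticalProps(0.076, 10.9, 0.9, 1.37),   # Lungs
}

_DIGIMOUSE_NAMES = {
    1: "Skin", 2: "Skeleton", 3: "Eye", 4: "Medulla", 5: "Cerebellum",
    6: "Olfactory bulbs", 7: "External cerebrum", 8: "Striatum", 9: "Heart",
    10: "Rest of the brain", 11: "Masseter muscles", 12: "Lachrymal glands",
    13: "Bladder", 14: "Testis", 15: "Stomach", 16: "Spleen", 17: "Pancreas",
    18: "Liver", 19: "Kidneys", 20: "Adrenal glands", 21: "Lungs",
}


def build_benchmark(name: str, nphoton: int = 100000, seed: int = 1,
                    external_input=None,
                    rough_amplitude: float = 0.0005,
                    rough_seed: int = 0) -> BenchmarkSpec:
    """Return the fully populated benchmark configuration.

    ``rough_amplitude`` (mm, model scale before unit scaling is irrelevant —
    it is applied in mm directly) only affects ``skinvessel_rough``.
    """
    if name == "skinvessel":
        unit = 0.005
        scene = build_scene(Box((0, 0, 0), (200, 200, 200)), unit,
                            _skinvessel_regions())
        source = PhotonSource(
            position=(100 * unit, 100 * unit, -10 * unit),
            quaternion=_quat_about_x(180.0),
            srctype="disk", srcparam1=(50.0, 0.0, 0.0, 0.0),
            unit_scale=unit, nphoton=nphoton)
        return BenchmarkSpec(
            name=name, scene=scene, props=dict(_SKINVESSEL_PROPS),
            source=source,
            settings=SimSettings(seed=seed, do_reflection=False),
            meshing=MeshingOptions(max_tet_volume=30 * unit ** 3),
            region_names={1: "Low-slab", 2: "Mid-slab", 3: "High-slab",
                          4: "Cylinder"})

    if name == "skinvessel_rough":
        unit = 0.0005
        regions = _skinvessel_regions()
        # replace the Low/Mid interface (plane-1 at z=20 voxels) with a
        # randomized height field; extents/heights here are in voxel units,
        # scaled to mm by build_scene
        surf = roughsurf.make_grid_surface((200.0, 200.0), cuts=39,
                                           base_z=20.0)
        surf = roughsurf.randomize_normals(surf, rough_amplitude / unit,
                                           seed=rough_seed)
        hf = roughsurf.surface_to_region(surf)
        regions[0] = Region(1, hf, "Low-slab")
        regions[1] = Region(2, ZSlab(0.0, 32.0), "Mid-slab")
        # order: Mid fills [0,32), Low (height field) overrides below the
        # rough interface, High above, Cylinder last
        regions = [regions[1], regions[0], regions[2], regions[3]]
        scene = build_scene(Box((0, 0, 0), (200, 200, 200)), unit, regions)
        source = PhotonSource(
            position=(100 * unit, 50 * unit, -50 * unit),
            quaternion=_quat_about_x(150.0),
            srctype="disk", srcparam1=(50.0, 0.0, 0.0, 0.0),
            unit_scale=unit, nphoton=nphoton)
        return BenchmarkSpec(
            name=name, scene=scene, props=dict(_SKINVESSEL_PROPS),
            source=source,
            settings=SimSettings(seed=seed, do_reflection=False),
            meshing=MeshingOptions(max_tet_volume=30 * unit ** 3),
            region_names={1: "Low-slab", 2: "Mid-slab", 3: "High-slab",
                          4: "Cylinder"})

    if name == "slab_hair":
        # three-layer head slab, mm: brain 20, CSF 2.07, scalp/skull 12.44
        regions = [
            Region(1, ZSlab(0.0, 20.0), "Brain"),
            Region(2, ZSlab(20.0, 22.07), "CSF"),
            Region(3, ZSlab(22.07, 34.51), "Scalp/skull"),
        ]
        scene = build_scene(Box((0, 0, 0), (20, 50, 34.51)), 1.0, regions)
        props = {1: _COLIN27_PROPS[3], 2: _COLIN27_PROPS[2],
                 3: _COLIN27_PROPS[1]}
        source = PhotonSource(position=(10.0, 25.0, 34.51),
                              direction=(0.0, 0.0, -1.0),
                              srctype="pencil", nphoton=nphoton)
        return BenchmarkSpec(
            name=name, scene=scene, props=props, source=source,
            settings=SimSettings(seed=seed, do_reflection=False),
            meshing=MeshingOptions(max_tet_volume=4.0),
            region_names={1: "Brain", 2: "CSF", 3: "Scalp/skull"},
            hair_params=HairParams(count=1000, length=8.0, segments=8,
                                   tilt_angle=45.0, tilt_axis=(1, 0, 0),
                                   randomness=0.2, gravity=1.0, seed=seed),
            hair_surface_label=3)

    if name == "colin27":
        spec = BenchmarkSpec(
            name=name, scene=None, props=dict(_COLIN27_PROPS),
            source=PhotonSource(position=(75.76, 66.99, 168.21),
                                direction=_unit((0.1636, 0.4569, -0.873)),
                                srctype="pencil", nphoton=nphoton),
            settings=SimSettings(seed=seed, do_reflection=False),
            meshing=MeshingOptions(max_tet_volume=100.0),
            region_names=dict(_COLIN27_NAMES),
            external_input=Path(external_input) if external_input else None)
        return spec

    if name == "digimouse":
        spec = BenchmarkSpec(
            name=name, scene=None, props=dict(_DIGIMOUSE_PROPS),
            source=PhotonSource(position=(40.0, 160.0, 80.0),
                                direction=(0.0, 0.0, -1.0),
                                srctype="pencil", unit_scale=0.8,
                                nphoton=nphoton),
            settings=SimSettings(seed=seed, do_reflection=False),
            meshing=MeshingOptions(max_tet_volume=100.0),
            region_names=dict(_DIGIMOUSE_NAMES),
            external_input=Path(external_input) if external_input else None)
        return spec

    raise ValueError(f"unknown benchmark {name!r}; "
                     f"available: {', '.join(BENCHMARK_NAMES)}")


def _unit(v):
    v = np.asarray(v, dtype=np.float64)
    return tuple(v / np.linalg.norm(v))


def _quat_about_x(deg: float):
    half = np.deg2rad(deg) / 2.0
    return (np.cos(half), np.sin(half), 0.0, 0.0)


def _top_surface(mesh: TetMesh, label: int) -> SurfMesh:
    """Triangles of a region's shell lying on the domain's top plane."""
    shell = extract_region_surface(mesh, label)
    zmax = mesh.node[:, 2].max()
    on_top = np.all(
        np.abs(shell.vertices[shell.faces][:, :, 2] - zmax) < 1e-9, axis=1)
    return SurfMesh(vertices=shell.vertices, faces=shell.faces[on_top])


def run_pipeline(spec: BenchmarkSpec, outdir, nphoton: int | None = None,
                 seed: int | None = None) -> dict:
    """Execute scene → mesh → simulate → write; returns artifact paths.

    Missing external inputs (colin27/digimouse) raise FileNotFoundError with
    a remediation hint.  Reruns with identical inputs and seed reproduce
    identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {"name": spec.name}
    if nphoton is not None:
        spec.source.nphoton = nphoton
    if seed is not None:
        spec.settings.seed = seed

    t0 = time.perf_counter()
    if spec.scene is not None:
        scene_path = outdir / "scene.json"
        save_scene(spec.scene, scene_path)
        artifacts["scene"] = scene_path
        log.info("stage scene: wrote %s", scene_path)
        mesh = tetrahedralize_scene(spec.scene, spec.meshing)
    elif spec.name == "digimouse":
        if spec.external_input is None or not spec.external_input.exists():
            raise FileNotFoundError(
                "the digimouse benchmark needs the segmented mouse atlas "
                "volume (.jnii or .nii); pass external_input=<path> "
                "(downloadable from the mcx.space dataset collection)")
        vol = jmesh.read_volume(spec.external_input)
        mesh = volume_to_tetmesh(vol, spec.meshing)
    else:  # colin27
        if spec.external_input is None or not spec.external_input.exists():
            raise FileNotFoundError(
                "the colin27 benchmark needs the pregenerated brain-atlas "
                "tetrahedral mesh (.jmsh with MeshTet4 labels); pass "
                "external_input=<path>")
        doc = jmesh.read_mesh_document(spec.external_input)
        if not len(doc.tetrahedra):
            raise ValueError("colin27 input carries no tetrahedra")
        labels = doc.tet_labels if doc.tet_labels is not None else \
            np.ones(len(doc.tetrahedra), dtype=np.int32)
        mesh = TetMesh(node=doc.vertices, elem=doc.tetrahedra, labels=labels)
    t1 = time.perf_counter()
    metrics = mesh_metrics(mesh)
    log.info("stage mesh: %.2fs, %d nodes, %d elems, volume %.6g mm^3",
             t1 - t0, metrics["nodes"], metrics["elems"], metrics["volume"])
    mesh_path = outdir / "mesh.jmsh"
    jmesh.write_mesh_document(
        jmesh.MeshDocument(vertices=mesh.node, triangles=mesh.face,
                           tetrahedra=mesh.elem, tet_labels=mesh.labels),
        mesh_path)
    artifacts["mesh"] = mesh_path
    artifacts["mesh_metrics"] = metrics

    if spec.hair_params is not None:
        surf = _top_surface(mesh, spec.hair_surface_label)
        roots, normals = sample_roots(surf, spec.hair_params.count,
                                      spec.hair_params.seed)
        hairs = grow_hairs(roots, normals, spec.hair_params)
        hairs = apply_gravity_bend(hairs, spec.hair_params.gravity)
        hair_path = outdir / "hairs.jmsh"
        export_hairs(hairs, hair_path)
        artifacts["hairs"] = hair_path
        log.info("stage hairs: %d fibers exported", len(hairs.fibers))

    t2 = time.perf_counter()
    fluence = run_simulation(mesh, spec.props, spec.source, spec.settings)
    t3 = time.perf_counter()
    s = fluence.stats
    log.info("stage mcsim: %.2fs, launched %.6g, absorbed %.4f, escaped "
             "%.4f, truncated %.4f", t3 - t2, s["launched"],
             s["absorbed_fraction"], s["escaped_fraction"],
             s["truncated_fraction"])
    fl_path = outdir / "fluence.jmsh"
    jmesh.write_fluence(mesh, fluence, fl_path)
    artifacts["fluence"] = fl_path
    artifacts["stats"] = s
    artifacts["mesh_obj"] = mesh
    artifacts["fluence_obj"] = fluence
    return artifacts
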