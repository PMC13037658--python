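"""Seeded fixture generation: toy cortex, sensor cap, and shape basis.

The toy cortex is a folded sphere — an icosphere whose radius is modulated
by a deterministic sinusoidal pattern standing in for gyri and sulci — so
vertex normals vary over the surface the way cortical dipole orientations
do, at a fraction of a real cortical mesh's vertex count. Two presets are
provided: ``tiny`` (642 vertices, for fast suites) and ``standard``
(2562 vertices).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .bench import SimulationSpec
from .forward import SensorArray, make_sensor_array
from .mesh import Mesh
from .shape import ShapeBasis, synthesize_basis

PRESETS = {
    "tiny": dict(subdivisions=3, n_vertices=642, n_sensors=96),
    "standard": dict(subdivisions=4, n_vertices=2562, n_sensors=120),
}
DEFAULT_RADIUS_MM = 70.0
SENSOR_RADIUS_MM = 110.0


@dataclass
class FixtureSet:
    """Everything a benchmark run needs, regenerable from (preset, seed)."""

    mesh: Mesh
    sensors: SensorArray
    basis: ShapeBasis
    sim_spec: SimulationSpec
    master_seed: int
    preset: str
    paths: dict = field(default_factory=dict)


def folded_sphere_mesh(
    subdivisions: int = 3,
    radius: float = DEFAULT_RADIUS_MM,
    gyral_amplitude: float = 0.08,
    gyral_frequency: float = 6.0,
) -> Mesh:
    """Icosphere with deterministic sinusoidal radial folding, centred at 0.

    r(u) = radius * (1 + a * (sin(f u_x) sin(f u_y) + sin(f u_z)) / 2) for a
    unit direction u — a closed genus-0 surface whose folds mimic gyral
    curvature while staying star-shaped (no self-intersections).
    """
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    u = np.asarray(ico.vertices, dtype=np.float64)
    u /= np.linalg.norm(u, axis=1)[:, None]
    f = gyral_frequency
    mod = 0.5 * (np.sin(f * u[:, 0]) * np.sin(f * u[:, 1]) + np.sin(f * u[:, 2]))
    vertices = u * (radius * (1.0 + gyral_amplitude * mod))[:, None]
    vertices = vertices - vertices.mean(axis=0)
    return Mesh(vertices=vertices, faces=np.asarray(ico.faces, dtype=np.int64))


def default_source_vertex(mesh: Mesh) -> int:
    """Vertex nearest a canonical superior-lateral direction (sensorimotor-ish)."""
    d = np.array([-0.4, -0.2, 0.9])
    d /= np.linalg.norm(d)
    return int(np.argmax(mesh.vertices @ d))


def generate_fixtures(
    master_seed: int = 0,
    preset: str = "tiny",
    outdir: str | Path | None = None,
    K: int = 100,
    calibration_target_mm: float = 3.5,
    smoothness_mm: float = 20.0,
) -> FixtureSet:
    """Build (and optionally write) the full seeded fixture set.

    Writes, when ``outdir`` is given: the mesh as OFF and GIFTI, the sensor
    table, the basis table with its JSON sidecar, and a config echo.
    Regeneration from the same (preset, master_seed) is bit-identical.
    """
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r} (expected one of {sorted(PRESETS)})")
    p = PRESETS[preset]
    mesh = folded_sphere_mesh(subdivisions=p["subdivisions"])
    sensors = make_sensor_array(
        n=p["n_sensors"], radius=SENSOR_RADIUS_MM, seed=master_seed
    )
    basis = synthesize_basis(
        mesh,
        K=K,
        smoothness=smoothness_mm,
        seed=master_seed,
        calibration_target_mm=calibration_target_mm,
    )
    spec = SimulationSpec(source_vertex=default_source_vertex(mesh), seed=master_seed)
    fx = FixtureSet(
        mesh=mesh,
        sensors=sensors,
        basis=basis,
        sim_spec=spec,
        master_seed=master_seed,
        preset=preset,
    )
    if outdir is not None:
        from . import io as cio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_mesh(mesh, outdir / "cortex.off")
        cio.write_mesh(mesh, outdir / "cortex.surf.gii")
        cio.save_sensors(sensors, outdir / "sensors.tsv")
        cio.save_basis(basis, outdir / "basis.tsv")
        cio.save_json(
            outdir / "fixtures.json",
            dict(
                preset=preset,
                master_seed=master_seed,
                K=K,
                calibration_target_mm=calibration_target_mm,
                smoothness_mm=smoothness_mm,
                n_vertices=mesh.n_vertices,
                n_sensors=sensors.n_channels,
                source_vertex=spec.source_vertex,
            ),
        )
        fx.paths = {
            "mesh_off": str(outdir / "cortex.off"),
            "mesh_gii": str(outdir / "cortex.surf.gii"),
            "sensors": str(outdir / "sensors.tsv"),
            "basis": str(outdir / "basis.tsv"),
            "meta": str(outdir / "fixtures.json"),
        }
    return fx
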