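"""Single-sphere MEG forward model for surface-normal current dipoles.

The conductor is a homogeneous sphere, for which the external magnetic field
of a current dipole has the classic closed form (volume currents included);
radial magnetometers sample the field along their orientation. Gains are in
fT per nAm with positions in mm. The sphere centre is the only conductor
parameter and is held fixed across a distortion trajectory so that only the
source geometry varies between surrogate anatomies.

Permuting the channel rows of a lead field breaks the biophysical link
between the data and the anatomy while leaving the data untouched; such
permuted lead fields serve as the null model for chance-level scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import Mesh

MU0 = 4e-7 * np.pi  # T m / A
_MM = 1e-3  # mm -> m
_FT_PER_T = 1e15
_NAM = 1e-9  # nAm -> Am


@dataclass
class SensorArray:
    """Magnetometer positions (mm), unit orientations, and labels."""

    positions: np.ndarray
    orientations: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.orientations = np.asarray(self.orientations, dtype=np.float64)
        if self.positions.shape != self.orientations.shape:
            raise ValueError("positions and orientations must have equal shape")
        nrm = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(nrm, 1.0, atol=1e-9):
            raise ValueError("orientations must be unit vectors")

    @property
    def n_channels(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class SphereModel:
    """Spherically symmetric conductor; only the centre matters for MEG."""

    center: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.center, dtype=np.float64)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValueError("center must be a finite 3-vector")
        object.__setattr__(self, "center", c)


@dataclass
class LeadField:
    """Channels x sources gain matrix in fT per nAm.

    ``permuted`` flags a null-model lead field whose channel rows were
    shuffled with ``permutation_seed``.
    """

    matrix: np.ndarray
    channel_labels: list[str]
    n_sources: int = 0
    units: str = "fT/nAm"
    permuted: bool = False
    permutation_seed: int | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("non-finite lead-field gains")
        if self.n_sources == 0:
            self.n_sources = self.matrix.shape[1]
        if self.matrix.shape != (len(self.channel_labels), self.n_sources):
            raise ValueError("lead-field shape inconsistent with labels/sources")

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[0]


def make_sensor_array(
    n: int = 120,
    radius: float = 110.0,
    coverage_deg: float = 105.0,
    seed: int = 0,
) -> SensorArray:
    """Near-uniform radial magnetometers on an upper spherical cap.

    Points follow a Fibonacci spiral over polar angles [0, coverage_deg]
    measured from +z; the seed sets the (arbitrary) azimuthal phase. The
    array is centred on the origin, which after fixture generation coincides
    with the conductor-sphere centre.
    """
    if n < 10:
        raise ValueError("need at least 10 sensors")
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    i = np.arange(n)
    cos_max = np.cos(np.deg2rad(coverage_deg))
    z = 1.0 - (1.0 - cos_max) * (i + 0.5) / n  # uniform in cos(theta) on the cap
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = phase + golden * i
    u = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    labels = [f"MEG{k + 1:03d}" for k in range(n)]
    return SensorArray(positions=radius * u, orientations=u, labels=labels)


def fit_sphere(mesh: Mesh) -> SphereModel:
    """Sphere centre = vertex centroid of the (undistorted) source mesh."""
    return SphereModel(center=mesh.centroid())


def vertex_normals(mesh: Mesh, sphere: SphereModel | None = None) -> np.ndarray:
    """Area-weighted per-vertex unit normals, oriented outward.

    Face normals (weighted by face area via the raw cross product) are
    accumulated onto their vertices and normalized. Orientation is made
    outward — away from the sphere centre (the mesh centroid when no sphere
    is given). Raises on isolated vertices with no incident face.
    """
    tri = mesh.vertices[mesh.faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # 2*area weighted
    acc = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(acc, mesh.faces[:, k], fn)
    nrm = np.linalg.norm(acc, axis=1)
    if np.any(nrm < 1e-300):
        bad = int(np.argmin(nrm))
        raise ValueError(f"vertex {bad} has no incident face (isolated or degenerate)")
    normals = acc / nrm[:, None]
    center = sphere.center if sphere is not None else mesh.centroid()
    outward = np.einsum("ij,ij->i", normals, mesh.vertices - center)
    normals[outward < 0] *= -1.0
    return normals


def compute_leadfield(
    mesh: Mesh,
    normals: np.ndarray,
    sphere: SphereModel,
    sensors: SensorArray,
) -> LeadField:
    """Closed-form spherical-conductor gains for unit dipoles along ``normals``.

    Column i is the field of a 1 nAm dipole at vertex i, oriented along
    normals[i], projected on each magnetometer's orientation, in fT. Radial
    dipoles are magnetically silent in this model by construction.
    """
    normals = np.asarray(normals, dtype=np.float64)
    if normals.shape != mesh.vertices.shape:
        raise ValueError("normals must match mesh vertices in shape")
    r0 = (mesh.vertices - sphere.center) * _MM  # (Nv, 3) dipole positions, m
    rs = (sensors.positions - sphere.center) * _MM  # (Nc, 3) sensor positions, m
    q = normals * _NAM  # unit 1 nAm moments, Am

    r0n = np.linalg.norm(r0, axis=1)
    if np.any(r0n < 1e-9 * _MM):
        raise ValueError("dipole at the sphere centre (field undefined)")
    rsn = np.linalg.norm(rs, axis=1)
    if rsn.min() <= r0n.max():
        raise ValueError("sensors must lie strictly outside all dipoles")

    qxr0 = np.cross(q, r0)  # (Nv, 3)
    gains = np.empty((sensors.n_channels, mesh.n_vertices))
    for c in range(sensors.n_channels):
        r = rs[c]
        rn = rsn[c]
        a_vec = r[None, :] - r0  # (Nv, 3)
        a = np.linalg.norm(a_vec, axis=1)
        if np.any(a < 1e-12):
            raise ValueError("dipole coincident with a sensor")
        ar = a_vec @ r  # a . r
        r0r = r0 @ r  # r0 . r
        F = a * (rn * a + rn * rn - r0r)
        gradF = (
            (a * a / rn + ar / a + 2.0 * a + 2.0 * rn)[:, None] * r[None, :]
            - (a + 2.0 * rn + ar / a)[:, None] * r0
        )
        B = (MU0 / (4.0 * np.pi * F * F))[:, None] * (
            F[:, None] * qxr0 - (qxr0 @ r)[:, None] * gradF
        )
        gains[c] = (B @ sensors.orientations[c]) * _FT_PER_T
    return LeadField(matrix=gains, channel_labels=list(sensors.labels))


def permute_leadfield_rows(
    leadfield: LeadField,
    seed: int,
    permutation: np.ndarray | None = None,
) -> LeadField:
    """Null-model lead field with channel rows shuffled by a seeded permutation.

    The multiset of rows is preserved; ``permutation`` overrides the seeded
    draw when an explicit row order is wanted.
    """
    if permutation is None:
        rng = np.random.default_rng(seed)
        permutation = rng.permutation(leadfield.n_channels)
    permutation = np.asarray(permutation, dtype=np.int64)
    if sorted(permutation.tolist()) != list(range(leadfield.n_channels)):
        raise ValueError("not a valid permutation of channel rows")
    return LeadField(
        matrix=leadfield.matrix[permutation],
        channel_labels=list(leadfield.channel_labels),
        permuted=True,
        permutation_seed=int(seed),
    )
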