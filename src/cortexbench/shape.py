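"""Synthetic latent shape space and distortion trajectories.

A cortical surface is distorted by stepping a K-dimensional latent code away
from the origin (the true anatomy) along a pseudo-random sign pattern. The
displacement basis here is synthetic: the first seven components are global
affine (size/shear) fields, which trajectories clamp to zero so brain volume
is approximately conserved; the remaining components are graph-smoothed random
vertex displacement fields, orthonormalized so a latent step of unit norm
produces a comparable deformation whatever its direction.

Deformation is linear in the latent code (vertex' = vertex + scale * W dz),
so the zero code is an exact identity and opposite codes produce mirror-image
displacements of equal magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import Mesh, mesh_distance

DEFAULT_K = 100
DEFAULT_SIZE_COMPONENTS = tuple(range(1, 8))  # 1-based component indices
DEFAULT_Z = 3.0
DEFAULT_N = 17
DEFAULT_CALIBRATION_MM = 3.5
DEFAULT_CALIBRATION_SEED = 1


@dataclass(frozen=True)
class SignVector:
    """Pseudo-random component signs defining a trajectory direction.

    Entries are +/-1 for free components and exactly 0 for the size
    (low-order) components; fully determined by ``seed``.
    """

    s: np.ndarray
    seed: int
    size_components: tuple[int, ...]

    @property
    def K(self) -> int:
        return len(self.s)

    @property
    def n_free(self) -> int:
        return int(np.count_nonzero(self.s))


@dataclass(frozen=True)
class Trajectory:
    """N latent-step vectors moving symmetrically through the true anatomy.

    ``steps[j-1]`` (1-based j) is the latent offset dz for surface j:
    dz_{i,j} = 2 Z (j - (N+1)/2) s_i / N. The midpoint step (N+1)/2 is the
    all-zero vector and steps are antisymmetric about it.
    """

    sign_vector: SignVector
    Z: float
    N: int
    steps: np.ndarray  # (N, K)

    def step(self, j: int) -> np.ndarray:
        """Latent offset for surface j (1-based, 1 <= j <= N)."""
        if not 1 <= j <= self.N:
            raise IndexError(f"step index {j} outside 1..{self.N}")
        return self.steps[j - 1]

    @property
    def midpoint(self) -> int:
        """1-based index of the undistorted (dz = 0) surface."""
        return (self.N + 1) // 2

    @property
    def seed(self) -> int:
        return self.sign_vector.seed


@dataclass
class ShapeBasis:
    """K orthonormal displacement fields over the vertices of one mesh.

    ``fields`` has shape (K, Nv, 3) in mm per unit z-score before global
    calibration; ``global_scale`` converts latent steps into mm so that a
    default trajectory endpoint yields a target mean vertex displacement.
    """

    fields: np.ndarray
    size_components: tuple[int, ...]
    global_scale: float
    seed: int
    calibration_target_mm: float

    @property
    def K(self) -> int:
        return self.fields.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.fields.shape[1]


def make_sign_vector(
    seed: int,
    K: int = DEFAULT_K,
    size_components: tuple[int, ...] = DEFAULT_SIZE_COMPONENTS,
) -> SignVector:
    """Seeded fair-coin sign vector with size components clamped to zero.

    Each free component draws r in {0, 1} with probability 1/2 and maps to
    s = 2r - 1; components listed in ``size_components`` (1-based) are 0.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError("seed must be an integer")
    if K < 1:
        raise ValueError("K must be >= 1")
    size_components = tuple(size_components)
    if any(not 1 <= i <= K for i in size_components):
        raise ValueError("size_components must lie in 1..K")
    rng = np.random.default_rng(seed)
    r = rng.integers(0, 2, size=K)
    s = (2 * r - 1).astype(np.int8)
    idx = np.asarray(size_components, dtype=np.int64) - 1
    s[idx] = 0
    return SignVector(s=s, seed=int(seed), size_components=size_components)


def make_trajectory(
    sign_vector: SignVector, Z: float = DEFAULT_Z, N: int = DEFAULT_N
) -> Trajectory:
    """Build the N-step latent trajectory for one sign vector.

    dz_{i,j} = 2 Z (j - (N+1)/2) s_i / N for j = 1..N; N must be odd so the
    midpoint surface sits exactly at the origin.
    """
    if N % 2 == 0 or N < 3:
        raise ValueError("N must be odd and >= 3 (midpoint undefined otherwise)")
    if Z <= 0:
        raise ValueError("Z must be positive")
    j = np.arange(1, N + 1, dtype=np.float64)
    mag = 2.0 * Z * (j - (N + 1) / 2.0) / N  # (N,)
    steps = mag[:, None] * sign_vector.s[None, :].astype(np.float64)
    return Trajectory(sign_vector=sign_vector, Z=float(Z), N=int(N), steps=steps)


def _affine_fields(vertices: np.ndarray, n: int = 7) -> np.ndarray:
    """Global size/shape fields: 3 axis scalings, 3 symmetric shears, 1 rotation."""
    x = vertices - vertices.mean(axis=0)
    z = np.zeros(len(x))
    gens = [
        np.column_stack([x[:, 0], z, z]),        # scale x
        np.column_stack([z, x[:, 1], z]),        # scale y
        np.column_stack([z, z, x[:, 2]]),        # scale z
        np.column_stack([x[:, 1], x[:, 0], z]),  # shear xy
        np.column_stack([x[:, 2], z, x[:, 0]]),  # shear xz
        np.column_stack([z, x[:, 2], x[:, 1]]),  # shear yz
        np.column_stack([x[:, 1], -x[:, 0], z]), # rotation about z
    ]
    return np.stack(gens[:n])


def _smooth_fields(fields: np.ndarray, mesh: Mesh, rounds: int) -> np.ndarray:
    """Repeated half-self/half-neighbour averaging on the mesh graph."""
    from scipy import sparse

    e = mesh.edges()
    nv = mesh.n_vertices
    adj = sparse.coo_matrix(
        (np.ones(2 * len(e)), (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
        shape=(nv, nv),
    ).tocsr()
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    out = fields
    for _ in range(rounds):
        nbr = np.stack([adj @ out[k] for k in range(out.shape[0])])
        out = 0.5 * out + 0.5 * nbr / deg[None, :, None]
    return out


def synthesize_basis(
    mesh: Mesh,
    K: int = DEFAULT_K,
    smoothness: float = 20.0,
    seed: int = 0,
    calibration_target_mm: float = DEFAULT_CALIBRATION_MM,
    size_components: tuple[int, ...] = DEFAULT_SIZE_COMPONENTS,
    calibration_seed: int = DEFAULT_CALIBRATION_SEED,
) -> ShapeBasis:
    """Generate an orthonormal synthetic displacement basis on a mesh.

    The first seven components are global affine fields (clamped by default
    trajectories); the rest are seeded Gaussian per-vertex displacement
    fields smoothed by repeated neighbour averaging (the number of rounds is
    set so the diffusion length matches ``smoothness`` in mm) and then
    orthonormalized by modified Gram-Schmidt, affine fields first. Finally
    ``global_scale`` is calibrated so that deforming to the endpoint of the
    default trajectory (seed ``calibration_seed``, Z=3, N=17) displaces
    vertices by ``calibration_target_mm`` on average.
    """
    if smoothness <= 0:
        raise ValueError("smoothness must be positive (mm)")
    if calibration_target_mm <= 0:
        raise ValueError("calibration target must be positive (mm)")
    if K > 3 * mesh.n_vertices:
        raise ValueError("K exceeds the degrees of freedom of the mesh")
    n_size = len(size_components)
    if K <= n_size:
        raise ValueError("K must exceed the number of size components")

    nv = mesh.n_vertices
    e = mesh.edges()
    mean_edge = float(
        np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1).mean()
    )
    rounds = max(1, int(round((smoothness / mean_edge) ** 2)))

    rng = np.random.default_rng(seed)
    raw = rng.standard_normal((K - n_size, nv, 3))
    raw = _smooth_fields(raw, mesh, rounds)
    fields = np.concatenate([_affine_fields(mesh.vertices, n_size), raw])

    # Modified Gram-Schmidt over flattened (3 Nv)-vectors, affine fields first
    # so the random fields end up orthogonal to every global size/shear mode.
    flat = fields.reshape(K, -1)
    for i in range(K):
        for j in range(i):
            flat[i] -= (flat[j] @ flat[i]) * flat[j]
        nrm = np.linalg.norm(flat[i])
        if nrm < 1e-12:
            raise ValueError(f"basis field {i + 1} degenerate after orthogonalization")
        flat[i] /= nrm
    fields = flat.reshape(K, nv, 3)

    basis = ShapeBasis(
        fields=fields,
        size_components=tuple(size_components),
        global_scale=1.0,
        seed=int(seed),
        calibration_target_mm=float(calibration_target_mm),
    )
    sv = make_sign_vector(calibration_seed, K=K, size_components=size_components)
    traj = make_trajectory(sv, Z=DEFAULT_Z, N=DEFAULT_N)
    end = deform_mesh(mesh, basis, traj.step(traj.N))
    raw_mean = mesh_distance(mesh, end).mean_mm
    basis.global_scale = float(calibration_target_mm / raw_mean)
    return basis


def deform_mesh(mesh: Mesh, basis: ShapeBasis, dz: np.ndarray) -> Mesh:
    """Apply a latent offset: vertex' = vertex + global_scale * sum_i dz_i field_i.

    Linear in dz, so dz = 0 is an exact identity and successive applications
    add. Topology and vertex order are preserved.
    """
    dz = np.asarray(dz, dtype=np.float64)
    if dz.shape != (basis.K,):
        raise ValueError(f"dz must have length K={basis.K}, got shape {dz.shape}")
    if not np.all(np.isfinite(dz)):
        raise ValueError("non-finite entries in dz")
    if basis.n_vertices != mesh.n_vertices:
        raise ValueError("basis was built on a mesh with a different vertex count")
    disp = np.tensordot(dz, basis.fields, axes=1)
    return mesh.with_vertices(mesh.vertices + basis.global_scale * disp)


def trajectory_similarity(traj_a: Trajectory, traj_b: Trajectory) -> float:
    """Squared Pearson correlation between two trajectories' direction vectors.

    The direction vector is the latent offset at the last (nonzero) step;
    the squared correlation is invariant to the step chosen and to a global
    sign flip of either trajectory.
    """
    a = traj_a.step(traj_a.N)
    b = traj_b.step(traj_b.N)
    if len(a) != len(b):
        raise ValueError("trajectories have different K")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance direction vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def mean_pairwise_similarity(trajectories: list[Trajectory]) -> float:
    """Mean squared correlation over all distinct trajectory pairs."""
    if len(trajectories) < 2:
        raise ValueError("need at least two trajectories")
    vals = [
        trajectory_similarity(trajectories[i], trajectories[j])
        for i in range(len(trajectories))
        for j in range(i + 1, len(trajectories))
    ]
    return float(np.mean(vals))
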