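"""Shared fixtures: the tiny seeded toy cortex and its forward/simulated data.

Session-scoped so the expensive pieces (basis synthesis, lead field,
simulation) are built once for the whole suite.
"""

import numpy as np
import pytest

import cortexbench as cb


@pytest.fixture(scope="session")
def fx():
    """Tiny preset fixture set (642-vertex folded sphere, 96 sensors)."""
    return cb.generate_fixtures(master_seed=0, preset="tiny")


@pytest.fixture(scope="session")
def sphere(fx):
    return cb.fit_sphere(fx.mesh)


@pytest.fixture(scope="session")
def leadfield(fx, sphere):
    normals = cb.vertex_normals(fx.mesh, sphere)
    return cb.compute_leadfield(fx.mesh, normals, sphere, fx.sensors)


@pytest.fixture(scope="session")
def evoked(fx, leadfield):
    """Default single-dipole simulation on the tiny fixture."""
    return cb.simulate_evoked(fx.mesh, leadfield, fx.sim_spec)


@pytest.fixture(scope="session")
def trajectories():
    """The eight default seeded trajectories (K=100, components 1-7 clamped)."""
    return [
        cb.make_trajectory(cb.make_sign_vector(seed, K=100)) for seed in range(1, 9)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
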