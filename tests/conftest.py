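"""Shared fixtures: small meshes and solved states reused across the suite."""

import numpy as np
import pytest

from furrowshell.geometry import (
    GeometryParams,
    GaussianRowProfile,
    assign_prestrain,
    build_vitelline,
    generate_embryo_mesh,
)
from furrowshell.shell_solver import ElasticParams, ShellModel, minimize_energy

GAP = 0.004


@pytest.fixture(scope="session")
def small_mesh():
    """Coarse embryo mesh (512 facets) for fast structural tests."""
    return generate_embryo_mesh(GeometryParams(subdivisions=3))


@pytest.fixture(scope="session")
def test_mesh():
    """Test-resolution embryo mesh (2048 facets)."""
    return generate_embryo_mesh(GeometryParams(subdivisions=4))


@pytest.fixture(scope="session")
def elastic():
    return ElasticParams()


@pytest.fixture(scope="session")
def small_vitelline(small_mesh):
    return build_vitelline(small_mesh, GAP)


@pytest.fixture(scope="session")
def solved_043(small_mesh, elastic, small_vitelline):
    """Converged equilibrium at graded midline pre-strain 0.43 (coarse mesh)."""
    mesh = assign_prestrain(small_mesh, GaussianRowProfile(), 0.43)
    model = ShellModel(mesh, elastic, small_vitelline)
    state = minimize_energy(
        small_mesh.vertices,
        mesh,
        elastic,
        small_vitelline,
        tolerance=1e-3,
        model=model,
        eps_midline=0.43,
    )
    assert state.converged
    return mesh, state


@pytest.fixture(scope="session")
def small_ramp(small_mesh, elastic, small_vitelline):
    """Short warm-started ramp (0 -> 0.43) on the coarse mesh."""
    from furrowshell.shell_solver import RampSchedule, ramp_prestrain

    schedule = RampSchedule((0.0, 0.2, 0.43))
    traj = ramp_prestrain(
        small_mesh, elastic, small_vitelline, schedule, tolerance=1e-3
    )
    assert not traj.truncated
    return traj


def mirror_map(vertices, axis):
    """Index map pairing each vertex with its mirror partner about ``axis``."""
    key = np.round(vertices / 1e-8).astype(np.int64)
    mirrored = key.copy()
    mirrored[:, axis] *= -1
    lookup = {tuple(k): i for i, k in enumerate(key)}
    return np.array([lookup[tuple(m)] for m in mirrored])
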