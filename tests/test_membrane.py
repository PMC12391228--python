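"""Membrane elasticity: energies, exact gradients, pair viscosity."""

import numpy as np
import pytest

from cellflow import _kernels
from cellflow import membrane as mb
from cellflow.dpd import ParticleSystem, ParticleType, kinetic_temperature
from cellflow.engine import MembraneInstance, Simulation

from conftest import membrane_params_for


def _fd_check(mesh, params, efun, ffun, rng, n_vertices=8, h=1e-6):
    pos = mesh.vertices + 0.02 * rng.standard_normal(mesh.vertices.shape)
    f = ffun(mesh, params, pos)
    worst = 0.0
    scale = max(1.0, np.abs(f).max())
    for i in rng.integers(0, mesh.n_vertices, n_vertices):
        for d in range(3):
            pp = pos.copy()
            pp[i, d] += h
            pm = pos.copy()
            pm[i, d] -= h
            fd = -(efun(mesh, params, pp) - efun(mesh, params, pm)) / (2 * h)
            worst = max(worst, abs(fd - f[i, d]) / scale)
    return worst


@pytest.mark.parametrize("term", ["inplane", "bending", "area_volume", "total"])
def test_forces_are_exact_negative_gradients(term, tiny_mesh, rng):
    """Analytic forces match central finite differences to < 1e-5."""
    params = membrane_params_for(tiny_mesh)
    efun = getattr(mb, f"{term}_energy")
    ffun = getattr(mb, f"{term}_forces")
    for _ in range(5):
        assert _fd_check(tiny_mesh, params, efun, ffun, rng) < 1e-5


def test_wlc_bond_energy_strictly_increasing_on_unit_interval():
    x = np.linspace(0.01, 0.95, 400)
    u = (3 * x**2 - 2 * x**3) / (1 - x)
    assert np.all(np.diff(u) > 0)
    # and it vanishes at x = 0
    assert u[0] == pytest.approx(0.0, abs=1e-3)


def test_bond_overextension_raises(tiny_mesh):
    params = membrane_params_for(tiny_mesh, l_max=0.6)
    pos = tiny_mesh.vertices * 1.5  # stretches every bond past l_max
    with pytest.raises(mb.BondOverextensionError, match="bond"):
        mb.inplane_energy(tiny_mesh, params, pos)


def test_bending_minimum_and_folded_pair():
    # flat quadruple: theta = 0, energy 0, forces 0
    pos = np.array([
        [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, 1.0, 0.0], [0.5, -1.0, 0.0]
    ])
    dihedrals = np.array([[0, 1, 2, 3]])
    f = np.zeros_like(pos)
    e, bad = _kernels.bending_forces(pos, dihedrals, 65.0, 0.0, f)
    assert bad == -1
    assert e == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(f, 0.0, atol=1e-10)
    # fully folded pair (theta - theta_0 = pi): second triangle flipped
    # onto the first, energy 2 k_b
    pos_folded = np.array([
        [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, 1.0, 0.0], [0.5, 0.9, 0.0]
    ])
    f2 = np.zeros_like(pos_folded)
    e2, _ = _kernels.bending_forces(pos_folded, dihedrals, 65.0, 0.0, f2)
    assert e2 == pytest.approx(2 * 65.0, rel=1e-9)


def test_sphere_dihedral_angles_positive(small_mesh):
    """Convex-outward surfaces carry positive dihedral angles: shifting
    theta_0 slightly positive lowers the bending energy of a sphere."""
    params0 = membrane_params_for(small_mesh, theta_0=0.0)
    params1 = membrane_params_for(small_mesh, theta_0=0.1)
    assert mb.bending_energy(small_mesh, params1) < mb.bending_energy(
        small_mesh, params0
    )


def test_area_penalty_value_at_ten_percent_inflation(small_mesh):
    """U_a = 0.005 k_a kBT A_0 / l_0^2 when A = 1.1 A_0."""
    params = membrane_params_for(small_mesh, k_vol=0.0)
    pos = small_mesh.vertices * np.sqrt(1.1)
    expected = 0.005 * params.k_a * params.kbt * params.a_0 / params.l_0**2
    assert mb.area_volume_energy(small_mesh, params, pos) == pytest.approx(
        expected, rel=1e-9
    )
    assert mb.area_volume_energy(small_mesh, params) == pytest.approx(0.0, abs=1e-9)


def test_membrane_forces_conserve_momentum(small_mesh, rng):
    params = membrane_params_for(small_mesh)
    pos = small_mesh.vertices + 0.02 * rng.standard_normal((small_mesh.n_vertices, 3))
    total = mb.total_forces(small_mesh, params, pos).sum(axis=0)
    assert np.allclose(total, 0.0, atol=1e-9)


def test_pair_dissipative_decomposition():
    from cellflow.membrane import MembraneParams, membrane_pair_dissipative_random

    p = MembraneParams(p=0.00141, l_max=3.0, l_0=0.5, k_b=65.0, k_a=0.0,
                       k_vol=0.0, a_0=1.0, v_0=1.0, gamma=4.0, kbt=0.1)
    r_i = np.array([0.5, 0.0, 0.0])
    r_j = np.zeros(3)
    # at rest with zero noise: zero force
    f_i, f_j = membrane_pair_dissipative_random(
        r_i, r_j, np.zeros(3), np.zeros(3), p, np.zeros((3, 3)), 0.01
    )
    assert np.allclose(f_i, 0.0) and np.allclose(f_j, 0.0)
    # purely tangential relative velocity: force is -gamma^T v_ij only
    v_i = np.array([0.0, 0.7, 0.0])
    f_i, f_j = membrane_pair_dissipative_random(
        r_i, r_j, v_i, np.zeros(3), p, np.zeros((3, 3)), 0.01
    )
    assert np.allclose(f_i, -p.gamma * v_i, atol=1e-12)
    assert np.allclose(f_i, -f_j, atol=1e-12)


def test_membrane_thermostat_reaches_kbt(small_mesh):
    """A membrane thermostated only by its own bond dissipative+random
    pair forces equilibrates to kBT within 10%."""
    params = membrane_params_for(small_mesh)
    n = small_mesh.n_vertices
    s = ParticleSystem(
        positions=small_mesh.vertices.copy(), velocities=np.zeros((n, 3)),
        types=np.full(n, ParticleType.CELL_MEMBRANE, dtype=np.int64),
        box=np.array([20.0] * 3), periodic=np.array([False] * 3),
    )
    sim = Simulation(s, membranes=[MembraneInstance(small_mesh, params, 0)], seed=6)
    sim.dt = 0.005
    sim.run(3000)
    temps = []
    for _ in range(200):
        sim.run(5)
        temps.append(kinetic_temperature(s))
    assert np.mean(temps) == pytest.approx(params.kbt, rel=0.10)
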