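"""KV bond mechanics and network wiring (M1/M2, nucleus 5x rule)."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellflow.builder import build_cell
from cellflow.cytoskeleton import (
    NUCLEUS_STIFFNESS_FACTOR,
    BondNetwork,
    KvBond,
    TopologySpec,
    build_cytoskeleton,
    build_nucleus_network,
    kv_bond_force,
    select_eligible,
)
from cellflow.dpd import ParticleSystem, ParticleType
from cellflow.engine import Simulation
from cellflow.mesh import make_sphere_mesh


def test_bond_validation():
    with pytest.raises(ValueError):
        KvBond(1, 1, 1.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        KvBond(0, 1, -1.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        KvBond(0, 1, 1.0, 1.0, 0.0)


def test_kv_force_zero_at_rest_and_linear_in_strain():
    bond = KvBond(0, 1, k_s=120.0, k_v_damp=10.0, l_0b=2.0)
    r_i, r_j = np.array([2.0, 0, 0]), np.zeros(3)
    f_i, f_j = kv_bond_force(bond, r_i, r_j, np.zeros(3), np.zeros(3))
    assert np.allclose(f_i, 0.0) and np.allclose(f_j, 0.0)
    # held step strain, no velocity: tension k_s * eps exactly
    eps = 0.25
    f_i, f_j = kv_bond_force(
        bond, np.array([2.0 * (1 + eps), 0, 0]), r_j, np.zeros(3), np.zeros(3)
    )
    assert f_i[0] == pytest.approx(-120.0 * eps, rel=1e-12)
    assert np.allclose(f_i, -f_j)


def test_kv_force_coincident_particles_error():
    bond = KvBond(0, 1, 1.0, 1.0, 1.0)
    with pytest.raises(ValueError, match="coincident"):
        kv_bond_force(bond, np.zeros(3), np.zeros(3), np.zeros(3), np.zeros(3))


@settings(max_examples=30, deadline=None)
@given(
    st.floats(0.5, 3.0), st.floats(-0.5, 0.5), st.floats(-0.5, 0.5)
)
def test_kv_force_antisymmetric(l, vx, vy):
    bond = KvBond(0, 1, 50.0, 5.0, 1.0)
    r_i = np.array([l, 0.1, -0.2])
    v_i = np.array([vx, vy, 0.0])
    f_i, f_j = kv_bond_force(bond, r_i, np.zeros(3), v_i, np.zeros(3))
    assert np.allclose(f_i + f_j, 0.0, atol=1e-12)


def test_single_bond_creep_matches_kelvin_voigt_closed_form():
    """Constant tension on one KV bond: eps(t) = (sigma/k_s)(1 - e^(-t k_s/k_v))
    within 1% over five time constants."""
    k_s, k_v, l0 = 2.0, 20.0, 1.0
    tau = k_v / k_s
    sigma = 0.6
    net = BondNetwork(
        i=np.array([0]), j=np.array([1]), k_s=np.array([k_s]),
        k_v_damp=np.array([k_v]), l_0b=np.array([l0]),
    )
    pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    s = ParticleSystem(
        positions=pos, velocities=np.zeros((2, 3)),
        types=np.zeros(2, dtype=np.int64), box=np.array([100.0] * 3),
        periodic=np.array([False] * 3), origin=np.array([-50.0] * 3),
    )

    def tension(p, v, t):
        f = np.zeros_like(p)
        f[0, 0] = -sigma
        f[1, 0] = sigma
        return f

    sim = Simulation(s, kv_networks=[net], external_force=tension, seed=0)
    sim.dt = 0.002
    samples = []

    def cb(sm):
        l = sm.system.positions[1, 0] - sm.system.positions[0, 0]
        samples.append((sm.time, (l - l0) / l0))

    sim.run(int(5 * tau / sim.dt), callback=cb, every=50)
    t = np.array([a for a, _ in samples])
    eps = np.array([b for _, b in samples])
    ref = (sigma / k_s) * (1.0 - np.exp(-t / tau))
    late = t > 0.3 * tau  # skip the inertial transient of the particle pair
    err = np.abs(eps[late] - ref[late]) / (sigma / k_s)
    assert err.max() < 0.01


# ------------------------------------------------------------ eligibility
def test_select_eligible_limits(small_mesh):
    all_v = select_eligible(small_mesh, small_mesh.n_vertices, seed=0)
    assert len(all_v) == small_mesh.n_vertices
    one = select_eligible(small_mesh, 1, seed=0)
    assert len(one) == 1


def test_select_eligible_uniform_spacing(small_mesh):
    from scipy.spatial import cKDTree

    idx = select_eligible(small_mesh, 50, seed=0)
    pts = small_mesh.vertices[idx]
    d, _ = cKDTree(pts).query(pts, k=2)
    spacing = d[:, 1]
    assert spacing.std() / spacing.mean() < 0.35


def test_select_eligible_deterministic(small_mesh):
    a = select_eligible(small_mesh, 40, seed=7)
    b = select_eligible(small_mesh, 40, seed=7)
    assert np.array_equal(a, b)


# ------------------------------------------------------------- networks
def test_bond_density_accounting(small_mesh):
    nucleus = make_sphere_mesh(0.85, 0.5)
    n_outer = small_mesh.n_vertices  # 162
    for variant, w in (("M1", 1), ("M2", 5)):
        spec = TopologySpec(variant=variant, w=w, rho=0.8, seed=0)
        bonds = build_cytoskeleton(small_mesh, nucleus, spec, 120.0, 10.0)
        assert len(bonds) == round(0.8 * n_outer)
        # nucleus-side indices are offset past the outer mesh
        assert all(b.j >= n_outer for b in bonds)
        assert len({(b.i, b.j) for b in bonds}) == len(bonds)


def test_m2_bond_count_arithmetic(small_mesh):
    """rho = 0.8 on 162 outer particles with w = 5 wires ceil(130/5) = 26
    eligible outer vertices, 5 bonds each, trimmed to 130."""
    nucleus = make_sphere_mesh(0.85, 0.5)
    spec = TopologySpec(variant="M2", w=5, rho=0.8, seed=0)
    bonds = build_cytoskeleton(small_mesh, nucleus, spec, 120.0, 10.0)
    outer_used = {b.i for b in bonds}
    assert len(bonds) == 130
    assert len(outer_used) == 26


def test_nucleus_network_five_x_rule_and_density(small_mesh):
    bonds = build_nucleus_network(small_mesh, 0.8, 120.0, 10.0, seed=0)
    assert len(bonds) == round(0.8 * small_mesh.n_vertices)
    assert all(b.k_s == pytest.approx(5.0 * 120.0) for b in bonds)
    assert all(b.k_v_damp == 10.0 for b in bonds)
    assert NUCLEUS_STIFFNESS_FACTOR == 5.0


def test_most_distant_partner_is_near_antipodal():
    mesh = make_sphere_mesh(3.3, 0.5)  # 642 vertices
    bonds = build_nucleus_network(mesh, 0.3, 120.0, 10.0, seed=0, variant="M1")
    for b in bonds[:40]:
        p, q = mesh.vertices[b.i], mesh.vertices[b.j - mesh.n_vertices * 0 ]
        # partner within 5% of the true antipode distance
        assert np.linalg.norm(p - q) > 0.95 * 2.0 * np.linalg.norm(p)


def test_m1_chains_straight_m2_not():
    """M1 wiring admits geometrically straight bond chains linking
    opposite sides of the cell through the nucleus network (the stress
    teleportation artifact); M2 with w = 5 breaks them."""

    def max_straightness(cell):
        pos = cell.all_positions()
        g = nx.Graph()
        for net in (cell.cytoskeleton, cell.nucleus_bonds):
            for i, j in zip(net.i, net.j):
                g.add_edge(int(i), int(j),
                           w=float(np.linalg.norm(pos[i] - pos[j])))
        outer_nodes = [v for v in g.nodes if v < cell.n_outer]
        best = 0.0
        for s in outer_nodes:
            t = max(outer_nodes, key=lambda v: np.linalg.norm(pos[s] - pos[v]))
            try:
                plen = nx.shortest_path_length(g, s, t, weight="w")
            except nx.NetworkXNoPath:
                continue
            best = max(best, np.linalg.norm(pos[s] - pos[t]) / plen)
        return best

    m1 = build_cell(6.6, 0.29, topology=TopologySpec(variant="M1", seed=0))
    m2 = build_cell(6.6, 0.29, topology=TopologySpec(variant="M2", w=5, seed=0))
    s1, s2 = max_straightness(m1), max_straightness(m2)
    assert s1 > 0.999  # a perfectly straight chain exists
    assert s2 < 0.999  # w = 5 fan-out bends every cross-cell chain


def test_network_forces_conserve_momentum(small_cell, rng):
    from cellflow import _kernels

    pos = small_cell.all_positions()
    pos += 0.05 * rng.standard_normal(pos.shape)
    vel = rng.standard_normal(pos.shape)
    f = np.zeros_like(pos)
    for net in (small_cell.cytoskeleton, small_cell.nucleus_bonds):
        _kernels.kv_bond_forces(pos, vel, net.i, net.j, net.k_s,
                                net.k_v_damp, net.l_0b, True, f)
    assert np.allclose(f.sum(axis=0), 0.0, atol=1e-10)
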