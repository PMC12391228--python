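"""DPD pair forces, neighbor search, integration, walls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellflow.dpd import (
    DpdParams,
    ParticleSystem,
    ParticleType,
    build_neighbor_lists,
    conservative_force,
    dissipative_random_force,
    kinetic_temperature,
    weight_dissipative,
)
from cellflow.engine import Simulation, TimeStepError, make_fluid_box
from cellflow.walls import SlabWall


@pytest.fixture(scope="module")
def params():
    return DpdParams.standard(kbt=0.1, dt=0.005)


# ------------------------------------------------------------------ forces
def test_conservative_force_examples(params):
    # exactly at the cutoff: zero
    f = conservative_force(np.array([params.rc, 0, 0]), params)
    assert np.allclose(f, 0.0)
    # half cutoff with a_ij = 25: magnitude 12.5 along r_hat
    p25 = DpdParams(a=np.full((1, 1), 25.0), rc=1.0, gamma_d=4.5, kbt=0.1, dt=0.005)
    f = conservative_force(np.array([0.5, 0.0, 0.0]), p25)
    assert np.allclose(f, [12.5, 0.0, 0.0])


def test_overlap_returns_zero_with_warning(params):
    with pytest.warns(UserWarning):
        f = conservative_force(np.zeros(3), params)
    assert np.allclose(f, 0.0)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-2, 2), min_size=3, max_size=3))
def test_conservative_pair_antisymmetry(vec):
    params = DpdParams.standard(kbt=0.1)
    r = np.asarray(vec)
    if np.linalg.norm(r) < 1e-6:
        return
    f_ij = conservative_force(r, params)
    f_ji = conservative_force(-r, params)
    assert np.allclose(f_ij, -f_ji, atol=1e-12)
    if np.linalg.norm(r) >= params.rc:
        assert np.allclose(f_ij, 0.0)


def test_dissipative_weight_at_half_cutoff(params):
    # (1 - 1/2)^(2*0.75) = 0.5^1.5
    assert weight_dissipative(0.5, params) == pytest.approx(0.35355, abs=1e-5)


def test_dissipative_random_zero_cases(params):
    r = np.array([0.5, 0.0, 0.0])
    assert np.allclose(dissipative_random_force(r, np.zeros(3), params, 0.0), 0.0)
    # purely central relative velocity gives a purely central force
    f = dissipative_random_force(r, np.array([1.0, 0.0, 0.0]), params, 0.0)
    assert f[1] == f[2] == 0.0 and f[0] < 0.0


def test_fluctuation_dissipation_enforced_at_construction():
    p = DpdParams.standard(kbt=0.25, gamma_d=3.0)
    assert p.sigma**2 == pytest.approx(2.0 * 3.0 * 0.25, rel=1e-14)


# ------------------------------------------------------- neighbor search
def test_neighbor_list_trivial_geometries(params):
    def system_of(points, box=(10.0, 10.0, 10.0)):
        pts = np.asarray(points, float)
        return ParticleSystem(
            positions=pts, velocities=np.zeros_like(pts),
            types=np.zeros(len(pts), dtype=np.int64),
            box=np.array(box), periodic=np.array([True] * 3),
        )

    # two particles at 1.5 rc: no pair
    s = system_of([[1, 1, 1], [1 + 1.5, 1, 1]])
    pi, pj = build_neighbor_lists(s, 1.0)
    assert len(pi) == 0
    # three collinear at 0.5 rc spacing: (0,1), (1,2) and also (0,2) at rc? no
    s = system_of([[1, 1, 1], [1.5, 1, 1], [2.0, 1, 1]])
    pi, pj = build_neighbor_lists(s, 1.0)
    pairs = set(zip(pi.tolist(), pj.tolist()))
    assert pairs == {(0, 1), (1, 2)}


def test_neighbor_list_matches_brute_oracle(rng):
    from cellflow._kernels import brute_pairs

    n = 500
    box = np.array([6.0, 6.0, 6.0])
    pos = rng.random((n, 3)) * box
    s = ParticleSystem(
        positions=pos, velocities=np.zeros((n, 3)),
        types=np.zeros(n, dtype=np.int64), box=box,
        periodic=np.array([True] * 3),
    )
    pi, pj = build_neighbor_lists(s, 1.0)
    oi = np.empty(n * 200, dtype=np.int64)
    oj = np.empty(n * 200, dtype=np.int64)
    m = brute_pairs(pos, box, s.periodic, 1.0, oi, oj)
    got = set(zip(pi.tolist(), pj.tolist()))
    want = set(zip(oi[:m].tolist(), oj[:m].tolist()))
    assert got == want and len(want) > 1000


def test_thin_periodic_box_rejected():
    s = ParticleSystem(
        positions=np.zeros((2, 3)), velocities=np.zeros((2, 3)),
        types=np.zeros(2, dtype=np.int64),
        box=np.array([0.5, 10.0, 10.0]), periodic=np.array([True] * 3),
    )
    with pytest.raises(ValueError, match="thinner"):
        build_neighbor_lists(s, 1.0)


# ----------------------------------------------------------- integration
def test_free_streaming():
    n = 10
    pos = np.arange(30, dtype=float).reshape(n, 3)
    v = np.full((n, 3), 0.3)
    s = ParticleSystem(
        positions=pos.copy(), velocities=v.copy(),
        types=np.full(n, ParticleType.FLUID, dtype=np.int64),
        box=np.array([100.0] * 3), periodic=np.array([False] * 3),
    )
    sim = Simulation(s, seed=0)
    sim.dt = 0.01
    sim.run(10)
    assert np.allclose(s.positions, pos + 0.1 * v, atol=1e-12)


def test_momentum_conserved_in_isolated_fluid():
    params = DpdParams.standard(kbt=0.1, dt=0.01)
    sim = make_fluid_box([5.0, 5.0, 5.0], 3.0, params, seed=4)
    sim.run(2000)
    drift = np.abs(sim.system.momentum()).max() / sim.system.n
    assert drift < 1e-10


def test_pair_trajectory_matches_small_dt_reference():
    """Single conservative pair vs an explicit tiny-step reference."""
    params = DpdParams(
        a=np.full((4, 4), 5.0), rc=1.0, gamma_d=0.0, kbt=0.0, dt=0.01
    )
    pos0 = np.array([[4.7, 5.0, 5.0], [5.3, 5.0, 5.0]])

    def make_sim(dt):
        p = DpdParams(a=params.a, rc=1.0, gamma_d=0.0, kbt=0.0, dt=dt)
        s = ParticleSystem(
            positions=pos0.copy(), velocities=np.zeros((2, 3)),
            types=np.zeros(2, dtype=np.int64),
            box=np.array([10.0] * 3), periodic=np.array([False] * 3),
        )
        return Simulation(s, dpd=p, seed=0)

    sim = make_sim(0.01)
    sim.run(100)
    ref = make_sim(0.0001)
    ref.run(10_000)
    sep_sim = np.linalg.norm(np.diff(sim.system.positions, axis=0))
    sep_ref = np.linalg.norm(np.diff(ref.system.positions, axis=0))
    assert sep_sim == pytest.approx(sep_ref, rel=0.01)


def test_too_large_time_step_aborts():
    params = DpdParams.standard(kbt=0.1, dt=0.01)
    sim = make_fluid_box([5.0, 5.0, 5.0], 3.0, params, seed=4)
    sim.system.velocities[0] = [500.0, 0.0, 0.0]
    with pytest.raises(TimeStepError, match="time step too large"):
        sim.run(2)


def test_equilibrium_temperature_near_kbt():
    params = DpdParams.standard(kbt=0.1, dt=0.005)
    sim = make_fluid_box([7.0, 7.0, 7.0], 3.0, params, seed=9)
    sim.run(1200)
    temps = []
    for _ in range(150):
        sim.run(5)
        temps.append(kinetic_temperature(sim.system))
    assert np.mean(temps) == pytest.approx(0.1, rel=0.05)


# ----------------------------------------------------------------- walls
def test_bounce_back_plane_reflection():
    wall = SlabWall(0, 0.0, 10.0)
    pos = np.array([[10.4, 1.0, 1.0], [5.0, 5.0, 5.0]])
    vel = np.array([[2.0, 0.0, 0.0], [1.0, 1.0, 1.0]])
    n = wall.apply(pos, vel, np.array([True, True]))
    assert n == 1
    assert np.allclose(pos[0], [9.6, 1.0, 1.0])
    assert np.allclose(vel[0], [-2.0, 0.0, 0.0])
    # non-crossing particle untouched
    assert np.allclose(pos[1], [5.0, 5.0, 5.0]) and np.allclose(vel[1], 1.0)


def test_body_force_flow_obeys_no_slip():
    """Plate-bounded body-force flow: near-wall mean velocity is small
    compared to the channel centre."""
    rng = np.random.default_rng(3)
    box = np.array([8.0, 8.0, 8.0])
    n = int(3.0 * box.prod())
    pos = rng.random((n, 3)) * box
    fluid = (pos[:, 2] > 1.0) & (pos[:, 2] < 7.0)
    types = np.where(fluid, ParticleType.FLUID, ParticleType.WALL).astype(np.int64)
    s = ParticleSystem(
        positions=pos, velocities=np.zeros((n, 3)), types=types,
        box=box, periodic=np.array([True, True, False]),
        frozen=~fluid,
    )
    params = DpdParams.standard(kbt=0.1, dt=0.005)
    sim = Simulation(
        s, dpd=params, walls=[SlabWall(2, 1.0, 7.0)], seed=5,
        body_force=np.array([0.15, 0.0, 0.0]),
    )
    sim.run(2500)
    vx = np.zeros(6)
    cnt = np.zeros(6)
    for _ in range(30):
        sim.run(20)
        z = s.positions[fluid, 2]
        b = np.clip(((z - 1.0) / 6.0 * 6).astype(int), 0, 5)
        for k in range(6):
            sel = b == k
            if sel.any():
                vx[k] += s.velocities[fluid, 0][sel].mean()
                cnt[k] += 1
    prof = vx / np.maximum(cnt, 1)
    centre = prof[2:4].mean()
    edge = prof[[0, 5]].mean()
    assert centre > 0.01
    assert abs(edge) < 0.5 * centre
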