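"""Virtual instruments: micropipette aspiration and obstacle-channel flow.

Micropipette aspiration pulls a cell against a flat plate with a circular
mouth opening into a cylindrical tube; the suction pressure difference dP
acts on the membrane patch exposed inside the mouth.  In *ramp* mode dP
is raised in quasi-static steps and the aspirated projection length L_p
recorded per step; in *creep* mode dP is held constant and L_p(t)
recorded.  The normalized aspiration length L_n = (L_p - L_0)/R_p removes
the initial-configuration offset (L_0 is the projection under the first,
minute pressure step).

The obstacle channel is a slab bounded by no-slip walls with rows of
triangular prism obstacles; a body force on the fluid drives the flow and
the cell is advected through the constrictions.  Transit velocity and the
post-constriction shape-relaxation time are extracted from the centroid
and asphericity time series.

Scaled-resolution defaults keep both instruments at desk scale (a few
hundred membrane particles, thousands of steps); the same code paths run
full-resolution studies by passing larger cells, more rows and longer
schedules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .builder import CellModel, build_cell
from .cytoskeleton import BondNetwork
from .dpd import DpdParams, ParticleSystem, ParticleType
from .engine import MembraneInstance, Simulation, embed_cell
from .walls import PipetteWall, SlabWall, TriangularPrismWall, fill_random_particles

logger = logging.getLogger(__name__)

__all__ = [
    "PipetteProtocol",
    "AspirationTrace",
    "ChannelDevice",
    "TransitMeasurement",
    "run_aspiration",
    "run_channel_flow",
    "calibrate_body_force",
    "asphericity",
]


# --------------------------------------------------------------------------
# micropipette aspiration
# --------------------------------------------------------------------------


@dataclass
class PipetteProtocol:
    """Aspiration schedule (simulation units).

    Ramp mode raises the pressure from 0 to ``max_pressure`` in
    ``n_levels`` quasi-static steps of ``hold_time`` each; the effective
    ramp rate is max_pressure / (n_levels * hold_time).  Creep mode holds
    ``creep_pressure`` for ``creep_time``.  The first (smallest) ramp
    level doubles as the minute-pressure reference defining L_0.
    """

    r_p: float = 1.0
    max_pressure: float = 60.0
    n_levels: int = 6
    hold_time: float = 20.0
    creep_pressure: float = 40.0
    creep_time: float = 60.0
    dt: float = 0.005
    sample_every: int = 20
    drag: float = 2.0  # quiescent-medium drag on membrane particles

    def __post_init__(self) -> None:
        if self.r_p <= 0:
            raise ValueError("pipette radius must be positive")
        if self.max_pressure < 0 or self.creep_pressure < 0:
            raise ValueError("pressures must be non-negative")

    @property
    def ramp_rate(self) -> float:
        return self.max_pressure / (self.n_levels * self.hold_time)


@dataclass
class AspirationTrace:
    """Time series of applied pressure and aspirated projection length."""

    time: np.ndarray
    pressure: np.ndarray
    aspiration_length: np.ndarray
    r_p: float
    l_0: float = 0.0
    status: str = "ok"
    meta: dict = field(default_factory=dict)

    def normalized_length(self) -> np.ndarray:
        """L_n = (L_p - L_0) / R_p at every sample."""
        return (np.asarray(self.aspiration_length) - self.l_0) / self.r_p

    def write_tsv(self, path) -> None:
        ln = self.normalized_length()
        with open(path, "w") as fh:
            fh.write(f"# r_p[sim]={self.r_p}\tl_0[sim]={self.l_0}\tstatus={self.status}\n")
            fh.write("time[sim]\tpressure[sim]\tL_p[sim]\tL_n[-]\n")
            for t, p, lp, n in zip(self.time, self.pressure, self.aspiration_length, ln):
                fh.write(f"{t:.6g}\t{p:.6g}\t{lp:.6g}\t{n:.6g}\n")

    @classmethod
    def read_tsv(cls, path) -> "AspirationTrace":
        with open(path) as fh:
            header = fh.readline().strip().lstrip("# ").split("\t")
            meta = dict(kv.split("=", 1) for kv in header)
            fh.readline()
            data = np.loadtxt(fh)
        return cls(
            time=data[:, 0], pressure=data[:, 1], aspiration_length=data[:, 2],
            r_p=float(meta["r_p[sim]"]), l_0=float(meta["l_0[sim]"]),
            status=meta.get("status", "ok"),
        )


def _aspiration_sim(cell: CellModel, protocol: PipetteProtocol, seed: int):
    """Assemble the pipette system: cell resting against the plate."""
    r_cell = 0.5 * cell.diameter_um / cell.length_scale_um
    if 2.0 * protocol.r_p >= 2.0 * r_cell:
        raise ValueError("pipette mouth must be smaller than the cell diameter")
    centre = np.array([-(r_cell + 0.05), 0.0, 0.0])
    pos = cell.all_positions() + centre
    n = cell.n_particles
    types = np.concatenate([
        np.full(cell.n_outer, ParticleType.CELL_MEMBRANE, dtype=np.int64),
        np.full(cell.n_nucleus, ParticleType.NUCLEUS_MEMBRANE, dtype=np.int64),
    ])
    # tight non-periodic box: cell on the left, tongue room in the tube
    x_lo = -(2.0 * r_cell + 1.0)
    x_hi = 6.0 * protocol.r_p + 1.0
    half_yz = r_cell + 1.0
    system = ParticleSystem(
        positions=pos, velocities=np.zeros((n, 3)), types=types,
        box=np.array([x_hi - x_lo, 2 * half_yz, 2 * half_yz]),
        periodic=np.array([False, False, False]),
        origin=np.array([x_lo, -half_yz, -half_yz]),
    )
    # conservative-only soft repulsion keeps the two membranes apart;
    # kBT = 0 makes the scaled instrument deterministic
    kbt = cell.outer_params.kbt
    a = np.zeros((ParticleType.N_TYPES, ParticleType.N_TYPES))
    a[ParticleType.CELL_MEMBRANE, ParticleType.NUCLEUS_MEMBRANE] = 25.0 * kbt
    a[ParticleType.NUCLEUS_MEMBRANE, ParticleType.CELL_MEMBRANE] = 25.0 * kbt
    dpd = DpdParams(a=a, rc=1.0, gamma_d=0.0, kbt=0.0, dt=protocol.dt)
    membranes = [
        MembraneInstance(cell.outer, cell.outer_params, 0, thermal=False),
        MembraneInstance(cell.nucleus, cell.nucleus_params, cell.n_outer, thermal=False),
    ]
    a_per_particle = cell.outer.area() / cell.n_outer
    state = {"pressure": 0.0}

    def suction(pos_now, vel, t):
        f = np.zeros_like(pos_now)
        outer = pos_now[: cell.n_outer]
        rho = np.sqrt(outer[:, 1] ** 2 + outer[:, 2] ** 2)
        sel = (rho < protocol.r_p) & (outer[:, 0] > -cell.outer_params.l_0)
        f[: cell.n_outer][sel, 0] = state["pressure"] * a_per_particle
        return f

    sim = Simulation(
        system,
        dpd=dpd,
        membranes=membranes,
        kv_networks=[cell.cytoskeleton, cell.nucleus_bonds],
        walls=[PipetteWall(0.0, protocol.r_p)],
        seed=seed,
        background_drag=protocol.drag,
        external_force=suction,
    )
    return sim, state


def _projection_length(sim: Simulation, n_outer: int) -> float:
    """Axial extent of the outer membrane past the pipette mouth plane."""
    return float(max(0.0, sim.system.positions[:n_outer, 0].max()))


def _volume_ratio(sim: Simulation, cell: CellModel) -> float:
    """Current outer-membrane volume relative to its reference V_0."""
    from . import _kernels

    f = np.zeros((cell.n_outer, 3))
    _, _, vol = _kernels.area_volume_forces(
        sim.system.positions[: cell.n_outer], cell.outer.triangles,
        0.0, 0.0, 1.0, 1.0, 0.5, 0.1, f,
    )
    return float(vol / cell.outer_params.v_0)


def run_aspiration(
    cell: CellModel,
    protocol: PipetteProtocol,
    mode: str = "ramp",
    seed: int = 0,
) -> AspirationTrace:
    """Virtual micropipette aspiration; deterministic given the seed.

    Returns an :class:`AspirationTrace`; ``status`` is ``"aspirated"`` if
    the entire cell passed the mouth plane (run terminates early).
    """
    if mode not in ("ramp", "creep"):
        raise ValueError("mode must be 'ramp' or 'creep'")
    sim, state = _aspiration_sim(cell, protocol, seed)
    n_outer = cell.n_outer
    dt = protocol.dt
    times, pressures, lengths = [], [], []
    status = "ok"

    def sample(s):
        times.append(s.time)
        pressures.append(state["pressure"])
        lengths.append(_projection_length(s, n_outer))

    def fully_aspirated() -> bool:
        return bool(sim.system.positions[:n_outer, 0].min() > 0.0)

    # settle against the plate under zero suction with strong damping so
    # rigid-body motion is gone before the measurement starts
    settle_steps = int(round(protocol.hold_time / dt))
    sim.background_drag = max(protocol.drag, 5.0)
    sim.run(settle_steps)
    sim.system.velocities[:] = 0.0
    sim.background_drag = protocol.drag

    if mode == "ramp":
        hold_steps = int(round(protocol.hold_time / dt))
        l0 = None
        for level in range(1, protocol.n_levels + 1):
            state["pressure"] = protocol.max_pressure * level / protocol.n_levels
            sim.run(hold_steps, callback=sample, every=protocol.sample_every)
            if fully_aspirated():
                status = "aspirated"
                break
            tail = max(1, hold_steps // protocol.sample_every // 5)
            if l0 is None:
                # minute-pressure reference from the first hold
                l0 = float(np.mean(lengths[-tail:]))
        return AspirationTrace(
            np.array(times), np.array(pressures), np.array(lengths),
            r_p=protocol.r_p, l_0=l0 or 0.0, status=status,
            meta={"mode": "ramp", "ramp_rate": protocol.ramp_rate,
                  "final_volume_ratio": _volume_ratio(sim, cell)},
        )

    # creep: strongly damped minute-pressure hold defines L_0, then the
    # suction steps to its constant value and the transient is recorded
    state["pressure"] = 0.05 * protocol.creep_pressure
    pre_lengths = []

    def presample(s):
        pre_lengths.append(_projection_length(s, n_outer))

    sim.background_drag = max(protocol.drag, 5.0)
    sim.run(int(round(protocol.hold_time / dt)), callback=presample,
            every=protocol.sample_every)
    l0 = float(np.mean(pre_lengths[max(0, len(pre_lengths) - 5):]))
    sim.system.velocities[:] = 0.0
    sim.background_drag = protocol.drag
    state["pressure"] = protocol.creep_pressure
    sim.run(int(round(protocol.creep_time / dt)), callback=sample,
            every=protocol.sample_every)
    if fully_aspirated():
        status = "aspirated"
    return AspirationTrace(
        np.array(times), np.array(pressures), np.array(lengths),
        r_p=protocol.r_p, l_0=l0, status=status,
        meta={"mode": "creep", "pressure": protocol.creep_pressure,
              "final_volume_ratio": _volume_ratio(sim, cell)},
    )


# --------------------------------------------------------------------------
# obstacle channel
# --------------------------------------------------------------------------


@dataclass
class ChannelDevice:
    """Obstacle-channel geometry and drive (simulation units).

    The device is periodic along the flow (x) and spanwise (y)
    directions and bounded by no-slip walls in z.  Each obstacle row is
    one triangular prism per spanwise period, apex upstream, extruded
    through the full height; the free span between prism bases is the
    gap.  With x periodicity, ``n_rows`` rows repeat indefinitely.
    """

    height: float = 5.0
    length: float = 18.0
    span: float = 6.0
    n_rows: int = 2
    row_spacing: float = 9.0
    gap: float = 3.0
    obstacle_depth: float = 2.0
    body_force: float = 0.02
    number_density: float = 3.0
    wall_thickness: float = 1.0
    dt: float = 0.005
    kbt: float = 0.1
    wall_seed: int = 0  # one device = one frozen-particle realization

    def __post_init__(self) -> None:
        if self.gap >= self.span:
            raise ValueError("gap must be smaller than the spanwise period")
        if self.n_rows * self.row_spacing > self.length:
            raise ValueError("rows do not fit in the periodic length")

    def obstacle_prisms(self) -> list[TriangularPrismWall]:
        base_w = self.span - self.gap
        prisms = []
        yc = 0.5 * self.span  # gap straddles the periodic y boundary
        for k in range(self.n_rows):
            xr = (k + 0.5) * self.row_spacing
            tri = np.array([
                [xr - 0.6 * self.obstacle_depth, yc],
                [xr + 0.4 * self.obstacle_depth, yc - 0.5 * base_w],
                [xr + 0.4 * self.obstacle_depth, yc + 0.5 * base_w],
            ])
            prisms.append(TriangularPrismWall(tri))
        return prisms

    @classmethod
    def scaled(cls, gap: float = 3.0, **kw) -> "ChannelDevice":
        return cls(gap=gap, **kw)

    @classmethod
    def full(cls, gap_um: float = 12.0, length_scale_um: float = 1.0) -> "ChannelDevice":
        """Experiment-scale geometry: 28 um height, 10 rows 60 um apart."""
        s = 1.0 / length_scale_um
        return cls(
            height=28.0 * s, length=600.0 * s, span=60.0 * s, n_rows=10,
            row_spacing=60.0 * s, gap=gap_um * s, obstacle_depth=20.0 * s,
        )


@dataclass
class TransitMeasurement:
    """Cell transport summary for one channel run."""

    transit_velocity: float
    relaxation_time: float
    transit_time: float
    ratio: float
    status: str = "ok"
    series: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status == "ok" and not (0.0 <= self.ratio <= 1.0):
            raise ValueError("relaxation/transit ratio must lie in [0, 1]")


def asphericity(points: np.ndarray) -> float:
    """Gyration-tensor asphericity: 0 for a sphere, up to 1 for a rod."""
    x = points - points.mean(axis=0)
    g = x.T @ x / len(x)
    lam = np.sort(np.linalg.eigvalsh(g))[::-1]
    s = lam.sum()
    return float(
        ((lam[0] - lam[1]) ** 2 + (lam[1] - lam[2]) ** 2 + (lam[2] - lam[0]) ** 2)
        / (2.0 * s * s)
    )


def scaled_channel_cell(
    diameter: float = 3.3,
    softening: float = 10.0,
    *,
    gamma_factor: float = 0.5,
    seed: int = 0,
) -> CellModel:
    """Compliant cell configuration for desk-scale channel runs.

    A desk-scale DPD fluid column can only exert pressure differences of
    order n kBT across the cell, far below what is needed to squeeze the
    full-stiffness membrane through a constriction at this resolution.
    For qualitative channel studies all elastic coefficients (membrane
    in-plane via 1/p, bending, area/volume constraints, KV spring) are
    divided by ``softening`` and the viscous ones (KV damper, membrane
    gamma) reduced in proportion, preserving the elastic-to-viscous
    balance while bringing the deformation scale into reach of the
    scaled fluid stresses.
    """
    import dataclasses as _dc

    from .cytoskeleton import TopologySpec as _TS

    cell = build_cell(
        diameter, topology=_TS(seed=seed),
        k_s=120.0 / softening, k_v_damp=10.0 / softening,
    )
    for name in ("outer_params", "nucleus_params"):
        cur = getattr(cell, name)
        setattr(cell, name, _dc.replace(
            cur, p=cur.p * softening, k_a=cur.k_a / softening,
            k_vol=cur.k_vol / softening, k_b=cur.k_b / softening,
            gamma=cur.gamma * gamma_factor,
        ))
    return cell


def _channel_system(
    device: ChannelDevice, seed: int, params: DpdParams
) -> tuple[ParticleSystem, list]:
    """Periodic channel with frozen wall/obstacle particles and fluid.

    Wall particles are drawn from the device's own ``wall_seed`` so every
    run sees the same physical device; ``seed`` only randomizes the
    initial fluid configuration.
    """
    wall_rng = np.random.default_rng(device.wall_seed)
    rng = np.random.default_rng(seed)
    lo = np.array([0.0, 0.0, -device.wall_thickness])
    hi = np.array([device.length, device.span,
                   device.height + device.wall_thickness])
    box = hi - lo
    prisms = device.obstacle_prisms()

    def in_solid(pts):
        z = pts[:, 2]
        solid = (z < 0.0) | (z > device.height)
        ywrap = pts.copy()
        ywrap[:, 1] = np.mod(ywrap[:, 1], device.span)
        for pr in prisms:
            solid |= pr.contains(ywrap)
        return solid

    wall_pos = fill_random_particles(in_solid, lo, hi, device.number_density, wall_rng)
    n_try = int(round(device.number_density * box.prod()))
    fluid_pos = lo + rng.random((n_try, 3)) * box
    fluid_pos = fluid_pos[~in_solid(fluid_pos)]
    pos = np.vstack([fluid_pos, wall_pos])
    n_f, n_w = len(fluid_pos), len(wall_pos)
    types = np.concatenate([
        np.full(n_f, ParticleType.FLUID, dtype=np.int64),
        np.full(n_w, ParticleType.WALL, dtype=np.int64),
    ])
    frozen = np.concatenate([np.zeros(n_f, bool), np.ones(n_w, bool)])
    system = ParticleSystem(
        positions=pos, velocities=np.zeros((len(pos), 3)), types=types,
        box=box, periodic=np.array([True, True, False]), origin=lo,
        frozen=frozen,
    )
    walls = [SlabWall(2, 0.0, device.height)] + [
        _WrappedPrism(pr, device.span, device.length) for pr in prisms
    ]
    return system, walls


class _WrappedPrism:
    """Prism bounce-back applied in the periodic fundamental domain.

    Positions are integrated unwrapped (membrane bonds must stay
    contiguous), so both periodic coordinates are folded into the box
    before the containment test and the reflection displacement is
    carried back to the unwrapped frame.
    """

    def __init__(self, prism: TriangularPrismWall, span: float, length: float):
        self.prism = prism
        self.span = span
        self.length = length

    def apply(self, pos, vel, mask):
        off_x = pos[:, 0] - np.mod(pos[:, 0], self.length)
        off_y = pos[:, 1] - np.mod(pos[:, 1], self.span)
        pos[:, 0] -= off_x
        pos[:, 1] -= off_y
        n = self.prism.apply(pos, vel, mask)
        pos[:, 0] += off_x
        pos[:, 1] += off_y
        return n


def calibrate_body_force(
    device: ChannelDevice,
    target_velocity: float,
    seed: int = 0,
    *,
    transient_steps: int = 1200,
    sample_steps: int = 800,
    tol: float = 0.02,
    max_iter: int = 6,
    params: DpdParams | None = None,
) -> float:
    """Body-force magnitude yielding the target cell-free mean velocity.

    Secant iteration on the (nearly linear at low Reynolds) force-velocity
    relation; converges when the measured mean axial fluid velocity is
    within ``tol`` of target.
    """
    if target_velocity == 0.0:
        return 0.0
    if params is None:
        params = DpdParams.standard(kbt=device.kbt, dt=device.dt)

    def mean_velocity(f: float, run_seed: int) -> float:
        system, walls = _channel_system(device, run_seed, params)
        sim = Simulation(system, dpd=params, walls=walls, seed=run_seed + 7,
                         body_force=np.array([f, 0.0, 0.0]))
        sim.run(transient_steps)
        acc, cnt = 0.0, 0
        fluid = system.types == ParticleType.FLUID
        for _ in range(sample_steps // 50):
            sim.run(50)
            acc += system.velocities[fluid, 0].mean()
            cnt += 1
        return acc / cnt

    f1 = device.body_force
    v1 = mean_velocity(f1, seed)
    if abs(v1 - target_velocity) / abs(target_velocity) < tol:
        return f1
    f2 = f1 * target_velocity / max(v1, 1e-12)
    for _ in range(max_iter):
        v2 = mean_velocity(f2, seed)
        if abs(v2 - target_velocity) / abs(target_velocity) < tol:
            return f2
        df = (f2 - f1) if abs(v2 - v1) < 1e-15 else (f2 - f1) * (
            target_velocity - v2
        ) / (v2 - v1)
        f1, v1, f2 = f2, v2, f2 + df
    raise RuntimeError("body-force calibration did not converge")


def run_channel_flow(
    cell: CellModel,
    device: ChannelDevice,
    seed: int = 0,
    *,
    n_rows_to_cross: int | None = None,
    max_steps: int = 60_000,
    sample_every: int = 25,
    recovery_fraction: float = 0.05,
    stall_window: float = 50.0,
) -> TransitMeasurement:
    """Advect a cell through the obstacle channel and measure transport.

    Transit velocity is centroid displacement over elapsed time.  After
    each row passage the relaxation time is the delay until asphericity
    returns within ``recovery_fraction`` of its pre-gap baseline.  A cell
    whose velocity stays below 1% of the fluid-free mean for
    ``stall_window`` time units is reported as ``"clogged"``.
    """
    n_rows_to_cross = n_rows_to_cross or device.n_rows
    params = DpdParams.standard(kbt=device.kbt, dt=device.dt)
    base_system, walls = _channel_system(device, seed, params)
    # place the cell in the gap corridor upstream of the first row
    r_cell = 0.5 * cell.diameter_um / cell.length_scale_um
    start = np.array([max(r_cell + 0.2, 0.5 * device.row_spacing - r_cell - 1.5),
                      0.0, 0.5 * device.height])
    shift = start - cell.all_positions().mean(axis=0)
    cell.outer.vertices += shift
    cell.nucleus.vertices += shift
    system, membranes, networks = embed_cell(cell, base_system)
    sim = Simulation(
        system, dpd=params, membranes=membranes, kv_networks=networks,
        walls=walls, seed=seed + 13,
        body_force=np.array([device.body_force, 0.0, 0.0]),
    )
    outer_sl = slice(membranes[0].offset, membranes[0].offset + cell.n_outer)

    times, xs, asph = [], [], []
    rows_x = [(k + 0.5) * device.row_spacing + 0.4 * device.obstacle_depth
              for k in range(device.n_rows)]
    x0 = float(system.positions[outer_sl, 0].mean())
    target_dx = n_rows_to_cross * device.row_spacing
    status = "ok"
    last_progress_t, last_x = 0.0, x0
    for _ in range(max_steps // sample_every):
        sim.run(sample_every)
        pts = system.positions[outer_sl]
        xc = float(pts[:, 0].mean())
        times.append(sim.time)
        xs.append(xc)
        asph.append(asphericity(pts))
        if xc - last_x > 0.2:
            last_progress_t, last_x = sim.time, xc
        elif sim.time - last_progress_t > stall_window:
            status = "clogged"
            break
        if xc - x0 >= target_dx:
            break
    times = np.array(times)
    xs = np.array(xs)
    asph = np.array(asph)
    transit_time = float(times[-1] - times[0]) if len(times) > 1 else 0.0
    transit_velocity = (
        float((xs[-1] - xs[0]) / transit_time) if transit_time > 0 else 0.0
    )
    # relaxation per row passage: from the deformation peak after clearing
    # the row until asphericity decays to within recovery_fraction of the
    # peak excess over the undeformed baseline
    n_base = max(5, len(asph) // 25)
    baseline = float(np.median(asph[:n_base]))
    relax_times = []
    for krow in range(n_rows_to_cross + 1):
        # row exit planes repeat with the periodic length
        xr = (rows_x[krow % device.n_rows]
              + (krow // device.n_rows) * device.length)
        after = np.flatnonzero(xs > xr)
        if len(after) == 0:
            continue
        i0 = after[0]
        i1 = np.flatnonzero(xs > xr + 0.8 * device.row_spacing)
        i1 = i1[0] if len(i1) else len(asph)
        if i1 <= i0:
            continue
        ipk = i0 + int(np.argmax(asph[i0:i1]))
        peak = asph[ipk]
        if peak <= baseline:
            continue
        thresh = baseline + recovery_fraction * (peak - baseline)
        rec = np.flatnonzero(asph[ipk:] <= thresh)
        if len(rec):
            relax_times.append(float(times[ipk + rec[0]] - times[ipk]))
    relaxation_time = float(np.mean(relax_times)) if relax_times else float("nan")
    ratio = relaxation_time / transit_time if transit_time > 0 else float("nan")
    if status == "clogged" or not np.isfinite(ratio):
        ratio = min(max(ratio, 0.0), 1.0) if np.isfinite(ratio) else 1.0
    return TransitMeasurement(
        transit_velocity=transit_velocity,
        relaxation_time=relaxation_time,
        transit_time=transit_time,
        ratio=float(np.clip(ratio, 0.0, 1.0)),
        status=status,
        series={"time": times, "x": xs, "asphericity": asph,
                "baseline": baseline},
    )
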