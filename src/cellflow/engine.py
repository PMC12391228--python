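"""Time integration of the coupled fluid-membrane-cytoskeleton system.

One :class:`Simulation` owns a :class:`~cellflow.dpd.ParticleSystem` and a
set of force contributors: DPD pair forces (with per-type-pair
conservative, dissipative and random coefficients), membrane elastic and
viscous forces per membrane instance, Kelvin-Voigt bond networks, analytic
bounce-back walls, and optional external drives (body force on the fluid,
experiment-specific tractions, background drag).

Integration uses the modified velocity-Verlet scheme: positions advance
with the current force, the force at the new positions is evaluated with a
velocity *prediction* v + lambda dt f (lambda = 0.5 by default), and the
velocity update averages old and new forces.  All randomness flows from a
single root seed, so trajectories are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _kernels
from .builder import CellModel
from .cytoskeleton import BondNetwork
from .dpd import DpdParams, ParticleSystem, ParticleType, build_neighbor_lists
from .membrane import MembraneParams
from .mesh import TriMesh

__all__ = ["MembraneInstance", "Simulation", "TimeStepError", "make_fluid_box"]


class TimeStepError(RuntimeError):
    """A particle moved farther than the interaction cutoff in one step."""


@dataclass
class MembraneInstance:
    """One membrane surface embedded in the global particle system."""

    mesh: TriMesh
    params: MembraneParams
    offset: int  # global index of the membrane's first vertex
    thermal: bool = True  # apply the bond dissipative+random pair forces


class Simulation:
    def __init__(
        self,
        system: ParticleSystem,
        *,
        dpd: DpdParams | None = None,
        membranes: Sequence[MembraneInstance] = (),
        kv_networks: Sequence[BondNetwork] = (),
        walls: Sequence = (),
        seed: int = 0,
        lam: float = 0.5,
        strain_based_kv: bool = True,
        background_drag: float = 0.0,
        body_force: np.ndarray | None = None,
        body_force_region: Callable[[np.ndarray], np.ndarray] | None = None,
        external_force: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
        | None = None,
        component_ids: np.ndarray | None = None,
    ):
        self.system = system
        self.dpd = dpd
        self.membranes = list(membranes)
        self.kv_networks = list(kv_networks)
        self.walls = list(walls)
        self.lam = lam
        self.strain_based_kv = strain_based_kv
        self.background_drag = background_drag
        self.body_force = None if body_force is None else np.asarray(body_force, float)
        self.body_force_region = body_force_region
        self.external_force = external_force
        self.rng = np.random.default_rng(seed)
        self._dt = 0.01  # used only when no DPD parameter block is present
        self.time = 0.0
        self.step_count = 0
        self.n_overlap_warnings = 0

        n = system.n
        if component_ids is None:
            component_ids = np.full(n, -1, dtype=np.int64)
            for ci, mem in enumerate(self.membranes):
                component_ids[mem.offset : mem.offset + mem.mesh.n_vertices] = ci
        self.component_ids = np.ascontiguousarray(component_ids, dtype=np.int64)

        if dpd is not None:
            nt = dpd.a.shape[0]
            gamma = np.full((nt, nt), dpd.gamma_d)
            # membrane-membrane and wall-wall pairs are not DPD-thermostated:
            # membranes carry their own dissipation/noise, walls are frozen
            for t1 in (ParticleType.CELL_MEMBRANE, ParticleType.NUCLEUS_MEMBRANE):
                for t2 in (ParticleType.CELL_MEMBRANE, ParticleType.NUCLEUS_MEMBRANE):
                    if t1 < nt and t2 < nt:
                        gamma[t1, t2] = 0.0
            if ParticleType.WALL < nt:
                gamma[ParticleType.WALL, ParticleType.WALL] = 0.0
            self._gamma_mat = gamma
            self._sigma_mat = np.sqrt(2.0 * gamma * dpd.kbt)
            cap = max(4096, int(n * 160))
            self._pair_buffers = (
                np.empty(cap, dtype=np.int64),
                np.empty(cap, dtype=np.int64),
            )
            # Verlet skin: pair list built at rc + skin, reused until any
            # particle has moved skin/2 since the build
            self._skin = 0.3 * dpd.rc
            self._pairs = None
            self._pos_at_build = None
        self._forces = None

    # ------------------------------------------------------------------
    @property
    def mobile(self) -> np.ndarray:
        return ~self.system.frozen

    def compute_forces(self, pos: np.ndarray, vel: np.ndarray) -> np.ndarray:
        sysd = self.system
        f = np.zeros_like(pos)
        if self.dpd is not None:
            p = self.dpd
            view = ParticleSystem.__new__(ParticleSystem)
            view.positions = pos
            view.velocities = vel
            view.types = sysd.types
            view.box = sysd.box
            view.periodic = sysd.periodic
            view.origin = sysd.origin
            view.frozen = sysd.frozen
            view.mass = sysd.mass
            rebuild = self._pairs is None or (
                np.abs(pos - self._pos_at_build).max() > 0.5 * self._skin
            )
            if rebuild:
                self._pairs = build_neighbor_lists(
                    view, p.rc + self._skin, buffers=self._pair_buffers
                )
                self._pos_at_build = pos.copy()
            pi, pj = self._pairs
            noise = self.rng.standard_normal(len(pi))
            n_overlap = _kernels.dpd_pair_forces(
                pos, vel, pi, pj, len(pi), sysd.types, self.component_ids,
                p.a, self._gamma_mat, self._sigma_mat, p.rc, p.s,
                1.0 / np.sqrt(p.dt), noise, sysd.box, sysd.periodic, f,
            )
            self.n_overlap_warnings += n_overlap
        for mem in self.membranes:
            sl = slice(mem.offset, mem.offset + mem.mesh.n_vertices)
            posm = pos[sl]
            fm = np.zeros_like(posm)
            mp = mem.params
            _, bad = _kernels.wlc_bond_forces(
                posm, mem.mesh.edges, mp.kbt, mp.p, mp.l_max, fm
            )
            if bad >= 0:
                raise RuntimeError(
                    f"bond overextension in membrane at offset {mem.offset}, "
                    f"bond {bad}: reduce the time step or loading rate"
                )
            _, bad = _kernels.triangle_repulsion_forces(
                posm, mem.mesh.triangles, mp.cq, fm
            )
            if bad >= 0:
                raise RuntimeError(f"degenerate membrane triangle {bad}")
            _, bad = _kernels.bending_forces(
                posm, mem.mesh.dihedrals, mp.k_b, mp.theta_0, fm
            )
            if bad >= 0:
                raise RuntimeError(f"degenerate dihedral {bad}")
            _kernels.area_volume_forces(
                posm, mem.mesh.triangles, mp.k_a, mp.k_vol,
                mp.a_0, mp.v_0, mp.l_0, mp.kbt, fm,
            )
            if mp.gamma > 0:
                # dissipative part always acts; the matched noise only in
                # thermal mode (deterministic instruments run noise-free)
                if mem.thermal and mp.kbt > 0:
                    bond_noise = self.rng.standard_normal((mem.mesh.n_edges, 3, 3))
                else:
                    bond_noise = np.zeros((mem.mesh.n_edges, 3, 3))
                _kernels.membrane_pair_visc_random(
                    posm, vel[sl], mem.mesh.edges, mp.gamma_t, mp.gamma_c,
                    mp.kbt, 1.0 / np.sqrt(self.dt), bond_noise, fm,
                )
            f[sl] += fm
        for net in self.kv_networks:
            bad = _kernels.kv_bond_forces(
                pos, vel, net.i, net.j, net.k_s, net.k_v_damp, net.l_0b,
                self.strain_based_kv, f,
            )
            if bad >= 0:
                raise RuntimeError(f"coincident particles on KV bond {bad}")
        if self.background_drag > 0.0:
            f -= self.background_drag * vel
        if self.body_force is not None:
            sel = sysd.types == ParticleType.FLUID
            if self.body_force_region is not None:
                sel = sel & self.body_force_region(pos)
            f[sel] += self.body_force
        if self.external_force is not None:
            f += self.external_force(pos, vel, self.time)
        f[sysd.frozen] = 0.0
        return f

    # ------------------------------------------------------------------
    @property
    def dt(self) -> float:
        if self.dpd is not None:
            return self.dpd.dt
        return self._dt

    @dt.setter
    def dt(self, value: float) -> None:
        self._dt = float(value)

    def step(self) -> None:
        """One modified velocity-Verlet step with bounce-back walls."""
        sysd = self.system
        dt = self.dt
        mob = self.mobile
        if self._forces is None:
            self._forces = self.compute_forces(sysd.positions, sysd.velocities)
        f0 = self._forces
        dr = (sysd.velocities + 0.5 * dt * f0 / sysd.mass) * dt
        dr[~mob] = 0.0
        if self.dpd is not None:
            max_dr = np.abs(dr).max() if len(dr) else 0.0
            if max_dr > self.dpd.rc:
                raise TimeStepError(
                    f"time step too large: displacement {max_dr:.3g} exceeds "
                    f"cutoff {self.dpd.rc}"
                )
        sysd.positions += dr
        v_pred = sysd.velocities + self.lam * dt * f0 / sysd.mass
        v_pred[~mob] = 0.0
        f1 = self.compute_forces(sysd.positions, v_pred)
        sysd.velocities += 0.5 * dt * (f0 + f1) / sysd.mass
        sysd.velocities[~mob] = 0.0
        for wall in self.walls:
            wall.apply(sysd.positions, sysd.velocities, mob)
        self._forces = f1
        self.time += dt
        self.step_count += 1

    def run(self, n_steps: int, callback=None, every: int = 1) -> None:
        for k in range(n_steps):
            self.step()
            if callback is not None and (self.step_count % every) == 0:
                callback(self)


def make_fluid_box(
    box: Sequence[float],
    number_density: float,
    params: DpdParams,
    seed: int = 0,
    periodic: Sequence[bool] = (True, True, True),
) -> Simulation:
    """Quiescent periodic DPD fluid at the given number density."""
    box = np.asarray(box, float)
    rng = np.random.default_rng(seed)
    n = int(round(number_density * box.prod()))
    pos = rng.random((n, 3)) * box
    vel = np.zeros((n, 3))
    system = ParticleSystem(
        positions=pos,
        velocities=vel,
        types=np.full(n, ParticleType.FLUID, dtype=np.int64),
        box=box,
        periodic=np.asarray(periodic, bool),
    )
    return Simulation(system, dpd=params, seed=seed + 1)


def embed_cell(
    cell: CellModel,
    system: ParticleSystem,
) -> tuple[ParticleSystem, list[MembraneInstance], list[BondNetwork]]:
    """Append a cell's particles to an existing system.

    Fluid particles overlapping either membrane interior are removed
    first so the cell displaces its own volume.  Returns the combined
    system, membrane instances and globally re-indexed KV networks.
    """
    from scipy.spatial import cKDTree

    pos_f = system.positions
    keep = np.ones(len(pos_f), dtype=bool)
    centre = cell.outer.vertices.mean(axis=0)
    r_out = np.linalg.norm(cell.outer.vertices - centre, axis=1).mean()
    keep &= ~(np.linalg.norm(pos_f - centre, axis=1) < r_out)
    # also clear a shell around membrane vertices
    tree = cKDTree(np.vstack([cell.outer.vertices, cell.nucleus.vertices]))
    d, _ = tree.query(pos_f, k=1)
    keep &= d > 0.3
    pos_f = pos_f[keep]
    vel_f = system.velocities[keep]
    typ_f = system.types[keep]
    frz_f = system.frozen[keep]

    n_f = len(pos_f)
    off_outer = n_f
    off_nuc = n_f + cell.n_outer
    pos = np.vstack([pos_f, cell.outer.vertices, cell.nucleus.vertices])
    vel = np.vstack([vel_f, np.zeros((cell.n_particles, 3))])
    types = np.concatenate([
        typ_f,
        np.full(cell.n_outer, ParticleType.CELL_MEMBRANE, dtype=np.int64),
        np.full(cell.n_nucleus, ParticleType.NUCLEUS_MEMBRANE, dtype=np.int64),
    ])
    frozen = np.concatenate([frz_f, np.zeros(cell.n_particles, dtype=bool)])
    combined = ParticleSystem(
        positions=pos, velocities=vel, types=types, box=system.box,
        periodic=system.periodic, origin=system.origin, frozen=frozen,
        mass=system.mass,
    )
    membranes = [
        MembraneInstance(cell.outer, cell.outer_params, off_outer),
        MembraneInstance(cell.nucleus, cell.nucleus_params, off_nuc),
    ]
    cyt = BondNetwork(
        i=cell.cytoskeleton.i + off_outer,
        j=(cell.cytoskeleton.j - cell.n_outer) + off_nuc,
        k_s=cell.cytoskeleton.k_s,
        k_v_damp=cell.cytoskeleton.k_v_damp,
        l_0b=cell.cytoskeleton.l_0b,
    )
    nuc = BondNetwork(
        i=(cell.nucleus_bonds.i - cell.n_outer) + off_nuc,
        j=(cell.nucleus_bonds.j - cell.n_outer) + off_nuc,
        k_s=cell.nucleus_bonds.k_s,
        k_v_damp=cell.nucleus_bonds.k_v_damp,
        l_0b=cell.nucleus_bonds.l_0b,
    )
    return combined, membranes, [cyt, nuc]
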