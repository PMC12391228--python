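"""Elastic and viscous membrane forces on a triangulated surface.

The elastic energy of a membrane is the sum of four terms: a worm-like
chain (WLC) attraction on every bond, a per-triangle expansion term
(together these set the in-plane shear response), a dihedral bending
resistance kb [1 - cos(theta - theta_0)], and global quadratic penalties
tying total surface area and enclosed volume to their reference values.
Viscosity enters through a pairwise dissipative force on every bond with a
matched random force (fluid-particle-model form), so the membrane is its
own thermostat.

Forces returned by this module are exact analytic negative gradients of
the stated energies; tests verify them against central finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .mesh import TriMesh

__all__ = [
    "MembraneParams",
    "BondOverextensionError",
    "inplane_energy",
    "inplane_forces",
    "bending_energy",
    "bending_forces",
    "area_volume_energy",
    "area_volume_forces",
    "total_energy",
    "total_forces",
    "membrane_pair_dissipative_random",
    "pair_visc_random_forces",
]


class BondOverextensionError(RuntimeError):
    """A membrane bond reached l >= l_max (WLC energy diverges)."""


class DegenerateTriangleError(RuntimeError):
    """A zero-area triangle makes the local energy/angle undefined."""


@dataclass
class MembraneParams:
    """Membrane material constants (simulation units).

    ``p`` persistence length; ``l_max`` maximum bond extension; ``l_0``
    equilibrium bond length; ``k_b`` bending modulus (energy units);
    ``theta_0`` equilibrium dihedral angle; ``k_a``/``k_vol`` dimensionless
    area/volume constraint coefficients (energies carry an explicit kBT);
    ``gamma`` membrane viscosity with the translational and central
    dissipative coefficients tied, gamma^T = gamma^C = gamma.
    """

    p: float
    l_max: float
    l_0: float
    k_b: float
    k_a: float
    k_vol: float
    a_0: float
    v_0: float
    gamma: float
    kbt: float
    theta_0: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.l_0 < self.l_max):
            raise ValueError("require 0 < l_0 < l_max (so 0 < x_0 < 1)")
        for name in ("p", "k_b", "k_a", "k_vol", "gamma", "kbt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.p <= 0:
            raise ValueError("persistence length must be positive")

    @property
    def x_0(self) -> float:
        return self.l_0 / self.l_max

    @property
    def gamma_t(self) -> float:
        return self.gamma

    @property
    def gamma_c(self) -> float:
        return self.gamma

    @property
    def cq(self) -> float:
        """Coefficient of the 1/A_alpha triangle expansion term.

        cq = 3 sqrt(3) kBT l_max^3 x0^4 (4 x0^2 - 9 x0 + 6) / (64 p (1 - x0^2)).
        """
        x0 = self.x_0
        return (
            3.0
            * np.sqrt(3.0)
            * self.kbt
            * self.l_max**3
            * x0**4
            * (4.0 * x0**2 - 9.0 * x0 + 6.0)
            / (64.0 * self.p * (1.0 - x0**2))
        )


def _inplane(mesh: TriMesh, params: MembraneParams, positions=None):
    pos = mesh.vertices if positions is None else np.asarray(positions, float)
    forces = np.zeros_like(pos)
    e_wlc, bad = _kernels.wlc_bond_forces(
        pos, mesh.edges, params.kbt, params.p, params.l_max, forces
    )
    if bad >= 0:
        raise BondOverextensionError(
            f"bond overextension: bond {bad} "
            f"({mesh.edges[bad, 0]}-{mesh.edges[bad, 1]}) reached l >= l_max"
        )
    e_tri, bad_t = _kernels.triangle_repulsion_forces(
        pos, mesh.triangles, params.cq, forces
    )
    if bad_t >= 0:
        raise DegenerateTriangleError(f"degenerate triangle {bad_t}")
    return e_wlc + e_tri, forces


def inplane_energy(mesh: TriMesh, params: MembraneParams, positions=None) -> float:
    """WLC bond + triangle-expansion in-plane shear energy."""
    return _inplane(mesh, params, positions)[0]


def inplane_forces(mesh: TriMesh, params: MembraneParams, positions=None) -> np.ndarray:
    return _inplane(mesh, params, positions)[1]


def _bending(mesh: TriMesh, params: MembraneParams, positions=None):
    pos = mesh.vertices if positions is None else np.asarray(positions, float)
    forces = np.zeros_like(pos)
    energy, bad = _kernels.bending_forces(
        pos, mesh.dihedrals, params.k_b, params.theta_0, forces
    )
    if bad >= 0:
        raise DegenerateTriangleError(f"degenerate triangle at dihedral {bad}")
    return energy, forces


def bending_energy(mesh: TriMesh, params: MembraneParams, positions=None) -> float:
    """Sum of kb [1 - cos(theta - theta_0)] over edge-adjacent triangle pairs."""
    return _bending(mesh, params, positions)[0]


def bending_forces(mesh: TriMesh, params: MembraneParams, positions=None) -> np.ndarray:
    return _bending(mesh, params, positions)[1]


def _area_volume(mesh: TriMesh, params: MembraneParams, positions=None):
    pos = mesh.vertices if positions is None else np.asarray(positions, float)
    forces = np.zeros_like(pos)
    energy, _, _ = _kernels.area_volume_forces(
        pos,
        mesh.triangles,
        params.k_a,
        params.k_vol,
        params.a_0,
        params.v_0,
        params.l_0,
        params.kbt,
        forces,
    )
    return energy, forces


def area_volume_energy(mesh: TriMesh, params: MembraneParams, positions=None) -> float:
    """Global area + volume constraint energy."""
    return _area_volume(mesh, params, positions)[0]


def area_volume_forces(
    mesh: TriMesh, params: MembraneParams, positions=None
) -> np.ndarray:
    return _area_volume(mesh, params, positions)[1]


def total_energy(mesh: TriMesh, params: MembraneParams, positions=None) -> float:
    return (
        inplane_energy(mesh, params, positions)
        + bending_energy(mesh, params, positions)
        + area_volume_energy(mesh, params, positions)
    )


def total_forces(mesh: TriMesh, params: MembraneParams, positions=None) -> np.ndarray:
    return (
        inplane_forces(mesh, params, positions)
        + bending_forces(mesh, params, positions)
        + area_volume_forces(mesh, params, positions)
    )


def membrane_pair_dissipative_random(
    r_i: np.ndarray,
    r_j: np.ndarray,
    v_i: np.ndarray,
    v_j: np.ndarray,
    params: MembraneParams,
    dw_ij: np.ndarray,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Dissipative + random force pair for one membrane bond.

    ``dw_ij`` is the 3x3 Wiener increment matrix for the step (entries
    N(0,1) * sqrt(dt)), shared by the pair so the force is exactly
    antisymmetric.  With gamma^T = gamma^C the trace-term amplitude
    sqrt(3 gamma^C - gamma^T) reduces to sqrt(2 gamma).  The random term
    acts along the unit bond vector, the convention under which this
    pair thermostats the membrane to kBT.
    """
    gt, gc = params.gamma_t, params.gamma_c
    if 3.0 * gc < gt:
        raise ValueError("3 gamma^C < gamma^T: negative random-force radicand")
    r_ij = np.asarray(r_i, float) - np.asarray(r_j, float)
    v_ij = np.asarray(v_i, float) - np.asarray(v_j, float)
    r = np.linalg.norm(r_ij)
    e = r_ij / r
    f_d = -gt * v_ij - gc * float(v_ij @ e) * e
    dw = np.asarray(dw_ij, float)
    dws = 0.5 * (dw + dw.T)
    dws_bar = dws - (np.trace(dws) / 3.0) * np.eye(3)
    f_r = (
        np.sqrt(2.0 * params.kbt)
        * (
            np.sqrt(2.0 * gt) * dws_bar
            + np.sqrt(3.0 * gc - gt) * (np.trace(dw) / 3.0) * np.eye(3)
        )
        @ e
    ) / dt
    f_i = f_d + f_r
    return f_i, -f_i


def pair_visc_random_forces(
    mesh: TriMesh,
    positions: np.ndarray,
    velocities: np.ndarray,
    params: MembraneParams,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized viscous + random forces over all bonds of a mesh."""
    forces = np.zeros_like(positions)
    noise = rng.standard_normal((mesh.n_edges, 3, 3))
    _kernels.membrane_pair_visc_random(
        positions,
        velocities,
        mesh.edges,
        params.gamma_t,
        params.gamma_c,
        params.kbt,
        1.0 / np.sqrt(dt),
        noise,
        forces,
    )
    return forces
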