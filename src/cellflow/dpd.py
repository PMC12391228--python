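"""Dissipative particle dynamics: particle state, parameters, pair forces.

DPD advances N equal-mass particles under three pairwise forces inside the
cutoff r_c: a soft linear conservative repulsion a_ij (1 - r/r_c) r_hat, a
dissipative drag -gamma^D w^D(r) (r_hat . v_ij) r_hat, and a random kick
sigma w^R(r) theta_ij dt^(-1/2) r_hat.  The dissipative and random terms
form a momentum-conserving thermostat when the fluctuation-dissipation
constraints sigma^2 = 2 gamma^D kBT and w^D = (w^R)^2 hold; both are
enforced at parameter construction.  The generalized weight
w^R(r) = (1 - r/r_c)^s with s = 0.75 softens the dissipative envelope
relative to the classic s = 1 choice, raising fluid viscosity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels

logger = logging.getLogger(__name__)

__all__ = [
    "ParticleType",
    "ParticleSystem",
    "DpdParams",
    "conservative_force",
    "dissipative_random_force",
    "build_neighbor_lists",
    "kinetic_temperature",
]


class ParticleType:
    """Integer type tags used throughout the package."""

    FLUID = 0
    WALL = 1
    CELL_MEMBRANE = 2
    NUCLEUS_MEMBRANE = 3

    N_TYPES = 4


@dataclass
class ParticleSystem:
    """Positions, velocities and tags of every particle in a (periodic) box.

    ``frozen`` particles (walls) never move; ``box`` is the edge length per
    dimension and ``periodic`` flags which dimensions wrap.  ``origin`` is
    the lower corner of the box.
    """

    positions: np.ndarray
    velocities: np.ndarray
    types: np.ndarray
    box: np.ndarray
    periodic: np.ndarray
    origin: np.ndarray = None  # type: ignore[assignment]
    frozen: np.ndarray = None  # type: ignore[assignment]
    mass: float = 1.0

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=np.float64)
        self.types = np.ascontiguousarray(self.types, dtype=np.int64)
        self.box = np.asarray(self.box, dtype=np.float64)
        self.periodic = np.asarray(self.periodic, dtype=np.bool_)
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.frozen is None:
            self.frozen = np.zeros(len(self.positions), dtype=np.bool_)
        self.frozen = np.asarray(self.frozen, dtype=np.bool_)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("non-finite particle position")

    @property
    def n(self) -> int:
        return len(self.positions)

    def wrap(self) -> None:
        """Wrap positions of mobile particles into the periodic box."""
        for d in range(3):
            if self.periodic[d]:
                self.positions[:, d] = (
                    np.mod(self.positions[:, d] - self.origin[d], self.box[d])
                    + self.origin[d]
                )

    def momentum(self) -> np.ndarray:
        return self.mass * self.velocities[~self.frozen].sum(axis=0)


@dataclass
class DpdParams:
    """DPD interaction constants with fluctuation-dissipation enforced.

    ``a`` is the conservative coefficient matrix indexed by type pair;
    ``sigma`` is derived, not free: sigma^2 = 2 gamma_d kBT.
    """

    a: np.ndarray
    rc: float
    gamma_d: float
    kbt: float
    dt: float
    s: float = 0.75
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        self.a = np.ascontiguousarray(np.atleast_2d(self.a), dtype=np.float64)
        if self.a.shape[0] != self.a.shape[1]:
            raise ValueError("a_ij matrix must be square")
        if not np.allclose(self.a, self.a.T):
            raise ValueError("a_ij matrix must be symmetric")
        if self.rc <= 0 or self.dt <= 0 or self.s <= 0:
            raise ValueError("rc, dt and s must be positive")
        if self.gamma_d < 0 or self.kbt < 0:
            raise ValueError("gamma_d and kBT must be non-negative")
        self.sigma = float(np.sqrt(2.0 * self.gamma_d * self.kbt))

    @classmethod
    def standard(
        cls,
        kbt: float,
        *,
        rc: float = 1.0,
        gamma_d: float = 4.5,
        dt: float = 0.005,
        s: float = 0.75,
        a_scale: float = 25.0,
        n_types: int = ParticleType.N_TYPES,
    ) -> "DpdParams":
        """Uniform repulsion a_ij = a_scale * kBT / r_c for all type pairs."""
        a = np.full((n_types, n_types), a_scale * kbt / rc)
        return cls(a=a, rc=rc, gamma_d=gamma_d, kbt=kbt, dt=dt, s=s)


def conservative_force(
    r_ij: np.ndarray, params: DpdParams, type_i: int = 0, type_j: int = 0
) -> np.ndarray:
    """Soft repulsion a_ij (1 - r/r_c) r_hat for r < r_c, zero beyond.

    At exact overlap (r = 0) the direction is undefined; the soft potential
    admits it, so the force is zero and a warning is emitted.
    """
    r_ij = np.asarray(r_ij, dtype=float)
    r = float(np.linalg.norm(r_ij))
    if r >= params.rc:
        return np.zeros(3)
    if r < 1e-12:
        warnings.warn("overlapping soft particles: conservative force set to zero")
        return np.zeros(3)
    aij = params.a[type_i, type_j]
    return aij * (1.0 - r / params.rc) * (r_ij / r)


def dissipative_random_force(
    r_ij: np.ndarray,
    v_ij: np.ndarray,
    params: DpdParams,
    theta_ij: float,
) -> np.ndarray:
    """Dissipative + random pair force with shared pair noise theta_ij.

    -gamma^D w^D(r)(r_hat . v_ij) r_hat + sigma w^R(r) theta dt^(-1/2) r_hat,
    with w^R = (1 - r/r_c)^s, w^D = (w^R)^2.
    """
    r_ij = np.asarray(r_ij, dtype=float)
    v_ij = np.asarray(v_ij, dtype=float)
    r = float(np.linalg.norm(r_ij))
    if r >= params.rc or r < 1e-12:
        return np.zeros(3)
    e = r_ij / r
    wr = (1.0 - r / params.rc) ** params.s
    wd = wr * wr
    fd = -params.gamma_d * wd * float(e @ v_ij)
    fr = params.sigma * wr * theta_ij / np.sqrt(params.dt)
    return (fd + fr) * e


def weight_dissipative(r: float, params: DpdParams) -> float:
    """w^D(r) = (1 - r/r_c)^(2s) inside the cutoff, zero outside."""
    if r >= params.rc:
        return 0.0
    return (1.0 - r / params.rc) ** (2.0 * params.s)


def build_neighbor_lists(
    system: ParticleSystem,
    rc: float,
    *,
    max_pairs: int | None = None,
    buffers: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """All pairs (i < j) with minimum-image distance < rc.

    Uses a linked-cell sweep when every periodic box dimension spans at
    least 3 r_c, otherwise an exact O(N^2) minimum-image search.  A
    periodic dimension thinner than r_c is rejected: the minimum-image
    convention would miss self-interactions through the boundary.
    """
    for d in range(3):
        if system.periodic[d] and system.box[d] < rc:
            raise ValueError(
                f"periodic box dimension {d} ({system.box[d]}) thinner than rc={rc}"
            )
    n = system.n
    if buffers is not None:
        out_i, out_j = buffers
    else:
        if max_pairs is None:
            max_pairs = max(1024, int(n * 120))
        out_i = np.empty(max_pairs, dtype=np.int64)
        out_j = np.empty(max_pairs, dtype=np.int64)
    use_cells = n > 400 and all(
        (not system.periodic[d]) or system.box[d] >= 3.0 * rc for d in range(3)
    )
    if use_cells:
        m = _kernels.cell_list_pairs(
            system.positions, system.box, system.origin, system.periodic, rc,
            out_i, out_j,
        )
    else:
        m = _kernels.brute_pairs(
            system.positions, system.box, system.periodic, rc, out_i, out_j
        )
    if m < 0:
        raise RuntimeError("neighbor pair buffer overflow; raise max_pairs")
    if buffers is not None:
        return out_i[:m], out_j[:m]
    return out_i[:m].copy(), out_j[:m].copy()


def kinetic_temperature(system: ParticleSystem) -> float:
    """Instantaneous kinetic temperature of mobile particles, kBT units.

    Uses the peculiar velocity (centre-of-mass drift removed) and 3(N-1)
    degrees of freedom.
    """
    v = system.velocities[~system.frozen]
    v = v - v.mean(axis=0)
    n = len(v)
    return float(system.mass * (v**2).sum() / (3.0 * (n - 1)))
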