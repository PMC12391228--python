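"""Analytic wall surfaces with bounce-back reflection.

Bounce-back enforces no-slip impermeable boundaries: a particle ending a
step inside a wall is mirrored back across the surface it crossed and its
velocity is fully negated.  Walls are applied after each position update;
frozen DPD particles filling the solid region supply the near-wall
dissipative structure, while these analytic surfaces guarantee no
penetration.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SlabWall", "PipetteWall", "TriangularPrismWall", "fill_random_particles"]


class SlabWall:
    """Planar pair of walls confining ``axis`` to [lo, hi]."""

    def __init__(self, axis: int, lo: float, hi: float):
        if hi <= lo:
            raise ValueError("hi must exceed lo")
        self.axis = axis
        self.lo = lo
        self.hi = hi

    def apply(self, pos: np.ndarray, vel: np.ndarray, mask: np.ndarray) -> int:
        x = pos[:, self.axis]
        below = mask & (x < self.lo)
        above = mask & (x > self.hi)
        n = int(below.sum() + above.sum())
        if n:
            pos[below, self.axis] = 2.0 * self.lo - x[below]
            pos[above, self.axis] = 2.0 * self.hi - x[above]
            vel[below | above] *= -1.0
        return n


class PipetteWall:
    """Flat plate at x = x0 with a circular mouth of radius r_p opening
    into a cylindrical tube along +x.

    Forbidden region: x > x0 and cylindrical radius >= r_p.  A violating
    particle is mirrored across the plate or across the tube wall,
    whichever it penetrated least, with velocity negation.
    """

    def __init__(self, x0: float, r_p: float, axis_yz=(0.0, 0.0)):
        if r_p <= 0:
            raise ValueError("pipette radius must be positive")
        self.x0 = x0
        self.r_p = r_p
        self.cy, self.cz = axis_yz

    def radial(self, pos: np.ndarray) -> np.ndarray:
        return np.sqrt((pos[:, 1] - self.cy) ** 2 + (pos[:, 2] - self.cz) ** 2)

    def apply(self, pos: np.ndarray, vel: np.ndarray, mask: np.ndarray) -> int:
        rho = self.radial(pos)
        bad = mask & (pos[:, 0] > self.x0) & (rho >= self.r_p)
        idx = np.flatnonzero(bad)
        if len(idx) == 0:
            return 0
        depth_plane = pos[idx, 0] - self.x0
        depth_tube = rho[idx] - self.r_p
        use_plane = depth_plane <= depth_tube
        ip = idx[use_plane]
        pos[ip, 0] = 2.0 * self.x0 - pos[ip, 0]
        it = idx[~use_plane]
        if len(it):
            scale = (2.0 * self.r_p - rho[it]) / rho[it]
            pos[it, 1] = self.cy + (pos[it, 1] - self.cy) * scale
            pos[it, 2] = self.cz + (pos[it, 2] - self.cz) * scale
        vel[idx] *= -1.0
        return len(idx)


class TriangularPrismWall:
    """Solid triangular prism: triangle cross-section in the xy plane,
    extruded through the full channel height (z)."""

    def __init__(self, triangle_xy: np.ndarray):
        tri = np.asarray(triangle_xy, dtype=float)
        if tri.shape != (3, 2):
            raise ValueError("triangle_xy must be (3, 2)")
        # ensure counter-clockwise so inward normals are consistent
        area2 = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        if area2 < 0:
            tri = tri[::-1]
        self.tri = tri
        self.normals = np.empty((3, 2))
        self.offsets = np.empty(3)
        for k in range(3):
            a, b = tri[k], tri[(k + 1) % 3]
            edge = b - a
            n = np.array([edge[1], -edge[0]])  # outward for CCW winding
            n /= np.linalg.norm(n)
            self.normals[k] = n
            self.offsets[k] = n @ a

    def signed_depths(self, pos: np.ndarray) -> np.ndarray:
        """Per-face signed distance inward (positive = inside that face)."""
        return self.offsets[None, :] - pos[:, :2] @ self.normals.T

    def contains(self, pos: np.ndarray) -> np.ndarray:
        return (self.signed_depths(pos) > 0).all(axis=1)

    def apply(self, pos: np.ndarray, vel: np.ndarray, mask: np.ndarray) -> int:
        depths = self.signed_depths(pos)
        inside = mask & (depths > 0).all(axis=1)
        idx = np.flatnonzero(inside)
        if len(idx) == 0:
            return 0
        face = depths[idx].argmin(axis=1)  # shallowest penetration
        d = depths[idx, face]
        pos[idx, :2] += 2.0 * d[:, None] * self.normals[face]
        vel[idx] *= -1.0
        return len(idx)


def fill_random_particles(
    region_test,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    number_density: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Randomly distributed frozen-particle positions filling a solid region.

    ``region_test(points) -> bool mask`` selects points inside the solid.
    """
    lo = np.asarray(bounds_lo, float)
    hi = np.asarray(bounds_hi, float)
    vol = float(np.prod(hi - lo))
    n_try = max(1, int(round(number_density * vol)))
    pts = lo + rng.random((n_try, 3)) * (hi - lo)
    return pts[region_test(pts)]
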