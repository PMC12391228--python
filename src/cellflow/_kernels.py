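"""Numba-compiled force and neighbor-search kernels.

All kernels accumulate into a caller-supplied force array so independent
contributions (fluid pairs, membrane elasticity, cytoskeleton bonds,
external drives) compose additively.  Every pairwise kernel writes exact
action–reaction pairs, so linear momentum is conserved to floating-point
accumulation error by construction.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _min_image(dx, dy, dz, box, periodic):
    if periodic[0]:
        dx -= box[0] * np.round(dx / box[0])
    if periodic[1]:
        dy -= box[1] * np.round(dy / box[1])
    if periodic[2]:
        dz -= box[2] * np.round(dz / box[2])
    return dx, dy, dz


# --------------------------------------------------------------------------
# neighbor search
# --------------------------------------------------------------------------


@njit(cache=True)
def brute_pairs(pos, box, periodic, rc, out_i, out_j):
    """All-pairs minimum-image search; reference oracle and small-box path."""
    n = pos.shape[0]
    rc2 = rc * rc
    m = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            dx, dy, dz = _min_image(dx, dy, dz, box, periodic)
            if dx * dx + dy * dy + dz * dz < rc2:
                if m >= out_i.shape[0]:
                    return -1
                out_i[m] = i
                out_j[m] = j
                m += 1
    return m


@njit(cache=True)
def cell_list_pairs(pos, box, origin, periodic, rc, out_i, out_j):
    """Linked-cell pair search, pairs with minimum-image distance < rc.

    Requires at least 3 cells along every periodic dimension (guaranteed by
    the caller); non-periodic dimensions are clamped.
    """
    n = pos.shape[0]
    rc2 = rc * rc
    ncx = max(1, int(box[0] / rc))
    ncy = max(1, int(box[1] / rc))
    ncz = max(1, int(box[2] / rc))
    ncells = ncx * ncy * ncz
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.full(n, -1, dtype=np.int64)
    cx = np.empty(n, dtype=np.int64)
    cy = np.empty(n, dtype=np.int64)
    cz = np.empty(n, dtype=np.int64)
    for i in range(n):
        ix = int(np.floor((pos[i, 0] - origin[0]) / box[0] * ncx))
        iy = int(np.floor((pos[i, 1] - origin[1]) / box[1] * ncy))
        iz = int(np.floor((pos[i, 2] - origin[2]) / box[2] * ncz))
        ix = min(max(ix, 0), ncx - 1) if not periodic[0] else ix % ncx
        iy = min(max(iy, 0), ncy - 1) if not periodic[1] else iy % ncy
        iz = min(max(iz, 0), ncz - 1) if not periodic[2] else iz % ncz
        cx[i], cy[i], cz[i] = ix, iy, iz
        c = (ix * ncy + iy) * ncz + iz
        nxt[i] = head[c]
        head[c] = i
    m = 0
    for ix in range(ncx):
        for iy in range(ncy):
            for iz in range(ncz):
                c = (ix * ncy + iy) * ncz + iz
                for ox in range(-1, 2):
                    jx = ix + ox
                    if periodic[0]:
                        jx %= ncx
                    elif jx < 0 or jx >= ncx:
                        continue
                    for oy in range(-1, 2):
                        jy = iy + oy
                        if periodic[1]:
                            jy %= ncy
                        elif jy < 0 or jy >= ncy:
                            continue
                        for oz in range(-1, 2):
                            jz = iz + oz
                            if periodic[2]:
                                jz %= ncz
                            elif jz < 0 or jz >= ncz:
                                continue
                            c2 = (jx * ncy + jy) * ncz + jz
                            if c2 < c:
                                continue
                            i = head[c]
                            while i >= 0:
                                j = head[c2] if c2 != c else nxt[i]
                                while j >= 0:
                                    dx = pos[i, 0] - pos[j, 0]
                                    dy = pos[i, 1] - pos[j, 1]
                                    dz = pos[i, 2] - pos[j, 2]
                                    dx, dy, dz = _min_image(
                                        dx, dy, dz, box, periodic
                                    )
                                    if dx * dx + dy * dy + dz * dz < rc2:
                                        if m >= out_i.shape[0]:
                                            return -1
                                        if i < j:
                                            out_i[m] = i
                                            out_j[m] = j
                                        else:
                                            out_i[m] = j
                                            out_j[m] = i
                                        m += 1
                                    j = nxt[j]
                                i = nxt[i]
    return m


# --------------------------------------------------------------------------
# DPD pair forces
# --------------------------------------------------------------------------


@njit(cache=True)
def dpd_pair_forces(
    pos,
    vel,
    pi,
    pj,
    npairs,
    types,
    comp,
    a_matrix,
    gamma_matrix,
    sigma_matrix,
    rc,
    s_exp,
    inv_sqrt_dt,
    noise,
    box,
    periodic,
    forces,
):
    """Conservative + dissipative + random DPD forces over a pair list.

    One shared standard-normal deviate per pair per step (``noise``)
    guarantees exact antisymmetry of the random force.  Pairs belonging to
    the same membrane component (equal non-negative ``comp`` tag) are
    skipped: their interactions are carried by the membrane model.
    """
    n_overlap = 0
    for m in range(npairs):
        i = pi[m]
        j = pj[m]
        if comp[i] >= 0 and comp[i] == comp[j]:
            continue
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx, dy, dz = _min_image(dx, dy, dz, box, periodic)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc * rc:
            continue
        r = np.sqrt(r2)
        if r < 1e-12:
            n_overlap += 1
            continue
        ex = dx / r
        ey = dy / r
        ez = dz / r
        u = 1.0 - r / rc
        if s_exp == 0.75:  # common case: u^0.75 = sqrt(u) * u^(1/4)
            su = np.sqrt(u)
            wr = su * np.sqrt(su)
        else:
            wr = u**s_exp
        wd = wr * wr
        aij = a_matrix[types[i], types[j]]
        fc = aij * (1.0 - r / rc)
        dvx = vel[i, 0] - vel[j, 0]
        dvy = vel[i, 1] - vel[j, 1]
        dvz = vel[i, 2] - vel[j, 2]
        ev = ex * dvx + ey * dvy + ez * dvz
        fd = -gamma_matrix[types[i], types[j]] * wd * ev
        fr = sigma_matrix[types[i], types[j]] * wr * noise[m] * inv_sqrt_dt
        f = fc + fd + fr
        forces[i, 0] += f * ex
        forces[i, 1] += f * ey
        forces[i, 2] += f * ez
        forces[j, 0] -= f * ex
        forces[j, 1] -= f * ey
        forces[j, 2] -= f * ez
    return n_overlap


# --------------------------------------------------------------------------
# membrane elastic forces
# --------------------------------------------------------------------------


@njit(cache=True)
def wlc_bond_forces(pos, edges, kbt, p, lmax, forces):
    """Worm-like-chain attraction on every membrane bond.

    Energy per bond: (kBT lmax / 4p) (3x^2 - 2x^3)/(1 - x), x = l/lmax.
    Returns (energy, index of first over-extended bond or -1).
    """
    energy = 0.0
    pref = kbt / (4.0 * p)
    for e in range(edges.shape[0]):
        i = edges[e, 0]
        j = edges[e, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        l = np.sqrt(dx * dx + dy * dy + dz * dz)
        x = l / lmax
        if x >= 1.0:
            return energy, e
        energy += pref * lmax * (3.0 * x * x - 2.0 * x**3) / (1.0 - x)
        # dU/dl = pref * (6x - 9x^2 + 4x^3)/(1-x)^2
        dudl = pref * (6.0 * x - 9.0 * x * x + 4.0 * x**3) / (1.0 - x) ** 2
        fx = -dudl * dx / l
        fy = -dudl * dy / l
        fz = -dudl * dz / l
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return energy, -1


@njit(cache=True)
def triangle_repulsion_forces(pos, triangles, cq, forces):
    """Per-triangle expansion term: energy cq / A_alpha per triangle.

    This is the elastic counterpart balancing WLC bond attraction; its
    gradient includes the full 1/A_alpha dependence.
    Returns (energy, index of first degenerate triangle or -1).
    """
    energy = 0.0
    for t in range(triangles.shape[0]):
        a = triangles[t, 0]
        b = triangles[t, 1]
        c = triangles[t, 2]
        abx = pos[b, 0] - pos[a, 0]
        aby = pos[b, 1] - pos[a, 1]
        abz = pos[b, 2] - pos[a, 2]
        acx = pos[c, 0] - pos[a, 0]
        acy = pos[c, 1] - pos[a, 1]
        acz = pos[c, 2] - pos[a, 2]
        nx = aby * acz - abz * acy
        ny = abz * acx - abx * acz
        nz = abx * acy - aby * acx
        n2 = nx * nx + ny * ny + nz * nz
        if n2 < 1e-24:
            return energy, t
        area = 0.5 * np.sqrt(n2)
        energy += cq / area
        coef = -cq / (area * area)  # dU/dA
        # dA/dr_v = 0.5 * n_hat x (opposite edge vector)
        inv2n = 0.5 / np.sqrt(n2)
        # vertex a: opposite edge c-b
        ex = pos[c, 0] - pos[b, 0]
        ey = pos[c, 1] - pos[b, 1]
        ez = pos[c, 2] - pos[b, 2]
        forces[a, 0] -= coef * inv2n * (ny * ez - nz * ey)
        forces[a, 1] -= coef * inv2n * (nz * ex - nx * ez)
        forces[a, 2] -= coef * inv2n * (nx * ey - ny * ex)
        # vertex b: opposite edge a-c
        ex = pos[a, 0] - pos[c, 0]
        ey = pos[a, 1] - pos[c, 1]
        ez = pos[a, 2] - pos[c, 2]
        forces[b, 0] -= coef * inv2n * (ny * ez - nz * ey)
        forces[b, 1] -= coef * inv2n * (nz * ex - nx * ez)
        forces[b, 2] -= coef * inv2n * (nx * ey - ny * ex)
        # vertex c: opposite edge b-a
        ex = pos[b, 0] - pos[a, 0]
        ey = pos[b, 1] - pos[a, 1]
        ez = pos[b, 2] - pos[a, 2]
        forces[c, 0] -= coef * inv2n * (ny * ez - nz * ey)
        forces[c, 1] -= coef * inv2n * (nz * ex - nx * ez)
        forces[c, 2] -= coef * inv2n * (nx * ey - ny * ex)
    return energy, -1


@njit(cache=True)
def bending_forces(pos, dihedrals, kb, theta0, forces):
    """Dihedral bending: kb [1 - cos(theta - theta0)] per adjacent pair.

    theta is the signed angle between outward triangle normals (positive
    for the convex configuration of a sphere).  Forces use the analytic
    torsion-angle gradient of the 4-site chain (k, i, j, l).
    Returns (energy, index of first degenerate dihedral or -1).
    """
    energy = 0.0
    for d in range(dihedrals.shape[0]):
        i = dihedrals[d, 0]
        j = dihedrals[d, 1]
        k = dihedrals[d, 2]
        l = dihedrals[d, 3]
        # chain k - i - j - l
        b1x = pos[i, 0] - pos[k, 0]
        b1y = pos[i, 1] - pos[k, 1]
        b1z = pos[i, 2] - pos[k, 2]
        b2x = pos[j, 0] - pos[i, 0]
        b2y = pos[j, 1] - pos[i, 1]
        b2z = pos[j, 2] - pos[i, 2]
        b3x = pos[l, 0] - pos[j, 0]
        b3y = pos[l, 1] - pos[j, 1]
        b3z = pos[l, 2] - pos[j, 2]
        mx = b1y * b2z - b1z * b2y
        my = b1z * b2x - b1x * b2z
        mz = b1x * b2y - b1y * b2x
        nx = b2y * b3z - b2z * b3y
        ny = b2z * b3x - b2x * b3z
        nz = b2x * b3y - b2y * b3x
        m2 = mx * mx + my * my + mz * mz
        n2 = nx * nx + ny * ny + nz * nz
        if m2 < 1e-24 or n2 < 1e-24:
            return energy, d
        b2n = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        # torsion phi: cos from m.n, sin from (m x n).b2_hat
        mn = mx * nx + my * ny + mz * nz
        cxx = my * nz - mz * ny
        cxy = mz * nx - mx * nz
        cxz = mx * ny - my * nx
        sphi = (cxx * b2x + cxy * b2y + cxz * b2z) / b2n
        # signed angle between outward normals, convex-outward positive:
        # theta = phi - pi up to sign; realized as atan2(-sin phi, -cos phi)
        theta = np.arctan2(-sphi, -mn)
        energy += kb * (1.0 - np.cos(theta - theta0))
        # force = -dU/dr = -kb sin(theta-theta0) dtheta/dr, dtheta/dphi = +1
        g = -kb * np.sin(theta - theta0)
        f1 = -b2n / m2  # dphi/dr_k = f1 * m
        f4 = b2n / n2  # dphi/dr_l = f4 * n
        dkx = f1 * mx
        dky = f1 * my
        dkz = f1 * mz
        dlx = f4 * nx
        dly = f4 * ny
        dlz = f4 * nz
        s12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (b2n * b2n)
        s32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (b2n * b2n)
        dix = -dkx - s12 * dkx + s32 * dlx
        diy = -dky - s12 * dky + s32 * dly
        diz = -dkz - s12 * dkz + s32 * dlz
        djx = -dlx + s12 * dkx - s32 * dlx
        djy = -dly + s12 * dky - s32 * dly
        djz = -dlz + s12 * dkz - s32 * dlz
        forces[k, 0] += g * dkx
        forces[k, 1] += g * dky
        forces[k, 2] += g * dkz
        forces[i, 0] += g * dix
        forces[i, 1] += g * diy
        forces[i, 2] += g * diz
        forces[j, 0] += g * djx
        forces[j, 1] += g * djy
        forces[j, 2] += g * djz
        forces[l, 0] += g * dlx
        forces[l, 1] += g * dly
        forces[l, 2] += g * dlz
    return energy, -1


@njit(cache=True)
def area_volume_forces(pos, triangles, ka, kvol, a0, v0, l0, kbt, forces):
    """Global surface-area and enclosed-volume penalties (whole surface).

    U_a = ka kBT (A - A0)^2 / (2 l0^2 A0),
    U_v = kvol kBT (V - V0)^2 / (2 l0^3 V0).
    Returns (energy, A, V).
    """
    nt = triangles.shape[0]
    area = 0.0
    vol = 0.0
    for t in range(nt):
        a = triangles[t, 0]
        b = triangles[t, 1]
        c = triangles[t, 2]
        abx = pos[b, 0] - pos[a, 0]
        aby = pos[b, 1] - pos[a, 1]
        abz = pos[b, 2] - pos[a, 2]
        acx = pos[c, 0] - pos[a, 0]
        acy = pos[c, 1] - pos[a, 1]
        acz = pos[c, 2] - pos[a, 2]
        nx = aby * acz - abz * acy
        ny = abz * acx - abx * acz
        nz = abx * acy - aby * acx
        area += 0.5 * np.sqrt(nx * nx + ny * ny + nz * nz)
        vol += (
            pos[a, 0] * (pos[b, 1] * pos[c, 2] - pos[b, 2] * pos[c, 1])
            + pos[a, 1] * (pos[b, 2] * pos[c, 0] - pos[b, 0] * pos[c, 2])
            + pos[a, 2] * (pos[b, 0] * pos[c, 1] - pos[b, 1] * pos[c, 0])
        ) / 6.0
    ca = ka * kbt * (area - a0) / (l0 * l0 * a0)  # dU_a/dA
    cv = kvol * kbt * (vol - v0) / (l0**3 * v0)  # dU_v/dV
    energy = 0.5 * ca * (area - a0) + 0.5 * cv * (vol - v0)
    for t in range(nt):
        a = triangles[t, 0]
        b = triangles[t, 1]
        c = triangles[t, 2]
        abx = pos[b, 0] - pos[a, 0]
        aby = pos[b, 1] - pos[a, 1]
        abz = pos[b, 2] - pos[a, 2]
        acx = pos[c, 0] - pos[a, 0]
        acy = pos[c, 1] - pos[a, 1]
        acz = pos[c, 2] - pos[a, 2]
        nx = aby * acz - abz * acy
        ny = abz * acx - abx * acz
        nz = abx * acy - aby * acx
        inv2n = 0.5 / np.sqrt(nx * nx + ny * ny + nz * nz)
        for vtx in range(3):
            if vtx == 0:
                va, ox1, ox2 = a, c, b  # opposite edge c-b
            elif vtx == 1:
                va, ox1, ox2 = b, a, c
            else:
                va, ox1, ox2 = c, b, a
            ex = pos[ox1, 0] - pos[ox2, 0]
            ey = pos[ox1, 1] - pos[ox2, 1]
            ez = pos[ox1, 2] - pos[ox2, 2]
            dax = inv2n * (ny * ez - nz * ey)
            day = inv2n * (nz * ex - nx * ez)
            daz = inv2n * (nx * ey - ny * ex)
            forces[va, 0] -= ca * dax
            forces[va, 1] -= ca * day
            forces[va, 2] -= ca * daz
        # volume gradient: dV/dr_a = (r_b x r_c)/6, cyclic
        forces[a, 0] -= cv * (pos[b, 1] * pos[c, 2] - pos[b, 2] * pos[c, 1]) / 6.0
        forces[a, 1] -= cv * (pos[b, 2] * pos[c, 0] - pos[b, 0] * pos[c, 2]) / 6.0
        forces[a, 2] -= cv * (pos[b, 0] * pos[c, 1] - pos[b, 1] * pos[c, 0]) / 6.0
        forces[b, 0] -= cv * (pos[c, 1] * pos[a, 2] - pos[c, 2] * pos[a, 1]) / 6.0
        forces[b, 1] -= cv * (pos[c, 2] * pos[a, 0] - pos[c, 0] * pos[a, 2]) / 6.0
        forces[b, 2] -= cv * (pos[c, 0] * pos[a, 1] - pos[c, 1] * pos[a, 0]) / 6.0
        forces[c, 0] -= cv * (pos[a, 1] * pos[b, 2] - pos[a, 2] * pos[b, 1]) / 6.0
        forces[c, 1] -= cv * (pos[a, 2] * pos[b, 0] - pos[a, 0] * pos[b, 2]) / 6.0
        forces[c, 2] -= cv * (pos[a, 0] * pos[b, 1] - pos[a, 1] * pos[b, 0]) / 6.0
    return energy, area, vol


@njit(cache=True)
def membrane_pair_visc_random(
    pos, vel, edges, gamma_t, gamma_c, kbt, inv_sqrt_dt, noise, forces
):
    """Membrane bond dissipative + random forces (fluid-particle-model form).

    Dissipative: f = -gT v_ij - gC (v_ij . r_hat) r_hat on particle i,
    opposite on j.  Random: sqrt(2 kBT)(sqrt(2 gT) dWbarS
    + sqrt(3 gC - gT) tr[dW]/3 I) . r_hat / dt, with one 3x3 unit-normal
    matrix per bond per step (``noise``), shared by the pair.  The random
    term projects onto the *unit* bond vector, the form for which the
    pair satisfies fluctuation-dissipation with the drag above.
    """
    amp_s = np.sqrt(2.0 * kbt) * np.sqrt(2.0 * gamma_t)
    amp_tr = np.sqrt(2.0 * kbt) * np.sqrt(3.0 * gamma_c - gamma_t)
    for e in range(edges.shape[0]):
        i = edges[e, 0]
        j = edges[e, 1]
        rx = pos[i, 0] - pos[j, 0]
        ry = pos[i, 1] - pos[j, 1]
        rz = pos[i, 2] - pos[j, 2]
        r = np.sqrt(rx * rx + ry * ry + rz * rz)
        if r < 1e-12:
            continue
        ex = rx / r
        ey = ry / r
        ez = rz / r
        vx = vel[i, 0] - vel[j, 0]
        vy = vel[i, 1] - vel[j, 1]
        vz = vel[i, 2] - vel[j, 2]
        ev = ex * vx + ey * vy + ez * vz
        fdx = -gamma_t * vx - gamma_c * ev * ex
        fdy = -gamma_t * vy - gamma_c * ev * ey
        fdz = -gamma_t * vz - gamma_c * ev * ez
        # traceless symmetric part of the unit-normal Wiener matrix
        w00 = noise[e, 0, 0]
        w11 = noise[e, 1, 1]
        w22 = noise[e, 2, 2]
        tr = w00 + w11 + w22
        s01 = 0.5 * (noise[e, 0, 1] + noise[e, 1, 0])
        s02 = 0.5 * (noise[e, 0, 2] + noise[e, 2, 0])
        s12 = 0.5 * (noise[e, 1, 2] + noise[e, 2, 1])
        d00 = w00 - tr / 3.0
        d11 = w11 - tr / 3.0
        d22 = w22 - tr / 3.0
        frx = (
            amp_s * (d00 * ex + s01 * ey + s02 * ez)
            + amp_tr * (tr / 3.0) * ex
        ) * inv_sqrt_dt
        fry = (
            amp_s * (s01 * ex + d11 * ey + s12 * ez)
            + amp_tr * (tr / 3.0) * ey
        ) * inv_sqrt_dt
        frz = (
            amp_s * (s02 * ex + s12 * ey + d22 * ez)
            + amp_tr * (tr / 3.0) * ez
        ) * inv_sqrt_dt
        forces[i, 0] += fdx + frx
        forces[i, 1] += fdy + fry
        forces[i, 2] += fdz + frz
        forces[j, 0] -= fdx + frx
        forces[j, 1] -= fdy + fry
        forces[j, 2] -= fdz + frz


# --------------------------------------------------------------------------
# Kelvin-Voigt bonds
# --------------------------------------------------------------------------


@njit(cache=True)
def kv_bond_forces(pos, vel, bi, bj, ks, kv, l0b, strain_based, forces):
    """Kelvin-Voigt (spring || damper) bond tensions.

    Strain-based law (default): T = ks (l - l0)/l0 + kv (dl/dt)/l0.
    Extension-based variant:    T = ks (l - l0)    + kv  dl/dt.
    Returns index of first zero-length bond, or -1.
    """
    for b in range(bi.shape[0]):
        i = bi[b]
        j = bj[b]
        rx = pos[i, 0] - pos[j, 0]
        ry = pos[i, 1] - pos[j, 1]
        rz = pos[i, 2] - pos[j, 2]
        l = np.sqrt(rx * rx + ry * ry + rz * rz)
        if l < 1e-12:
            return b
        ex = rx / l
        ey = ry / l
        ez = rz / l
        ldot = (
            ex * (vel[i, 0] - vel[j, 0])
            + ey * (vel[i, 1] - vel[j, 1])
            + ez * (vel[i, 2] - vel[j, 2])
        )
        if strain_based:
            tension = ks[b] * (l - l0b[b]) / l0b[b] + kv[b] * ldot / l0b[b]
        else:
            tension = ks[b] * (l - l0b[b]) + kv[b] * ldot
        forces[i, 0] -= tension * ex
        forces[i, 1] -= tension * ey
        forces[i, 2] -= tension * ez
        forces[j, 0] += tension * ex
        forces[j, 1] += tension * ey
        forces[j, 2] += tension * ez
    return -1
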