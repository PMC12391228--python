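"""Kelvin-Voigt bond networks: cytoskeleton and nucleus interior.

The cytoskeleton is a set of Kelvin-Voigt bonds (spring k_s and damper k_v
in parallel, sigma = k_s eps + k_v d eps/dt) linking outer-membrane
particles to nucleus-membrane particles.  Wiring matters: connecting each
eligible outer particle to its single nearest nucleus partner (model M1)
creates straight chains through the cell that propagate stress nonlocally,
while fanning each outer particle out to its w nearest nucleus partners
(model M2) distributes stress and removes the artifact.  The nucleus
interior uses the same machinery but links the most distant particle
pairs, and its springs are built five times stiffer than the cytoskeleton
(k_s^nuc = 5 k_s^cyt) with equal damper viscosity.

Bond count is controlled by the density rho = bonds / outer-membrane
particles, which makes whole-cell mechanics independent of mesh
resolution and cell size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .mesh import TriMesh

logger = logging.getLogger(__name__)

__all__ = [
    "KvBond",
    "BondNetwork",
    "TopologySpec",
    "NUCLEUS_STIFFNESS_FACTOR",
    "select_eligible",
    "build_cytoskeleton",
    "build_nucleus_network",
    "kv_bond_force",
]

#: The nucleus is ~5x stiffer than the surrounding cytoskeleton.
NUCLEUS_STIFFNESS_FACTOR = 5.0


@dataclass(frozen=True)
class KvBond:
    """One spring-damper bond between particles i and j."""

    i: int
    j: int
    k_s: float
    k_v_damp: float
    l_0b: float

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("bond endpoints must differ")
        if self.k_s < 0 or self.k_v_damp < 0:
            raise ValueError("k_s and k_v_damp must be non-negative")
        if self.l_0b <= 0:
            raise ValueError("equilibrium length must be positive")


@dataclass
class BondNetwork:
    """Array-of-struct view of a KV bond list for the force kernels."""

    i: np.ndarray
    j: np.ndarray
    k_s: np.ndarray
    k_v_damp: np.ndarray
    l_0b: np.ndarray

    @classmethod
    def from_bonds(cls, bonds: list[KvBond]) -> "BondNetwork":
        return cls(
            i=np.array([b.i for b in bonds], dtype=np.int64),
            j=np.array([b.j for b in bonds], dtype=np.int64),
            k_s=np.array([b.k_s for b in bonds], dtype=np.float64),
            k_v_damp=np.array([b.k_v_damp for b in bonds], dtype=np.float64),
            l_0b=np.array([b.l_0b for b in bonds], dtype=np.float64),
        )

    def __len__(self) -> int:
        return len(self.i)

    def to_bonds(self) -> list[KvBond]:
        return [
            KvBond(int(i), int(j), float(ks), float(kv), float(l0))
            for i, j, ks, kv, l0 in zip(
                self.i, self.j, self.k_s, self.k_v_damp, self.l_0b
            )
        ]


@dataclass
class TopologySpec:
    """Wiring recipe for the cytoskeleton network.

    variant 'M1': nearest single partner per eligible outer vertex.
    variant 'M2': w nearest partners per eligible outer vertex.
    rho: bonds per outer-membrane particle.
    """

    variant: str = "M2"
    w: int = 5
    rho: float = 0.8
    seed: int = 0
    nucleus_clusters: int | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("M1", "M2"):
            raise ValueError("variant must be 'M1' or 'M2'")
        if self.rho <= 0:
            raise ValueError("bond density rho must be positive")
        if self.w < 1:
            raise ValueError("connectivity width w must be >= 1")
        if self.variant == "M1":
            self.w = 1


def select_eligible(mesh: TriMesh, n_clusters: int, seed: int) -> np.ndarray:
    """k-means-selected subset of vertices eligible for bonding.

    Clusters the vertex coordinates and keeps, per cluster, the vertex
    nearest the centroid (ties broken by lowest index).  This spreads the
    eligible set near-uniformly over the surface.
    """
    n_v = mesh.n_vertices
    if not (1 <= n_clusters <= n_v):
        raise ValueError(f"n_clusters must be in [1, {n_v}]")
    if n_clusters == n_v:
        return np.arange(n_v, dtype=np.int64)
    km = KMeans(n_clusters=n_clusters, random_state=int(seed) % (2**31), n_init=4)
    labels = km.fit_predict(mesh.vertices)
    chosen = []
    for c in range(n_clusters):
        members = np.flatnonzero(labels == c)
        if len(members) == 0:  # pragma: no cover - sklearn avoids empty clusters
            logger.warning("empty k-means cluster %d; skipped", c)
            continue
        d = np.linalg.norm(mesh.vertices[members] - km.cluster_centers_[c], axis=1)
        chosen.append(members[np.lexsort((members, d))[0]])
    return np.unique(np.array(chosen, dtype=np.int64))


def _rank_partners(
    sources: np.ndarray,
    targets: np.ndarray,
    src_xyz: np.ndarray,
    tgt_xyz: np.ndarray,
    w: int,
    farthest: bool,
    exclude_self: bool,
) -> list[list[int]]:
    """Per source, the w nearest (or farthest) targets, ties to low index."""
    out = []
    for s, sx in zip(sources, src_xyz):
        d = np.linalg.norm(tgt_xyz - sx, axis=1)
        if farthest:
            d = -d
        order = np.lexsort((targets, d))
        picks = []
        for t in targets[order]:
            if exclude_self and t == s:
                continue
            picks.append(int(t))
            if len(picks) == w:
                break
        out.append(picks)
    return out


def build_cytoskeleton(
    outer: TriMesh,
    nucleus: TriMesh,
    spec: TopologySpec,
    k_s: float,
    k_v_damp: float,
) -> list[KvBond]:
    """Wire outer membrane to nucleus membrane with KV bonds.

    The number of eligible outer vertices is chosen so the total bond
    count approximates round(rho * N_outer); equilibrium lengths are the
    construction-time distances; duplicate pairs are removed.  Returned
    bonds use the combined cell indexing: outer vertices keep their mesh
    indices, nucleus vertex indices are shifted by ``outer.n_vertices``.
    """
    n_outer = outer.n_vertices
    target = int(round(spec.rho * n_outer))
    if target < 1:
        raise ValueError("bond density too low: zero bonds requested")
    n_elig_outer = min(
        n_outer, target if spec.variant == "M1" else int(np.ceil(target / spec.w))
    )
    elig_outer = select_eligible(outer, n_elig_outer, spec.seed)
    n_clusters_nuc = spec.nucleus_clusters
    if n_clusters_nuc is None:
        n_clusters_nuc = min(nucleus.n_vertices, len(elig_outer) * spec.w)
    elig_nuc = select_eligible(nucleus, n_clusters_nuc, spec.seed + 1)
    if target > len(elig_outer) * min(spec.w, len(elig_nuc)):
        raise ValueError(
            f"requested {target} bonds exceeds the w * eligible-nucleus capacity "
            f"({len(elig_outer)} x {min(spec.w, len(elig_nuc))})"
        )
    if spec.w > len(elig_nuc):
        raise ValueError(
            f"requested {target} bonds needs w={spec.w} partners but only "
            f"{len(elig_nuc)} eligible nucleus vertices exist"
        )
    partner_lists = _rank_partners(
        elig_outer,
        elig_nuc,
        outer.vertices[elig_outer],
        nucleus.vertices[elig_nuc],
        spec.w,
        farthest=False,
        exclude_self=False,
    )
    bonds: list[KvBond] = []
    seen: set[tuple[int, int]] = set()
    for oi, partners in zip(elig_outer, partner_lists):
        for pj in partners:
            key = (int(oi), int(pj))
            if key in seen:
                continue
            seen.add(key)
            l0 = float(np.linalg.norm(outer.vertices[oi] - nucleus.vertices[pj]))
            bonds.append(KvBond(int(oi), int(pj) + n_outer, k_s, k_v_damp, l0))
            if len(bonds) >= target:
                break
        if len(bonds) >= target:
            break
    return bonds


def build_nucleus_network(
    nucleus: TriMesh,
    rho_nucl: float,
    k_s_cyt: float,
    k_v_damp: float,
    seed: int,
    *,
    variant: str = "M2",
    w: int = 5,
) -> list[KvBond]:
    """Internal nucleus KV network linking the most distant eligible pairs.

    The 5x stiffness rule is applied here: bonds carry
    k_s = NUCLEUS_STIFFNESS_FACTOR * k_s_cyt, with the damper viscosity
    unchanged.
    """
    if rho_nucl <= 0:
        raise ValueError("rho_nucl must be positive")
    n_v = nucleus.n_vertices
    target = int(round(rho_nucl * n_v))
    if target < 1:
        raise ValueError("nucleus bond density too low: zero bonds requested")
    if variant == "M1":
        w = 1
    n_elig = min(n_v, target if variant == "M1" else int(np.ceil(target / w)))
    elig = select_eligible(nucleus, n_elig, seed)
    if len(elig) < 2:
        raise ValueError("need at least 2 eligible nucleus vertices")
    # full farthest-first ranking per eligible vertex; symmetric duplicates
    # are removed, so partners are consumed round-robin until the target
    # density is reached
    rankings = _rank_partners(
        elig,
        elig,
        nucleus.vertices[elig],
        nucleus.vertices[elig],
        len(elig) - 1,
        farthest=True,
        exclude_self=True,
    )
    k_s_nuc = NUCLEUS_STIFFNESS_FACTOR * k_s_cyt
    bonds: list[KvBond] = []
    seen: set[tuple[int, int]] = set()
    depth = 0
    max_depth = max(len(r) for r in rankings)
    while len(bonds) < target and depth < max_depth:
        for si, partners in zip(elig, rankings):
            if depth >= len(partners):
                continue
            pj = partners[depth]
            key = (min(int(si), pj), max(int(si), pj))
            if key in seen:
                continue
            seen.add(key)
            l0 = float(np.linalg.norm(nucleus.vertices[si] - nucleus.vertices[pj]))
            bonds.append(KvBond(int(si), int(pj), k_s_nuc, k_v_damp, l0))
            if len(bonds) >= target:
                break
        depth += 1
    if len(bonds) < target:
        raise ValueError(
            f"nucleus network saturated at {len(bonds)} bonds; requested {target}"
        )
    return bonds


def kv_bond_force(
    bond: KvBond,
    r_i: np.ndarray,
    r_j: np.ndarray,
    v_i: np.ndarray,
    v_j: np.ndarray,
    *,
    strain_based: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Force pair from one KV bond (reference scalar-tension form).

    Tension T = k_s eps + k_v d eps/dt with strain eps = (l - l_0)/l_0 and
    d eps/dt = (v_ij . r_hat)/l_0; positive tension pulls i toward j.  The
    extension-based variant drops the 1/l_0 normalization.
    """
    r_ij = np.asarray(r_i, float) - np.asarray(r_j, float)
    l = float(np.linalg.norm(r_ij))
    if l < 1e-12:
        raise ValueError("coincident bonded particles: bond direction undefined")
    e = r_ij / l
    ldot = float(e @ (np.asarray(v_i, float) - np.asarray(v_j, float)))
    if strain_based:
        tension = bond.k_s * (l - bond.l_0b) / bond.l_0b + bond.k_v_damp * ldot / bond.l_0b
    else:
        tension = bond.k_s * (l - bond.l_0b) + bond.k_v_damp * ldot
    f_i = -tension * e
    return f_i, -f_i
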