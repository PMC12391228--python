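"""Assemble a complete cell model: two membranes plus KV networks.

A cell is two concentric closed triangulated spheres (outer membrane and
nucleus membrane) meshed at the same target bond length, a cytoskeleton
KV-bond network wiring them together, and an internal nucleus KV network.
The nuclear-cytoplasmic ratio is interpreted as a volume ratio (the
conventional usage), so the nucleus radius is nc_ratio^(1/3) times the
cell radius; after meshing, the nucleus is rescaled so the realized
mesh-volume ratio matches the requested one exactly.

Global particle indexing convention: outer-membrane vertices occupy
[0, N_outer), nucleus vertices [N_outer, N_outer + N_nucl).  Bond index
arrays stored on the model use this global convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .cytoskeleton import (
    BondNetwork,
    TopologySpec,
    build_cytoskeleton,
    build_nucleus_network,
)
from .membrane import MembraneParams
from .mesh import TriMesh, make_sphere_mesh

__all__ = ["CellModel", "build_cell"]


@dataclass
class CellModel:
    """Complete mechanical model of one cell."""

    outer: TriMesh
    nucleus: TriMesh
    cytoskeleton: BondNetwork  # global indices
    nucleus_bonds: BondNetwork  # global indices
    outer_params: MembraneParams
    nucleus_params: MembraneParams
    diameter_um: float
    nc_ratio: float
    length_scale_um: float  # micrometres per simulation length unit

    @property
    def n_outer(self) -> int:
        return self.outer.n_vertices

    @property
    def n_nucleus(self) -> int:
        return self.nucleus.n_vertices

    @property
    def n_particles(self) -> int:
        return self.n_outer + self.n_nucleus

    def all_positions(self) -> np.ndarray:
        return np.vstack([self.outer.vertices, self.nucleus.vertices])

    def volume_ratio(self) -> float:
        return self.nucleus.volume() / self.outer.volume()

    def min_membrane_gap(self) -> float:
        """Smallest outer-vertex-to-nucleus-vertex distance (cheap proxy)."""
        from scipy.spatial import cKDTree

        tree = cKDTree(self.nucleus.vertices)
        d, _ = tree.query(self.outer.vertices, k=1)
        return float(d.min())

    def parameter_sidecar(self) -> dict:
        """JSON-serializable record of every model parameter."""
        return {
            "schema": "cellflow-cell/1",
            "diameter_um": self.diameter_um,
            "nc_ratio": self.nc_ratio,
            "length_scale_um": self.length_scale_um,
            "n_outer": self.n_outer,
            "n_nucleus": self.n_nucleus,
            "outer_params": asdict(self.outer_params),
            "nucleus_params": asdict(self.nucleus_params),
            "n_cytoskeleton_bonds": len(self.cytoskeleton),
            "n_nucleus_bonds": len(self.nucleus_bonds),
            "k_s_cyt": float(self.cytoskeleton.k_s[0]) if len(self.cytoskeleton) else None,
            "k_s_nuc": float(self.nucleus_bonds.k_s[0]) if len(self.nucleus_bonds) else None,
        }

    def save_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.parameter_sidecar(), fh, indent=1)


def _default_membrane_params(
    which: str, kbt: float, a_0: float, v_0: float
) -> MembraneParams:
    """Calibrated membrane constants for the cell or nucleus surface."""
    if which == "cell":
        return MembraneParams(
            p=0.00141, l_max=3.0, l_0=0.5, k_b=65.0, k_a=10_000.0,
            k_vol=15_000.0, a_0=a_0, v_0=v_0, gamma=4.0, kbt=kbt,
        )
    return MembraneParams(
        p=0.00141, l_max=1.2, l_0=0.5, k_b=250.0, k_a=5_000.0,
        k_vol=15_000.0, a_0=a_0, v_0=v_0, gamma=4.0, kbt=kbt,
    )


def build_cell(
    diameter_um: float,
    nc_ratio: float = 0.29,
    *,
    topology: TopologySpec | None = None,
    k_s: float = 120.0,
    k_v_damp: float = 10.0,
    rho_nucl: float | None = None,
    target_edge_length: float = 0.5,
    length_scale_um: float = 1.0,
    kbt: float = 0.1,
    outer_params: MembraneParams | None = None,
    nucleus_params: MembraneParams | None = None,
    nc_ratio_is_volume: bool = True,
    center: np.ndarray | None = None,
) -> CellModel:
    """Build a concentric two-membrane cell with its KV networks.

    Bond density rho (in ``topology``) is bonds per outer-membrane
    particle and is independent of diameter, which is what makes the
    mechanics size-invariant.  Reference area/volume (A_0, V_0) are taken
    from the built meshes.
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    if not (0.0 < nc_ratio < 1.0):
        raise ValueError("nuclear-cytoplasmic ratio must lie in (0, 1)")
    topology = topology or TopologySpec()
    rho_nucl = topology.rho if rho_nucl is None else rho_nucl

    r_cell = 0.5 * diameter_um / length_scale_um
    r_nuc = r_cell * (nc_ratio ** (1.0 / 3.0) if nc_ratio_is_volume else nc_ratio)
    outer = make_sphere_mesh(r_cell, target_edge_length)
    nucleus = make_sphere_mesh(r_nuc, target_edge_length)
    if nc_ratio_is_volume:
        # exact volume-ratio correction for discretization shrinkage
        scale = (nc_ratio * outer.volume() / nucleus.volume()) ** (1.0 / 3.0)
        nucleus.vertices *= scale
        nucleus.rest_lengths *= scale
    r_nuc_max = np.linalg.norm(nucleus.vertices, axis=1).max()
    r_out_min = np.linalg.norm(outer.vertices, axis=1).min()
    # demand clearance of at least half a bond length between membranes
    if r_nuc_max >= r_out_min - 0.5 * target_edge_length:
        raise ValueError(
            "nucleus is not strictly inside the outer membrane; "
            "lower nc_ratio or refine the mesh"
        )

    cyt = build_cytoskeleton(outer, nucleus, topology, k_s, k_v_damp)
    nuc = build_nucleus_network(
        nucleus, rho_nucl, k_s, k_v_damp, topology.seed + 2,
        variant=topology.variant, w=topology.w,
    )
    cyt_net = BondNetwork.from_bonds(cyt)  # already in the global convention
    nuc_net = BondNetwork.from_bonds(nuc)
    n_outer = outer.n_vertices
    nuc_net.i = nuc_net.i + n_outer
    nuc_net.j = nuc_net.j + n_outer

    op = outer_params or _default_membrane_params(
        "cell", kbt, outer.area(), outer.volume()
    )
    np_ = nucleus_params or _default_membrane_params(
        "nucleus", kbt, nucleus.area(), nucleus.volume()
    )

    model = CellModel(
        outer=outer,
        nucleus=nucleus,
        cytoskeleton=cyt_net,
        nucleus_bonds=nuc_net,
        outer_params=op,
        nucleus_params=np_,
        diameter_um=diameter_um,
        nc_ratio=nc_ratio,
        length_scale_um=length_scale_um,
    )
    if center is not None:
        shift = np.asarray(center, float)
        model.outer.vertices += shift
        model.nucleus.vertices += shift
    return model
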