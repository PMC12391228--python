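"""LAMMPS data-file export/import of the cell topology.

The file records the complete interaction bookkeeping of a cell model:
atoms (membrane particles), bonds with one type per component (1 =
membrane edge, 2 = cytoskeleton KV, 3 = nucleus KV), angles (one per
surface triangle, carrying the in-plane/area elements) and dihedrals
(one per edge-adjacent triangle pair, carrying bending).  For closed
surfaces the counts obey

    angles    = 2 * N_vertices - 4 * N_surfaces
    dihedrals = 3 * N_vertices - 6 * N_surfaces

which the writer asserts.  The writer targets interchange and auditing;
a commented header documents the intended styles.
"""

from __future__ import annotations

import numpy as np

from .builder import CellModel
from .cytoskeleton import BondNetwork
from .mesh import TriMesh

__all__ = ["write_lammps_data", "read_lammps_data", "topology_counts"]

BOND_TYPE_MEMBRANE = 1
BOND_TYPE_CYTOSKELETON = 2
BOND_TYPE_NUCLEUS = 3


def topology_counts(meshes: list[TriMesh]) -> dict:
    """Aggregate particle/edge/angle/dihedral counts over closed surfaces."""
    nv = sum(m.n_vertices for m in meshes)
    ne = sum(m.n_edges for m in meshes)
    nt = sum(m.n_triangles for m in meshes)
    nd = sum(len(m.dihedrals) for m in meshes)
    ns = len(meshes)
    assert nt == 2 * nv - 4 * ns, "angle count violates the Euler identity"
    assert nd == 3 * nv - 6 * ns, "dihedral count violates the Euler identity"
    return {"particles": nv, "edges": ne, "angles": nt, "dihedrals": nd,
            "surfaces": ns}


def write_lammps_data(cell: CellModel, path) -> dict:
    """Serialize a cell model to a LAMMPS data file; returns the counts."""
    meshes = [cell.outer, cell.nucleus]
    counts = topology_counts(meshes)
    n_outer = cell.n_outer
    n_atoms = counts["particles"]
    n_bonds = counts["edges"] + len(cell.cytoskeleton) + len(cell.nucleus_bonds)
    pos = cell.all_positions()
    lo = pos.min(axis=0) - 2.0
    hi = pos.max(axis=0) + 2.0
    with open(path, "w") as fh:
        fh.write(
            "# cellflow cell model (intended styles: bond wlc/kelvin-voigt,"
            " angle area, dihedral bend)\n\n"
        )
        fh.write(f"{n_atoms} atoms\n{n_bonds} bonds\n")
        fh.write(f"{counts['angles']} angles\n{counts['dihedrals']} dihedrals\n\n")
        fh.write("2 atom types\n3 bond types\n2 angle types\n2 dihedral types\n\n")
        for d, lab in enumerate("xyz"):
            fh.write(f"{lo[d]:.8g} {hi[d]:.8g} {lab}lo {lab}hi\n")
        fh.write("\nMasses\n\n1 1.0\n2 1.0\n\n")
        fh.write("Atoms # molecular (id mol type x y z)\n\n")
        for i, p in enumerate(pos, start=1):
            mol, typ = (1, 1) if i <= n_outer else (2, 2)
            fh.write(f"{i} {mol} {typ} {p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
        fh.write("\nBonds\n\n")
        bid = 1
        for mesh, off in ((cell.outer, 0), (cell.nucleus, n_outer)):
            for a, b in mesh.edges:
                fh.write(f"{bid} {BOND_TYPE_MEMBRANE} {a + off + 1} {b + off + 1}\n")
                bid += 1
        for net, btype in (
            (cell.cytoskeleton, BOND_TYPE_CYTOSKELETON),
            (cell.nucleus_bonds, BOND_TYPE_NUCLEUS),
        ):
            for a, b in zip(net.i, net.j):
                fh.write(f"{bid} {btype} {a + 1} {b + 1}\n")
                bid += 1
        fh.write("\nAngles\n\n")
        aid = 1
        for stype, (mesh, off) in enumerate(
            ((cell.outer, 0), (cell.nucleus, n_outer)), start=1
        ):
            for a, b, c in mesh.triangles:
                fh.write(f"{aid} {stype} {a + off + 1} {b + off + 1} {c + off + 1}\n")
                aid += 1
        fh.write("\nDihedrals\n\n")
        did = 1
        for stype, (mesh, off) in enumerate(
            ((cell.outer, 0), (cell.nucleus, n_outer)), start=1
        ):
            for i, j, k, l in mesh.dihedrals:
                # chain k-i-j-l around the shared edge (i, j)
                fh.write(
                    f"{did} {stype} {k + off + 1} {i + off + 1} "
                    f"{j + off + 1} {l + off + 1}\n"
                )
                did += 1
    return counts


def read_lammps_data(path) -> dict:
    """Parse a data file written by :func:`write_lammps_data`.

    Returns positions plus raw bond/angle/dihedral index arrays
    (0-based) keyed by section; used for round-trip topology audits.
    """
    sections: dict[str, list] = {}
    counts: dict[str, int] = {}
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip() if "#" in line else line.strip()
            if not line:
                continue
            parts = line.split()
            if parts[-1] in ("atoms", "bonds", "angles", "dihedrals") and len(parts) == 2:
                counts[parts[1]] = int(parts[0])
                continue
            if parts[0] in ("Atoms", "Bonds", "Angles", "Dihedrals", "Masses"):
                current = parts[0]
                sections[current] = []
                continue
            if current is not None and parts[0].lstrip("-").isdigit():
                sections[current].append([float(x) for x in parts])
    atoms = np.array(sections.get("Atoms", []))
    order = np.argsort(atoms[:, 0])
    atoms = atoms[order]
    out = {
        "counts": counts,
        "positions": atoms[:, 3:6],
        "types": atoms[:, 2].astype(int),
        "molecules": atoms[:, 1].astype(int),
    }
    for key, width in (("Bonds", 2), ("Angles", 3), ("Dihedrals", 4)):
        rows = np.array(sections.get(key, []), dtype=np.int64)
        if len(rows):
            out[key.lower()] = rows[:, 2:2 + width] - 1
            out[key.lower() + "_types"] = rows[:, 1]
        else:
            out[key.lower()] = np.empty((0, width), dtype=np.int64)
            out[key.lower() + "_types"] = np.empty(0, dtype=np.int64)
    return out
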