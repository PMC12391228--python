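"""Closed triangulated surface meshes for cell and nucleus membranes.

A membrane is a closed, outward-oriented, genus-0 triangulation.  Every
vertex is one coarse-grained particle; every edge is an elastic bond; every
pair of triangles sharing an edge is a bending (dihedral) element.  The
topological bookkeeping of a closed genus-0 surface is fixed by Euler's
formula::

    N_v - N_e + N_t = 2,   N_e = 3 (N_v - 2),   N_t = 2 (N_v - 2)

which this module audits for every mesh it produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh

__all__ = [
    "TriMesh",
    "make_sphere_mesh",
    "make_uv_sphere_mesh",
    "mesh_geometry",
    "write_off",
    "write_vtk",
]

#: Hard ceiling on generated mesh size (overridable per call).
DEFAULT_VERTEX_CAP = 200_000


class MeshTopologyError(ValueError):
    """Raised when a surface fails the closed-orientable-surface audit."""


@dataclass
class TriMesh:
    """Closed triangulated surface.

    Attributes
    ----------
    vertices : (N_v, 3) float array
        Vertex positions.
    edges : (N_e, 2) int array
        Unique undirected edges, each row sorted ``i < j``.
    triangles : (N_t, 3) int array
        Consistently outward-oriented triangles.
    dihedrals : (N_e, 4) int array
        One row ``(i, j, k, l)`` per edge: triangles ``(i, j, k)`` and
        ``(j, i, l)`` are the two outward-oriented faces sharing edge
        ``(i, j)``.
    rest_lengths : (N_e,) float array
        Per-edge equilibrium bond length ``l_0`` (construction length by
        default).
    """

    vertices: np.ndarray
    edges: np.ndarray
    triangles: np.ndarray
    dihedrals: np.ndarray
    rest_lengths: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.edges = np.ascontiguousarray(self.edges, dtype=np.int64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        self.dihedrals = np.ascontiguousarray(self.dihedrals, dtype=np.int64)
        if self.rest_lengths is None:
            self.rest_lengths = self.edge_lengths()
        self.rest_lengths = np.ascontiguousarray(self.rest_lengths, dtype=np.float64)
        self.validate()

    # -- counts ---------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    # -- geometry -------------------------------------------------------
    def edge_lengths(self) -> np.ndarray:
        d = self.vertices[self.edges[:, 0]] - self.vertices[self.edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def triangle_areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        n = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return 0.5 * np.linalg.norm(n, axis=1)

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def volume(self) -> float:
        """Signed enclosed volume (positive for outward orientation)."""
        v = self.vertices
        t = self.triangles
        return float(
            np.einsum(
                "ij,ij->i", v[t[:, 0]], np.cross(v[t[:, 1]], v[t[:, 2]])
            ).sum()
            / 6.0
        )

    # -- audits ---------------------------------------------------------
    def validate(self) -> None:
        nv, ne, nt = self.n_vertices, self.n_edges, self.n_triangles
        if nv - ne + nt != 2:
            raise MeshTopologyError(
                f"Euler characteristic {nv - ne + nt} != 2 "
                f"(N_v={nv}, N_e={ne}, N_t={nt})"
            )
        if ne != 3 * (nv - 2) or nt != 2 * (nv - 2):
            raise MeshTopologyError("closed genus-0 count identities violated")
        # every directed edge must occur exactly once -> consistent winding
        directed = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        keys = directed[:, 0] * nv + directed[:, 1]
        uniq, counts = np.unique(keys, return_counts=True)
        if len(uniq) != 3 * nt or counts.max() != 1:
            bad = directed[np.searchsorted(np.sort(keys), uniq[counts > 1][:1])]
            raise MeshTopologyError(
                f"inconsistent triangle orientation at edge {bad.tolist()}"
            )
        if self.volume() <= 0.0:
            raise MeshTopologyError(
                "non-positive enclosed volume: inward-oriented surface"
            )

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.edges.copy(),
            self.triangles.copy(),
            self.dihedrals.copy(),
            self.rest_lengths.copy(),
        )


def _topology_from_faces(faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Edge list and dihedral quadruples from oriented faces.

    For each undirected edge (i, j) the two adjacent outward faces are
    ``(i, j, k)`` and ``(j, i, l)``; the quadruple stored is (i, j, k, l).
    """
    faces = np.asarray(faces, dtype=np.int64)
    # map directed edge -> opposite vertex
    opposite: dict[tuple[int, int], int] = {}
    for a, b, c in faces:
        opposite[(a, b)] = c
        opposite[(b, c)] = a
        opposite[(c, a)] = b
    seen = set()
    edges = []
    dihedrals = []
    for (a, b), k in opposite.items():
        key = (min(a, b), max(a, b))
        if key in seen:
            continue
        seen.add(key)
        if (b, a) not in opposite:
            raise MeshTopologyError(f"edge {key} bounds only one triangle")
        l = opposite[(b, a)]
        edges.append(key)
        dihedrals.append((a, b, k, l))
    order = np.lexsort(np.array(edges, dtype=np.int64).T[::-1])
    return (
        np.array(edges, dtype=np.int64)[order],
        np.array(dihedrals, dtype=np.int64)[order],
    )


def from_vertices_faces(vertices: np.ndarray, faces: np.ndarray) -> TriMesh:
    """Build a :class:`TriMesh` (with full audit) from raw triangle soup."""
    edges, dihedrals = _topology_from_faces(faces)
    return TriMesh(np.asarray(vertices, float), edges, np.asarray(faces), dihedrals)


def _geodesic_sphere(radius: float, frequency: int) -> tuple[np.ndarray, np.ndarray]:
    """Class-I geodesic sphere: icosahedron faces split into f^2 triangles.

    Unlike repeated 4-fold subdivision, any integer frequency is allowed,
    so achievable mean edge lengths are densely spaced.
    """
    ico = _trimesh.creation.icosphere(subdivisions=0, radius=1.0)
    base_v = np.asarray(ico.vertices)
    f = frequency
    verts: list[np.ndarray] = []
    faces: list[tuple[int, int, int]] = []
    index: dict[tuple[int, int, int], int] = {}

    def vid(p: np.ndarray) -> int:
        key = tuple(np.round(p * 1e9).astype(np.int64))
        if key not in index:
            index[key] = len(verts)
            verts.append(p)
        return index[key]

    for a, b, c in np.asarray(ico.faces):
        A, B, C = base_v[a], base_v[b], base_v[c]
        grid = {}
        for i in range(f + 1):
            for j in range(f + 1 - i):
                p = (A * (f - i - j) + B * i + C * j) / f
                grid[(i, j)] = vid(p / np.linalg.norm(p))
        for i in range(f):
            for j in range(f - i):
                faces.append((grid[(i, j)], grid[(i + 1, j)], grid[(i, j + 1)]))
                if j < f - i - 1:
                    faces.append(
                        (grid[(i + 1, j)], grid[(i + 1, j + 1)], grid[(i, j + 1)])
                    )
    return radius * np.array(verts), np.array(faces, dtype=np.int64)


def make_sphere_mesh(
    radius: float,
    target_edge_length: float,
    *,
    vertex_cap: int = DEFAULT_VERTEX_CAP,
) -> TriMesh:
    """Geodesic icosphere whose mean edge length approximates the target.

    The subdivision frequency f (N_v = 10 f^2 + 2) is chosen to minimize
    the deviation of the mean realized edge length from
    ``target_edge_length``; per-edge rest lengths are the constructed
    lengths.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not (0 < target_edge_length < radius * 2.5):
        raise ValueError("target_edge_length must be positive and below the diameter")
    best = None
    for f in range(1, 1000):
        n_v = 10 * f * f + 2
        n_t = 2 * (n_v - 2)
        # area-equipartition estimate of the mean edge length
        mean_edge = np.sqrt(4.0 * np.pi * radius**2 / (n_t * np.sqrt(3.0) / 4.0))
        dev = abs(mean_edge - target_edge_length)
        if best is None or dev < best[1]:
            best = (f, dev, n_v)
        if mean_edge < 0.5 * target_edge_length:
            break
    f, _, n_v = best
    if n_v > vertex_cap:
        raise ValueError(
            f"requested resolution needs {n_v} vertices, above cap {vertex_cap}"
        )
    verts, faces = _geodesic_sphere(radius, f)
    return from_vertices_faces(verts, faces)


def make_uv_sphere_mesh(radius: float, count: tuple[int, int]) -> TriMesh:
    """Latitude/longitude sphere; permits vertex counts icospheres cannot hit."""
    uv = _trimesh.creation.uv_sphere(radius=radius, count=count)
    uv.merge_vertices()
    if not uv.is_watertight:
        raise MeshTopologyError("uv sphere failed to close")
    return from_vertices_faces(np.asarray(uv.vertices), np.asarray(uv.faces))


def mesh_geometry(mesh: TriMesh) -> tuple[float, float, np.ndarray]:
    """Surface area, signed enclosed volume, and per-triangle areas."""
    areas = mesh.triangle_areas()
    return float(areas.sum()), mesh.volume(), areas


# -- plain-text exports -------------------------------------------------

def write_off(mesh: TriMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{mesh.n_vertices} {mesh.n_triangles} {mesh.n_edges}\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def write_vtk(mesh: TriMesh, path) -> None:
    """Legacy ASCII VTK polydata snapshot of the surface."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncellflow membrane\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}\n")
        fh.write(f"POLYGONS {mesh.n_triangles} {4 * mesh.n_triangles}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
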