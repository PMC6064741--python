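"""Length, surface-area and volume measurements on meshes and selections.

Three length modes are provided: straight-line distance between two points,
the shortest path through the mesh's own vertex graph (a graph geodesic,
not an exact polyhedral geodesic — it can only overestimate the true
surface distance), and the summed length of an explicit edge selection.
Surface area sums triangle areas over a face selection. Volume first caps
any boundary loops of the selected region (centroid fan), orients the
faces coherently, and applies the divergence theorem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .mesh_core import (
    SurfaceMesh,
    boundary_loops,
    face_areas,
    submesh,
    unique_edges,
)

__all__ = [
    "FaceSelection", "distance_between_points", "shortest_path_on_mesh",
    "selected_edge_length", "surface_area", "close_holes", "volume",
]


@dataclass
class FaceSelection:
    """A subset of a mesh's faces (may be empty → zero-valued measures)."""

    mesh: SurfaceMesh
    face_indices: np.ndarray

    def __post_init__(self) -> None:
        self.face_indices = np.asarray(sorted(set(int(i) for i in np.atleast_1d(
            np.asarray(self.face_indices, dtype=np.int64)))), dtype=np.int64)
        if len(self.face_indices) and (
            self.face_indices.min() < 0 or self.face_indices.max() >= self.mesh.n_faces
        ):
            raise IndexError("face index out of selection range")

    @classmethod
    def all_faces(cls, mesh: SurfaceMesh) -> "FaceSelection":
        return cls(mesh, np.arange(mesh.n_faces))

    def to_submesh(self) -> SurfaceMesh:
        return submesh(self.mesh, self.face_indices)


def distance_between_points(p, q) -> float:
    """Euclidean distance between two 3D points, ignoring any mesh surface."""
    return float(np.linalg.norm(np.asarray(p, dtype=float) - np.asarray(q, dtype=float)))


def _edge_graph(mesh: SurfaceMesh):
    edges = unique_edges(mesh)
    if not len(edges):
        raise ValueError("mesh has no edges")
    w = np.linalg.norm(mesh.vertices[edges[:, 0]] - mesh.vertices[edges[:, 1]], axis=1)
    n = mesh.n_vertices
    return coo_matrix((w, (edges[:, 0], edges[:, 1])), shape=(n, n)).tocsr()


def shortest_path_on_mesh(mesh: SurfaceMesh, v_start: int, v_end: int):
    """Shortest path between two vertices along the mesh edge graph.

    Returns ``(length_um, path_vertex_indices)``. Dijkstra with Euclidean
    edge weights; raises ``ValueError`` when the vertices lie in different
    connected components.
    """
    n = mesh.n_vertices
    if not (0 <= v_start < n and 0 <= v_end < n):
        raise IndexError("vertex index out of range")
    graph = _edge_graph(mesh)
    dist, pred = dijkstra(graph, directed=False, indices=v_start, return_predecessors=True)
    if not np.isfinite(dist[v_end]):
        raise ValueError(
            f"no path between vertices {v_start} and {v_end} (different components)"
        )
    path = [v_end]
    while path[-1] != v_start:
        path.append(int(pred[path[-1]]))
    path.reverse()
    return float(dist[v_end]), path


def selected_edge_length(mesh: SurfaceMesh, edges) -> float:
    """Total Euclidean length of the selected edges (µm)."""
    known = {tuple(sorted(map(int, e))) for e in unique_edges(mesh)}
    total = 0.0
    for e in edges:
        key = tuple(sorted(map(int, e)))
        if key not in known:
            raise ValueError(f"edge {key} does not exist in mesh {mesh.name!r}")
        total += float(np.linalg.norm(mesh.vertices[key[0]] - mesh.vertices[key[1]]))
    return total


def surface_area(sel) -> float:
    """Surface area (µm²) of a mesh or a :class:`FaceSelection`."""
    if isinstance(sel, SurfaceMesh):
        return float(face_areas(sel).sum())
    areas = face_areas(sel.mesh)
    return float(areas[sel.face_indices].sum()) if len(sel.face_indices) else 0.0


def close_holes(mesh_or_sel) -> SurfaceMesh:
    """Cap every boundary loop with a centroid fan; returns a watertight mesh.

    Each loop of boundary edges (edges with exactly one incident face) is
    triangulated against the loop's vertex centroid. Raises ``ValueError``
    on a non-manifold boundary, with the advice to run ``clean_mesh``.
    """
    mesh = mesh_or_sel.to_submesh() if isinstance(mesh_or_sel, FaceSelection) else mesh_or_sel
    loops = boundary_loops(mesh)
    if not loops:
        return mesh.copy()
    vertices = [mesh.vertices]
    new_faces = [mesh.faces]
    next_idx = mesh.n_vertices
    for loop in loops:
        centroid = mesh.vertices[loop].mean(axis=0)
        vertices.append(centroid[None, :])
        fan = np.column_stack([
            loop,
            np.roll(loop, -1),
            np.full(len(loop), next_idx, dtype=np.int64),
        ])
        new_faces.append(fan)
        next_idx += 1
    return SurfaceMesh(
        name=mesh.name,
        vertices=np.vstack(vertices),
        faces=np.vstack(new_faces),
        provenance=mesh.provenance or "close_holes",
    )


def _orient_coherently(mesh: SurfaceMesh) -> np.ndarray:
    """Return faces flipped as needed so adjacent faces wind consistently.

    Two triangles sharing an edge are consistent when they traverse that
    edge in opposite directions. BFS over the face adjacency propagates a
    consistent choice; a parity conflict means the surface is non-orientable
    and raises ``ValueError``.
    """
    faces = mesh.faces.copy()
    if not len(faces):
        return faces
    # map undirected edge -> list of (face, direction)
    edge_key = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    directed = faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    forward = directed[:, 0] < directed[:, 1]
    uniq, inverse = np.unique(edge_key, axis=0, return_inverse=True)
    face_of = np.repeat(np.arange(len(faces)), 3)
    incidence: dict[int, list[tuple[int, bool]]] = {}
    for slot, (ei, fi) in enumerate(zip(inverse, face_of)):
        incidence.setdefault(int(ei), []).append((int(fi), bool(forward[slot])))

    flipped = np.zeros(len(faces), dtype=bool)
    state = np.full(len(faces), -1, dtype=np.int8)  # -1 unvisited, 0 keep, 1 flip
    for seed in range(len(faces)):
        if state[seed] >= 0:
            continue
        state[seed] = 0
        queue = [seed]
        while queue:
            fi = queue.pop()
            for ei in inverse[3 * fi:3 * fi + 3]:
                pair = incidence[int(ei)]
                if len(pair) != 2:
                    continue
                for fj, fwd_j in pair:
                    if fj == fi:
                        continue
                    fwd_i = next(d for f, d in pair if f == fi)
                    # consistent orientation = opposite traversal directions
                    want = state[fi] if fwd_i != fwd_j else 1 - state[fi]
                    if state[fj] == -1:
                        state[fj] = want
                        queue.append(fj)
                    elif state[fj] != want:
                        raise ValueError("non-orientable surface; cannot sign volume")
    flipped = state == 1
    faces[flipped] = faces[flipped][:, ::-1]
    return faces


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    v0, v1, v2 = vertices[faces[:, 0]], vertices[faces[:, 1]], vertices[faces[:, 2]]
    # translation invariance: sum about the vertex mean, not the origin
    c = vertices.mean(axis=0)
    return float(np.einsum("ij,ij->i", v0 - c, np.cross(v1 - c, v2 - c)).sum() / 6.0)


def volume(sel) -> float:
    """Volume (µm³) of the closed region bounded by a mesh or face selection.

    The selection's submesh is split into connected components; each is
    capped with :func:`close_holes`, coherently oriented, and measured by
    the divergence theorem. Multi-component selections return the sum of
    absolute component volumes. Translation-invariant.
    """
    from .mesh_core import connected_components

    mesh = sel.to_submesh() if isinstance(sel, FaceSelection) else sel
    if not len(mesh.faces):
        return 0.0
    total = 0.0
    for comp in connected_components(mesh):
        closed = close_holes(comp)
        faces = _orient_coherently(closed)
        total += abs(_signed_volume(closed.vertices, faces))
    return total
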