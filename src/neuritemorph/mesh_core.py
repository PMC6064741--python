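"""Core mesh and polyline types, Wavefront OBJ I/O, cleaning, and elementary geometry.

All coordinates are micrometers in a right-handed frame; no scaling is
applied on I/O. Faces are triangles internally (polygons are
fan-triangulated on load) and indices are 0-based internally, 1-based in
OBJ files as the format requires.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "SurfaceMesh", "Contour", "PointSet", "CleanReport", "ObjParseError",
    "read_obj", "write_obj", "clean_mesh", "face_area", "face_areas",
    "face_centroid", "face_centroids", "object_centroid",
    "connected_components", "is_watertight", "unique_edges",
    "boundary_loops", "points_inside",
]


class ObjParseError(ValueError):
    """Raised on a malformed OBJ record; the message names the line number."""


@dataclass
class SurfaceMesh:
    """A triangle surface mesh (possibly open), or a faceless polyline object.

    Parameters
    ----------
    name : str
        Object identifier (the ``o``/``g`` name in an OBJ file).
    vertices : (n, 3) float array
        Vertex positions in micrometers.
    faces : (m, 3) int array
        Triangle vertex indices; may be empty for polyline objects.
    edges : (k, 2) int array
        Explicit polyline edges (OBJ ``l`` records). Usually empty for
        surface meshes, whose edges are implied by the faces.
    provenance : str
        Free-text source tag (file of origin, generator, ...).
    """

    name: str
    vertices: np.ndarray
    faces: np.ndarray = field(default_factory=lambda: np.empty((0, 3), dtype=np.int64))
    edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.int64))
    provenance: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if self.faces.size:
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError(f"face index out of range for mesh {self.name!r}")
            if np.any(
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            ):
                raise ValueError(f"face repeats a vertex in mesh {self.name!r}")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.name, self.vertices.copy(), self.faces.copy(),
                           self.edges.copy(), self.provenance)


@dataclass
class Contour:
    """An ordered 3D polyline from one image plane.

    ``vertices`` are ordered along the curve; ``edges`` connect consecutive
    indices (closing edge included when ``closed``). ``plane_key`` is the
    scalar position of the source image plane in micrometers.
    """

    vertices: np.ndarray
    closed: bool = False
    plane_key: float = 0.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        if len(self.vertices) < 2:
            raise ValueError("a contour needs at least 2 vertices")

    @property
    def edges(self) -> np.ndarray:
        n = len(self.vertices)
        idx = np.arange(n)
        if self.closed:
            return np.column_stack([idx, np.roll(idx, -1)])
        return np.column_stack([idx[:-1], idx[1:]])

    def length(self) -> float:
        seg = np.diff(self.vertices, axis=0)
        total = float(np.linalg.norm(seg, axis=1).sum())
        if self.closed:
            total += float(np.linalg.norm(self.vertices[0] - self.vertices[-1]))
        return total

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def validate_planar(self, eps_plane: float = 1e-6, axis: int = 2) -> bool:
        """True when all vertices lie within ``eps_plane`` of a common plane."""
        coord = self.vertices[:, axis]
        return float(coord.max() - coord.min()) <= eps_plane


@dataclass
class PointSet:
    """Marker points (e.g. vesicle centers), with optional per-point radii (µm)."""

    points: np.ndarray
    radii: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        if self.radii is not None:
            self.radii = np.asarray(self.radii, dtype=np.float64).ravel()
            if len(self.radii) != len(self.points):
                raise ValueError("radii length must match point count")
            if np.any(self.radii <= 0):
                raise ValueError("radii must be positive")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CleanReport:
    """Tally of elements removed by :func:`clean_mesh`."""

    merged_vertices: int = 0
    degenerate_faces: int = 0
    duplicate_faces: int = 0
    nonmanifold_faces: int = 0
    floating_vertices: int = 0
    warning: str | None = None

    @property
    def total_removed_faces(self) -> int:
        return self.degenerate_faces + self.duplicate_faces + self.nonmanifold_faces

    def to_dict(self) -> dict:
        return {
            "merged_vertices": self.merged_vertices,
            "degenerate_faces": self.degenerate_faces,
            "duplicate_faces": self.duplicate_faces,
            "nonmanifold_faces": self.nonmanifold_faces,
            "floating_vertices": self.floating_vertices,
            "warning": self.warning,
        }


# ---------------------------------------------------------------------------
# OBJ I/O


def _parse_index(token: str, n_vertices: int, lineno: int) -> int:
    # OBJ faces may carry v/vt/vn triplets; only the vertex index is used.
    head = token.split("/")[0]
    try:
        idx = int(head)
    except ValueError:
        raise ObjParseError(f"line {lineno}: bad index token {token!r}") from None
    if idx == 0:
        raise ObjParseError(f"line {lineno}: OBJ indices are 1-based, got 0")
    if idx < 0:
        idx = n_vertices + idx  # relative indexing
    else:
        idx -= 1
    if idx < 0 or idx >= n_vertices:
        raise ObjParseError(f"line {lineno}: index {token!r} out of range")
    return idx


def read_obj(path) -> list[SurfaceMesh]:
    """Read a Wavefront OBJ file into a list of :class:`SurfaceMesh`.

    Supports ``v``, ``f``, ``l``, ``o`` and ``g`` records. Each ``o``/``g``
    record starts a new object; polygon faces are fan-triangulated; objects
    with only ``l`` records come back with empty ``faces`` and populated
    ``edges``, usable as contour or centerline sources. Vertex indices in
    the file are global (OBJ convention) and are remapped per object.
    """
    all_vertices: list[list[float]] = []
    objects: list[dict] = []
    current: dict | None = None

    def ensure_object(name: str | None = None) -> dict:
        nonlocal current
        if current is None or name is not None:
            current = {"name": name or f"object{len(objects)}", "faces": [], "lines": []}
            objects.append(current)
        return current

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise ObjParseError(f"line {lineno}: vertex needs 3 coordinates")
                all_vertices.append([float(parts[1]), float(parts[2]), float(parts[3])])
            elif tag in ("o", "g"):
                ensure_object(" ".join(parts[1:]) or None)
            elif tag == "f":
                if len(parts) < 4:
                    raise ObjParseError(f"line {lineno}: face needs >=3 indices")
                idx = [_parse_index(t, len(all_vertices), lineno) for t in parts[1:]]
                ensure_object()["faces"].append(idx)
            elif tag == "l":
                if len(parts) < 3:
                    raise ObjParseError(f"line {lineno}: line record needs >=2 indices")
                idx = [_parse_index(t, len(all_vertices), lineno) for t in parts[1:]]
                ensure_object()["lines"].append(idx)
            # other records (vn, vt, s, usemtl, ...) are ignored

    verts = np.asarray(all_vertices, dtype=np.float64).reshape(-1, 3)
    meshes: list[SurfaceMesh] = []
    for obj in objects:
        referenced: set[int] = set()
        for poly in obj["faces"]:
            referenced.update(poly)
        for chain in obj["lines"]:
            referenced.update(chain)
        used = sorted(referenced)  # keep the file's vertex declaration order
        seen = {g: k for k, g in enumerate(used)}

        tris: list[tuple[int, int, int]] = []
        for poly in obj["faces"]:
            loc = [seen[i] for i in poly]
            for k in range(1, len(loc) - 1):  # fan triangulation
                tris.append((loc[0], loc[k], loc[k + 1]))
        edges: list[tuple[int, int]] = []
        for chain in obj["lines"]:
            loc = [seen[i] for i in chain]
            edges.extend(zip(loc[:-1], loc[1:]))
        meshes.append(
            SurfaceMesh(
                name=obj["name"],
                vertices=verts[used] if used else np.empty((0, 3)),
                faces=np.asarray(tris, dtype=np.int64).reshape(-1, 3),
                edges=np.asarray(edges, dtype=np.int64).reshape(-1, 2),
                provenance=str(path),
            )
        )
    return meshes


def write_obj(meshes, path) -> None:
    """Write meshes to a Wavefront OBJ file re-readable by :func:`read_obj`.

    Faceless objects are emitted as ``l`` polyline records. Accepts a single
    mesh or a list.
    """
    if isinstance(meshes, SurfaceMesh):
        meshes = [meshes]
    offset = 1  # OBJ indices are 1-based and global
    with open(path, "w") as fh:
        fh.write("# neuritemorph OBJ export\n")
        for mesh in meshes:
            fh.write(f"o {mesh.name}\n")
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.9f} {v[1]:.9f} {v[2]:.9f}\n")
            for f in mesh.faces:
                fh.write(f"f {f[0] + offset} {f[1] + offset} {f[2] + offset}\n")
            for e in mesh.edges:
                fh.write(f"l {e[0] + offset} {e[1] + offset}\n")
            offset += mesh.n_vertices


# ---------------------------------------------------------------------------
# Elementary geometry


def face_areas(mesh: SurfaceMesh) -> np.ndarray:
    """Areas of all faces (µm²), half the cross-product magnitude each."""
    v = mesh.vertices
    f = mesh.faces
    if not len(f):
        return np.empty(0)
    cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
    return 0.5 * np.linalg.norm(cross, axis=1)


def face_area(mesh: SurfaceMesh, face_index: int) -> float:
    """Area of one face in µm²."""
    f = mesh.faces[face_index]
    a, b, c = mesh.vertices[f]
    return 0.5 * float(np.linalg.norm(np.cross(b - a, c - a)))


def face_centroids(mesh: SurfaceMesh) -> np.ndarray:
    return mesh.vertices[mesh.faces].mean(axis=1)


def face_centroid(mesh: SurfaceMesh, face_index: int) -> np.ndarray:
    return mesh.vertices[mesh.faces[face_index]].mean(axis=0)


def object_centroid(mesh: SurfaceMesh) -> np.ndarray:
    """Unweighted mean of the boundary-surface vertices."""
    if not len(mesh.vertices):
        raise ValueError("empty mesh has no centroid")
    return mesh.vertices.mean(axis=0)


def unique_edges(mesh: SurfaceMesh, return_counts: bool = False):
    """Undirected unique edges implied by the faces (plus explicit edges).

    With ``return_counts`` also returns how many faces share each edge
    (explicit polyline edges contribute zero face incidence).
    """
    if len(mesh.faces):
        e = mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2)
    else:
        e = np.empty((0, 2), dtype=np.int64)
    face_edge_count = len(e)
    if len(mesh.edges):
        e = np.vstack([e, mesh.edges])
    if not len(e):
        empty = np.empty((0, 2), dtype=np.int64)
        return (empty, np.empty(0, dtype=np.int64)) if return_counts else empty
    e = np.sort(e, axis=1)
    uniq, inverse = np.unique(e, axis=0, return_inverse=True)
    if not return_counts:
        return uniq
    counts = np.bincount(inverse[:face_edge_count], minlength=len(uniq))
    return uniq, counts


def is_watertight(mesh: SurfaceMesh) -> bool:
    """True when every face edge is shared by exactly two faces."""
    if not len(mesh.faces):
        return False
    _, counts = unique_edges(mesh, return_counts=True)
    return bool(np.all(counts == 2))


def boundary_loops(mesh: SurfaceMesh) -> list[np.ndarray]:
    """Ordered vertex loops of the boundary (edges with exactly one face).

    Raises ``ValueError`` when the boundary is non-manifold (some vertex on
    more than two boundary edges), which centroid-fan capping cannot handle.
    """
    uniq, counts = unique_edges(mesh, return_counts=True)
    bedges = uniq[counts == 1]
    if not len(bedges):
        return []
    # adjacency of boundary vertices
    adj: dict[int, list[int]] = {}
    for a, b in bedges:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    for v, nbrs in adj.items():
        if len(nbrs) != 2:
            raise ValueError(
                f"non-manifold boundary at vertex {v} "
                "(more than two boundary edges); run clean_mesh first"
            )
    loops: list[np.ndarray] = []
    visited: set[int] = set()
    for start in sorted(adj):
        if start in visited:
            continue
        loop = [start]
        visited.add(start)
        prev, cur = None, start
        while True:
            nxt = [n for n in adj[cur] if n != prev]
            nxt = nxt[0] if nxt else adj[cur][0]
            if nxt == start:
                break
            loop.append(nxt)
            visited.add(nxt)
            prev, cur = cur, nxt
        loops.append(np.asarray(loop, dtype=np.int64))
    return loops


def points_inside(mesh: SurfaceMesh, points: np.ndarray) -> np.ndarray:
    """Even-odd ray-cast containment test for a closed mesh.

    Casts a fixed irrational-direction ray from each point and counts
    triangle crossings (Möller–Trumbore, vectorized over faces). Points on
    the surface are classified arbitrarily; intended for strictly
    inside/outside queries on watertight fixtures.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    direction = np.array([0.57735027, 0.29934817, 0.75963771])
    direction /= np.linalg.norm(direction)
    v = mesh.vertices
    f = mesh.faces
    v0, v1, v2 = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    e1 = v1 - v0
    e2 = v2 - v0
    h = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, h)
    ok = np.abs(det) > 1e-14
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    inside = np.zeros(len(points), dtype=bool)
    for i, p in enumerate(points):
        s = p - v0
        u = np.einsum("ij,ij->i", s, h) * inv_det
        q = np.cross(s, e1)
        vv = q @ direction * inv_det
        t = np.einsum("ij,ij->i", q, e2) * inv_det
        hit = ok & (u >= 0) & (vv >= 0) & (u + vv <= 1) & (t > 1e-12)
        inside[i] = bool(np.count_nonzero(hit) % 2)
    return inside


# ---------------------------------------------------------------------------
# Cleaning


def _merge_close_vertices(vertices: np.ndarray, tol: float):
    """Union-find merge of vertices closer than ``tol``; returns (new, remap, n_merged)."""
    n = len(vertices)
    if n == 0 or tol <= 0:
        return vertices.copy(), np.arange(n), 0
    tree = cKDTree(vertices)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    parent = np.arange(n)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a, b in pairs:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(i) for i in range(n)])
    uniq_roots, remap = np.unique(roots, return_inverse=True)
    new_vertices = vertices[uniq_roots]  # representative = lowest-index member
    return new_vertices, remap, n - len(uniq_roots)


def clean_mesh(mesh: SurfaceMesh, merge_tol: float = 1e-5):
    """Remove non-standard geometry; returns ``(cleaned, CleanReport)``.

    Pipeline, iterated where noted: (1) merge duplicate vertices within
    ``merge_tol`` (default 1e-5 µm, below EM voxel size so distinct
    membranes are never welded); (2) drop degenerate faces (repeated vertex
    or zero area); (3) drop duplicate faces (same vertex set); (4) drop
    extra faces on edges shared by more than two faces, keeping the two
    lowest-index faces per offending edge, to a fixpoint; (5) drop
    unreferenced (floating) vertices. The input mesh is not modified. A
    report warning is set when more than half the faces vanish — the sign
    that the mesh needs manual inspection.
    """
    report = CleanReport()
    n_faces_in = mesh.n_faces

    vertices, remap, n_merged = _merge_close_vertices(mesh.vertices, merge_tol)
    report.merged_vertices = n_merged
    faces = remap[mesh.faces] if len(mesh.faces) else mesh.faces.copy()
    edges = remap[mesh.edges] if len(mesh.edges) else mesh.edges.copy()

    if len(faces):
        # degenerate: repeated vertex after merging, or numerically zero area
        repeated = (
            (faces[:, 0] == faces[:, 1])
            | (faces[:, 1] == faces[:, 2])
            | (faces[:, 0] == faces[:, 2])
        )
        cross = np.cross(
            vertices[faces[:, 1]] - vertices[faces[:, 0]],
            vertices[faces[:, 2]] - vertices[faces[:, 0]],
        )
        zero_area = 0.5 * np.linalg.norm(cross, axis=1) <= 1e-12
        bad = repeated | zero_area
        report.degenerate_faces = int(bad.sum())
        faces = faces[~bad]

    if len(faces):
        key = np.sort(faces, axis=1)
        _, first = np.unique(key, axis=0, return_index=True)
        keep = np.zeros(len(faces), dtype=bool)
        keep[first] = True
        report.duplicate_faces = int((~keep).sum())
        faces = faces[keep]

    # non-manifold edge rule to fixpoint: an edge may border at most 2 faces
    while len(faces):
        e = np.sort(faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
        uniq, inverse, counts = np.unique(e, axis=0, return_inverse=True, return_counts=True)
        offending = np.where(counts > 2)[0]
        if not len(offending):
            break
        face_of_edge = np.repeat(np.arange(len(faces)), 3)
        drop = set()
        for ei in offending:
            incident = np.sort(face_of_edge[inverse == ei])
            drop.update(int(fi) for fi in incident[2:])  # keep two lowest-index faces
        keep = np.ones(len(faces), dtype=bool)
        keep[list(drop)] = False
        report.nonmanifold_faces += int((~keep).sum())
        faces = faces[keep]

    # drop unreferenced vertices
    referenced = np.zeros(len(vertices), dtype=bool)
    if len(faces):
        referenced[faces.ravel()] = True
    if len(edges):
        referenced[edges.ravel()] = True
    report.floating_vertices = int((~referenced).sum())
    new_index = np.cumsum(referenced) - 1
    vertices = vertices[referenced]
    faces = new_index[faces] if len(faces) else faces
    edges = new_index[edges] if len(edges) else edges

    if n_faces_in and report.total_removed_faces > 0.5 * n_faces_in:
        report.warning = (
            f"cleaning removed {report.total_removed_faces}/{n_faces_in} faces; "
            "inspect the mesh near the deletion point and repair by hand"
        )
        warnings.warn(report.warning, stacklevel=2)

    cleaned = SurfaceMesh(mesh.name, vertices, faces, edges,
                          provenance=mesh.provenance or "clean_mesh")
    return cleaned, report


def connected_components(mesh: SurfaceMesh) -> list[SurfaceMesh]:
    """Partition the faces into shared-edge connected components.

    Vertices are duplicated into each component as needed; component order
    follows the lowest face index in each component.
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components as cc

    if not len(mesh.faces):
        return []
    e = np.sort(mesh.faces[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uniq, inverse = np.unique(e, axis=0, return_inverse=True)
    face_of_edge = np.repeat(np.arange(len(mesh.faces)), 3)
    # link faces sharing an edge
    rows, cols = [], []
    order = np.argsort(inverse, kind="stable")
    sorted_inv = inverse[order]
    sorted_face = face_of_edge[order]
    starts = np.searchsorted(sorted_inv, np.arange(len(uniq)))
    ends = np.append(starts[1:], len(sorted_inv))
    for s, t in zip(starts, ends):
        group = sorted_face[s:t]
        if len(group) > 1:
            rows.extend(group[:-1])
            cols.extend(group[1:])
    n = len(mesh.faces)
    graph = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = cc(graph, directed=False)
    components: list[SurfaceMesh] = []
    for label in range(n_comp):
        fsel = mesh.faces[labels == label]
        used, local = np.unique(fsel, return_inverse=True)
        components.append(
            SurfaceMesh(
                name=f"{mesh.name}.{len(components):03d}",
                vertices=mesh.vertices[used],
                faces=local.reshape(-1, 3),
                provenance=mesh.provenance,
            )
        )
    return components


def submesh(mesh: SurfaceMesh, face_indices) -> SurfaceMesh:
    """Extract the faces in ``face_indices`` as a standalone mesh."""
    face_indices = np.asarray(sorted(set(int(i) for i in face_indices)), dtype=np.int64)
    if len(face_indices) and (face_indices.min() < 0 or face_indices.max() >= mesh.n_faces):
        raise IndexError("face index out of range")
    fsel = mesh.faces[face_indices]
    if not len(fsel):
        return SurfaceMesh(mesh.name + ".sub", np.empty((0, 3)),
                           provenance=mesh.provenance)
    used, local = np.unique(fsel, return_inverse=True)
    return SurfaceMesh(
        name=mesh.name + ".sub",
        vertices=mesh.vertices[used],
        faces=local.reshape(-1, 3),
        provenance=mesh.provenance,
    )
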