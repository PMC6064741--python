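"""Centerline-anchored axon profiling.

A centerline is a non-branching vertex chain lying inside a tubular mesh.
At every centerline vertex this module builds the perpendicular cross
section of the mesh (a planar polygon with area, centroid and max radius),
projects point objects (vesicle markers) and surface patches (synapses)
onto their nearest centerline vertices, and exports the per-vertex profile
as CSV. Centerlines are imported from an external skeletonizer (OBJ
edges-only or CSV with an optional per-vertex minimum-radius column, which
is passed through, never re-computed) or approximated for simple tubes by
:func:`fallback_centerline`.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh_core import (
    Contour,
    PointSet,
    SurfaceMesh,
    face_areas,
    face_centroids,
    object_centroid,
    points_inside,
    read_obj,
)

log = logging.getLogger(__name__)

__all__ = [
    "Centerline", "CrossSection", "load_centerline", "fallback_centerline",
    "cross_sections", "max_radius", "project_points", "project_faces",
    "export_profile", "read_profile",
]

#: per-vertex spacing below which the guidance "not less than 100 nm" applies
MIN_RECOMMENDED_SPACING = 0.1

PROFILE_COLUMNS = [
    "vertex_index", "x", "y", "z", "arc_length_um", "cross_section_area_um2",
    "min_radius_um", "max_radius_um", "sphere_count", "projected_area_um2",
]


@dataclass
class Centerline:
    """Ordered non-branching vertex chain with per-vertex analysis slots.

    ``arc_length[i]`` is the cumulative Euclidean length from the first
    vertex; consecutive spacings are generally not exactly equal, so the
    exact values are carried and exported. Attribute slots start unset
    (``None``) and are filled by the analysis functions.
    """

    vertices: np.ndarray
    min_radius: np.ndarray | None = None
    cross_section_area: np.ndarray | None = None
    max_radius_attr: np.ndarray | None = None
    sphere_count: np.ndarray | None = None
    projected_area: np.ndarray | None = None
    arc_length: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        if len(self.vertices) < 2:
            raise ValueError("a centerline needs at least 2 vertices")
        seg = np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)
        if np.any(seg <= 0):
            raise ValueError("centerline has coincident consecutive vertices")
        self.arc_length = np.concatenate([[0.0], np.cumsum(seg)])
        if self.min_radius is not None:
            self.min_radius = np.asarray(self.min_radius, dtype=np.float64).ravel()
            if len(self.min_radius) != len(self.vertices):
                raise ValueError("min_radius length must match vertex count")

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def length(self) -> float:
        return float(self.arc_length[-1])

    def spacing(self) -> np.ndarray:
        return np.diff(self.arc_length)

    def tangents(self) -> np.ndarray:
        """Unit tangents: central differences, one-sided at the ends."""
        v = self.vertices
        t = np.empty_like(v)
        t[0] = v[1] - v[0]
        t[-1] = v[-1] - v[-2]
        t[1:-1] = v[2:] - v[:-2]
        return t / np.linalg.norm(t, axis=1, keepdims=True)

    def updated(self, vertices: np.ndarray) -> "Centerline":
        """User-edited geometry: re-derive arc length, clear stale attributes."""
        return Centerline(vertices)

    def validate_inside(self, mesh: SurfaceMesh) -> np.ndarray:
        """Boolean per-vertex containment in a closed mesh."""
        return points_inside(mesh, self.vertices)


@dataclass
class CrossSection:
    """Planar polygonal slice of the mesh at one centerline vertex."""

    owner_vertex: int
    plane_point: np.ndarray
    plane_normal: np.ndarray
    boundary: np.ndarray          # (k, 3) ordered loop points; empty if none
    area: float = 0.0
    truncated: bool = False       # loop hit the intersection-disc limit
    empty: bool = False

    @property
    def centroid(self) -> np.ndarray:
        if not len(self.boundary):
            raise ValueError("empty cross section has no centroid")
        return self.boundary.mean(axis=0)

    @property
    def max_radius(self) -> float:
        return max_radius(self)


def max_radius(cs: CrossSection) -> float:
    """Largest distance from the boundary-vertex centroid to any boundary vertex.

    The centroid is the unweighted mean of the boundary vertices; the
    centerline's own intersection point plays no role. For C-shaped
    sections the centroid may fall outside the polygon — the value is
    still returned.
    """
    if not len(cs.boundary):
        raise ValueError("empty cross section has no max radius")
    return float(np.linalg.norm(cs.boundary - cs.centroid, axis=1).max())


# ---------------------------------------------------------------------------
# Centerline ingestion


def _chain_from_edges(vertices: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Order an edge soup into a single open chain; reject branches/cycles."""
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    degrees = {v: len(n) for v, n in adj.items()}
    if any(d > 2 for d in degrees.values()):
        raise ValueError(
            "branching centerline detected; supply a single non-branching "
            "chain per axon (run branches separately and combine the output)"
        )
    ends = sorted(v for v, d in degrees.items() if d == 1)
    if len(ends) != 2 or len(adj) != len(edges) + 1:
        raise ValueError("centerline edges must form one open chain")
    order = [ends[0]]
    prev = None
    while True:
        nxt = [n for n in adj[order[-1]] if n != prev]
        if not nxt:
            break
        prev = order[-1]
        order.append(nxt[0])
    return vertices[order]


def _resample_chain(points: np.ndarray, values: np.ndarray | None, n: int):
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, s[-1], n)
    out = np.column_stack([np.interp(t, s, points[:, k]) for k in range(3)])
    vout = np.interp(t, s, values) if values is not None else None
    return out, vout


def load_centerline(source, n_vertices: int = 200) -> Centerline:
    """Load and resample a centerline from OBJ, CSV, array or polyline mesh.

    The chain is ordered end to end and arc-length resampled to
    ``n_vertices`` (about 200 in routine use, which is the precision of
    every downstream per-vertex analysis). A CSV may carry a fourth
    ``min_radius`` column from the external skeletonizer; it is linearly
    interpolated alongside the points. Branching input is rejected.
    """
    min_radius = None
    if isinstance(source, Centerline):
        points, min_radius = source.vertices, source.min_radius
    elif isinstance(source, SurfaceMesh):
        if len(source.faces):
            raise ValueError("expected an edges-only polyline object")
        points = _chain_from_edges(source.vertices, source.edges)
    elif isinstance(source, Contour):
        points = source.vertices
    elif isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        path = str(source)
        if path.lower().endswith(".obj"):
            meshes = [m for m in read_obj(path) if len(m.edges)]
            if len(meshes) != 1:
                raise ValueError(f"expected exactly one polyline object in {path}")
            points = _chain_from_edges(meshes[0].vertices, meshes[0].edges)
        else:
            df = pd.read_csv(path, comment="#")
            cols = [c.strip().lower() for c in df.columns]
            df.columns = cols
            points = df[["x", "y", "z"]].to_numpy(float)
            if "min_radius" in cols:
                min_radius = df["min_radius"].to_numpy(float)
    else:
        arr = np.asarray(source, dtype=float)
        if arr.ndim != 2 or arr.shape[1] not in (3, 4):
            raise ValueError("expected an (n, 3) or (n, 4) array of points")
        points = arr[:, :3]
        if arr.shape[1] == 4:
            min_radius = arr[:, 3]
    if n_vertices < 2:
        raise ValueError("n_vertices must be >= 2")
    points, min_radius = _resample_chain(points, min_radius, n_vertices)
    cl = Centerline(points, min_radius=min_radius)
    if np.any(cl.spacing() < MIN_RECOMMENDED_SPACING - 1e-9):
        log.warning(
            "centerline vertex spacing below %.0f nm; consider fewer vertices",
            MIN_RECOMMENDED_SPACING * 1e3,
        )
    return cl


def fallback_centerline(mesh: SurfaceMesh, axis_hint=None, n_slabs: int = 30,
                        n_vertices: int | None = None) -> Centerline:
    """Naive centerline for simple tube-like meshes: smoothed slab centroids.

    Mesh vertices are binned into slabs along the principal axis (or
    ``axis_hint``), each slab's centroid becomes a chain vertex, the chain
    is smoothed by a moving average and each vertex is verified to lie
    inside the mesh (outside vertices are pulled toward their inside
    neighbors). No per-vertex minimum radius is produced — that is
    skeletonizer output, passed through, never re-computed here. Intended
    only for gently curved tubes; anything else should go through a proper
    skeletonization tool.
    """
    v = mesh.vertices
    centered = v - v.mean(axis=0)
    if axis_hint is not None:
        axis = np.asarray(axis_hint, dtype=float)
        axis /= np.linalg.norm(axis)
    else:
        _, svals, vt = np.linalg.svd(centered, full_matrices=False)
        if svals[0] < 1.5 * svals[1]:
            raise ValueError(
                "mesh is not elongated enough for the naive centerline; "
                "use an external skeletonizer"
            )
        axis = vt[0]
    proj = centered @ axis
    edges = np.linspace(proj.min(), proj.max(), n_slabs + 1)
    chain = []
    for k in range(n_slabs):
        hi = edges[k + 1] + (1e-12 if k == n_slabs - 1 else 0.0)
        sel = (proj >= edges[k]) & (proj < hi)
        if not np.any(sel):
            raise ValueError(
                "empty slab encountered; mesh is not tube-like along this axis "
                "— use an external skeletonizer"
            )
        chain.append(v[sel].mean(axis=0))
    chain = np.asarray(chain)
    # moving-average smoothing, endpoints kept
    smoothed = chain.copy()
    smoothed[1:-1] = (chain[:-2] + chain[1:-1] + chain[2:]) / 3.0
    chain = smoothed

    inside = points_inside(mesh, chain)
    for _ in range(8):
        if inside.all():
            break
        for i in np.where(~inside)[0]:
            nbrs = [j for j in (i - 1, i + 1) if 0 <= j < len(chain) and inside[j]]
            if nbrs:
                chain[i] = (chain[i] + chain[nbrs[0]]) / 2.0
        inside = points_inside(mesh, chain)
    if not inside.all():
        warnings.warn("some naive-centerline vertices remain outside the mesh",
                      stacklevel=2)
    if n_vertices is not None:
        chain, _ = _resample_chain(chain, None, n_vertices)
    return Centerline(chain)


# ---------------------------------------------------------------------------
# Cross sections


def _plane_basis(normal: np.ndarray):
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    w = np.cross(normal, u)
    return u, w


def _polygon_area_2d(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _point_in_polygon(xy: np.ndarray, p: np.ndarray) -> bool:
    x, y = xy[:, 0] - p[0], xy[:, 1] - p[1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    crosses = ((y <= 0) != (y2 <= 0)) & ((x - y * (x2 - x) / np.where(y2 - y == 0, 1e-300, y2 - y)) > 0)
    return bool(np.count_nonzero(crosses) % 2)


def _slice_loops(mesh: SurfaceMesh, point: np.ndarray, normal: np.ndarray,
                 radius: float):
    """Intersection polylines of the mesh with a plane, within ``radius``.

    Only faces with a vertex inside the intersection disc (with one
    edge-length margin) are considered — this is what the plane-diameter
    parameter limits. Returns ``(loops, any_open)`` where each loop is an
    ordered (k, 3) array; chains that failed to close because they left
    the disc are returned open and flagged.
    """
    v = mesh.vertices
    f = mesh.faces
    d = (v - point) @ normal
    d = np.where(d == 0.0, 1e-12, d)  # nudge on-plane vertices off the plane

    vertex_near = np.linalg.norm(v - point, axis=1) <= radius * 1.15
    crossing = np.where(
        (np.sign(d[f]).max(axis=1) > 0) & (np.sign(d[f]).min(axis=1) < 0)
        & vertex_near[f].any(axis=1)
    )[0]
    if not len(crossing):
        return [], False

    # each crossing face yields a segment between two crossed edges
    seg_pts: dict[tuple[int, int], np.ndarray] = {}
    adjacency: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for fi in crossing:
        a, b, c = f[fi]
        keys = []
        for p0, p1 in ((a, b), (b, c), (c, a)):
            if d[p0] * d[p1] < 0:
                key = (p0, p1) if p0 < p1 else (p1, p0)
                if key not in seg_pts:
                    t = d[p0] / (d[p0] - d[p1])
                    seg_pts[key] = v[p0] + t * (v[p1] - v[p0])
                keys.append(key)
        if len(keys) == 2:
            adjacency.setdefault(keys[0], []).append(keys[1])
            adjacency.setdefault(keys[1], []).append(keys[0])

    def walk(start, visited):
        chain = [start]
        visited.add(start)
        prev = None
        cur = start
        while True:
            nxt = [k for k in adjacency[cur] if k != prev and k not in visited]
            if not nxt:
                back = [k for k in adjacency[cur] if k == start and prev != start]
                return chain, bool(back) and len(chain) > 2
            prev, cur = cur, nxt[0]
            chain.append(cur)
            visited.add(cur)

    loops: list[np.ndarray] = []
    any_open = False
    visited: set[tuple[int, int]] = set()
    endpoints = sorted(k for k, n in adjacency.items() if len(n) == 1)
    for start in endpoints:  # open chains: truncated by the disc
        if start in visited:
            continue
        chain, _ = walk(start, visited)
        any_open = True
        loops.append(np.asarray([seg_pts[k] for k in chain]))
    for start in sorted(adjacency):  # remaining nodes lie on closed loops
        if start in visited:
            continue
        chain, _ = walk(start, visited)
        loops.append(np.asarray([seg_pts[k] for k in chain]))
    return loops, any_open


def cross_sections(mesh: SurfaceMesh, cl: Centerline,
                   plane_diameter: float | None = None) -> list[CrossSection]:
    """Perpendicular cross sections of the mesh at every centerline vertex.

    The cutting plane at vertex *i* is normal to the local tangent
    (central differences; one-sided at the ends) and limited to a disc of
    ``plane_diameter`` — by default three times the largest transverse
    extent of the mesh, which never truncates a section but can be lowered
    for speed on very wide meshes. When the plane meets the mesh in
    several loops (U- or S-shaped axons), the loop containing the owner
    vertex is kept, falling back to the nearest loop. Sections in
    high-curvature bends may intersect each other; each polygon's area is
    nevertheless correct for its own plane.

    Also fills ``cl.cross_section_area`` and ``cl.max_radius_attr``.
    """
    if plane_diameter is None:
        span = cl.vertices[-1] - cl.vertices[0]
        norm = np.linalg.norm(span)
        axis = span / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        rel = mesh.vertices - mesh.vertices.mean(axis=0)
        transverse = rel - np.outer(rel @ axis, axis)
        extent = np.ptp(transverse, axis=0).max() if len(rel) else 1.0
        plane_diameter = 3.0 * float(extent)
    radius = plane_diameter / 2.0

    tangents = cl.tangents()
    sections: list[CrossSection] = []
    areas = np.zeros(len(cl))
    radii = np.full(len(cl), np.nan)
    for i in range(len(cl)):
        p, n = cl.vertices[i], tangents[i]
        loops, any_open = _slice_loops(mesh, p, n, radius)
        if not loops and i in (0, len(cl) - 1):
            # an end vertex can sit exactly on the end-cap plane of the mesh;
            # nudge the plane a hair inward along the chain
            step = cl.spacing()[0 if i == 0 else -1]
            inward = 1.0 if i == 0 else -1.0
            p = p + inward * 1e-3 * step * tangents[i]
            loops, any_open = _slice_loops(mesh, p, n, radius)
        if any_open:
            warnings.warn(
                f"cross section {i}: intersection truncated by the plane "
                f"diameter ({plane_diameter:g} µm); increase it for a full loop",
                stacklevel=2,
            )
        if not loops:
            warnings.warn(
                f"cross section {i}: no intersection loop found "
                "(is the vertex outside the mesh?)", stacklevel=2,
            )
            sections.append(CrossSection(i, p, n, np.empty((0, 3)), 0.0, empty=True))
            continue
        u, w = _plane_basis(n)
        chosen = None
        for loop in loops:
            xy = np.column_stack([(loop - p) @ u, (loop - p) @ w])
            if _point_in_polygon(xy, np.zeros(2)):
                chosen = loop
                break
        if chosen is None:  # fallback: nearest loop to the owner vertex
            chosen = min(loops, key=lambda L: np.linalg.norm(L - p, axis=1).min())
        xy = np.column_stack([(chosen - p) @ u, (chosen - p) @ w])
        area = _polygon_area_2d(xy)
        cs = CrossSection(i, p, n, chosen, area, truncated=any_open)
        sections.append(cs)
        areas[i] = area
        radii[i] = cs.max_radius if len(chosen) else np.nan
    cl.cross_section_area = areas
    cl.max_radius_attr = radii
    return sections


# ---------------------------------------------------------------------------
# Projections


def _centroids_of(objs) -> np.ndarray:
    if isinstance(objs, PointSet):
        return objs.points
    if isinstance(objs, SurfaceMesh):
        objs = [objs]
    return np.asarray([object_centroid(m) for m in objs]).reshape(-1, 3)


def project_points(cl: Centerline, objs) -> np.ndarray:
    """Count of objects whose centroid projects to each centerline vertex.

    Objects are reduced to their vertex centroids (irregular shapes are
    accepted; whether the centroid represents them is the user's call).
    Each centroid goes to its arg-min-distance vertex; exact ties go to
    the lowest vertex index. Fills ``cl.sphere_count``.
    """
    centroids = _centroids_of(objs)
    counts = np.zeros(len(cl), dtype=np.int64)
    if len(centroids):
        d = np.linalg.norm(centroids[:, None, :] - cl.vertices[None, :, :], axis=2)
        nearest = d.argmin(axis=1)  # argmin returns the lowest index on ties
        np.add.at(counts, nearest, 1)
    cl.sphere_count = counts
    return counts


def project_faces(cl: Centerline, surf) -> np.ndarray:
    """Sum of face areas projecting to each centerline vertex (µm²).

    Surfaces need not be contiguous. Every face's centroid is assigned to
    its nearest centerline vertex and the face's area is added there, so
    the per-vertex sums conserve the total input area. Fills
    ``cl.projected_area``.
    """
    meshes = [surf] if isinstance(surf, SurfaceMesh) else list(surf)
    sums = np.zeros(len(cl))
    for m in meshes:
        if not len(m.faces):
            continue
        fc = face_centroids(m)
        fa = face_areas(m)
        d = np.linalg.norm(fc[:, None, :] - cl.vertices[None, :, :], axis=2)
        nearest = d.argmin(axis=1)
        np.add.at(sums, nearest, fa)
    cl.projected_area = sums
    return sums


# ---------------------------------------------------------------------------
# Export


def export_profile(cl: Centerline, path) -> pd.DataFrame:
    """Write the per-vertex profile CSV; returns the frame written.

    One row per centerline vertex: index, coordinates, length along the
    centerline (measured from the first vertex of the stored chain, as
    noted in the header), cross-section area, minimum radius (passthrough),
    maximum radius, projected sphere count and projected area sum.
    Attributes never computed are emitted as empty columns.
    """
    def col(values):
        if values is None:
            return [""] * len(cl)
        return ["" if (isinstance(x, float) and np.isnan(x)) else x for x in values]

    df = pd.DataFrame({
        "vertex_index": np.arange(len(cl)),
        "x": cl.vertices[:, 0],
        "y": cl.vertices[:, 1],
        "z": cl.vertices[:, 2],
        "arc_length_um": cl.arc_length,
        "cross_section_area_um2": col(cl.cross_section_area),
        "min_radius_um": col(cl.min_radius),
        "max_radius_um": col(cl.max_radius_attr),
        "sphere_count": col(cl.sphere_count),
        "projected_area_um2": col(cl.projected_area),
    })
    buf = io.StringIO()
    buf.write("# arc_length_um is measured from the first vertex of the chain\n")
    df.to_csv(buf, index=False, float_format="%.9f")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
    return df


def read_profile(path) -> pd.DataFrame:
    """Read back a profile CSV written by :func:`export_profile`."""
    return pd.read_csv(path, comment="#")
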