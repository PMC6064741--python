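"""Batch construction tools: marker spheres, surface stitching from stacked
contours (holes preserved), and closed tubes with end caps.

The stitcher fits a linear surface through each adjacent pair of contour
planes and welds the shared contour rows so the result is one continuous
surface. When a plane holds several contours (a perforated surface), each
contour is matched to its nearest neighbors on the adjacent plane and
stitched per match, which leaves the annotated hole open.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .mesh_core import Contour, SurfaceMesh

log = logging.getLogger(__name__)

__all__ = [
    "SphereSpec", "ContourStack", "OrientationDecision", "place_sphere",
    "make_icosphere", "resample_contour", "correspond_endpoints",
    "stitch_surface", "stitch_tube",
]


@dataclass
class SphereSpec:
    """An icosphere marker: center (µm), radius (µm), subdivision level ≥ 0."""

    center: tuple = (0.0, 0.0, 0.0)
    radius: float = 0.02
    subdivisions: int = 2

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")
        if self.subdivisions < 0:
            raise ValueError("subdivisions must be >= 0")


@dataclass
class ContourStack:
    """Contours ordered by plane position; ``closed`` applies to all of them."""

    contours: list = field(default_factory=list)
    closed: bool = False

    def __post_init__(self) -> None:
        self.contours = sorted(self.contours, key=lambda c: c.plane_key)
        for c in self.contours:
            if c.closed != self.closed:
                raise ValueError("all contours in a stack must share the closed flag")

    def planes(self) -> list[float]:
        keys: list[float] = []
        for c in self.contours:
            if not keys or abs(c.plane_key - keys[-1]) > 1e-9:
                keys.append(c.plane_key)
        return keys

    def on_plane(self, key: float) -> list[Contour]:
        return [c for c in self.contours if abs(c.plane_key - key) <= 1e-9]


# ---------------------------------------------------------------------------
# Icosphere


def make_icosphere(center=(0.0, 0.0, 0.0), radius: float = 1.0,
                   subdivisions: int = 2, name: str = "sphere") -> SurfaceMesh:
    """Icosphere with ``10 * 4**s + 2`` vertices, watertight, deterministic."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts[0])
    faces = np.array([
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ], dtype=np.int64)

    for _ in range(subdivisions):
        vlist = list(verts)
        cache: dict[tuple[int, int], int] = {}

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in cache:
                m = vlist[a] + vlist[b]
                m /= np.linalg.norm(m)
                cache[key] = len(vlist)
                vlist.append(m)
            return cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces.extend([[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]])
        verts = np.asarray(vlist)
        faces = np.asarray(new_faces, dtype=np.int64)

    return SurfaceMesh(
        name=name,
        vertices=verts * radius + np.asarray(center, dtype=float),
        faces=faces,
        provenance="icosphere",
    )


def place_sphere(spec: SphereSpec, name: str = "sphere") -> SurfaceMesh:
    """Create a watertight icosphere marker from a :class:`SphereSpec`."""
    return make_icosphere(spec.center, spec.radius, spec.subdivisions, name=name)


# ---------------------------------------------------------------------------
# Contour resampling and correspondence


def resample_contour(contour: Contour, n: int) -> np.ndarray:
    """Uniform arc-length resampling to ``n`` points.

    Open contours keep both endpoints; closed contours yield ``n`` points
    around the cycle starting at the first vertex (no duplicate endpoint).
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    pts = contour.vertices
    if contour.closed:
        pts = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        return np.repeat(pts[:1], n, axis=0)
    if contour.closed:
        t = np.linspace(0.0, total, n, endpoint=False)
    else:
        t = np.linspace(0.0, total, n)
    x = np.column_stack([np.interp(t, s, pts[:, k]) for k in range(3)])
    return x


@dataclass
class OrientationDecision:
    """Result of endpoint correspondence between two contours."""

    flip: bool
    offset: int = 0
    cost: float = 0.0
    ambiguous: bool = False


def correspond_endpoints(c1, c2, n: int = 32) -> OrientationDecision:
    """Decide how ``c2`` should be traversed to correspond with ``c1``.

    Open curves: the orientation minimizing the summed distance between
    matched endpoint pairs. Closed curves: the cyclic offset and direction
    minimizing the total correspondence cost after arc-length resampling.
    A near-tie is flagged ambiguous and logged (near-perpendicular adjacent
    curves risk a self-intersecting surface; add intermediate contours).

    Accepts :class:`Contour` objects or pre-resampled ``(n, 3)`` arrays
    (arrays are treated per the ``closed`` flag of neither — both open).
    """
    closed = isinstance(c1, Contour) and c1.closed
    if isinstance(c1, Contour) and isinstance(c2, Contour) and c1.closed != c2.closed:
        raise ValueError("contours must be both open or both closed")
    p1 = resample_contour(c1, n) if isinstance(c1, Contour) else np.asarray(c1)
    p2 = resample_contour(c2, n) if isinstance(c2, Contour) else np.asarray(c2)

    if not closed:
        keep = np.linalg.norm(p1[0] - p2[0]) + np.linalg.norm(p1[-1] - p2[-1])
        flip = np.linalg.norm(p1[0] - p2[-1]) + np.linalg.norm(p1[-1] - p2[0])
        decision = OrientationDecision(flip=bool(flip < keep), cost=float(min(keep, flip)))
        hi, lo = max(keep, flip), min(keep, flip)
        if hi > 0 and lo / hi > 0.9:
            decision.ambiguous = True
            log.warning(
                "ambiguous endpoint correspondence (cost ratio %.2f); "
                "surface may self-intersect — add intermediate contours", lo / hi,
            )
        return decision

    m = min(len(p1), len(p2))
    q1 = p1[np.linspace(0, len(p1) - 1, m).round().astype(int)]
    q2 = p2[np.linspace(0, len(p2) - 1, m).round().astype(int)]
    best = None
    costs = []
    for direction in (1, -1):
        r2 = q2 if direction == 1 else q2[::-1]
        for k in range(m):
            cost = float(np.linalg.norm(q1 - np.roll(r2, -k, axis=0), axis=1).sum())
            costs.append(cost)
            if best is None or cost < best[0] - 1e-12:
                best = (cost, direction == -1, k)
    cost, flip, k = best
    costs = sorted(costs)
    ambiguous = len(costs) > 1 and costs[0] > 0 and costs[1] / max(costs[0], 1e-30) < 1.02
    return OrientationDecision(flip=flip, offset=k, cost=cost, ambiguous=ambiguous)


# ---------------------------------------------------------------------------
# Stitching


def _quad_strip(rowA: np.ndarray, rowB: np.ndarray, verts: np.ndarray,
                closed: bool) -> list[tuple[int, int, int]]:
    """Triangles joining two equal-length index rows, shorter diagonal per quad."""
    n = len(rowA)
    faces: list[tuple[int, int, int]] = []
    last = n if closed else n - 1
    for i in range(last):
        j = (i + 1) % n
        a0, a1 = int(rowA[i]), int(rowA[j])
        b0, b1 = int(rowB[i]), int(rowB[j])
        d1 = np.linalg.norm(verts[a0] - verts[b1])
        d2 = np.linalg.norm(verts[a1] - verts[b0])
        if d1 <= d2:  # deterministic tie-break: first diagonal
            faces.append((a0, a1, b1))
            faces.append((a0, b1, b0))
        else:
            faces.append((a0, a1, b0))
            faces.append((a1, b1, b0))
    return faces


def _march_strip(rowA: np.ndarray, rowB: np.ndarray, verts: np.ndarray) -> list:
    """Zigzag triangulation between two open rows of unequal length.

    Advances along both rows by arc-length fraction, emitting one triangle
    per step; used when a contour is stitched against part of a longer one.
    """
    def fractions(row):
        p = verts[row]
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        return s / s[-1] if s[-1] > 0 else np.linspace(0, 1, len(row))

    fa, fb = fractions(rowA), fractions(rowB)
    faces = []
    i = j = 0
    while i < len(rowA) - 1 or j < len(rowB) - 1:
        advance_a = j >= len(rowB) - 1 or (
            i < len(rowA) - 1 and fa[i + 1] <= fb[j + 1]
        )
        if advance_a:
            faces.append((int(rowA[i]), int(rowA[i + 1]), int(rowB[j])))
            i += 1
        else:
            faces.append((int(rowA[i]), int(rowB[j + 1]), int(rowB[j])))
            j += 1
    return faces


def _oriented_open_row(ra: np.ndarray, rb: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Flip ``rb`` if that lowers the summed endpoint-pair distance to ``ra``."""
    pa, pb = vertices[ra], vertices[rb]
    keep = np.linalg.norm(pa[0] - pb[0]) + np.linalg.norm(pa[-1] - pb[-1])
    flip = np.linalg.norm(pa[0] - pb[-1]) + np.linalg.norm(pa[-1] - pb[0])
    return rb[::-1] if flip < keep else rb


def _composite_row(single: np.ndarray, parts: list[np.ndarray],
                   vertices: np.ndarray) -> np.ndarray:
    """Concatenate several partner rows into one row ordered along ``single``.

    Each part is oriented so its own parameter increases along the single
    row's parameter, then the blocks are ordered by where they project onto
    the single row. Used when one contour faces several on the next plane:
    marching against the composite row bridges the gaps, so a perforation
    stays an interior hole instead of splitting the sheet.
    """
    sp = vertices[single]
    blocks = []
    for part in parts:
        pp = vertices[part]
        # parameter on the single row of each part sample's nearest neighbor
        d = np.linalg.norm(pp[:, None, :] - sp[None, :, :], axis=2)
        nearest = d.argmin(axis=1)
        if len(nearest) > 1 and nearest[0] > nearest[-1]:
            part = part[::-1]
            nearest = nearest[::-1]
        blocks.append((float(nearest.mean()), part))
    blocks.sort(key=lambda t: t[0])
    return np.concatenate([b for _, b in blocks])


def stitch_surface(stack: ContourStack, samples_per_contour: int = 32,
                   name: str = "surface") -> SurfaceMesh:
    """Fit a triangle surface through each adjacent pair of contour planes.

    Every contour is arc-length resampled once to ``samples_per_contour``
    points; those canonical rows are shared by the strips above and below
    a contour, welding the segments into a single continuous surface.
    Where a plane holds several contours (a perforation), contours are
    matched to their nearest counterparts on the adjacent plane by centroid
    distance; a lone contour facing several partners is stitched against
    their concatenation, which leaves the annotated hole open in the
    interior of the sheet.
    """
    contours = stack.contours
    if len(contours) < 2:
        raise ValueError("need at least 2 contours to stitch")
    planes = stack.planes()
    if len(planes) < 2:
        raise ValueError("need contours on at least 2 distinct planes")

    rows: list[np.ndarray] = []     # canonical resampled points per contour
    row_idx: list[np.ndarray] = []  # global vertex indices per contour row
    offset = 0
    for c in contours:
        pts = resample_contour(c, samples_per_contour)
        rows.append(pts)
        row_idx.append(np.arange(offset, offset + len(pts)))
        offset += len(pts)
    vertices = np.vstack(rows)
    centroids = {i: rows[i].mean(axis=0) for i in range(len(contours))}

    by_plane: dict[float, list[int]] = {}
    for i, c in enumerate(contours):
        key = min(planes, key=lambda p: abs(p - c.plane_key))
        by_plane.setdefault(key, []).append(i)

    matched: set[int] = set()
    faces: list[tuple[int, int, int]] = []
    for pa, pb in zip(planes[:-1], planes[1:]):
        ga, gb = by_plane[pa], by_plane[pb]
        if len(ga) == len(gb):
            pairs = []
            used: set[int] = set()
            for a in ga:  # greedy nearest-centroid one-to-one matching
                cands = [b for b in gb if b not in used]
                b = min(cands, key=lambda b: np.linalg.norm(centroids[a] - centroids[b]))
                used.add(b)
                pairs.append((a, b))
            for a, b in pairs:
                matched.update((a, b))
                ra, rb = row_idx[a], row_idx[b]
                if stack.closed:
                    dec = correspond_endpoints(contours[a], contours[b],
                                               n=samples_per_contour)
                    order = np.arange(len(rb))
                    if dec.flip:
                        order = order[::-1]
                    order = np.roll(order, -dec.offset)
                    faces.extend(_quad_strip(ra, rb[order], vertices, closed=True))
                else:
                    rb = _oriented_open_row(ra, rb, vertices)
                    faces.extend(_quad_strip(ra, rb, vertices, closed=False))
        else:
            # one-to-many: group the bigger plane's contours by their nearest
            # partner on the smaller plane and stitch composite rows
            small, big = (ga, gb) if len(ga) < len(gb) else (gb, ga)
            groups: dict[int, list[int]] = {s: [] for s in small}
            for b in big:
                s = min(small, key=lambda s: np.linalg.norm(centroids[s] - centroids[b]))
                groups[s].append(b)
            for s, members in groups.items():
                if not members:
                    continue
                matched.add(s)
                matched.update(members)
                rs = row_idx[s]
                if len(members) == 1:
                    rb = _oriented_open_row(rs, row_idx[members[0]], vertices)
                else:
                    rb = _composite_row(rs, [row_idx[m] for m in members], vertices)
                    rb = _oriented_open_row(rs, rb, vertices)
                if len(rs) == len(rb):
                    faces.extend(_quad_strip(rs, rb, vertices, closed=False))
                else:
                    faces.extend(_march_strip(rs, rb, vertices))

    for i, c in enumerate(contours):
        key = min(planes, key=lambda p: abs(p - c.plane_key))
        if i not in matched and key not in (planes[0], planes[-1]):
            warnings.warn(
                f"contour {i} on interior plane {key:g} had no match; skipped",
                stacklevel=2,
            )

    mesh = SurfaceMesh(name=name, vertices=vertices,
                       faces=np.asarray(faces, dtype=np.int64).reshape(-1, 3),
                       provenance="stitch_surface")
    from .mesh_core import clean_mesh
    cleaned, _ = clean_mesh(mesh, merge_tol=1e-9)
    cleaned.name = name
    return cleaned


def stitch_tube(stack: ContourStack, cap_ends: bool = True,
                samples_per_contour: int = 32, name: str = "tube") -> SurfaceMesh:
    """Connect closed contours, one per plane, into a tube; optionally cap.

    Raises when a plane carries more than one closed contour: U-shaped
    objects must be constructed in parts (one cross section per plane each)
    and merged afterwards.
    """
    if not stack.closed:
        raise ValueError("stitch_tube requires closed contours")
    planes = stack.planes()
    for key in planes:
        if len(stack.on_plane(key)) > 1:
            raise ValueError(
                f"plane {key:g} has more than one closed contour; construct the "
                "object in parts with one cross section per plane, then merge"
            )
    mesh = stitch_surface(stack, samples_per_contour, name=name)
    if cap_ends:
        from .measurements import close_holes
        mesh = close_holes(mesh)
        mesh.name = name
    return mesh
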