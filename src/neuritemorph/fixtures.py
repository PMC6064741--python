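"""Deterministic synthetic geometry for tests, demos and benchmarks.

Everything an analysis needs can be generated here with known analytic
ground truth: icosphere markers, bulged tubes of revolution (an idealized
axon with a Gaussian bouton-like swelling and its true centerline and
radius function), contour stacks sliced from analytic shapes, scattered
vesicle points, and parallel plate pairs for contact-area tests. All
generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotate import make_icosphere
from .centerline_analysis import Centerline
from .mesh_core import Contour, PointSet, SurfaceMesh

__all__ = [
    "TubeSpec", "make_icosphere", "make_bulged_tube", "make_contour_stack",
    "scatter_vesicles", "make_plate_pair",
]


@dataclass
class TubeSpec:
    """Surface of revolution: radius r(t) = r0 + h·exp(−(t−t0)²/(2σ²))."""

    length: float = 10.0
    base_radius: float = 0.15
    bulge_height: float = 0.0
    bulge_center: float = 5.0
    bulge_width: float = 0.5
    axial_samples: int = 80
    radial_samples: int = 32
    curve: str = "straight"   # straight | s | u | hairpin
    bend_radius: float = 1.0  # hairpin only: radius of the 180° bend
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_radius <= 0:
            raise ValueError("base_radius must be positive")
        if self.axial_samples < 2 or self.radial_samples < 3:
            raise ValueError("need axial_samples >= 2 and radial_samples >= 3")

    def radius_at(self, t):
        t = np.asarray(t, dtype=float)
        if self.bulge_height == 0:
            return np.broadcast_to(self.base_radius, t.shape).copy()
        return self.base_radius + self.bulge_height * np.exp(
            -((t - self.bulge_center) ** 2) / (2.0 * self.bulge_width ** 2)
        )


def _axis_points(spec: TubeSpec, t: np.ndarray) -> np.ndarray:
    if spec.curve == "straight":
        return np.column_stack([np.zeros_like(t), np.zeros_like(t), t])
    if spec.curve == "s":
        # gentle lateral sine sweep, arc-length approximately preserved
        amp = spec.length / 12.0
        x = amp * np.sin(2.0 * np.pi * t / spec.length)
        return np.column_stack([x, np.zeros_like(t), t])
    if spec.curve == "u":
        # semicircular axis in the x-z plane
        R = spec.length / np.pi
        theta = t / R
        return np.column_stack([R * (1 - np.cos(theta)), np.zeros_like(t),
                                R * np.sin(theta)])
    if spec.curve == "hairpin":
        # two parallel straight arms joined by a 180° bend: a plane
        # perpendicular to one arm slices both of them
        Rb = spec.bend_radius
        arm = (spec.length - np.pi * Rb) / 2.0
        if arm <= 0:
            raise ValueError("hairpin needs length > pi * bend_radius")
        pts = np.empty((len(t), 3))
        for i, ti in enumerate(t):
            if ti <= arm:
                pts[i] = (0.0, 0.0, ti)
            elif ti <= arm + np.pi * Rb:
                phi = (ti - arm) / Rb
                pts[i] = (Rb * (1 - np.cos(phi)), 0.0, arm + Rb * np.sin(phi))
            else:
                pts[i] = (2 * Rb, 0.0, arm - (ti - arm - np.pi * Rb))
        return pts
    raise ValueError(f"unknown curve kind {spec.curve!r}")


def _curvature_radius(spec: TubeSpec) -> float:
    if spec.curve == "straight":
        return np.inf
    if spec.curve == "u":
        return spec.length / np.pi
    if spec.curve == "hairpin":
        return spec.bend_radius
    amp = spec.length / 12.0
    k = amp * (2 * np.pi / spec.length) ** 2  # max |x''| of the sine sweep
    return 1.0 / k


def make_bulged_tube(spec: TubeSpec, name: str = "tube"):
    """Watertight tube of revolution with ground truth.

    Returns ``(mesh, centerline, radius_fn)`` — the capped surface, the
    true axis as a :class:`Centerline`, and the analytic radius profile.
    Rings are placed with parallel-transported frames so curved axes do
    not twist. Raises when the bulge radius exceeds the axis' radius of
    curvature (the surface would self-intersect on the inner side).
    """
    max_r = float(spec.radius_at(np.linspace(0, spec.length, 512)).max())
    if max_r >= _curvature_radius(spec):
        raise ValueError("profile radius exceeds axis curvature radius; "
                         "the tube would self-intersect")
    t = np.linspace(0.0, spec.length, spec.axial_samples)
    axis = _axis_points(spec, t)
    radii = spec.radius_at(t)

    # parallel-transported orthonormal frames along the axis
    tangents = np.gradient(axis, t, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.empty_like(tangents)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(tangents[0] @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    normals[0] = np.cross(tangents[0], ref)
    normals[0] /= np.linalg.norm(normals[0])
    for i in range(1, len(t)):
        n = normals[i - 1] - (normals[i - 1] @ tangents[i]) * tangents[i]
        normals[i] = n / np.linalg.norm(n)
    binormals = np.cross(tangents, normals)

    phi = np.linspace(0.0, 2.0 * np.pi, spec.radial_samples, endpoint=False)
    rings = (
        axis[:, None, :]
        + radii[:, None, None] * (
            np.cos(phi)[None, :, None] * normals[:, None, :]
            + np.sin(phi)[None, :, None] * binormals[:, None, :]
        )
    )
    m = spec.radial_samples
    vertices = rings.reshape(-1, 3)
    faces = []
    for i in range(spec.axial_samples - 1):
        base, nxt = i * m, (i + 1) * m
        for j in range(m):
            k = (j + 1) % m
            faces.append((base + j, base + k, nxt + k))
            faces.append((base + j, nxt + k, nxt + j))
    # end caps: centroid fans (cap centroids are the axis endpoints)
    vi0, vi1 = len(vertices), len(vertices) + 1
    vertices = np.vstack([vertices, axis[0], axis[-1]])
    last = (spec.axial_samples - 1) * m
    for j in range(m):
        k = (j + 1) % m
        faces.append((k, j, vi0))
        faces.append((last + j, last + k, vi1))
    mesh = SurfaceMesh(name=name, vertices=vertices,
                       faces=np.asarray(faces, dtype=np.int64),
                       provenance="make_bulged_tube")
    centerline = Centerline(axis)
    return mesh, centerline, spec.radius_at


def make_contour_stack(shape: str, planes: int = 5, radius: float = 1.0,
                       height: float = 1.0, width: float = 1.0,
                       gap: tuple = (0.4, 0.6), samples: int = 48):
    """Analytic contour stacks for the stitching tools.

    ``cylinder``: closed circles of constant radius over ``height``.
    ``sphere``: closed circles of radius sqrt(r² − z²) through a ball.
    ``perforated-sheet``: open line contours of length ``width``; interior
    planes carry two segments separated by the ``gap`` fractions, the way a
    perforated synapse is annotated by drawing on either side of the hole.
    """
    from .annotate import ContourStack

    contours = []
    if shape == "cylinder":
        for z in np.linspace(0.0, height, planes):
            phi = np.linspace(0, 2 * np.pi, samples, endpoint=False)
            pts = np.column_stack([radius * np.cos(phi), radius * np.sin(phi),
                                   np.full(samples, z)])
            contours.append(Contour(pts, closed=True, plane_key=float(z)))
        return ContourStack(contours, closed=True)
    if shape == "sphere":
        zs = np.linspace(-radius, radius, planes + 2)[1:-1]
        for z in zs:
            r = float(np.sqrt(radius ** 2 - z ** 2))
            phi = np.linspace(0, 2 * np.pi, samples, endpoint=False)
            pts = np.column_stack([r * np.cos(phi), r * np.sin(phi),
                                   np.full(samples, z)])
            contours.append(Contour(pts, closed=True, plane_key=float(z)))
        return ContourStack(contours, closed=True)
    if shape == "perforated-sheet":
        if planes < 4:
            raise ValueError("perforated sheet needs >= 4 planes")
        g0, g1 = gap[0] * width, gap[1] * width
        for pi, z in enumerate(np.linspace(0.0, height, planes)):
            full_plane = pi in (0, planes - 1)
            if full_plane:
                x = np.linspace(0.0, width, samples)
                pts = np.column_stack([x, np.zeros(samples), np.full(samples, z)])
                contours.append(Contour(pts, closed=False, plane_key=float(z)))
            else:
                for x0, x1 in ((0.0, g0), (g1, width)):
                    x = np.linspace(x0, x1, max(4, samples // 2))
                    pts = np.column_stack([x, np.zeros_like(x), np.full_like(x, z)])
                    contours.append(Contour(pts, closed=False, plane_key=float(z)))
        return ContourStack(contours, closed=False)
    raise ValueError(f"unknown contour stack shape {shape!r}")


def scatter_vesicles(region, n: int, seed: int = 0,
                     radius: float | None = None) -> PointSet:
    """Reproducible uniform points inside a region.

    ``region`` is an axis-aligned box ``(xmin, ymin, zmin, xmax, ymax,
    zmax)`` or ``("tube", length, radius)`` for the interior of a straight
    z-aligned tube. Streams are isolated per call via the seed.
    """
    rng = np.random.default_rng(seed)
    if n < 0:
        raise ValueError("n must be >= 0")
    if isinstance(region, tuple) and len(region) == 3 and region[0] == "tube":
        _, length, r = region
        z = rng.uniform(0.0, length, n)
        rho = r * np.sqrt(rng.uniform(0.0, 1.0, n))
        phi = rng.uniform(0.0, 2 * np.pi, n)
        pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    else:
        lo = np.asarray(region[:3], dtype=float)
        hi = np.asarray(region[3:], dtype=float)
        pts = rng.uniform(lo, hi, size=(n, 3))
    radii = np.full(n, radius) if radius is not None else None
    return PointSet(pts.reshape(-1, 3), radii=radii)


def make_plate_pair(side: float = 1.0, gap: float = 0.03, grid: int = 21):
    """Two parallel triangulated square plates separated by ``gap`` in z."""
    if grid < 2:
        raise ValueError("grid must be >= 2")

    def plate(z: float, name: str) -> SurfaceMesh:
        lin = np.linspace(0.0, side, grid)
        xx, yy = np.meshgrid(lin, lin, indexing="ij")
        verts = np.column_stack([xx.ravel(), yy.ravel(), np.full(grid * grid, z)])
        faces = []
        for i in range(grid - 1):
            for j in range(grid - 1):
                a = i * grid + j
                b = a + 1
                c = a + grid
                d = c + 1
                faces.append((a, b, d))
                faces.append((a, d, c))
        return SurfaceMesh(name, verts, np.asarray(faces, dtype=np.int64),
                           provenance="make_plate_pair")

    return plate(0.0, "plate1"), plate(gap, "plate2")
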