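"""Bouton detection along an axon centerline.

Boutons — presynaptic swellings of the axon — show up as local surges of
cross-sectional area and radius. Three marker criteria, evaluated at every
centerline vertex (direction = increasing vertex index), flag candidate
bouton boundaries:

* green: some vertex within the next D µm of arc length has cross-section
  area at least A times larger (area increasing);
* red:   some vertex within the next D µm has area at least A times
  smaller (area decreasing);
* blue:  the cross section's max radius exceeds M µm.

Defaults A=2.0, D=0.2 µm, M=0.2 µm. Markers flag where a condition
*starts*; consecutive marks each hold independently and do not delimit the
whole region. Pairing two markers into an actual bouton stays a user
decision; :func:`extract_bouton` then cuts the axon between the two chosen
vertices and returns a closed object with its volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .centerline_analysis import Centerline
from .measurements import close_holes, volume
from .mesh_core import SurfaceMesh, connected_components, face_centroids, submesh

__all__ = ["BoutonParams", "MarkerSet", "detect_markers", "extract_bouton"]


@dataclass
class BoutonParams:
    """Geometric bouton criteria: area ratio A, arc window D (µm), radius M (µm)."""

    A: float = 2.0
    D: float = 0.2
    M: float = 0.2

    def __post_init__(self) -> None:
        if self.A <= 1:
            raise ValueError("area-change ratio A must be > 1")
        if self.D <= 0 or self.M <= 0:
            raise ValueError("D and M must be positive")


@dataclass
class MarkerSet:
    """Vertex indices marked by each criterion; the sets may overlap."""

    green: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    red: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    blue: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    def as_dict(self) -> dict:
        return {"green": self.green.tolist(), "red": self.red.tolist(),
                "blue": self.blue.tolist()}


def detect_markers(cl: Centerline, params: BoutonParams | None = None) -> MarkerSet:
    """Evaluate the three marker criteria at every centerline vertex.

    Requires ``cl.cross_section_area`` and ``cl.max_radius_attr`` (run
    ``cross_sections`` first). The look-ahead window on arc length is
    ``(0, D]`` — a vertex exactly D away still counts, with a 1e-9 µm slack
    so accumulated rounding in the arc lengths cannot drop it. The scan slides a
    single window pointer along the chain, so it is linear in practice.
    """
    params = params or BoutonParams()
    if cl.cross_section_area is None:
        raise ValueError("cross-section areas missing: run cross_sections first")
    if cl.max_radius_attr is None:
        raise ValueError("max radii missing: run cross_sections first")
    area = np.asarray(cl.cross_section_area, dtype=float)
    radius = np.asarray(cl.max_radius_attr, dtype=float)
    s = cl.arc_length
    n = len(cl)

    green, red = [], []
    hi = 0
    for i in range(n):
        if hi < i + 1:
            hi = i + 1
        while hi < n and s[hi] - s[i] <= params.D + 1e-9:
            hi += 1
        window = area[i + 1:hi]  # strictly ahead, within (0, D] of arc length
        if len(window):
            if np.nanmax(window) >= params.A * area[i]:
                green.append(i)
            if np.nanmin(window) <= area[i] / params.A:
                red.append(i)
    blue = np.where(np.nan_to_num(radius, nan=-np.inf) > params.M)[0]
    return MarkerSet(
        green=np.asarray(green, dtype=np.int64),
        red=np.asarray(red, dtype=np.int64),
        blue=np.asarray(blue, dtype=np.int64),
    )


def extract_bouton(mesh: SurfaceMesh, cl: Centerline, v_start: int, v_end: int):
    """Cut the axon between two centerline vertices; returns ``(mesh, µm³)``.

    The surface is cut by the cross-section planes at ``v_start`` and
    ``v_end`` (each plane's normal oriented toward the other vertex).
    Faces are assigned by which side their centroid falls on — no face
    splitting — and the two cut rims are capped, giving a closed bouton
    object whose volume is measured by the divergence theorem.
    """
    if not 0 <= v_start < v_end < len(cl):
        raise ValueError("need 0 <= v_start < v_end < len(centerline)")
    tangents = cl.tangents()
    p1, p2 = cl.vertices[v_start], cl.vertices[v_end]
    n1 = tangents[v_start]   # oriented toward v_end (increasing index)
    n2 = -tangents[v_end]    # oriented toward v_start
    fc = face_centroids(mesh)
    keep = ((fc - p1) @ n1 >= 0) & ((fc - p2) @ n2 >= 0)
    idx = np.where(keep)[0]
    if not len(idx):
        raise ValueError("no faces between the two cut planes")
    cut = submesh(mesh, idx)
    shells = connected_components(cut)
    if len(shells) != 1:
        raise ValueError(
            f"cut produced {len(shells)} shells; choose different marker vertices"
        )
    closed = close_holes(shells[0])
    closed.name = f"{mesh.name}.bouton_{v_start}_{v_end}"
    return closed, volume(closed)
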