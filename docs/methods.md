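# Methods

This note records the geometric procedures, the parameters that matter,
the numerical choices made where the design was genuinely open, and what
the synthetic test geometry does and does not establish about real data.

## Conventions

All coordinates are micrometers in a right-handed frame; I/O never
rescales (a `--scale` flag is available for meshes exported in nm or
voxel units). Faces are triangles internally — polygons are
fan-triangulated on load — and indices are 0-based in memory, 1-based in
OBJ files. Imported face winding is untrusted: any operation that needs
orientation (volume) re-orients faces coherently first and fails
explicitly on non-orientable input rather than guessing.

## Mesh cleaning

`clean_mesh` runs: (1) weld vertices closer than `merge_tol` (union-find
over k-d-tree pairs; the representative is the lowest-index member);
(2) drop degenerate faces (repeated vertex or area ≤ 1e-12 µm²);
(3) drop duplicate faces (same vertex set); (4) for every edge bordered
by more than two faces, keep the two lowest-index faces and drop the
rest, iterated to a fixpoint; (5) drop unreferenced vertices. The order
merge → degenerate → duplicate → non-manifold → floating is a choice:
welding first lets near-duplicate geometry collapse into exactly
removable duplicates, and the floating-vertex sweep last also catches
vertices orphaned by the earlier stages. `merge_tol` defaults to
1e-5 µm, well below EM voxel size, so distinct membranes are never
welded. Removing more than half the faces raises a warning — the signal
that the mesh should be repaired by hand rather than trusted. True
mesh–mesh self-intersection surgery is out of scope; the degenerate- and
non-manifold-face rules approximate it, matching the expectation that
badly broken meshes get manual repair.

## Measurements

The mesh shortest path is a graph geodesic over existing vertices and
edges, not an exact polyhedral geodesic: it can only overestimate the
true surface distance, converging from above as the mesh is refined
(on the subdivision-4 icosphere the antipodal path exceeds the great
circle by a few percent). Volume uses the divergence theorem about the
vertex mean (for exact translation invariance) after `close_holes` caps
every boundary loop with a fan to the loop's vertex centroid. Centroid
fans were chosen over ear-clipping or minimum-area triangulation because
they are deterministic, linear, and exactly reproduce the "fill the hole
with simple faces" repair idiom; they can fold on strongly non-convex
rims, which for volume purposes still closes the region consistently.
Multi-component selections contribute the sum of absolute per-component
volumes.

## Contour stitching

Each contour is uniformly arc-length resampled once
(`samples_per_contour` points) and that canonical row is shared by the
strips above and below it, welding segments into one continuous surface.
Between equal rows, each quad is split along its shorter diagonal
(first diagonal on ties). Open-curve orientation minimizes the summed
endpoint-pair distance; closed-curve correspondence minimizes total
correspondence cost over cyclic offset and direction (the seam choice is
ours — the resampling start point is the contour's first vertex). A
near-tie in either cost is reported as an ambiguity warning: nearly
perpendicular adjacent curves are exactly the case where a
self-intersecting sheet can result, and the remedy is more intermediate
contours, not a cleverer matcher.

When one plane holds several contours (a perforated surface), contours
are matched across planes by centroid distance. A lone contour facing
`k` partners is stitched against their concatenation, ordered and
oriented along the lone row, by a two-pointer march over arc-length
fractions; the bridge triangles this produces across the inter-contour
gaps are what keep a perforation an *interior* hole of the sheet instead
of splitting it into ribbons. Closed tubes require one contour per
plane; U-shaped objects are built in parts and merged, and branching
input is rejected outright.

## Centerline analyses

Centerlines are externally produced skeletons (or hand-drawn chains);
the loader orders an edge soup end-to-end, rejects branches, and
resamples to `n_vertices` (default 200; spacings below 100 nm trigger
advice, since section spacing below the mesh resolution only samples
noise). A per-vertex `min_radius` column is interpolated and passed
through untouched — it is skeletonizer output, never re-computed.
`fallback_centerline` (slab centroids along the principal axis, smoothed,
pulled inside) is a convenience for gently curved tubes only; it refuses
meshes whose principal-axis elongation is below 1.5× and produces no
min-radius data.

Cross-section planes use central-difference tangents (one-sided at the
ends). The plane is limited to a disc whose default diameter is three
times the mesh's largest transverse extent — never truncating, at modest
cost — and can be lowered; loops that leave the disc come back flagged
`truncated` with a warning. The mesh–plane intersection keys crossing
points by mesh edge, which makes loop chaining exact (no coordinate
hashing); vertices lying exactly in the plane are nudged by 1e-12 µm.
Among multiple loops (U/S-shaped axons) the polygon containing the owner
vertex wins, falling back to the nearest loop. Sections at high-curvature
bends may intersect each other; each polygon's area is still correct in
its own plane, and no de-overlap is attempted. An end vertex lying
exactly on an end-cap plane is retried with the plane nudged 1e-3 of one
spacing inward; end sections of strongly curved tubes can still clip the
cap obliquely, so curved-axis analyses should trust interior vertices.

Max radius is measured from the unweighted mean of the boundary vertices
— the centerline's intersection point plays no role — and is reported
even when a C-shaped section puts that centroid outside the polygon.
Projections assign object centroids (sphere counts) and face centroids
(area sums) to their nearest centerline vertex; exact ties go to the
lowest vertex index, and both projections conserve their totals by
construction. The exported CSV orders columns: index, coordinates, arc
length (from the first vertex of the stored chain, stated in the file
header since "from which end" is otherwise ambiguous), cross-section
area, min radius, max radius, sphere count, projected area; attributes
never computed are left empty rather than zero-filled.

## Bouton detection

Direction is increasing vertex index. Green marks vertex `i` when some
`j > i` with `arc[j] − arc[i] ≤ D` has `area[j] ≥ A·area[i]`; red is the
mirrored shrink condition; blue is `max_radius > M`. The window is
inclusive at exactly `D` (with 1e-9 µm slack so accumulated arc-length
rounding cannot drop the boundary vertex) — the alternative exclusive
reading is defensible, but inclusive is fixed and documented here.
Consecutive marks hold independently; they flag where a condition
starts, not the extent of the region. Defaults `A=2.0`, `D=0.2 µm`,
`M=0.2 µm` are the standard working values for cortical boutons.
Pairing markers into an actual bouton stays a user decision.
`extract_bouton` keeps the faces whose centroids lie between the two
cross-section planes (each plane's normal oriented toward the other
vertex), refuses cuts that produce more than one shell, and caps the cut
rims with centroid fans before measuring the volume. Assigning whole
faces by centroid side — no face splitting — biases each cut by at most
half the axial face pitch in either direction; on the test cylinder the
partition-sums-to-total check holds within 2%.

## Proximity

Distances are vertex-to-vertex by design, in both the vesicle-distance
and interacting-regions tools; mesh resolution is therefore the user's
lever, and the remedy for missed thin contacts is subdividing the mesh,
not a different metric. (`point_to_surface` offers an exact
point-to-triangle refinement behind a flag, off by default.) A region's
faces must have *all three* vertices within `T` (an `any_vertex` mode
exists for sensitivity checks); selected vertices that end up in no face
are cleaned away, so a counterpart region can legitimately vanish at
zero area. Components are paired by the nearest-within-`T` counterpart
map taken symmetrically in both directions (the union rule — the
asymmetric cases where only one direction matches are included, which is
the more conservative reading). A component matched by several partners
appears once per pair, so summed pair areas can exceed the true contact
area; the per-object totals count each component once. Sub-regions are
named `<object>.001, .002, ...` in component order.

## Synthetic geometry and what the tests show

All test geometry is generated: icospheres (midpoint subdivision of an
icosahedron, `10·4^s+2` vertices), tubes of revolution with a Gaussian
radius bulge `r(t) = r0 + h·exp(−(t−t0)²/2σ²)` around straight, S-, U-
or hairpin-shaped axes (parallel-transported frames, capped ends,
self-intersection guarded by the axis curvature radius), analytic
contour stacks, uniform vesicle scatters, and parallel plate grids.
Default tube dimensions (radius 0.12–0.3 µm, bulges peaking at 0.3 µm,
lengths ~10 µm, ~200-vertex centerlines, vesicle radius 0.02 µm,
`T = 50 nm`) are chosen to match the scale of cortical axons and their
boutons in EM reconstructions. Generators are deterministic given their
seed, and every emitted mesh passes `clean_mesh` with zero removals.

These fixtures have exact ground truth, which is what the suite
exercises: agreement with closed-form areas/volumes at the 0.5–3% level
expected from polygonization, exact conservation laws, exact equality
with brute-force oracles (marker definitions, k-d-tree selections), and
byte-identical re-runs. What they do not show: robustness to the noise,
topological defects and anisotropic resolution of real segmentation
meshes (the cleaner addresses the common defect classes, but badly
broken meshes still need manual repair), accuracy of cross-sections when
the supplied centerline is poor, or the behavior of vertex-based
proximity on meshes much coarser than `T`. Problem sizes in the tests
(≤ 10⁴ faces, ≤ 200 centerline vertices) are the package's routine
working scale; all algorithms are near-linear or `n log n` in mesh size
except the O(faces) per-vertex slicing of `cross_sections`, whose cost
the plane-diameter parameter bounds.

## Known limitations

- Non-branching centerlines only; branches are run separately and the
  outputs combined downstream.
- Graph geodesics, not exact polyhedral geodesics.
- `fallback_centerline` is not a skeletonizer; use one for anything but
  gently curved tubes.
- Cut-plane face assignment does not split straddling faces.
- Stitching assumes adjacent contours are roughly parallel; nearly
  perpendicular neighbors are flagged, not repaired.
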