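# neuritemorph

Quantitative 3D morphometry for mesh reconstructions of neurites, as
produced by serial-section electron microscopy segmentation (Fiji,
Reconstruct, Microscopy Image Browser, ...). Where most reconstruction
pipelines stop at a picture, `neuritemorph` treats the triangle meshes of
axons, mitochondria, vesicles and synaptic contacts as measurable objects
in micrometer coordinates: it computes lengths, surface areas and volumes
of arbitrary sub-regions, rebuilds surfaces and closed tubes from stacked
contour drawings, profiles an axon along its centerline, flags candidate
bouton boundaries by geometric criteria, and measures how much two nearby
structures (a bouton and an astrocytic process, ER and mitochondria, ...)
appose each other.

## What it computes

For a triangulated surface `(V, F)` with vertices in µm:

- **Lengths** — straight-line `‖p−q‖`; graph geodesics over the mesh edge
  graph (Dijkstra with Euclidean weights); summed lengths of an edge
  selection.
- **Area and volume** — `A = Σ_f ½‖(v₁−v₀)×(v₂−v₀)‖` over a face
  selection; `V = |Σ_f (v₀−c)·((v₁−c)×(v₂−c))/6|` by the divergence
  theorem after boundary loops are capped (centroid fans) and faces are
  coherently oriented.
- **Surface stitching** — contours drawn on image planes are arc-length
  resampled and joined plane-to-plane into triangle strips; closed
  contours give capped, watertight tubes; contours drawn on either side
  of a perforation leave the hole in the reconstructed surface.
- **Centerline profiling** — at each vertex of a non-branching centerline,
  the perpendicular cross-section polygon of the axon, its area, its
  maximum radius (largest centroid-to-boundary-vertex distance), the
  number of marker objects (e.g. vesicles) whose centroids project to
  that vertex, and the summed face area of chosen surfaces (e.g.
  synapses) projecting there. Exported as one CSV row per vertex.
- **Bouton criteria** — markers where the cross-section area grows
  (green) or shrinks (red) by a factor `A` within arc distance `D`, and
  where the max radius exceeds `M` (blue); defaults `A=2.0`, `D=0.2 µm`,
  `M=0.2 µm`. The axon segment between two chosen vertices can be
  extracted as a closed object and its volume measured.
- **Proximity** — shortest distances from object centroids to a surface
  (50 nm histogram bins by default), and extraction of the paired
  contiguous sub-regions of two meshes lying within a threshold `T` of
  each other, with per-pair areas and per-object non-overlapping totals.

## Worked example

Generate a synthetic axon — a tube of radius 0.12 µm with a Gaussian
bouton-like swelling to 0.32 µm at arc position 5 µm — then profile it
and detect the bouton:

```sh
neuritemorph simulate tube -o axon.obj --length 10 --radius 0.12 \
    --bulge 0.2 --bulge-center 5 --bulge-width 0.2
neuritemorph crosssec --mesh axon.obj --centerline axon.centerline.csv \
    --n-vertices 101 -o profile.csv
neuritemorph boutons --mesh axon.obj --centerline axon.centerline.csv \
    --n-vertices 101 -o markers.csv
neuritemorph measure --mesh axon.obj --op volume
```

which prints

```
101 sections, mean area 0.056576 µm²
markers: 3 green, 3 red, 5 blue
0.567456428
```

`profile.csv` holds one row per centerline vertex; away from the swelling
the cross-section area is the thin-axon value `π·0.12² ≈ 0.045 µm²`, and
at the peak:

```
vertex_index,x,y,z,arc_length_um,cross_section_area_um2,min_radius_um,max_radius_um,sphere_count,projected_area_um2
45,0.000000000,0.000000000,4.500000000,4.500000000,0.053581596,,0.131017699,,
50,0.000000000,0.000000000,5.000000000,5.000000000,0.300420361,,0.310232168,,
```

i.e. the area peaks at 0.300 µm² (analytic `π·0.32² = 0.322 µm²` up to
polygonization) exactly at arc 5.0 µm, and the max radius there is
0.310 µm. The green markers (45–47) sit where the area starts doubling
within 0.2 µm, the red ones (51–53) mirror them on the shrinking side,
and the blue ones flag max radius above 0.2 µm — together bracketing the
bouton. The printed volume 0.5675 µm³ is the whole axon; extracting the
marked segment with `--extract` gives the bouton's own volume.

The `min_radius`, `sphere_count` and `projected_area` columns are empty
because no skeletonizer radii were supplied and no projections were run;
`neuritemorph project` fills the latter two.

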