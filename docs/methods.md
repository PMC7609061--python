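# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the `microvasc` pipeline.

## Coordinate and unit conventions

Channel arrays are indexed `[x, y, z]` so array axis *a* pairs with
`spacing[a]`; the physical center of voxel `(i, j, k)` is
`(idx + 0.5) · spacing` µm. All geometry is in µm; report normalizations
use mm³ (tissue, vessel volume), mm (vessel length) and mm² (tissue area).
The default phantom volume is 100 × 100 × 15 µm at 0.5 × 0.5 × 1.5 µm
sampling — a thin transverse section imaged with ~0.5 µm in-plane pixels
and 1.5 µm optical sections.

## Phantom generator

Rasterization uses the centers-in rule: a voxel belongs to a tube iff its
center lies within the tube radius of the centerline (evaluated against a
dense polyline resampling at min-spacing/4, so the residual error is well
below a voxel). The generated solid for an open tube is therefore a
*capsule* — cylinder plus hemispherical end caps — and
`Tube.analytic_volume()` returns the capsule volume; closed loops have no
caps. Voxelized capsule volume agrees with the closed form to within 5 %
at ≤ 1 µm isotropic sampling; at 1.5 µm z-sampling, tubes whose radius is
near the section spacing digitize coarsely and only the voxelized truth
(not the continuous form) is a fair reference.

Channel model: glass background ≈ 0, tissue background > glass (defaults
40/8/8 for nuclei/vessel/SMA), structures bright (≈ 200–220). Noise is
additive Gaussian with optional Poisson shot noise, applied per channel
after painting; both draw from a single `numpy` Generator seeded by the
caller, so identical (spec, noise, seed) regenerate bit-identical volumes.

SMA sheaths are annuli of configurable thickness (default 1.5 µm) around
flagged tubes; partial mural coverage masks the first fraction of the
centerline arc length. Nuclei are 2 µm spheres: endothelial on centerline
points; SMA+ perivascular at 1.0–1.7 µm from a vessel surface (the lower
bound keeps a voxel-quantization margin so a perivascular centroid can
never fall inside the digitized vessel); myofibroblasts and "other"
nuclei at least adjacency + nucleus radius + 2 µm from every surface, so
their SMA halos stay clear of the mural-coverage probe. Perivascular and
myofibroblast nuclei get a small SMA halo painted around them — these
cells are themselves SMA+.

The phantom emulates geometry, class layout, background contrast and
pixel noise. It does **not** emulate the point-spread function, depth
attenuation, spectral bleed-through, or irregular vessel cross-sections;
passing tests demonstrate correctness of the measurement chain on known
geometry, not robustness to every optical artifact of real microscopy.

SHG textures are anisotropically smoothed random fields thresholded at the
in-zone quantile so that exactly `round(density · n_zone)` pixels are
bright (above `SHG_FIBER_THRESHOLD` = 100); background lies below 30.
Flow-cytometry samples draw normal stained/FMO event distributions, so the
standardized MFI converges to `(µ_pos − µ_FMO)/(2σ_FMO)`.

## Tissue segmentation

Non-local-means denoising runs per channel (patch 3, search distance 3,
`h` = 1.15 × the noise SD estimated from the median absolute deviation of
a high-pass residual); output is clipped to the input intensity range and
`strength=0` is the exact identity.

Multi-level Otsu is an exact dynamic program over contiguous histogram
partitions maximizing Σ w_k µ_k² (equivalently the between-class
variance), O(classes · bins²), with ties broken toward the lowest cut.
Discrete data (≤ 256 distinct values) use the exact per-value histogram;
continuous data use 256 bins over the min–max range. Thresholds are
reported mid-gap between adjacent occupied bins so class membership is
unambiguous. An exhaustive combination-enumeration oracle in the test
suite confirms the maximization on random 6-bit histograms.

The 3-vs-4 class choice is automatic: take 4 classes iff the fourth
explains more than half of the intensity variance left unexplained by
three, i.e. `(η₄ − η₃)/(1 − η₃) > 0.5` with η the normalized between-class
variance. Histograms with three clear modes saturate η₃ and stay at 3; a
genuine fourth mode drives the residual reduction above the cutoff.

Tissue = every intensity class but the darkest, then 3D hole filling
(6-connected holes; filling is idempotent). Vessel and SMA masks are
multiplied element-wise by the tissue mask.

Structure segmentation is single-level Otsu within tissue (hysteresis
optional). Because Otsu always splits a histogram, a foreground class is
accepted only if its separation from background exceeds 4 × the robust
background spread — otherwise the channel is declared empty (with a
warning), which is what lets a vessel-free volume flow through the
pipeline with flagged-missing vascular metrics instead of noise-derived
ones. Connected components below 2 µm³ are discarded as residual noise.

## Skeletonization and the vessel graph

The vessel mask is resampled (nearest-neighbour) to an isotropic grid at
the finest spacing — thinning an anisotropic grid biases topology — and
thinned by an in-package sequential algorithm:

1. **Directional subpasses** (−x, −y, −z, +x, +y, +z, repeated to
   stability). Within a pass, candidate border voxels are deleted one at a
   time in ascending distance-transform order, re-checking the
   Bertrand–Malandain simple-point condition (exactly one 26-connected
   foreground component in the neighbourhood and one 6-connected
   background component touching a face neighbour) — so topology is
   preserved *exactly*: a component can shrink but never vanish. Voxels
   with ≤ 1 neighbour (curve endpoints) are never deleted. A voxel is only
   peeled when it has foreground behind it in the pass direction;
   1-voxel-thick sheets perpendicular to the pass are left to the
   orthogonal passes, which prevents unbounded axial consumption of thin
   structures. Opposite directions are separated in the pass order for the
   same reason.
2. **Cleanup** — the directional phase can leave 2-wide diagonal
   staircases (1 voxel thick along every axis). Simple voxels with ≥ 3
   neighbours are deleted in distance order until stable, reducing them to
   single zigzag lines without touching line interiors or run ends.

The ordering distance uses edge-replicated boundary conditions, and no
pass peels inward from an array face: a vessel cut by the field of view is
treated as continuing, not capped, so volume-spanning tubes keep their
full axial extent. Simple-point tests are cached per 3³ neighbourhood bit
pattern.

Graph construction clusters 26-connected junction voxels into single
branching nodes (their centroid is the node coordinate), walks degree-2
chains into edges, and represents isolated cycles as closed self-loop
edges with no blind ends. Per-point radii are the distance-transform
values at centerline voxels plus half a voxel — the distance transform
reaches the nearest background voxel *center*, while the physical surface
sits about half a voxel farther under the centers-in convention
(validated on digitized cylinders of radius 1–3 µm).

Artifact pruning: terminal segments shorter than the junction-side local
diameter are thinning spurs and are removed; short self-loops at junction
clusters (< 2 local diameters) are staircase residue; junctions reduced
to two edges merge into through-points. Centerlines are then smoothed
(three passes of a 7-point moving average, endpoints pinned) — voxel
chains zigzag around the true axis and would otherwise inflate arc length
and tortuosity by 3–7 % for oblique or curved vessels; the chosen window
brings a semicircle's tortuosity within 0.016 of π/2 without measurably
shortening curvature at vessel scale. Finally, blind-end tips are marched
along their outgoing tangent in half-voxel steps while they remain inside
the vessel mask *and* the local depth stays at the tube radius, which
restores tip erosion without running into the rounded rasterization caps;
at a volume face the march finishes on the face.

Segment metrics: length is polyline arc length; tortuosity is
length/chord (≥ 1; undefined and flagged for closed loops); surface and
volume are conical-frustum sums over per-point radii; mean diameter is
twice the mean interior radius. Size classes partition at 3 and 6 µm; a
capillary requires diameter < 3 µm *and* SMA coverage fraction < 0.1
(configurable SMA-negativity cutoff).

Surface-area density counts exposed voxel faces (spacing-weighted),
scaled by the standard 2/3 digitization bias constant; faces on the array
boundary are not counted (no end caps for spanning tubes). For
axis-aligned cylinders this estimator is accurate to roughly ±20 % — it
is reported as the conventional face-count estimate, not a
marching-cubes area.

## Oxygen-diffusion proxies

Distances are spacing-weighted Euclidean transforms to the vessel phase
(zero inside vessels) — the physical oxygen path length; they match an
exhaustive nearest-vessel-voxel search to float tolerance. Capillary
density is the mean over z-planes containing tissue of centerline–plane
crossings divided by that plane's tissue area (planes without tissue are
skipped). Intercapillary distance is the mean over capillary centerline
points of the distance to the nearest point of a *different* capillary,
excluding segments that share a graph node (which would be trivially zero
at branch points). Diffusion distance is the 95th percentile
(configurable, logged) of the capillary-only extravascular distance
distribution — the quantity is named but not defined in the literature
this pipeline follows, so the percentile convention is an explicit
package decision. The capillary-only mask is re-rasterized from the
classified graph edges.

## Cell metrics

Nuclei are Otsu-thresholded within tissue, labelled (26-connectivity),
filtered below 4 µm³, and reduced to centroids; blobs larger than 1.25 ×
the median volume are flagged as merged detections (two nuclei fused at
1 µm separation union to ≈ 1.3 × a single volume, while single-nucleus
digitization varies by ≲ 10 %).

Classification: endothelial iff the centroid voxel lies in the vessel
mask; otherwise SMA positivity is the upper-quartile SMA intensity in a
2 µm neighbourhood exceeding the SMA channel's Otsu threshold (gated by
the same foreground test as segmentation), and the perivascular /
myofibroblast split is at 2 µm from the vessel surface (configurable).
The distance to the vessel is interpolated from a distance field computed
on the isotropically resampled vessel mask — anisotropic voxel-center
lookups overestimate the surface distance by up to half the coarsest
spacing, enough to flip borderline perivascular calls.

Mural metrics: a centerline point is SMA-covered if SMA signal lies
within local radius + 2 µm of it; a segment is covered at ≥ 50 % covered
points (configurable); sheath thickness at a covered point is the 90th
percentile of radial distances of SMA voxels in a thin slab perpendicular
to the local tangent, minus the vessel radius (the percentile rejects
digitization spikes). The damage index is the fraction of non-capillary
segments (> 3 µm) with coverage below the cutoff — an in-package
operational definition, labelled as such, since the source literature
names the quantity without a formula.

## Scalar scores

SMFI divides the median shift by twice the FMO standard deviation (sample
SD, ddof = 1); the literal product reading of the printed formula is
available behind `literal=True` but is dimensionally inflated and not the
default. WMSI is the mean of the 12 segment scores; infarct size is the
percentage of segments scored > 1. SHG kurtosis is reported non-excess
(normal = 3) with the excess value alongside; the "auto" threshold is
single-level Otsu within the zone; constant zones keep a well-defined
area fraction but flag the moments undefined. Score tables accept long
(level, wall, score) CSV or a bare 3 × 4 matrix.

## Pipeline and aggregation

`run_pipeline` executes preprocess → vasculometry → perfusion →
cellmetrics, aborts with a stage-tagged error on failure, echoes every
effective parameter into the report, and emits every canonical metric row
exactly once — values that cannot be computed are flagged missing with a
reason (empty vasculature, fewer than two capillaries, …) rather than
dropped. Reports round-trip losslessly through JSON and CSV with a fixed
CSV column order. Multi-image studies average per-image reports within a
subject and then across subjects; the within-subject mean is associative
over equal-size batches.

## Problem sizes

The validation phantoms are 48–100 µm per side at 0.5 µm (in-plane) and
0.5–1.5 µm (axial) sampling — 10⁵–10⁶ voxels per volume, matching the
thin-section geometry the pipeline targets while keeping the whole
ground-truth battery and test suite runnable on a laptop in about a
minute. Larger volumes change runtime, not the algorithms.

## Known limitations

- The thinning's blind-end count is sensitive to mask surface roughness;
  spur pruning suppresses but cannot eliminate this on very noisy masks.
- Diameters from the distance transform underestimate by up to ~0.5 voxel
  for tubes whose radius is near the axial spacing; size-class boundaries
  at exactly 3 or 6 µm are therefore soft at coarse sampling.
- The surface-area density is a face-count estimate (±20 %), adequate for
  group comparisons, not for absolute surface areas.
- Intercapillary and diffusion distances follow the package's explicit
  conventions (nearest-foreign-centerline mean; 95th percentile); other
  pipelines may define them differently, so absolute values are
  convention-dependent.
- FCS binary files are out of scope: flow events are read from CSV.
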