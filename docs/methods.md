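# Methods

## Coordinate and raster conventions

All lengths are micrometers. Cell coordinates are lesion-centered: the
user-defined lesion center is the origin, y increases "up" in figure
space. Sections are thin (10 µm in z), so all density and distance
analyses are 2D in the section plane; z is carried through unchanged.
Rasters are indexed (row, col) with row 0 at top; voxel stacks are
(plane, row, col) with voxel size (dx, dy, dz) carried in sidecar
metadata.

## kNN density maps and the permutation p-value map

At each node x of a regular grid (default ±1000 µm, 50 µm spacing — the
~1 mm lesion spans ~40 nodes per axis) the density of one section's
pattern is estimated as

    f̂(x) = k / (n π d_k(x)²)

with k = 8, d_k the distance to the k-th nearest cell, and n the
pattern's cell count. This is the standard 2D kNN estimator; the 1/n
scaling makes sections with different counts comparable (f̂ integrates
to ≈1, so it is a normalized spatial distribution, not an absolute
count density). The code is written so an alternative (k − 1) numerator
is a one-line change. Two numerical choices:

- **Coincident stacks.** If a node sits on ≥ k stacked cells, d_k = 0;
  d_k is floored at half the grid spacing. The floor acts as a cap on
  density (weak ordering preserved, no infinities).
- **No edge correction.** None is applied; the grid is restricted to the
  lesion window, and nodes near the window edge are biased low for both
  groups equally. This is a known, shared bias, not corrected.

Group comparison: per-section maps are averaged within group
(Δ(x) = mean_B − mean_A) and group labels are permuted at the pattern
level. The exchangeable unit defaults to the *section* (9 vs 9 in the
default design). Animal-level permutation is available, but with 3 vs 3
animals only C(6,3) = 20 arrangements exist, so the smallest attainable
two-sided p is 2/20 = 0.1 — useful for arithmetic checks, not for
mapping at α = 0.05. When the arrangement count is at most
`exhaustive_cap` (default 200) the null is enumerated exactly and
p(x) = #{|Δ*| ≥ |Δ|}/N (the observed arrangement is one of the N);
otherwise B = 999 random relabelings are sampled and
p(x) = (1 + #{|Δ*| ≥ |Δ|})/(B + 1), so p is never 0. p-values are
two-sided; ties are counted conservatively (≥ with a relative
tolerance so the observed arrangement always matches itself). No
multiple-testing correction is applied across nodes — the map is
thresholded at raw p < 0.05 per position by design; an FDR switch
exists but is off by default.

Significant-region summaries report flagged-node count × spacing²,
the Euclidean centroid, and the **mean radius** of flagged nodes from
the lesion center. For ring-shaped regions (the expected geometry of a
peri-infarct excess) the Euclidean centroid degenerates toward the
origin; the radial centroid is the meaningful localization statistic
and is what the planted-recovery tests check.

A consequence of the 1/n normalization worth knowing: a group with
*extra* cells in an annulus has a relatively *lower* normalized density
everywhere else, so maps may legitimately show compensating
opposite-direction regions far from the planted excess.

## Synthetic cohort generator

The generator emulates a two-group stroke cohort: 3 animals × 3
sections per group. Cells follow an inhomogeneous Poisson process —
a uniform baseline over the full ±1 mm analysis window (OPCs tile white
matter; ~400 cells/section ≈ 100 cells/mm², a realistic OPC areal
density for a 10 µm slab) plus, for group B only, baseline ×
`excess_ratio` extra intensity inside the circular peri-infarct annulus
(default 300–500 µm). `excess_ratio = 0` gives an exchangeable null
cohort; `excess_ratio = 1` plants a 2× annulus excess. The lesion
ellipse (default semi-axes 500 × 400 µm) is recorded as geometry
metadata. Counts are Poisson; z is uniform in the 10 µm slab; every
generator is a pure function of its spec plus a seed, with per-generator
substreams spawned from one global seed via a fixed registry
(`SeedSequence(seed, spawn_key=(stream_id, index))`), so adding a
generator never perturbs existing streams.

What the generator does **not** emulate: anisotropic lesion shapes,
within-animal correlation of sections (sections are iid given the
spec), spatially varying background (fiber tracts, ventricles), and
segmentation errors. Passing tests therefore demonstrate estimator and
test correctness under the stated point-process model, not robustness
to real-microscopy artifacts.

## Vessel networks and proximity

Synthetic vasculature is a branching persistent random-walk centerline
tree (default 40 branches × 50 steps of 20 µm over a 2 × 2 mm domain,
≈ 40 mm total length — capillary-scale density); later branches sprout
from existing interior nodes so degree ≥ 3 junctions form, and
ground-truth length/junction count are recorded. OPC placement mixes a
vessel-proximal channel (random point on the network, displaced by an
Exponential(decay_length = 10 µm) distance in a random direction — a
phenomenological attraction kernel, not a chemokine diffusion model)
with a uniform channel; the generating channel of each cell is recorded.

Distances are exact point-to-segment Euclidean distances to the
**centerline** (projection clamped to endpoints, ties to the lowest
segment id). With radii available an option subtracts the local radius
(floored at 0) to approximate tube-surface distance; centerline is the
default because the synthetic ground truth is centerline-based.
Distance distributions use half-open 5 µm bins over 0–35 µm plus an
overflow bin (bin width is a package choice; 7 bins across the reported
range). "Vessel-associated" means distance ≤ 5 µm (≈ one cell radius;
no published contact criterion exists, so the threshold is exposed in
config), and cells-per-mm divides the associated count by total
centerline length.

## Raster and voxel morphometry

Vessel rasters: threshold to [40, 255], drop 8-connected components
< 10000 px, apply a width band-pass for the 5–40 px diameter setting
(opening with a disk of radius 2 removes sub-minimum structures;
cores surviving an opening at radius 20 exceed the maximum and are
excluded — the published setting names a width band, not an algorithm,
so the band-pass is implemented morphologically), skeletonize, then
measure. Skeleton length counts each 8-adjacent pixel pair once
(orthogonal = 1 px, diagonal = √2 px), skipping diagonal edges whose
pixels share an orthogonal skeleton neighbor (corner triangles).
Junctions are skeleton pixels with ≥ 3 skeleton neighbors, merged by
8-connectivity so a thick branch zone counts once. Skeletons shorten by
roughly the tube radius at endpoints, which is why rendered-tube tests
use tubes much longer than their radius (5% tolerance).

Voxel operations use 26-connectivity: vessel volume removes components
< 30 µm³ before summing voxel volumes; object tables drop components
< 800 voxels. Colocalization is 100 × |marker ∩ vessel| / |marker| —
asymmetric by design (the denominator is the marker channel) and
undefined (NaN) for an empty marker. No default intensity threshold is
claimed for producing masks from raw fluorescence; masks are inputs.
g-ratio is computed from diameters (g = axon/fiber); an
equivalent-circle-diameter helper supports area-based inputs.

## Lesion-volume bootstrap

Per animal, each replicate draws `target_sections = 25` areas with
replacement from the observed 3–5 areas and sums area × 40 µm — i.e.
the resampled distribution stands in for full 25-section coverage of
the ~1 mm lesion. The alternative reading (few-section resamples scaled
to the full span) is available as `mode="replicates"`; both have the
same expectation. Resampling is with replacement (standard bootstrap)
and strictly per-animal; group comparison of per-animal means uses
Mann-Whitney U. An exact enumeration of the resample distribution is
provided for small cases and doubles as the oracle for the sampled
path. The synthetic ellipsoid default (56, 56, 500) µm has volume
≈ 6.6 × 10⁶ µm³, matching the scale of a 1 mm white-matter stroke.

## Group statistics

The experimental unit is the animal: per-FOV values are averaged per
animal (plain mean; FOV/section counts reported for audit) before
testing. `compare_groups` implements the named tests by delegating to
scipy/statsmodels — the tests are standard; the package's contribution
is the dispatch (which test for which output, encoded in
`DEFAULT_TESTS`) and the adjustment conventions (Holm-Šídák for two-way
ANOVA post hocs, Benjamini-Hochberg for multi-feature Kruskal-Wallis).
The "ordinal shift" comparison is an r × c Chi-square on ordinal
categories, with a linear-by-linear trend variant (M² = (N−1)r², df 1)
behind `trend=True`, since the named analysis does not pin down one
form. The Chi-square "comparison of distributions" operates on binned
count tables (e.g. radial-profile mass), sharing the bin scheme with
`radial_intensity_profile`.

Null-calibration test sizes in the suite (e.g. n = 8/group for
Mann-Whitney, 2 × 2 × 4 for the two-way ANOVA) were chosen so discrete
tests have attainable levels near 0.05; very small samples make exact
rank tests conservative by construction.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script problem sizes (20 null/planted
cohort seeds at B = 999 permutations on a 41 × 41 grid; 100-seed
detection loops; 2000-replicate null calibrations; 40³ voxel oracles)
were chosen as the smallest sizes at which the Monte-Carlo error is
comfortably below each criterion's band.

## Known limitations

- The permutation construction treats sections as exchangeable under
  the null; with strong animal-level random effects the section-level
  test would be anticonservative on real data (the generator has no
  animal effect; use `unit="animal"` when that matters and the design
  allows).
- No edge correction in the density estimator (shared bias near the
  window boundary).
- The width band-pass approximates an interactive tool's diameter
  setting; very heterogeneous vessel calibers interacting with the
  upper bound are not modeled.
- The attraction kernel is phenomenological; no chemokine transport or
  receptor kinetics are simulated.
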