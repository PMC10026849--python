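# oligoniche

Spatial and morphometric quantification of the **oligovascular niche** —
the functional unit of cerebral endothelial cells and oligodendrocyte
progenitor cells (OPCs, PDGFRα+) in white matter — after focal
white-matter stroke. The package is aimed at quantitative microscopists
who have extracted cell coordinates, vessel centerlines, masks, and EM
fiber measurements from their images and need the downstream statistics:

- **Lesion-centered density mapping** (the core method). Each section's
  OPC pattern is converted to a density surface on a regular grid with
  the k-nearest-neighbor estimator,

  f̂(x) = k / (n π d_k(x)²),  k = 8,

  where d_k(x) is the distance from grid node x to its k-th nearest
  cell and n the section's cell count. Surfaces are averaged per group,
  and the node-wise group difference Δ(x) = mean_B − mean_A is tested by
  permuting pattern-level group labels (exhaustive enumeration when the
  number of arrangements is small), giving a p-value map thresholded at
  p < 0.05 and significant-region areas/centroids.
- **OPC–vessel proximity**: exact point-to-segment nearest distances to
  a vessel centerline network, 0–35 µm distance-bin distributions, and
  vessel-association summaries (cells per mm of vessel).
- **Morphometry**: per-fiber g-ratio (axon/fiber diameter) statistics,
  raster vessel skeleton length + junction counts at the published tool
  settings (intensity 40–255, diameter band 5–40 px, particle filters),
  voxel colocalization percentages, particle-filtered object sizes, and
  radial intensity profiles.
- **Lesion volume**: per-animal bootstrap from 3–5 sampled 40 µm section
  areas, resampling to a full 25-section (1 mm) coverage.
- **Group statistics**: per-animal averaging (5 FOV × ≥3 sections) and
  the named tests (Welch's t, Mann-Whitney U, two-way ANOVA + Holm-Šídák,
  Chi-square of distributions, Kruskal-Wallis + FDR, one-sample t,
  ordinal shift Chi-square) with the dispatch encoded per output type.
- **Synthetic data**: seeded generators for every input with recorded
  ground truth (cohort point patterns with a peri-infarct density excess,
  branched vessel networks, vessel-attracted OPCs, fiber sets with set
  mean g-ratio, ellipsoid section areas, overlap-controlled voxel masks).

## Worked example

```bash
oligoniche all --seed 3 --outdir out
```

simulates a two-group cohort (3 animals × 3 sections per group, ~400
cells per section, a 2× OPC excess in the 300–500 µm peri-infarct
annulus of group B) and runs every stage. On this run the density stage
reported

```
B>A:  area_um2: 422500.0   node_count: 169   mean_radius: 405.9
```

— the region with significantly more stroke-responsive OPCs in group B
covers ≈0.42 mm² of the grid and sits at a mean radius of ≈406 µm from
the lesion center, i.e. inside the planted 300–500 µm annulus. The
morphometry stage printed

```
colocalization_percent: 49.98
mean_g_A: 0.802    mean_g_B: 0.882
```

recovering the planted 50% marker-in-vessel overlap and the group mean
g-ratios (0.80 vs 0.88) the fiber generator was calibrated to. The
bootstrap stage writes per-animal lesion-volume means with 95% CIs.

The same operations are available as library functions:

```python
from oligoniche import GridSpec, density_pvalue_map, significant_region_area
from oligoniche.synthetic import CohortSpec, gen_cohort_patterns

pats = gen_cohort_patterns(CohortSpec(excess_ratio=1.0, seed=3))
ga = [p for p in pats if p.group == "A"]
gb = [p for p in pats if p.group == "B"]
pv = density_pvalue_map(ga, gb, GridSpec(), k=8, b_perm=999, seed=3)
region = significant_region_area(pv, alpha=0.05, direction="B>A")
```

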