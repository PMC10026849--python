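"""Seeded synthetic-data generators with known ground truth.

Every pipeline input can be generated here: two-group cohorts of
lesion-centered OPC point patterns, branched vessel centerline networks,
OPC positions attracted to vessels by an exponential distance kernel, EM
fiber sets with a prescribed mean g-ratio, serial-section lesion areas
sampled from a known ellipsoid, and paired voxel masks with a set overlap
fraction.  Generators are pure functions of their parameters plus a seed
(bit-identical reruns) and always record ground truth alongside the data.

Seed substreams
---------------
One global seed expands into independent per-generator substreams via
``numpy.random.SeedSequence(seed, spawn_key=(stream_id, index))``, with a
fixed registry of stream ids below.  Adding a new generator appends a new
id and never perturbs existing streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import FiberSet, PointPattern, SectionAreaSet, VesselGraph, VoxelMask

__all__ = [
    "CohortSpec",
    "AttractionSpec",
    "substream_rng",
    "gen_cohort_patterns",
    "gen_vessel_network",
    "gen_opc_positions",
    "gen_fiber_set",
    "gen_section_areas",
    "gen_voxel_masks",
]

# Fixed stream registry (documented counter scheme); never reorder.
_STREAMS = {
    "cohort": 0,
    "vessels": 1,
    "opc_positions": 2,
    "fibers": 3,
    "section_areas": 4,
    "voxel_masks": 5,
}


def substream_rng(seed: int, stream: str, index: int = 0) -> np.random.Generator:
    """Independent generator for (seed, stream, index)."""
    key = (_STREAMS[stream], int(index))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


@dataclass
class CohortSpec:
    """Two-group stroke cohort layout and lesion geometry.

    The study design is 3 animals per group with 3 sections per animal.
    Cells are drawn from an inhomogeneous Poisson process: a uniform
    baseline over the full analysis window (white matter tiles the whole
    field), plus, for group B only, ``baseline * excess_ratio`` extra
    intensity inside the peri-infarct annulus — the stroke-responsive OPC
    excess.  ``excess_ratio = 0`` is the exchangeable null cohort.
    """

    n_animals_per_group: int = 3
    n_sections_per_animal: int = 3
    cells_per_section_mean: float = 400.0
    lesion_semi_axes: tuple[float, float] = (500.0, 400.0)
    excess_ratio: float = 0.0
    annulus: tuple[float, float] = (300.0, 500.0)
    window_halfwidth: tuple[float, float] = (1000.0, 1000.0)
    slab_thickness: float = 10.0  # z-extent of the imaged section, µm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals_per_group < 1 or self.n_sections_per_animal < 1:
            raise ValueError("cohort needs at least one animal and one section")
        if self.cells_per_section_mean <= 0:
            raise ValueError("cells_per_section_mean must be > 0")
        if min(self.lesion_semi_axes) <= 0 or min(self.window_halfwidth) <= 0:
            raise ValueError("all lengths must be > 0")
        if not (0 <= self.annulus[0] < self.annulus[1]):
            raise ValueError("annulus requires 0 ≤ r_inner < r_outer")
        if self.excess_ratio < 0:
            raise ValueError("excess_ratio must be ≥ 0")

    @property
    def window_area(self) -> float:
        return 4.0 * self.window_halfwidth[0] * self.window_halfwidth[1]

    @property
    def annulus_area(self) -> float:
        r_in, r_out = self.annulus
        return math.pi * (r_out**2 - r_in**2)

    @property
    def baseline_intensity(self) -> float:
        """Cells per µm² of the uniform baseline component."""
        return self.cells_per_section_mean / self.window_area


@dataclass
class AttractionSpec:
    """Vessel-attracted OPC placement around a centerline network."""

    n_cells: int = 300
    attraction_weight: float = 0.5  # fraction placed vessel-proximally
    decay_length: float = 10.0  # µm, exponential displacement kernel scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be ≥ 1")
        if not (0.0 <= self.attraction_weight <= 1.0):
            raise ValueError("attraction_weight must lie in [0, 1]")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be > 0")


def _sample_annulus(rng: np.random.Generator, n: int, r_in: float, r_out: float) -> np.ndarray:
    # Area-uniform radial sampling in the annulus.
    u = rng.random(n)
    r = np.sqrt(u * (r_out**2 - r_in**2) + r_in**2)
    theta = rng.uniform(0.0, 2.0 * math.pi, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def gen_cohort_patterns(spec: CohortSpec) -> list[PointPattern]:
    """Simulate all sections of a two-group cohort.

    Returns ``2 * n_animals_per_group * n_sections_per_animal`` patterns
    with group / animal / section labels.  Per-section counts are Poisson;
    coordinates are lesion-centered µm with z uniform in the imaging slab.
    """
    rng = substream_rng(spec.seed, "cohort")
    hw_x, hw_y = spec.window_halfwidth
    lam = spec.baseline_intensity
    patterns: list[PointPattern] = []
    for group in ("A", "B"):
        for a in range(spec.n_animals_per_group):
            animal = f"{group}{a + 1}"
            for s in range(spec.n_sections_per_animal):
                n_base = rng.poisson(spec.cells_per_section_mean)
                xy = rng.uniform([-hw_x, -hw_y], [hw_x, hw_y], size=(n_base, 2))
                if group == "B" and spec.excess_ratio > 0:
                    n_extra = rng.poisson(lam * spec.excess_ratio * spec.annulus_area)
                    xy = np.vstack([xy, _sample_annulus(rng, n_extra, *spec.annulus)])
                z = rng.uniform(0.0, spec.slab_thickness, len(xy))
                patterns.append(
                    PointPattern(
                        np.column_stack([xy, z]),
                        group=group,
                        animal=animal,
                        section=f"s{s + 1}",
                        meta={
                            "baseline_intensity": lam,
                            "excess_ratio": spec.excess_ratio if group == "B" else 0.0,
                            "annulus": spec.annulus,
                            "lesion_semi_axes": spec.lesion_semi_axes,
                        },
                    )
                )
    return patterns


def gen_vessel_network(
    domain: tuple[float, float] = (2000.0, 2000.0),
    n_branches: int = 40,
    step: float = 20.0,
    seed: int = 0,
    steps_per_branch: int = 50,
    turn_sd: float = 0.35,
    radius: float | None = 3.0,
) -> VesselGraph:
    """Branching persistent random-walk centerline tree.

    Each branch is a polyline of ``steps_per_branch`` segments of length
    ``step``; branches after the first sprout from a random existing node.
    Ground-truth total length and junction count (degree ≥ 3 nodes) are
    recorded in ``graph.meta``.
    """
    if n_branches < 1:
        raise ValueError("n_branches must be ≥ 1")
    if step <= 0:
        raise ValueError("step must be > 0")
    rng = substream_rng(seed, "vessels")
    hw = (domain[0] / 2.0, domain[1] / 2.0)
    nodes: list[np.ndarray] = []
    segments: list[tuple[int, int]] = []

    def _walk(start_idx: int) -> None:
        pos = nodes[start_idx][:2].copy()
        angle = rng.uniform(0.0, 2.0 * math.pi)
        prev = start_idx
        for _ in range(steps_per_branch):
            angle += rng.normal(0.0, turn_sd)
            nxt = pos + step * np.array([math.cos(angle), math.sin(angle)])
            # reflect off the domain boundary
            for d in range(2):
                if nxt[d] > hw[d]:
                    nxt[d] = 2 * hw[d] - nxt[d]
                    angle = math.pi - angle if d == 0 else -angle
                elif nxt[d] < -hw[d]:
                    nxt[d] = -2 * hw[d] - nxt[d]
                    angle = math.pi - angle if d == 0 else -angle
            nodes.append(np.array([nxt[0], nxt[1], 0.0]))
            segments.append((prev, len(nodes) - 1))
            prev = len(nodes) - 1
            pos = nxt

    start = rng.uniform([-hw[0] / 2, -hw[1] / 2], [hw[0] / 2, hw[1] / 2])
    nodes.append(np.array([start[0], start[1], 0.0]))
    _walk(0)
    for _ in range(n_branches - 1):
        # sprout from an interior node (degree 2) so a true junction forms
        _walk(int(rng.integers(1, len(nodes) - 1)))

    radii = None if radius is None else np.full(len(segments), float(radius))
    g = VesselGraph(
        np.array(nodes),
        np.array(segments, dtype=int),
        radii=radii,
        extent=((-hw[0], hw[0]), (-hw[1], hw[1])),
    )
    g.meta["true_total_length"] = g.total_length
    g.meta["true_junction_count"] = g.junction_count
    return g


def gen_opc_positions(vessels: VesselGraph, spec: AttractionSpec) -> PointPattern:
    """Place OPCs around a vessel network with a tunable attraction.

    ``round(attraction_weight * n_cells)`` cells are placed at a random
    point on the network (segments weighted by length) displaced by a
    distance drawn from ``Exponential(decay_length)`` in a uniform random
    direction; the remainder are uniform over the network's domain.  The
    generating channel of every cell ("vessel" / "uniform") is recorded in
    ``pattern.meta["channel"]``.
    """
    if vessels.n_segments == 0:
        raise ValueError("vessel graph is empty")
    rng = substream_rng(spec.seed, "opc_positions")
    n_prox = int(round(spec.attraction_weight * spec.n_cells))
    n_unif = spec.n_cells - n_prox

    lengths = vessels.segment_lengths()
    probs = lengths / lengths.sum()
    seg_idx = rng.choice(vessels.n_segments, size=n_prox, p=probs)
    t = rng.random(n_prox)
    p1 = vessels.nodes[vessels.segments[seg_idx, 0], :2]
    p2 = vessels.nodes[vessels.segments[seg_idx, 1], :2]
    base = p1 + t[:, None] * (p2 - p1)
    r = rng.exponential(spec.decay_length, n_prox)
    theta = rng.uniform(0.0, 2.0 * math.pi, n_prox)
    prox = base + np.column_stack([r * np.cos(theta), r * np.sin(theta)])

    (xmin, xmax), (ymin, ymax) = vessels.extent or vessels.bounding_box()
    unif = rng.uniform([xmin, ymin], [xmax, ymax], size=(n_unif, 2))

    xy = np.vstack([prox, unif])
    channel = np.array(["vessel"] * n_prox + ["uniform"] * n_unif)
    order = rng.permutation(len(xy))
    return PointPattern(
        np.column_stack([xy[order], np.zeros(len(xy))]),
        meta={"channel": channel[order], "attraction_weight": spec.attraction_weight,
              "decay_length": spec.decay_length},
    )


def gen_fiber_set(
    n: int,
    mean_g: float = 0.80,
    sd_g: float = 0.06,
    axon_diam_mean: float = 0.8,
    axon_diam_cv: float = 0.3,
    seed: int = 0,
    group: str = "",
) -> FiberSet:
    """EM fiber sample with lognormal axon diameters and prescribed g-ratio.

    Per-fiber g is truncated-normal(mean_g, sd_g) on (0, 1); the fiber
    diameter is ``axon / g`` so it always exceeds the axon diameter.  The
    default means mirror chow-fed (0.80) versus obese (0.88) corpus
    callosum calibration.
    """
    if not (0.0 < mean_g < 1.0):
        raise ValueError("mean_g must lie strictly inside (0, 1)")
    if n < 1:
        raise ValueError("n must be ≥ 1")
    if sd_g < 0:
        raise ValueError("sd_g must be ≥ 0")
    rng = substream_rng(seed, "fibers")
    sigma2 = math.log(1.0 + axon_diam_cv**2)
    mu = math.log(axon_diam_mean) - sigma2 / 2.0
    axon = rng.lognormal(mu, math.sqrt(sigma2), n)
    if sd_g == 0:
        g = np.full(n, mean_g)
    else:
        # solve for the location so the (0,1)-truncated mean equals mean_g
        from scipy.optimize import brentq

        def _trunc_mean(loc: float) -> float:
            return stats.truncnorm.mean((0.0 - loc) / sd_g, (1.0 - loc) / sd_g,
                                        loc=loc, scale=sd_g)

        lo, hi = mean_g - 4 * sd_g, mean_g + 4 * sd_g
        loc = brentq(lambda m: _trunc_mean(m) - mean_g, lo, hi, xtol=1e-10)
        a = (0.0 - loc) / sd_g
        b = (1.0 - loc) / sd_g
        g = stats.truncnorm.rvs(a, b, loc=loc, scale=sd_g, size=n, random_state=rng)
    fiber = axon / g
    return FiberSet(axon, fiber, meta={"mean_g": mean_g, "sd_g": sd_g, "group": group})


def gen_section_areas(
    semi_axes: tuple[float, float, float] = (56.0, 56.0, 500.0),
    section_spacing: float = 40.0,
    n_sampled: int = 4,
    noise_cv: float = 0.15,
    seed: int = 0,
    animal: str = "a1",
    group: str = "",
    mode: str = "random",
) -> SectionAreaSet:
    """Serial-section lesion areas from a known ellipsoid.

    The lesion is an axis-aligned ellipsoid with semi-axes ``(a, b, c)``,
    sectioned perpendicular to the c-axis; the true cross-section at
    height z is ``π a b (1 − z²/c²)`` (0 outside the lesion, retained),
    multiplied by unit-mean lognormal noise with the given CV.  The true
    volume ``(4/3) π a b c`` is recorded as ground truth.

    ``mode="random"`` samples plane heights uniformly across the lesion
    span (how sparse 3–5-section sampling works in practice);
    ``mode="grid"`` places an evenly spaced centered run of planes
    ``section_spacing`` apart (full-coverage Riemann sampling).
    """
    a, b, c = semi_axes
    if min(semi_axes) <= 0:
        raise ValueError("semi-axes must be > 0")
    if n_sampled < 1 or section_spacing <= 0:
        raise ValueError("need n_sampled ≥ 1 and positive spacing")
    if noise_cv < 0:
        raise ValueError("noise_cv must be ≥ 0")
    rng = substream_rng(seed, "section_areas")
    if mode == "grid":
        z = (np.arange(n_sampled) - (n_sampled - 1) / 2.0) * section_spacing
    elif mode == "random":
        z = np.sort(rng.uniform(-c, c, n_sampled))
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    true_area = math.pi * a * b * np.clip(1.0 - (z / c) ** 2, 0.0, None)
    if noise_cv > 0:
        s2 = math.log(1.0 + noise_cv**2)
        noise = rng.lognormal(-s2 / 2.0, math.sqrt(s2), n_sampled)
        areas = true_area * noise
    else:
        areas = true_area
    return SectionAreaSet(
        animal=animal,
        group=group,
        areas=areas,
        section_thickness=section_spacing,
        meta={
            "true_volume": 4.0 / 3.0 * math.pi * a * b * c,
            "plane_z": z,
            "true_areas": true_area,
            "semi_axes": semi_axes,
        },
    )


def gen_voxel_masks(
    shape: tuple[int, int, int] = (16, 64, 64),
    overlap_fraction: float = 0.5,
    seed: int = 0,
    vessel_fill: float = 0.10,
    marker_fill: float = 0.05,
    voxel_size=(1.0, 1.0, 1.0),
    blob_sigma: float = 2.0,
) -> tuple[VoxelMask, VoxelMask]:
    """Paired (vessel, marker) masks with a set marker-in-vessel overlap.

    The vessel mask is a random blob set (thresholded smoothed noise).
    The marker mask is built voxel-by-voxel so that
    ``|marker ∩ vessel| / |marker| = overlap_fraction`` exactly up to one
    voxel of rounding; the realized fraction is recorded in
    ``marker.meta["true_overlap_fraction"]``.
    """
    from scipy import ndimage

    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValueError("overlap_fraction must lie in [0, 1]")
    if min(shape) < 1:
        raise ValueError("shape must be positive")
    rng = substream_rng(seed, "voxel_masks")
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), blob_sigma)
    vessel = noise > np.quantile(noise, 1.0 - vessel_fill)

    size = int(np.prod(shape))
    n_marker = max(1, int(round(marker_fill * size)))
    k_in = int(round(overlap_fraction * n_marker))
    inside = np.flatnonzero(vessel.ravel())
    outside = np.flatnonzero(~vessel.ravel())
    if k_in > len(inside) or (n_marker - k_in) > len(outside):
        raise ValueError("requested overlap fraction impossible for these mask sizes")
    chosen = np.concatenate(
        [
            rng.choice(inside, size=k_in, replace=False),
            rng.choice(outside, size=n_marker - k_in, replace=False),
        ]
    )
    marker = np.zeros(size, dtype=bool)
    marker[chosen] = True
    marker = marker.reshape(shape)

    vm = VoxelMask(vessel, voxel_size, meta={"n_voxels": int(vessel.sum())})
    mm = VoxelMask(
        marker,
        voxel_size,
        meta={
            "n_voxels": n_marker,
            "n_in_vessel": k_in,
            "true_overlap_fraction": k_in / n_marker,
        },
    )
    return vm, mm
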