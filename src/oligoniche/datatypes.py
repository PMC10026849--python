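"""Core in-memory containers shared by every analysis stage.

Conventions used throughout the package
---------------------------------------
* All lengths are micrometers (µm); coordinates are lesion-centered, i.e.
  the user-defined lesion center is the origin ``(0, 0, 0)``.
* Point coordinates are stored as ``(n, 3)`` float arrays ``(x, y, z)``;
  purely 2D inputs are padded with ``z = 0``.
* Rasters are indexed ``(row, col)`` with row 0 at the top; voxel arrays
  are indexed ``(plane, row, col)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PointPattern",
    "GridSpec",
    "DensityGrid",
    "PValueMap",
    "VesselGraph",
    "DistanceSet",
    "FiberSet",
    "SectionAreaSet",
    "VoxelMask",
]


def _as_coords(coords) -> np.ndarray:
    arr = np.asarray(coords, dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 3)
    if arr.ndim != 2 or arr.shape[1] not in (2, 3):
        raise ValueError(f"coordinates must be (n, 2) or (n, 3); got shape {arr.shape}")
    if arr.shape[1] == 2:
        arr = np.column_stack([arr, np.zeros(len(arr))])
    if not np.all(np.isfinite(arr)):
        raise ValueError("coordinates must be finite")
    return arr


@dataclass
class PointPattern:
    """Labeled cell coordinates from one section, lesion-centered, in µm."""

    coords: np.ndarray
    group: str = ""
    animal: str = ""
    section: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = _as_coords(self.coords)

    @property
    def n(self) -> int:
        return len(self.coords)

    @property
    def xy(self) -> np.ndarray:
        """2D view; the thin (10 µm) z-axis is ignored by the grid analysis."""
        return self.coords[:, :2]


@dataclass(frozen=True)
class GridSpec:
    """Regular 2D lattice of query nodes, inclusive of both range endpoints."""

    x_range: tuple[float, float] = (-1000.0, 1000.0)
    y_range: tuple[float, float] = (-1000.0, 1000.0)
    spacing: float = 50.0

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.x_range[1] <= self.x_range[0] or self.y_range[1] <= self.y_range[0]:
            raise ValueError("grid ranges must be non-degenerate")

    @property
    def x_nodes(self) -> np.ndarray:
        return np.arange(self.x_range[0], self.x_range[1] + self.spacing / 2, self.spacing)

    @property
    def y_nodes(self) -> np.ndarray:
        return np.arange(self.y_range[0], self.y_range[1] + self.spacing / 2, self.spacing)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.y_nodes), len(self.x_nodes))

    def nodes_xy(self) -> np.ndarray:
        """All node coordinates, shape ``(ny * nx, 2)``, row-major in (y, x)."""
        xx, yy = np.meshgrid(self.x_nodes, self.y_nodes)
        return np.column_stack([xx.ravel(), yy.ravel()])


@dataclass
class DensityGrid:
    """Per-node kNN density estimate, cells per µm², for one point pattern."""

    grid: GridSpec
    k: int
    values: np.ndarray  # shape grid.shape, ≥ 0, finite
    n_cells: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        if self.k < 1:
            raise ValueError("k must be ≥ 1")


@dataclass
class PValueMap:
    """Node-wise signed density difference (B − A) with permutation p-values."""

    grid: GridSpec
    delta: np.ndarray
    p: np.ndarray
    alpha: float = 0.05
    b_perm: int = 999
    exhaustive: bool = False
    n_arrangements: int = 0
    unit: str = "section"
    meta: dict = field(default_factory=dict)

    @property
    def masks(self) -> dict[str, np.ndarray]:
        sig = self.p < self.alpha
        return {"B>A": sig & (self.delta > 0), "A>B": sig & (self.delta < 0)}


class VesselGraph:
    """Vessel centerline network: nodes (µm) joined by straight segments.

    The graph may be disconnected.  Junctions are nodes of degree ≥ 3.
    """

    def __init__(self, nodes, segments, radii=None, extent=None, meta=None):
        self.nodes = _as_coords(nodes)
        self.segments = np.asarray(segments, dtype=int).reshape(-1, 2)
        if len(self.segments) and self.segments.max() >= len(self.nodes):
            raise ValueError("segment endpoint index out of range")
        self.radii = None if radii is None else np.asarray(radii, dtype=float)
        if self.radii is not None and len(self.radii) != len(self.segments):
            raise ValueError("one radius per segment required")
        self.extent = extent  # ((xmin, xmax), (ymin, ymax)) µm, if known
        self.meta = dict(meta or {})

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def segment_lengths(self) -> np.ndarray:
        p1 = self.nodes[self.segments[:, 0]]
        p2 = self.nodes[self.segments[:, 1]]
        return np.linalg.norm(p2 - p1, axis=1)

    @property
    def total_length(self) -> float:
        return float(self.segment_lengths().sum())

    def degrees(self) -> np.ndarray:
        return np.bincount(self.segments.ravel(), minlength=len(self.nodes))

    @property
    def junction_count(self) -> int:
        return int(np.count_nonzero(self.degrees() >= 3))

    def bounding_box(self):
        lo = self.nodes.min(axis=0)
        hi = self.nodes.max(axis=0)
        return (lo[0], hi[0]), (lo[1], hi[1])


@dataclass
class DistanceSet:
    """Per-cell nearest distance to the vessel network, with nearest segment id."""

    distances: np.ndarray
    segment_ids: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.segment_ids = np.asarray(self.segment_ids, dtype=int)
        if np.any(self.distances < 0):
            raise ValueError("distances must be ≥ 0")

    @property
    def n(self) -> int:
        return len(self.distances)


class FiberSet:
    """Per-fiber EM measurements: axon diameter and total fiber diameter (µm).

    Derived quantities: g-ratio ``g = axon / fiber`` and myelin thickness
    ``(fiber − axon) / 2``.  Constraint ``0 < axon ≤ fiber`` is enforced.
    """

    def __init__(self, axon_diameter, fiber_diameter, meta=None):
        self.axon_diameter = np.asarray(axon_diameter, dtype=float)
        self.fiber_diameter = np.asarray(fiber_diameter, dtype=float)
        if self.axon_diameter.shape != self.fiber_diameter.shape:
            raise ValueError("axon and fiber diameter arrays must align")
        if np.any(self.axon_diameter <= 0):
            raise ValueError("axon diameters must be > 0")
        if np.any(self.axon_diameter > self.fiber_diameter):
            raise ValueError("axon diameter cannot exceed fiber diameter")
        self.meta = dict(meta or {})

    @property
    def n(self) -> int:
        return len(self.axon_diameter)

    @property
    def g(self) -> np.ndarray:
        return self.axon_diameter / self.fiber_diameter

    @property
    def myelin_thickness(self) -> np.ndarray:
        return (self.fiber_diameter - self.axon_diameter) / 2.0


@dataclass
class SectionAreaSet:
    """Sparse per-animal lesion areas (µm²) from serial 40 µm sections."""

    animal: str
    group: str
    areas: np.ndarray
    section_thickness: float = 40.0
    target_sections: int = 25
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.ndim != 1:
            raise ValueError("areas must be a flat list")
        if np.any(self.areas < 0):
            raise ValueError("areas must be ≥ 0")
        if self.section_thickness <= 0:
            raise ValueError("section thickness must be > 0")


class VoxelMask:
    """Binary voxel mask with physical voxel size ``(dx, dy, dz)`` in µm."""

    def __init__(self, data, voxel_size=(1.0, 1.0, 1.0), meta=None):
        self.data = np.asarray(data).astype(bool)
        vs = tuple(float(v) for v in np.atleast_1d(voxel_size))
        if len(vs) == 1:
            vs = vs * 3
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be three positive lengths (dx, dy, dz)")
        self.voxel_size = vs
        self.meta = dict(meta or {})

    @property
    def voxel_volume(self) -> float:
        dx, dy, dz = self.voxel_size
        return dx * dy * dz

    @property
    def shape(self):
        return self.data.shape
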