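"""Run configuration: every printed analysis setting in one place.

Defaults mirror the study's settings: k = 8 density smoothing, p < 0.05
map threshold, 0–35 µm proximity bins, 5 µm association threshold,
30 µm³ / 800-voxel / <10000-px particle filters, intensity 40–255 and
diameter 5–40 vessel band, 40 µm sections with a 25-section bootstrap
target.  CLI flags override config-file values, which override these
defaults; every run writes a resolved-config snapshot next to its
outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

__all__ = ["RunConfig"]


@dataclass
class GridConfig:
    x_range: tuple[float, float] = (-1000.0, 1000.0)
    y_range: tuple[float, float] = (-1000.0, 1000.0)
    spacing: float = 50.0
    k: int = 8
    alpha: float = 0.05
    b_perm: int = 999
    unit: str = "section"


@dataclass
class ProximityConfig:
    bin_width: float = 5.0
    max_range: float = 35.0
    assoc_threshold: float = 5.0


@dataclass
class MorphometryConfig:
    min_particle_um3: float = 30.0
    min_object_voxels: int = 800
    intensity_range: tuple[float, float] = (40.0, 255.0)
    diameter_range: tuple[float, float] = (5.0, 40.0)
    min_component_px: int = 10000


@dataclass
class BootstrapConfig:
    section_thickness: float = 40.0
    target_sections: int = 25
    n_boot: int = 2000


@dataclass
class SimulateConfig:
    n_animals_per_group: int = 3
    n_sections_per_animal: int = 3
    cells_per_section_mean: float = 400.0
    excess_ratio: float = 1.0
    annulus: tuple[float, float] = (300.0, 500.0)
    n_vessel_branches: int = 40
    attraction_weight: float = 0.5
    decay_length: float = 10.0
    n_opc: int = 300
    fiber_n: int = 300
    mean_g_a: float = 0.80
    mean_g_b: float = 0.88
    overlap_fraction: float = 0.5


@dataclass
class RunConfig:
    seed: int = 0
    grid: GridConfig = field(default_factory=GridConfig)
    proximity: ProximityConfig = field(default_factory=ProximityConfig)
    morphometry: MorphometryConfig = field(default_factory=MorphometryConfig)
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        sections = {
            "grid": cfg.grid,
            "proximity": cfg.proximity,
            "morphometry": cfg.morphometry,
            "bootstrap": cfg.bootstrap,
            "simulate": cfg.simulate,
        }
        for key, val in raw.items():
            if key == "seed":
                cfg.seed = int(val)
            elif key in sections and isinstance(val, dict):
                sec = sections[key]
                for k, v in val.items():
                    if not hasattr(sec, k):
                        raise ValueError(f"unknown config key {key}.{k}")
                    current = getattr(sec, k)
                    setattr(sec, k, tuple(v) if isinstance(current, tuple) else v)
            else:
                raise ValueError(f"unknown config section {key!r}")
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)

    def snapshot(self, path) -> None:
        """Write the fully resolved configuration used by a run."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
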