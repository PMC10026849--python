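"""Bootstrap lesion-volume estimation from sparse serial-section areas.

A lesion spanning about 1 mm is sectioned at 40 µm but only 3–5 sections
per animal are measured.  Each bootstrap replicate resamples
``target_sections`` (default 25) areas with replacement from the animal's
observed areas — a stand-in for full 25 x 40 µm coverage of the lesion —
and the replicate volume is the sum of resampled areas times the section
thickness.  Resampling is per-animal; group comparison of the resulting
distributions is delegated to :mod:`oligoniche.stats` (Mann-Whitney U).
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .datatypes import SectionAreaSet

__all__ = ["bootstrap_lesion_volume", "exhaustive_volume_distribution"]


def bootstrap_lesion_volume(
    s: SectionAreaSet,
    n_boot: int = 2000,
    seed: int | None = None,
    mode: str = "sections",
) -> dict:
    """Bootstrap distribution of one animal's lesion volume (µm³).

    ``mode="sections"`` (default): every replicate draws
    ``s.target_sections`` areas with replacement and sums
    ``area * thickness`` — the "full area sampling" reading of the n = 25
    bootstrap.  ``mode="replicates"`` is the alternative reading: each
    replicate resamples only the observed number of sections and scales
    the mean area to the full ``target_sections * thickness`` span; both
    have the same expectation.
    """
    if len(s.areas) == 0:
        raise ValueError("no section areas supplied")
    if n_boot < 1:
        raise ValueError("n_boot must be ≥ 1")
    rng = np.random.default_rng(seed)
    if mode == "sections":
        draws = rng.choice(s.areas, size=(n_boot, s.target_sections), replace=True)
        volumes = draws.sum(axis=1) * s.section_thickness
    elif mode == "replicates":
        draws = rng.choice(s.areas, size=(n_boot, len(s.areas)), replace=True)
        volumes = draws.mean(axis=1) * s.target_sections * s.section_thickness
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return {
        "animal": s.animal,
        "group": s.group,
        "volumes": volumes,
        "mean": float(volumes.mean()),
        "ci95": tuple(np.percentile(volumes, [2.5, 97.5])),
        "n_boot": n_boot,
        "mode": mode,
    }


def exhaustive_volume_distribution(s: SectionAreaSet, max_enum: int = 1_000_000):
    """Exact bootstrap volume distribution by enumerating every resample.

    Feasible only when ``len(areas) ** target_sections`` is small; used as
    the closed-form check of the sampled bootstrap.  Returns
    ``(volumes, probabilities)`` sorted by volume.
    """
    m = len(s.areas)
    if m == 0:
        raise ValueError("no section areas supplied")
    if m**s.target_sections > max_enum:
        raise ValueError("enumeration too large; use bootstrap_lesion_volume")
    sums: dict[float, float] = {}
    p_each = (1.0 / m) ** s.target_sections
    for combo in product(s.areas, repeat=s.target_sections):
        v = sum(combo) * s.section_thickness
        sums[v] = sums.get(v, 0.0) + p_each
    vols = np.array(sorted(sums))
    probs = np.array([sums[v] for v in vols])
    return vols, probs
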