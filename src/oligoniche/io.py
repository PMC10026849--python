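"""File formats: point-pattern and vessel-segment CSV, TSV map matrices
with YAML sidecar metadata, and multi-page TIFF masks with voxel size in
a sidecar.

Point-pattern CSV header: ``x_um, y_um, z_um, group, animal, section``
(optional ``channel``).  Vessel CSV: one segment per row,
``x1,y1,z1,x2,y2,z2,radius``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import GridSpec, PointPattern, PValueMap, VesselGraph, VoxelMask

__all__ = [
    "write_patterns_csv",
    "read_patterns_csv",
    "write_vessels_csv",
    "read_vessels_csv",
    "write_pvalue_map",
    "read_pvalue_map",
    "write_mask_tiff",
    "read_mask_tiff",
    "write_sidecar",
    "read_sidecar",
]

PATTERN_COLUMNS = ["x_um", "y_um", "z_um", "group", "animal", "section"]


def write_patterns_csv(patterns: list[PointPattern], path) -> None:
    frames = []
    for p in patterns:
        df = pd.DataFrame(p.coords, columns=["x_um", "y_um", "z_um"])
        df["group"] = p.group
        df["animal"] = p.animal
        df["section"] = p.section
        if "channel" in p.meta:
            df["channel"] = p.meta["channel"]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_patterns_csv(path) -> list[PointPattern]:
    df = pd.read_csv(path)
    missing = [c for c in PATTERN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pattern CSV missing columns {missing}")
    out = []
    for (group, animal, section), sub in df.groupby(["group", "animal", "section"], sort=True):
        meta = {}
        if "channel" in sub.columns:
            meta["channel"] = sub["channel"].to_numpy()
        out.append(
            PointPattern(
                sub[["x_um", "y_um", "z_um"]].to_numpy(),
                group=str(group),
                animal=str(animal),
                section=str(section),
                meta=meta,
            )
        )
    return out


def write_vessels_csv(graph: VesselGraph, path) -> None:
    p1 = graph.nodes[graph.segments[:, 0]]
    p2 = graph.nodes[graph.segments[:, 1]]
    df = pd.DataFrame(
        np.hstack([p1, p2]), columns=["x1", "y1", "z1", "x2", "y2", "z2"]
    )
    df["radius"] = graph.radii if graph.radii is not None else np.nan
    df.to_csv(path, index=False, float_format="%.6f")


def read_vessels_csv(path) -> VesselGraph:
    df = pd.read_csv(path)
    need = ["x1", "y1", "z1", "x2", "y2", "z2"]
    if any(c not in df.columns for c in need):
        raise ValueError(f"vessel CSV needs columns {need}")
    p1 = df[["x1", "y1", "z1"]].to_numpy()
    p2 = df[["x2", "y2", "z2"]].to_numpy()
    # merge endpoints that coincide (to 1e-6 µm) so junctions are recoverable
    pts = np.vstack([p1, p2])
    key = np.round(pts / 1e-6).astype(np.int64)
    _, idx, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    nodes = pts[idx]
    segments = np.column_stack([inv[: len(p1)], inv[len(p1) :]])
    radii = df["radius"].to_numpy() if "radius" in df.columns and df["radius"].notna().all() else None
    return VesselGraph(nodes, segments, radii=radii)


def write_sidecar(meta: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_sidecar(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_pvalue_map(pvmap: PValueMap, prefix) -> None:
    """TSV matrices (delta, p, masks) plus a YAML metadata sidecar."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".delta.tsv"), pvmap.delta, delimiter="\t")
    np.savetxt(prefix.with_suffix(".p.tsv"), pvmap.p, delimiter="\t")
    masks = pvmap.masks
    np.savetxt(prefix.with_suffix(".mask_b_gt_a.tsv"), masks["B>A"].astype(int),
               delimiter="\t", fmt="%d")
    np.savetxt(prefix.with_suffix(".mask_a_gt_b.tsv"), masks["A>B"].astype(int),
               delimiter="\t", fmt="%d")
    write_sidecar(
        {
            "x_range": list(pvmap.grid.x_range),
            "y_range": list(pvmap.grid.y_range),
            "spacing": pvmap.grid.spacing,
            "k": pvmap.meta.get("k"),
            "alpha": pvmap.alpha,
            "b_perm": pvmap.b_perm,
            "exhaustive": pvmap.exhaustive,
            "n_arrangements": pvmap.n_arrangements,
            "unit": pvmap.unit,
            "seed": pvmap.meta.get("seed"),
        },
        prefix.with_suffix(".meta.yaml"),
    )


def read_pvalue_map(prefix) -> PValueMap:
    prefix = Path(prefix)
    meta = read_sidecar(prefix.with_suffix(".meta.yaml"))
    grid = GridSpec(tuple(meta["x_range"]), tuple(meta["y_range"]), meta["spacing"])
    return PValueMap(
        grid=grid,
        delta=np.loadtxt(prefix.with_suffix(".delta.tsv"), delimiter="\t"),
        p=np.loadtxt(prefix.with_suffix(".p.tsv"), delimiter="\t"),
        alpha=meta["alpha"],
        b_perm=meta["b_perm"],
        exhaustive=meta["exhaustive"],
        n_arrangements=meta["n_arrangements"],
        unit=meta["unit"],
        meta={"k": meta.get("k"), "seed": meta.get("seed")},
    )


def write_mask_tiff(mask: VoxelMask, path) -> None:
    data = mask.data.astype(np.uint8)
    if data.ndim == 2:
        data = data[None]
    tifffile.imwrite(path, data, photometric="minisblack")
    write_sidecar({"voxel_size_um": list(mask.voxel_size)}, str(path) + ".meta.yaml")


def read_mask_tiff(path) -> VoxelMask:
    data = tifffile.imread(path)
    sidecar = Path(str(path) + ".meta.yaml")
    voxel_size = (1.0, 1.0, 1.0)
    if sidecar.exists():
        voxel_size = tuple(read_sidecar(sidecar)["voxel_size_um"])
    return VoxelMask(np.squeeze(data) > 0, voxel_size)
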