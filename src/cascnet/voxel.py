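"""Seed-based voxel-wise causal structural covariance mapping.

Given a seed region (typically the cluster surviving the group-difference
analysis) and the pseudo-time-ordered gray-matter volume maps, two
directed maps are computed: seed-to-map, where the seed's lagged volume
predicts each voxel, and map-to-seed, where each voxel's lagged volume
predicts the seed.  GC maps are converted to z by global standardization
over the analysis mask, and voxels pass jointly on |Z| and |GC|
magnitude thresholds; surviving voxels are reported as connected
clusters (26-neighbour) with peak coordinates in world (template) mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .gc import GCConfig, batched_lag1_paths, gc_to_z
from .pseudotime import residualize, standardize
from .vbm import ClusterRecord

__all__ = [
    "GCMap",
    "stack_maps",
    "extract_seed_series",
    "seed_to_map",
    "map_to_seed",
    "report_clusters",
]

log = logging.getLogger(__name__)

#: 26-neighbour connectivity structure for 3D cluster labeling.
CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class GCMap:
    """Voxel-wise signed GC and z maps for one direction of analysis."""

    direction: str  # "seed_to_map" | "map_to_seed"
    seed_label: str
    gc: np.ndarray  # 3D, NaN outside mask
    z: np.ndarray  # 3D, NaN outside mask
    mask: np.ndarray  # 3D bool
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("seed_to_map", "map_to_seed"):
            raise ValueError(f"unknown direction {self.direction!r}")
        for arr in (self.gc, self.z):
            if arr.shape != self.mask.shape:
                raise ValueError("gc/z/mask shapes differ")
            if np.any(np.isfinite(arr) & ~self.mask):
                raise ValueError("values defined outside the mask")

    def surviving(self, config: GCConfig | None = None) -> np.ndarray:
        config = config or GCConfig()
        with np.errstate(invalid="ignore"):
            if config.two_sided:
                ok = (np.abs(self.z) > config.z_threshold) & (
                    np.abs(self.gc) > config.gc_threshold
                )
            else:
                ok = (self.z > config.z_threshold) & (self.gc > config.gc_threshold)
        return np.nan_to_num(ok.astype(float)).astype(bool) & self.mask


def stack_maps(maps: dict[str, np.ndarray], order_index: list[str]) -> np.ndarray:
    """Stack per-subject volumes into a (T, x, y, z) array in pseudo-time order."""
    missing = [s for s in order_index if s not in maps]
    if missing:
        raise KeyError(f"subjects without a volume map: {missing}")
    return np.stack([np.asarray(maps[s], float) for s in order_index])


def extract_seed_series(vol4d: np.ndarray, seed_mask: np.ndarray) -> np.ndarray:
    """Mean over the seed voxels per (already ordered) subject."""
    seed_mask = np.asarray(seed_mask, bool)
    if not seed_mask.any():
        raise ValueError("empty seed cluster")
    if seed_mask.shape != vol4d.shape[1:]:
        raise ValueError("seed mask shape does not match the volume grid")
    return vol4d[:, seed_mask].mean(axis=1)


def _prepare_voxel_matrix(
    vol4d: np.ndarray,
    mask: np.ndarray,
    seed_series: np.ndarray,
    covariates,
    config: GCConfig,
):
    """Residualize + standardize seed and in-mask voxel series; drop flat voxels."""
    mask = np.asarray(mask, bool).copy()
    V = vol4d[:, mask]  # T x N
    flat = V.std(axis=0) == 0
    if flat.any():
        log.info("dropping %d zero-variance voxels from the analysis mask", flat.sum())
        idx = np.flatnonzero(mask.reshape(-1))
        m = mask.reshape(-1)
        m[idx[flat]] = False
        mask = m.reshape(mask.shape)
        V = V[:, ~flat]
    s = np.asarray(seed_series, float).copy()
    if covariates is not None:
        V = residualize(V, covariates)
        s = residualize(s, covariates)
    if config.standardize_series:
        V = standardize(V)
        s = standardize(s)
    return V, s, mask


def _gc_map(direction, seed_label, gc_flat, mask, affine):
    gc3d = np.full(mask.shape, np.nan)
    gc3d[mask] = gc_flat
    z3d = np.full(mask.shape, np.nan)
    if gc_flat.size >= 10:
        z3d[mask] = gc_to_z(gc_flat)
    else:
        log.info("mask too small for z-conversion (%d voxels); z left NaN",
                 gc_flat.size)
    return GCMap(
        direction=direction,
        seed_label=seed_label,
        gc=gc3d,
        z=z3d,
        mask=mask,
        affine=affine,
    )


def seed_to_map(
    seed_series: np.ndarray,
    vol4d: np.ndarray,
    mask: np.ndarray,
    covariates=None,
    config: GCConfig | None = None,
    *,
    seed_label: str = "seed",
    affine: np.ndarray | None = None,
) -> GCMap:
    """Seed as lagged predictor of every in-mask voxel."""
    config = config or GCConfig()
    V, s, mask = _prepare_voxel_matrix(vol4d, mask, seed_series, covariates, config)
    S = np.broadcast_to(s[:, None], V.shape)
    gc_flat = batched_lag1_paths(predictors=S, outcomes=V)
    return _gc_map("seed_to_map", seed_label, gc_flat, mask, affine)


def map_to_seed(
    vol4d: np.ndarray,
    seed_series: np.ndarray,
    mask: np.ndarray,
    covariates=None,
    config: GCConfig | None = None,
    *,
    seed_label: str = "seed",
    affine: np.ndarray | None = None,
) -> GCMap:
    """Every in-mask voxel as lagged predictor of the seed."""
    config = config or GCConfig()
    V, s, mask = _prepare_voxel_matrix(vol4d, mask, seed_series, covariates, config)
    S = np.broadcast_to(s[:, None], V.shape).copy()
    gc_flat = batched_lag1_paths(predictors=V, outcomes=S)
    return _gc_map("map_to_seed", seed_label, gc_flat, mask, affine)


def report_clusters(
    gcmap: GCMap,
    atlas=None,
    min_cluster_size: int = 10,
    config: GCConfig | None = None,
) -> list[ClusterRecord]:
    """Connected components of criterion-passing voxels.

    Each cluster reports its peak-|z| voxel's world coordinates, extent,
    gc and z at peak, and the atlas label under the peak.  Components
    smaller than ``min_cluster_size`` are dropped; an empty result is a
    valid outcome.
    """
    config = config or GCConfig()
    surviving = gcmap.surviving(config)
    if not surviving.any():
        return []
    lab, ncomp = ndimage.label(surviving, structure=CONN26)
    records: list[ClusterRecord] = []
    for k in range(1, ncomp + 1):
        comp = lab == k
        size = int(comp.sum())
        if size < min_cluster_size:
            continue
        zvals = np.where(comp, np.abs(gcmap.z), -np.inf)
        peak = np.unravel_index(np.argmax(zvals), zvals.shape)
        affine = gcmap.affine if gcmap.affine is not None else np.eye(4)
        world = (affine @ np.array([*peak, 1.0]))[:3]
        label_name = "unknown"
        if atlas is not None:
            lab_id = int(atlas.label_grid[peak])
            label_name = atlas.labels.get(lab_id, "background")
        records.append(
            ClusterRecord(
                peak_world_coords=tuple(float(c) for c in world),
                cluster_size=size,
                peak_stat=float(gcmap.z[peak]),
                atlas_label=label_name,
                sign="increase" if gcmap.gc[peak] > 0 else "decrease",
                peak_gc=float(gcmap.gc[peak]),
            )
        )
    records.sort(key=lambda r: r.cluster_size, reverse=True)
    return records
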