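"""Group-difference mapping and cognition correlation (seed identification).

A simplified voxel-based-morphometry stage: a per-voxel linear model
``volume ~ group + sex + age + education + tiv + months_post_rt`` gives a
t-map for the group term (patients minus controls); voxels below the
voxel-level p threshold form 26-connected clusters, and cluster-level
familywise error is controlled by a Freedman–Lane permutation null of the
maximum cluster extent: group labels are permuted within the
nuisance-residual framework, and observed clusters must exceed the 95th
percentile of the permuted maximum extents.  Permutation replaces
random-field-theory correction deliberately: it is assumption-light and
honours the same familywise error contract at desk scale.

The largest surviving cluster's atlas label is the seed region for the
causal structural covariance analysis; Spearman correlations (BH-FDR
corrected across the battery) relate the seed's volume to cognition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ClusterRecord",
    "GroupContrastMap",
    "group_contrast",
    "correlate_cognition",
]

CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ClusterRecord:
    """One suprathreshold cluster: peak location, extent, statistic, label."""

    peak_world_coords: tuple[float, float, float]
    cluster_size: int
    peak_stat: float
    atlas_label: str
    sign: str  # "decrease" | "increase"
    peak_gc: float = float("nan")

    def __post_init__(self) -> None:
        if self.cluster_size < 1:
            raise ValueError("cluster_size must be >= 1")
        if self.sign not in ("decrease", "increase"):
            raise ValueError(f"unknown sign {self.sign!r}")


@dataclass
class GroupContrastMap:
    """Voxel-wise group-difference statistics plus surviving clusters."""

    t_values: np.ndarray
    p_voxel: np.ndarray
    clusters: list[ClusterRecord]
    covariates_used: list[str]
    mask: np.ndarray
    cluster_extent_threshold: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))


def _group_t(Y: np.ndarray, X: np.ndarray, g_col: int) -> np.ndarray:
    """t statistic of the group column of design X for every voxel column of Y."""
    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(sigma2 * XtX_inv[g_col, g_col], 1e-300))
    return beta[g_col] / se


def _max_extent(supra: np.ndarray) -> int:
    lab, ncomp = ndimage.label(supra, structure=CONN26)
    if ncomp == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def group_contrast(
    patient_maps: dict[str, np.ndarray],
    control_maps: dict[str, np.ndarray],
    covariates: pd.DataFrame,
    atlas=None,
    voxel_p: float = 0.001,
    n_permutations: int = 1000,
    cluster_alpha: float = 0.05,
    rng_seed: int = 0,
    mask: np.ndarray | None = None,
) -> GroupContrastMap:
    """Two-group voxel-wise contrast with permutation cluster-extent FWE.

    ``covariates`` is indexed by subject id with columns sex (0/1), age,
    education, tiv and months_post_rt (0 for controls).  Patients are
    coded 1, controls 0; negative t means lower volume in patients.
    """
    if len(patient_maps) < 8 or len(control_maps) < 8:
        raise ValueError("need at least 8 subjects per group")
    if n_permutations < 100:
        warnings.warn(
            f"n_permutations = {n_permutations} < 100 gives a coarse cluster "
            "null; proceeding anyway",
            stacklevel=2,
        )
    ids = sorted(patient_maps) + sorted(control_maps)
    shapes = {np.asarray(v).shape for v in patient_maps.values()} | {
        np.asarray(v).shape for v in control_maps.values()
    }
    if len(shapes) != 1:
        raise ValueError(f"volume grids differ across subjects: {sorted(shapes)}")
    grid_shape = shapes.pop()
    if mask is None:
        if atlas is not None:
            if atlas.label_grid.shape != grid_shape:
                raise ValueError("atlas grid does not match the volume grid")
            mask = atlas.analysis_mask()
        else:
            mask = np.ones(grid_shape, bool)
    mask = np.asarray(mask, bool)

    allmaps = {**patient_maps, **control_maps}
    Y = np.stack([np.asarray(allmaps[s], float)[mask] for s in ids])
    missing = [s for s in ids if s not in covariates.index]
    if missing:
        raise KeyError(f"covariates missing for subjects: {missing}")
    cov_cols = ["sex", "age", "education", "tiv", "months_post_rt"]
    C = covariates.loc[ids, cov_cols].to_numpy(float)
    varying = np.ptp(C, axis=0) > 0  # constants duplicate the intercept
    C = C[:, varying]
    cov_cols = [c for c, keep in zip(cov_cols, varying) if keep]
    group = np.array([1.0 if s in patient_maps else 0.0 for s in ids])
    n = len(ids)
    X = np.column_stack([np.ones(n), group, C])
    g_col = 1
    dof = n - X.shape[1]

    tvals = _group_t(Y, X, g_col)
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    t_crit = stats.t.isf(voxel_p / 2, dof)

    # Freedman–Lane: permute nuisance-model residuals, keep nuisance fit
    Z = np.column_stack([np.ones(n), C])
    gamma = np.linalg.lstsq(Z, Y, rcond=None)[0]
    fitted = Z @ gamma
    resid = Y - fitted
    rng = np.random.default_rng(rng_seed)
    null_max = np.empty(n_permutations)
    supra_grid = np.zeros(grid_shape, bool)
    for b in range(n_permutations):
        perm = rng.permutation(n)
        t_b = _group_t(fitted + resid[perm], X, g_col)
        supra_grid[:] = False
        supra_grid[mask] = np.abs(t_b) > t_crit
        null_max[b] = _max_extent(supra_grid)
    extent_thr = float(np.quantile(null_max, 1 - cluster_alpha))

    t3d = np.full(grid_shape, np.nan)
    t3d[mask] = tvals
    p3d = np.full(grid_shape, np.nan)
    p3d[mask] = pvals
    supra_grid[:] = False
    supra_grid[mask] = np.abs(tvals) > t_crit
    lab, ncomp = ndimage.label(supra_grid, structure=CONN26)
    affine = atlas.voxel_to_world if atlas is not None else np.eye(4)
    clusters: list[ClusterRecord] = []
    for k in range(1, ncomp + 1):
        comp = lab == k
        size = int(comp.sum())
        if size <= extent_thr:
            continue
        stat = np.where(comp, np.abs(t3d), -np.inf)
        peak = np.unravel_index(np.argmax(stat), grid_shape)
        world = (affine @ np.array([*peak, 1.0]))[:3]
        label_name = "unknown"
        if atlas is not None:
            label_name = atlas.labels.get(int(atlas.label_grid[peak]), "background")
        clusters.append(
            ClusterRecord(
                peak_world_coords=tuple(float(c) for c in world),
                cluster_size=size,
                peak_stat=float(t3d[peak]),
                atlas_label=label_name,
                sign="decrease" if t3d[peak] < 0 else "increase",
            )
        )
    clusters.sort(key=lambda r: r.cluster_size, reverse=True)
    return GroupContrastMap(
        t_values=t3d,
        p_voxel=p3d,
        clusters=clusters,
        covariates_used=["group"] + cov_cols,
        mask=mask,
        cluster_extent_threshold=extent_thr,
        affine=np.asarray(affine, float),
    )


def correlate_cognition(
    feature_values,
    scores: pd.DataFrame,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation of a regional volume with each cognitive test.

    Missing scores are dropped pairwise; a zero-variance test is reported
    with NaN rho and a warning.  q is Benjamini–Hochberg across the
    battery; ``significant`` means q < ``fdr_q``.
    """
    feat = pd.Series(feature_values)
    if isinstance(scores, dict):
        scores = pd.DataFrame(scores)
    rows = []
    for test in scores.columns:
        pair = pd.concat([feat, scores[test]], axis=1, join="inner").dropna()
        n = len(pair)
        if n < 8:
            raise ValueError(f"test {test!r}: need >= 8 paired observations, got {n}")
        if pair.iloc[:, 1].nunique() == 1:
            warnings.warn(f"test {test!r} has zero score variance; rho undefined",
                          stacklevel=2)
            rows.append({"test": test, "n": n, "rho": np.nan, "p": np.nan})
            continue
        rho, p = stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
        rows.append({"test": test, "n": n, "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    out["q"] = np.nan
    if valid.any():
        out.loc[valid, "q"] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < fdr_q
    return out
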