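"""Synthetic post-radiotherapy cohorts with planted causal structure.

Emulates the study design the pipeline targets: ~38 patients scanned once
each at irregular times after radiotherapy (0.5–108 months, right-skewed)
plus ~23 healthy controls, with per-subject covariates (age, sex,
education, total intracranial volume), a cognitive battery, and regional
gray-matter volumes.

Volumes follow a lag-1 linear system over the time-sorted patient
sequence — the same order-1 model the GC engine estimates, which makes
parameter recovery well posed.  Each ROI's volume decomposes into a
deterministic part (baseline + atrophy slope x months + covariate
effects − patient group deficit) and a latent deviation d:

    d[t, roi] = sum_edges c * d[t-1, source] + rho_roi * d[t-1, roi] + eps

with eps ~ N(0, noise_sd) for every ROI.  Planted couplings act on the
source's *deviation*, so a coupling is directly a lag-1 path on the
latent scale.  Controls get baseline + covariate effects + noise only
(no time variable, no dynamics).

All randomness flows from one seed through numpy SeedSequence spawning;
identical config (including seed) reproduces output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "SubjectRecord",
    "SyntheticAtlas",
    "CovariateEffect",
    "generate_cohort",
    "make_synthetic_atlas",
    "rasterize_to_maps",
    "DEFAULT_ROI_NAMES",
    "COGNITIVE_TESTS",
]

#: Region labels mirroring the ROI set of the targeted analysis
#: (AAL-style abbreviations; the relay/sink temporal regions first).
DEFAULT_ROI_NAMES = (
    "TPOmid.L",
    "ITG.L",
    "PHG.L",
    "PHG.R",
    "CAU.L",
    "CAU.R",
    "REC.R",
    "PUT.L",
    "PCUN.L",
    "CC1.R",
)

#: test name -> (patient mean, control mean, sd).  Rough magnitudes of a
#: standard battery in a post-RT cohort vs healthy controls.
COGNITIVE_TESTS: dict[str, tuple[float, float, float]] = {
    "MoCA-B": (26.0, 28.0, 1.5),
    "AVLT_immediate": (20.1, 25.4, 3.5),
    "AVLT_5min": (8.3, 9.9, 1.8),
    "AVLT_20min": (8.0, 9.9, 1.6),
    "AVLT_recognition": (10.6, 11.8, 1.5),
    "TMT_A": (45.6, 32.4, 12.0),
    "TMT_B": (39.9, 27.9, 11.0),
    "DSST": (40.0, 53.7, 10.0),
    "DST_forward": (7.7, 8.6, 1.3),
    "DST_backward": (4.4, 5.6, 1.1),
}


@dataclass(frozen=True)
class CovariateEffect:
    """Linear loadings of one ROI's volume on the subject covariates."""

    age_slope: float = 0.0
    sex_offset: float = 0.0
    education_slope: float = 0.0
    tiv_slope: float = 0.0


@dataclass
class SubjectRecord:
    """One participant's metadata, covariates and cognitive scores."""

    subject_id: str
    group: str  # "patient" | "control"
    age: float
    sex: str  # "M" | "F"
    education: float
    tiv: float
    months_post_rt: float | None = None
    cognitive_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"unknown group {self.group!r}")
        if (self.months_post_rt is not None) != (self.group == "patient"):
            raise ValueError(
                f"subject {self.subject_id!r}: months_post_rt must be present "
                "iff group == 'patient'"
            )
        if min(self.age, self.education, self.tiv) <= 0:
            raise ValueError(
                f"subject {self.subject_id!r}: age, education and tiv must be positive"
            )


@dataclass(frozen=True)
class SimConfig:
    """Cohort generator settings; defaults emulate the target study scale."""

    n_patients: int = 38
    n_controls: int = 23
    time_range_months: tuple[float, float] = (0.5, 108.0)
    roi_names: tuple[str, ...] = DEFAULT_ROI_NAMES
    planted_edges: tuple[tuple[str, str, float], ...] = ()
    noise_sd: float = 0.3
    covariate_effects: Mapping[str, CovariateEffect] = field(default_factory=dict)
    atrophy_profile: Mapping[str, float] = field(default_factory=dict)
    persistence: Mapping[str, float] = field(default_factory=dict)
    group_deficit: Mapping[str, float] = field(default_factory=dict)
    baseline_volume: float = 10.0
    months_post_rt: tuple[float, ...] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 8:
            raise ValueError(
                f"n_patients = {self.n_patients} < 8: too short a pseudo-time "
                "series for a lag-1 GC fit"
            )
        lo, hi = self.time_range_months
        if not (0 < lo < hi):
            raise ValueError("time_range_months must satisfy 0 < min < max")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        rois = set(self.roi_names)
        if len(rois) != len(self.roi_names):
            raise ValueError("roi_names must be unique")
        for src, tgt, _ in self.planted_edges:
            if src not in rois or tgt not in rois:
                raise ValueError(
                    f"planted edge ({src!r} -> {tgt!r}) references an undeclared ROI"
                )
        for m in (self.covariate_effects, self.atrophy_profile,
                  self.persistence, self.group_deficit):
            unknown = set(m) - rois
            if unknown:
                raise ValueError(f"config references undeclared ROI(s): {sorted(unknown)}")
        if self.months_post_rt is not None:
            if len(self.months_post_rt) != self.n_patients:
                raise ValueError("explicit months_post_rt must have one entry per patient")
            if any(not (lo <= t <= hi) for t in self.months_post_rt):
                raise ValueError("explicit months_post_rt outside time_range_months")


def _draw_subjects(config: SimConfig, rng: np.random.Generator) -> list[SubjectRecord]:
    records: list[SubjectRecord] = []
    if config.months_post_rt is not None:
        months = np.asarray(config.months_post_rt, float)
    else:
        lo, hi = config.time_range_months
        # log-uniform: stand-in for the right-skewed post-RT time distribution
        months = np.exp(rng.uniform(np.log(lo), np.log(hi), config.n_patients))
    for i in range(config.n_patients):
        records.append(
            SubjectRecord(
                subject_id=f"P{i + 1:03d}",
                group="patient",
                age=float(np.clip(np.round(rng.normal(49.0, 9.0), 1), 27.0, 63.0)),
                sex="M" if rng.random() < 33 / 38 else "F",
                education=float(np.clip(np.round(rng.normal(12.0, 3.0)), 6, 20)),
                tiv=float(np.round(rng.normal(1450.0, 120.0), 1)),
                months_post_rt=float(np.round(months[i], 2)),
            )
        )
    for i in range(config.n_controls):
        records.append(
            SubjectRecord(
                subject_id=f"C{i + 1:03d}",
                group="control",
                age=float(np.clip(np.round(rng.normal(40.0, 11.0), 1), 24.0, 61.0)),
                sex="M" if rng.random() < 16 / 23 else "F",
                education=float(np.clip(np.round(rng.normal(14.0, 3.0)), 6, 20)),
                tiv=float(np.round(rng.normal(1450.0, 120.0), 1)),
            )
        )
    return records


def _cognitive_scores(group: str, rng: np.random.Generator) -> dict[str, float]:
    out = {}
    for test, (pat_mu, ctl_mu, sd) in COGNITIVE_TESTS.items():
        mu = pat_mu if group == "patient" else ctl_mu
        out[test] = float(np.round(max(rng.normal(mu, sd), 0.0), 1))
    return out


def _covariate_part(config: SimConfig, rec: SubjectRecord) -> np.ndarray:
    part = np.zeros(len(config.roi_names))
    for j, roi in enumerate(config.roi_names):
        eff = config.covariate_effects.get(roi)
        if eff is None:
            continue
        sex01 = 1.0 if rec.sex == "M" else 0.0
        part[j] = (
            eff.age_slope * rec.age
            + eff.sex_offset * sex01
            + eff.education_slope * rec.education
            + eff.tiv_slope * rec.tiv
        )
    return part


def generate_cohort(config: SimConfig) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Generate subject records and the subjects x ROIs volume table.

    Returns exactly ``n_patients + n_controls`` records and a DataFrame
    with one row per subject (sorted by subject_id) and one column per
    declared ROI.  Deterministic given the config (including its seed).
    """
    ss = np.random.SeedSequence(config.rng_seed)
    rng_meta, rng_scores, rng_dyn, rng_ctrl = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    records = _draw_subjects(config, rng_meta)
    for rec in records:
        rec.cognitive_scores = _cognitive_scores(rec.group, rng_scores)

    R = len(config.roi_names)
    idx = {roi: j for j, roi in enumerate(config.roi_names)}
    atrophy = np.array([config.atrophy_profile.get(r, 0.0) for r in config.roi_names])
    deficit = np.array([config.group_deficit.get(r, 0.0) for r in config.roi_names])
    rho = np.array([config.persistence.get(r, 0.0) for r in config.roi_names])

    patients = [r for r in records if r.group == "patient"]
    order = sorted(patients, key=lambda p: (p.months_post_rt, p.subject_id))
    T = len(order)
    dev = np.zeros((T, R))
    for t in range(T):
        dev[t] = rng_dyn.normal(0.0, config.noise_sd, R)
        if t > 0:
            dev[t] += rho * dev[t - 1]
            for src, tgt, c in config.planted_edges:
                dev[t, idx[tgt]] += c * dev[t - 1, idx[src]]

    volumes: dict[str, np.ndarray] = {}
    for t, rec in enumerate(order):
        volumes[rec.subject_id] = (
            config.baseline_volume
            + atrophy * rec.months_post_rt
            - deficit
            + _covariate_part(config, rec)
            + dev[t]
        )
    for rec in records:
        if rec.group == "control":
            volumes[rec.subject_id] = (
                config.baseline_volume
                + _covariate_part(config, rec)
                + rng_ctrl.normal(0.0, config.noise_sd, R)
            )

    ids = sorted(volumes)
    table = pd.DataFrame(
        np.vstack([volumes[s] for s in ids]),
        index=pd.Index(ids, name="subject_id"),
        columns=list(config.roi_names),
    )
    return records, table


@dataclass
class SyntheticAtlas:
    """Labeled integer grid (0 = background) with a voxel-to-world affine."""

    label_grid: np.ndarray
    voxel_to_world: np.ndarray
    labels: dict[int, str]

    def __post_init__(self) -> None:
        self.label_grid = np.asarray(self.label_grid)
        if self.label_grid.ndim != 3 or min(self.label_grid.shape) < 4:
            raise ValueError("label grid must be 3D with every axis >= 4")
        present = set(np.unique(self.label_grid)) - {0}
        missing = present - set(self.labels)
        if missing:
            raise ValueError(f"grid labels without a name entry: {sorted(missing)}")

    @property
    def names(self) -> list[str]:
        return [self.labels[k] for k in sorted(self.labels)]

    def label_of(self, name: str) -> int:
        for k, v in self.labels.items():
            if v == name:
                return k
        raise KeyError(f"unknown ROI name {name!r}")

    def mask(self, name: str) -> np.ndarray:
        return self.label_grid == self.label_of(name)

    def analysis_mask(self) -> np.ndarray:
        """Union of all labeled voxels."""
        return self.label_grid > 0


def make_synthetic_atlas(
    shape: tuple[int, int, int],
    n_rois: int,
    rng_seed: int = 0,
    roi_names: Sequence[str] | None = None,
) -> SyntheticAtlas:
    """Pack ``n_rois`` disjoint contiguous blocks into a grid.

    The grid is divided into equal cells with a one-voxel separating
    margin; a seeded permutation assigns labels to cells, so the layout is
    deterministic.  Raises when the grid cannot host the requested count.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 4:
        raise ValueError("shape must be 3D with every axis >= 4")
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    if roi_names is not None and len(roi_names) != n_rois:
        raise ValueError("roi_names length must equal n_rois")
    k = int(np.ceil(n_rois ** (1 / 3)))
    dims = None
    for ka in range(1, shape[0] + 1):
        for kb in range(1, shape[1] + 1):
            kc = int(np.ceil(n_rois / (ka * kb)))
            if ka * kb * kc >= n_rois and all(
                s // kk >= 3 for s, kk in zip(shape, (ka, kb, kc))
            ):
                dims = (ka, kb, kc)
                break
        if dims and ka >= k:
            break
    if dims is None or any(s // kk < 3 for s, kk in zip(shape, dims)):
        raise ValueError(f"cannot pack {n_rois} blocks into grid of shape {shape}")
    cells = [
        (ia, ib, ic)
        for ia in range(dims[0])
        for ib in range(dims[1])
        for ic in range(dims[2])
    ]
    rng = np.random.default_rng(rng_seed)
    chosen = [cells[i] for i in rng.permutation(len(cells))[:n_rois]]
    grid = np.zeros(shape, dtype=np.int16)
    sizes = [s // kk for s, kk in zip(shape, dims)]
    names = list(roi_names) if roi_names is not None else [
        f"ROI{i + 1:02d}" for i in range(n_rois)
    ]
    labels: dict[int, str] = {}
    for lab, cell in enumerate(chosen, start=1):
        sl = tuple(
            slice(c * sz, c * sz + sz - 1)  # leave a 1-voxel margin
            for c, sz in zip(cell, sizes)
        )
        grid[sl] = lab
        labels[lab] = names[lab - 1]
    affine = np.diag([4.0, 4.0, 4.0, 1.0])
    affine[:3, 3] = -2.0 * np.asarray(shape, float)  # roughly centered world origin
    return SyntheticAtlas(label_grid=grid, voxel_to_world=affine, labels=labels)


def rasterize_to_maps(
    table: pd.DataFrame,
    atlas: SyntheticAtlas,
    voxel_noise_sd: float = 0.0,
    rng_seed: int = 0,
) -> dict[str, np.ndarray]:
    """Paint each subject's ROI values into the atlas blocks.

    Every voxel of a label gets that subject's ROI value plus i.i.d.
    Gaussian voxel noise; background voxels stay exactly 0.
    """
    if voxel_noise_sd < 0:
        raise ValueError("voxel_noise_sd must be >= 0")
    unknown = [c for c in table.columns if c not in atlas.names]
    if unknown:
        raise ValueError(f"table columns not present in the atlas: {unknown}")
    rng = np.random.default_rng(rng_seed)
    masks = {roi: atlas.mask(roi) for roi in table.columns}
    labeled = atlas.analysis_mask()
    out: dict[str, np.ndarray] = {}
    for sid in table.index:
        vol = np.zeros(atlas.label_grid.shape, dtype=float)
        for roi in table.columns:
            vol[masks[roi]] = table.at[sid, roi]
        if voxel_noise_sd > 0:
            vol[labeled] += rng.normal(0.0, voxel_noise_sd, int(labeled.sum()))
        out[str(sid)] = vol
    return out
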