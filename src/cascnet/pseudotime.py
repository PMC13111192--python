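"""Pseudo-time ordering and nuisance removal.

Cross-sectional patients become a pseudo-time series by sorting ascending
on months post-radiotherapy; the irregular spacing enters downstream
models as an "interval" covariate (the gap between consecutive
pseudo-time points, assigned to the later observation, first entry 0).
Nuisance covariates — sex, age, education, total intracranial volume and
the interval — are regressed out of every feature column once, over the
full series, before any lagged model is fit; series are then z-scored so
fitted path coefficients live on a common unitless scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PseudoTimeSeries",
    "order_by_time",
    "covariate_matrix",
    "residualize",
    "standardize",
    "build_pseudotime_series",
]

COVARIATE_COLUMNS = ("intercept", "sex", "age", "education", "tiv", "interval")


@dataclass
class PseudoTimeSeries:
    """Feature matrix ordered ascending by months post-RT."""

    order_index: list[str]
    times: np.ndarray
    intervals: np.ndarray
    values: np.ndarray  # T x F
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.intervals = np.asarray(self.intervals, float)
        self.values = np.asarray(self.values, float)
        T = len(self.order_index)
        if self.values.ndim != 2 or self.values.shape[0] != T:
            raise ValueError("values must be T x F aligned with order_index")
        if T < 8 or self.values.shape[1] < 1:
            raise ValueError("need T >= 8 pseudo-time points and F >= 1 features")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be non-decreasing")
        if np.any(self.intervals < 0):
            raise ValueError("intervals must be non-negative")


def order_by_time(patients) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Sort patients ascending by months post-RT.

    Ties are broken by subject_id (lexicographic), making the ordering a
    pure function of (months_post_rt, subject_id).  Returns the ordered
    subject ids, their times, and consecutive intervals (first entry 0).
    """
    for p in patients:
        if p.months_post_rt is None:
            raise ValueError(f"subject {p.subject_id!r} has no months_post_rt")
    ranked = sorted(patients, key=lambda p: (p.months_post_rt, p.subject_id))
    ids = [p.subject_id for p in ranked]
    times = np.array([p.months_post_rt for p in ranked], float)
    intervals = np.concatenate([[0.0], np.diff(times)])
    return ids, times, intervals


def covariate_matrix(patients_ordered, intervals: np.ndarray) -> pd.DataFrame:
    """Nuisance design for the ordered patient sequence.

    Columns: intercept, sex (F=0/M=1), age, education, tiv, interval.
    Rows align with the pseudo-time order.
    """
    rows = []
    for p, dt in zip(patients_ordered, np.asarray(intervals, float), strict=True):
        rows.append(
            {
                "intercept": 1.0,
                "sex": 1.0 if p.sex == "M" else 0.0,
                "age": float(p.age),
                "education": float(p.education),
                "tiv": float(p.tiv),
                "interval": float(dt),
            }
        )
    return pd.DataFrame(rows, index=[p.subject_id for p in patients_ordered])


def _drop_constant_zero(C: np.ndarray, names: list[str]):
    """Drop zero columns and redundant constants (keep one intercept column)."""
    keep, have_const = [], False
    for i in range(C.shape[1]):
        col = C[:, i]
        if np.all(col == 0):
            continue
        if np.ptp(col) == 0:
            if have_const:
                continue
            have_const = True
        keep.append(i)
    return C[:, keep], [names[i] for i in keep]


def residualize(values: np.ndarray, covariates) -> np.ndarray:
    """OLS residuals of each feature column against the covariate columns.

    The covariates may be a DataFrame (column names used in error
    messages) or a plain T x C array.  Raises when the covariate matrix is
    rank deficient, naming the collinear columns.
    """
    V = np.asarray(values, float)
    one_d = V.ndim == 1
    V = V.reshape(-1, 1) if one_d else V
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        C = covariates.to_numpy(float)
    else:
        C = np.asarray(covariates, float)
        names = [f"c{i}" for i in range(C.shape[1])]
    if C.shape[0] != V.shape[0]:
        raise ValueError("covariate rows must match the number of pseudo-time points")
    if V.shape[0] <= C.shape[1] + 2:
        raise ValueError(
            f"too few pseudo-time points ({V.shape[0]}) for "
            f"{C.shape[1]} covariate columns"
        )
    C, names = _drop_constant_zero(C, names)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        # name the columns that add no rank over their predecessors
        bad, rank = [], 0
        for j in range(C.shape[1]):
            r = np.linalg.matrix_rank(C[:, : j + 1])
            if r == rank:
                bad.append(names[j])
            rank = r
        raise ValueError(f"rank-deficient covariates; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(C, V, rcond=None)
    R = V - C @ beta
    return R.ravel() if one_d else R


def standardize(values: np.ndarray, feature_ids=None) -> np.ndarray:
    """Z-score each column (population convention: divisor T).

    A zero-variance column is an error naming the feature.
    """
    V = np.asarray(values, float)
    one_d = V.ndim == 1
    V = V.reshape(-1, 1) if one_d else V
    sd = V.std(axis=0)
    if np.any(sd == 0):
        ids = list(feature_ids) if feature_ids is not None else list(range(V.shape[1]))
        bad = [ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance feature(s): {bad}")
    Z = (V - V.mean(axis=0)) / sd
    return Z.ravel() if one_d else Z


def build_pseudotime_series(patients, table: pd.DataFrame) -> PseudoTimeSeries:
    """Order a per-subject feature table into a PseudoTimeSeries.

    ``table`` is subjects x features indexed by subject_id; only the given
    patients (which must all carry months_post_rt) are used.
    """
    ids, times, intervals = order_by_time(patients)
    missing = [s for s in ids if s not in table.index]
    if missing:
        raise KeyError(f"subjects absent from the feature table: {missing}")
    values = table.loc[ids].to_numpy(float)
    return PseudoTimeSeries(
        order_index=ids,
        times=times,
        intervals=intervals,
        values=values,
        feature_ids=[str(c) for c in table.columns],
    )
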