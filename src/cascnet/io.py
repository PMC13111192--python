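"""Readers and writers for the pipeline's on-disk dialect.

TSV for tables (metadata, ROI volumes, label lookup, edge lists, degree
and cluster tables), NIfTI-1 for volumes and the atlas, JSON for the run
manifest.  Writers prepend comment headers carrying the config hash and
seed so every artifact is traceable; readers validate schemas strictly
and refuse silently malformed input.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .network import DirectedNetwork, network_from_edge_table
from .sim import SubjectRecord, SyntheticAtlas

__all__ = [
    "read_metadata",
    "write_metadata",
    "read_roi_table",
    "write_roi_table",
    "read_volumes",
    "write_volumes",
    "read_atlas",
    "write_atlas",
    "read_network",
    "write_network",
    "write_degree_table",
    "write_cluster_table",
    "write_table",
    "read_table",
]

METADATA_COLUMNS = ["subject_id", "group", "age", "sex", "education", "tiv",
                    "months_post_rt"]


def _header_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    parts = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"# cascnet {parts}\n"


def write_table(df: pd.DataFrame, path, meta: dict | None = None,
                index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_metadata(records: list[SubjectRecord], path, meta: dict | None = None) -> None:
    score_names = sorted({k for r in records for k in r.cognitive_scores})
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "group": r.group,
            "age": r.age,
            "sex": r.sex,
            "education": r.education,
            "tiv": r.tiv,
            "months_post_rt": "" if r.months_post_rt is None else r.months_post_rt,
        }
        for s in score_names:
            row[s] = r.cognitive_scores.get(s, "")
        rows.append(row)
    write_table(pd.DataFrame(rows), path, meta=meta, index=False)


def read_metadata(path) -> list[SubjectRecord]:
    df = read_table(path)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata file {path}: missing columns {missing}")
    score_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    records = []
    for i, row in df.iterrows():
        group = str(row["group"])
        if group not in ("patient", "control"):
            raise ValueError(
                f"metadata row {i} (subject {row['subject_id']!r}): "
                f"unknown group {group!r}"
            )
        months = row["months_post_rt"]
        has_months = pd.notna(months) and str(months) != ""
        if group == "control" and has_months:
            raise ValueError(
                f"metadata row {i}: control {row['subject_id']!r} carries "
                "months_post_rt"
            )
        if group == "patient" and not has_months:
            raise ValueError(
                f"metadata row {i}: patient {row['subject_id']!r} lacks "
                "months_post_rt"
            )
        sex = str(row["sex"])
        if sex not in ("M", "F"):
            raise ValueError(f"metadata row {i}: sex must be M or F, got {sex!r}")
        scores = {
            s: float(row[s]) for s in score_cols if pd.notna(row[s]) and row[s] != ""
        }
        records.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=group,
                age=float(row["age"]),
                sex=sex,
                education=float(row["education"]),
                tiv=float(row["tiv"]),
                months_post_rt=float(months) if group == "patient" else None,
                cognitive_scores=scores,
            )
        )
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"metadata file {path}: duplicate subject ids")
    return records


def write_roi_table(table: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_table(table, path, meta=meta, index=True)


def read_roi_table(path) -> pd.DataFrame:
    df = read_table(path, index_col=0)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            cell = df.index[bad.argmax()]
            raise ValueError(
                f"ROI table {path}: non-numeric value {df[col][bad].iloc[0]!r} "
                f"at row {cell!r}, column {col!r}"
            )
        if coerced.isna().any():
            cell = df.index[coerced.isna().argmax()]
            raise ValueError(f"ROI table {path}: missing value at row {cell!r}, "
                             f"column {col!r}")
        df[col] = coerced
    df.index = df.index.astype(str)
    df.index.name = "subject_id"
    return df


def write_volumes(maps: dict[str, np.ndarray], affine: np.ndarray, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sid, vol in maps.items():
        img = nib.Nifti1Image(np.asarray(vol, np.float32), np.asarray(affine, float))
        nib.save(img, out_dir / f"{sid}.nii")


def read_volumes(vol_dir, atlas: SyntheticAtlas | None = None) -> dict[str, np.ndarray]:
    vol_dir = Path(vol_dir)
    paths = sorted(vol_dir.glob("*.nii")) + sorted(vol_dir.glob("*.nii.gz"))
    if not paths:
        raise FileNotFoundError(f"no NIfTI volumes under {vol_dir}")
    out: dict[str, np.ndarray] = {}
    for p in paths:
        img = nib.load(p)
        data = np.asarray(img.get_fdata(), float)
        if atlas is not None:
            if data.shape != atlas.label_grid.shape:
                raise ValueError(
                    f"{p.name}: grid {data.shape} does not match atlas "
                    f"{atlas.label_grid.shape}"
                )
            if not np.allclose(img.affine, atlas.voxel_to_world, atol=1e-6):
                raise ValueError(f"{p.name}: affine does not match the atlas")
        out[p.name.removesuffix(".gz").removesuffix(".nii")] = data
    return out


def write_atlas(atlas: SyntheticAtlas, nifti_path, labels_path) -> None:
    img = nib.Nifti1Image(
        atlas.label_grid.astype(np.int16), np.asarray(atlas.voxel_to_world, float)
    )
    Path(nifti_path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, nifti_path)
    df = pd.DataFrame(
        [(k, v) for k, v in sorted(atlas.labels.items())],
        columns=["label_id", "roi_name"],
    )
    write_table(df, labels_path, index=False)


def read_atlas(nifti_path, labels_path) -> SyntheticAtlas:
    img = nib.load(nifti_path)
    grid = np.asarray(img.dataobj).astype(np.int16)
    df = read_table(labels_path)
    if list(df.columns) != ["label_id", "roi_name"]:
        raise ValueError(
            f"label lookup {labels_path}: expected columns [label_id, roi_name], "
            f"got {list(df.columns)}"
        )
    labels = {int(r.label_id): str(r.roi_name) for r in df.itertuples()}
    return SyntheticAtlas(label_grid=grid, voxel_to_world=img.affine, labels=labels)


def write_network(net: DirectedNetwork, path, meta: dict | None = None,
                  graphml_path=None) -> None:
    write_table(net.to_frame(), path, meta=meta, index=False)
    if graphml_path is not None:
        import networkx as nx

        nx.write_graphml(net.to_networkx(), graphml_path)


def read_network(path, threshold: float = 0.39,
                 nodes: list[str] | None = None) -> DirectedNetwork:
    return network_from_edge_table(read_table(path), threshold=threshold, nodes=nodes)


def write_degree_table(table: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_table(table, path, meta=meta, index=True)


def write_cluster_table(clusters, path, meta: dict | None = None) -> None:
    rows = []
    for c in clusters:
        x, y, z = c.peak_world_coords
        rows.append(
            {
                "atlas_label": c.atlas_label,
                "peak_x": x,
                "peak_y": y,
                "peak_z": z,
                "peak_stat": c.peak_stat,
                "peak_gc": c.peak_gc,
                "cluster_size": c.cluster_size,
                "sign": c.sign,
            }
        )
    cols = ["atlas_label", "peak_x", "peak_y", "peak_z", "peak_stat", "peak_gc",
            "cluster_size", "sign"]
    write_table(pd.DataFrame(rows, columns=cols), path, meta=meta, index=False)


def write_manifest(manifest: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
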