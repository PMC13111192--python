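"""ROI-to-ROI directed causal network and source/sink classification.

Every ordered ROI pair gets a bivariate signed lag-1 path coefficient;
edges whose |GC| clears the magnitude threshold (default 0.39, matching
the voxel-wise criterion) form a directed network.  Binarized out-degree
(paths projecting from a region), in-degree (paths projecting into it)
and their difference out − in classify regions: positive out − in marks a
source-like region whose structural change statistically precedes change
elsewhere, negative marks a sink-like region that receives it.

Because bivariate estimates are sensitive to indirect pathways and common
drivers, :func:`multivariate_robustness` refits each target conditioning
on all other ROIs' lagged values and reports how well edge signs and
node roles agree with the bivariate network.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gc import GCConfig, gc_to_z, signed_gc_bivariate, signed_gc_multivariate
from .pseudotime import residualize, standardize

__all__ = [
    "Edge",
    "DirectedNetwork",
    "extract_roi_series",
    "build_roi_network",
    "compute_degrees",
    "multivariate_robustness",
    "network_from_edge_table",
    "load_reference_edges",
]


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    gc: float
    z: float


@dataclass
class DirectedNetwork:
    """Thresholded directed ROI graph with signed edge weights."""

    nodes: list[str]
    edges: list[Edge]
    threshold_used: float

    def __post_init__(self) -> None:
        known = set(self.nodes)
        seen = set()
        for e in self.edges:
            if e.source == e.target:
                raise ValueError(f"self-edge on {e.source!r}")
            if e.source not in known or e.target not in known:
                raise ValueError(f"edge {e.source}->{e.target} references unknown node")
            if (e.source, e.target) in seen:
                raise ValueError(f"duplicate edge {e.source}->{e.target}")
            if abs(e.gc) <= self.threshold_used:
                raise ValueError(
                    f"edge {e.source}->{e.target} has |gc| = {abs(e.gc):.3f} "
                    f"<= threshold {self.threshold_used}"
                )
            seen.add((e.source, e.target))

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.source, e.target, gc=e.gc, z=e.z)
        return g

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.source, e.target, e.gc, e.z) for e in self.edges],
            columns=["source", "target", "gc", "z"],
        )


def extract_roi_series(
    source,
    atlas=None,
    roi_list=None,
    order_index=None,
) -> pd.DataFrame:
    """Per-subject ROI means, pseudo-time ordered (T x R).

    ``source`` is either a subjects x ROIs table (DataFrame) or a dict of
    subject id -> 3D volume, in which case ``atlas`` supplies the label
    masks.  ``order_index`` gives the pseudo-time subject order; column
    order follows ``roi_list``.
    """
    if roi_list is None:
        raise ValueError("roi_list is required")
    roi_list = list(roi_list)
    if isinstance(source, pd.DataFrame):
        unknown = [r for r in roi_list if r not in source.columns]
        if unknown:
            raise KeyError(f"unknown ROI(s): {unknown}")
        ids = list(order_index) if order_index is not None else list(source.index)
        return source.loc[ids, roi_list].copy()
    if atlas is None:
        raise ValueError("atlas is required when extracting from volumes")
    unknown = [r for r in roi_list if r not in atlas.names]
    if unknown:
        raise KeyError(f"unknown ROI(s): {unknown}")
    ids = list(order_index) if order_index is not None else sorted(source)
    masks = {r: atlas.mask(r) for r in roi_list}
    rows = [[float(source[s][masks[r]].mean()) for r in roi_list] for s in ids]
    return pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"), columns=roi_list)


def _z_or_nan(gmat: np.ndarray) -> np.ndarray:
    """Standardize over all ordered pairs; below 10 pairs z stays NaN."""
    mask = ~np.isnan(gmat)
    if mask.sum() >= 10:
        return gc_to_z(gmat, mask=mask)
    return np.full(gmat.shape, np.nan)


def _prepare(values: np.ndarray, covariates, config: GCConfig, feature_ids):
    if covariates is not None:
        values = residualize(values, covariates)
    if config.standardize_series:
        values = standardize(values, feature_ids)
    return values


def build_roi_network(
    roi_series: pd.DataFrame,
    covariates=None,
    config: GCConfig | None = None,
) -> DirectedNetwork:
    """Bivariate signed GC over every ordered ROI pair, thresholded on |GC|.

    Edge z-values standardize the GC coefficients over all R(R-1) ordered
    pairs (the network-level analogue of map-level z-conversion).
    """
    config = config or GCConfig()
    rois = [str(c) for c in roi_series.columns]
    R = len(rois)
    if R < 2:
        raise ValueError("need at least 2 ROIs")
    V = _prepare(roi_series.to_numpy(float), covariates, config, rois)
    # estimator-level standardization already applied on the full series
    cfg_fit = config.with_(standardize_series=False)
    gmat = np.full((R, R), np.nan)
    for i in range(R):
        for j in range(R):
            if i == j:
                continue
            est = signed_gc_bivariate(
                V[:, i], V[:, j], cfg_fit, source=rois[i], target=rois[j]
            )
            gmat[i, j] = est.gc
    zmat = _z_or_nan(gmat)
    edges = [
        Edge(rois[i], rois[j], float(gmat[i, j]), float(zmat[i, j]))
        for i in range(R)
        for j in range(R)
        if i != j and abs(gmat[i, j]) > config.gc_threshold
    ]
    return DirectedNetwork(nodes=rois, edges=edges, threshold_used=config.gc_threshold)


def compute_degrees(net: DirectedNetwork) -> pd.DataFrame:
    """Binarized degree table with source/sink roles.

    Columns: out_degree, in_degree, out_in (= out − in), role
    (source-like / sink-like / balanced by strict sign of out − in) and a
    transition_flag heuristic marking the node that both sends and
    receives and has the maximum in-degree among sender nodes (a region
    relaying causal influence from sources toward sinks).
    """
    out = {n: 0 for n in net.nodes}
    inn = {n: 0 for n in net.nodes}
    for e in net.edges:
        out[e.source] += 1
        inn[e.target] += 1
    rows = []
    senders_in = [inn[n] for n in net.nodes if out[n] >= 1]
    max_in_among_senders = max(senders_in, default=0)
    for n in net.nodes:
        oi = out[n] - inn[n]
        role = "source-like" if oi > 0 else "sink-like" if oi < 0 else "balanced"
        transition = (
            out[n] >= 1
            and inn[n] >= 1
            and inn[n] == max_in_among_senders
            and max_in_among_senders > 0
        )
        rows.append(
            {
                "roi": n,
                "out_degree": out[n],
                "in_degree": inn[n],
                "out_in": oi,
                "role": role,
                "transition_flag": bool(transition),
            }
        )
    return pd.DataFrame(rows).set_index("roi")


def multivariate_robustness(
    roi_series: pd.DataFrame,
    covariates=None,
    config: GCConfig | None = None,
) -> tuple[DirectedNetwork, pd.DataFrame, dict]:
    """Conditional (multivariate) network and its agreement with the bivariate one.

    For each target ROI one joint fit conditions on all other ROIs' lagged
    values; edges are thresholded as in the bivariate analysis.  The
    agreement report gives edge sign agreement on shared edges and the
    fraction of ROIs keeping their bivariate role.
    """
    config = config or GCConfig()
    rois = [str(c) for c in roi_series.columns]
    R = len(rois)
    T = len(roi_series)
    if R + 5 >= T:
        raise ValueError(
            f"{R} ROIs with T = {T} pseudo-time points is unfittable for the "
            "multivariate model; reduce the ROI count (need R + 5 < T)"
        )
    V = _prepare(roi_series.to_numpy(float), covariates, config, rois)
    cfg_fit = config.with_(standardize_series=False)
    gmat = np.full((R, R), np.nan)
    for j, tgt in enumerate(rois):
        src_idx = [i for i in range(R) if i != j]
        ests = signed_gc_multivariate(
            V[:, src_idx],
            V[:, j],
            cfg_fit,
            source_names=[rois[i] for i in src_idx],
            target=tgt,
        )
        for i, est in zip(src_idx, ests):
            gmat[i, j] = est.gc
    zmat = _z_or_nan(gmat)
    edges = [
        Edge(rois[i], rois[j], float(gmat[i, j]), float(zmat[i, j]))
        for i in range(R)
        for j in range(R)
        if i != j and abs(gmat[i, j]) > config.gc_threshold
    ]
    net_mv = DirectedNetwork(nodes=rois, edges=edges, threshold_used=config.gc_threshold)
    deg_mv = compute_degrees(net_mv)

    net_bv = build_roi_network(roi_series, covariates, config)
    deg_bv = compute_degrees(net_bv)
    bv = {(e.source, e.target): e.gc for e in net_bv.edges}
    mv = {(e.source, e.target): e.gc for e in net_mv.edges}
    common = set(bv) & set(mv)
    sign_agree = (
        float(np.mean([np.sign(bv[k]) == np.sign(mv[k]) for k in common]))
        if common
        else float("nan")
    )
    role_agree = float(np.mean(deg_bv["role"] == deg_mv["role"]))
    report = {
        "n_edges_bivariate": len(net_bv.edges),
        "n_edges_multivariate": len(net_mv.edges),
        "n_common_edges": len(common),
        "edge_sign_agreement": sign_agree,
        "role_agreement": role_agree,
    }
    return net_mv, deg_mv, report


def network_from_edge_table(
    edges: pd.DataFrame,
    threshold: float = 0.39,
    nodes: list[str] | None = None,
) -> DirectedNetwork:
    """Build a DirectedNetwork from a (source, target, gc, z) table."""
    required = {"source", "target", "gc", "z"}
    missing = required - set(edges.columns)
    if missing:
        raise ValueError(f"edge table missing columns: {sorted(missing)}")
    if nodes is None:
        nodes = sorted(set(edges["source"]) | set(edges["target"]))
    edge_objs = [
        Edge(str(r.source), str(r.target), float(r.gc), float(r.z))
        for r in edges.itertuples()
    ]
    return DirectedNetwork(nodes=list(nodes), edges=edge_objs, threshold_used=threshold)


def load_reference_edges() -> pd.DataFrame:
    """Published 22-edge directed network of a post-RT NPC cohort.

    A plain transcription of a reported ROI-wise causal edge list (source,
    target, signed GC, signed Z), shipped as a deterministic fixture for
    degree bookkeeping: its out/in-degree table reproduces the reported
    source-like / sink-like split of the ten regions.
    """
    ref = importlib.resources.files("cascnet.data").joinpath("rt_cohort_edges.tsv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
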