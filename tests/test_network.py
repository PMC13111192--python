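"""Directed ROI network construction, degree bookkeeping and robustness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cascnet.experiments import chain_robustness_experiment, roi_recovery_experiment
from cascnet.gc import GCConfig
from cascnet.network import (
    DirectedNetwork,
    Edge,
    build_roi_network,
    compute_degrees,
    extract_roi_series,
    load_reference_edges,
    multivariate_robustness,
    network_from_edge_table,
)
from cascnet.pseudotime import covariate_matrix, order_by_time
from cascnet.sim import SimConfig, generate_cohort


def _series(config):
    records, table = generate_cohort(config)
    patients = [r for r in records if r.group == "patient"]
    ids, _, intervals = order_by_time(patients)
    ordered = sorted(patients, key=lambda p: (p.months_post_rt, p.subject_id))
    return (
        extract_roi_series(table, roi_list=list(config.roi_names), order_index=ids),
        covariate_matrix(ordered, intervals),
    )


class TestBuildNetwork:
    def test_planted_edges_found_with_signs(self):
        config = SimConfig(
            roi_names=("A", "B", "C", "D"),
            planted_edges=(("A", "B", 2.0), ("A", "C", -2.0)),
            noise_sd=0.3,
            rng_seed=21,
        )
        series, cov = _series(config)
        net = build_roi_network(series, cov)
        found = {(e.source, e.target): e for e in net.edges}
        assert found[("A", "B")].gc > 0 and found[("A", "B")].z > 0
        assert found[("A", "C")].gc < 0 and found[("A", "C")].z < 0

    def test_threshold_monotonicity(self):
        config = SimConfig(roi_names=("A", "B", "C", "D"),
                           planted_edges=(("A", "B", 1.0),), rng_seed=3)
        series, cov = _series(config)
        low = build_roi_network(series, cov, GCConfig(gc_threshold=0.2))
        high = build_roi_network(series, cov, GCConfig(gc_threshold=0.6))
        low_pairs = {(e.source, e.target) for e in low.edges}
        high_pairs = {(e.source, e.target) for e in high.edges}
        assert high_pairs <= low_pairs

    def test_single_roi_rejected(self, rng):
        df = pd.DataFrame({"A": rng.standard_normal(12)})
        with pytest.raises(ValueError, match="at least 2"):
            build_roi_network(df)

    def test_network_invariants_enforced(self):
        with pytest.raises(ValueError, match="self-edge"):
            DirectedNetwork(nodes=["A"], edges=[Edge("A", "A", 0.5, 1.0)],
                            threshold_used=0.39)
        with pytest.raises(ValueError, match="duplicate"):
            DirectedNetwork(
                nodes=["A", "B"],
                edges=[Edge("A", "B", 0.5, 1.0), Edge("A", "B", 0.6, 1.0)],
                threshold_used=0.39,
            )
        with pytest.raises(ValueError, match="threshold"):
            DirectedNetwork(nodes=["A", "B"], edges=[Edge("A", "B", 0.3, 1.0)],
                            threshold_used=0.39)


class TestExtractSeries:
    def test_column_order_follows_roi_list(self, rng):
        table = pd.DataFrame(rng.standard_normal((5, 3)),
                             index=list("abcde"), columns=["X", "Y", "Z"])
        out = extract_roi_series(table, roi_list=["Z", "X"], order_index=list("edcba"))
        assert list(out.columns) == ["Z", "X"]
        assert list(out.index) == list("edcba")

    def test_unknown_roi_rejected(self, rng):
        table = pd.DataFrame(rng.standard_normal((5, 2)), columns=["X", "Y"])
        with pytest.raises(KeyError, match="NOPE"):
            extract_roi_series(table, roi_list=["NOPE"])


class TestDegrees:
    def test_reference_edge_list_degree_bookkeeping(self):
        """The published 22-edge network reproduces its reported degree table."""
        edges = load_reference_edges()
        assert len(edges) == 22
        net = network_from_edge_table(edges, threshold=0.39)
        deg = compute_degrees(net)
        assert deg.loc["PHG.R", ["out_degree", "in_degree", "out_in"]].tolist() \
            == [5, 1, 4]
        assert deg.loc["TPOmid.L", ["out_degree", "in_degree", "out_in"]].tolist() \
            == [1, 7, -6]
        assert deg.loc["ITG.L", ["out_degree", "in_degree", "out_in"]].tolist() \
            == [0, 5, -5]
        assert deg["out_degree"].sum() == deg["in_degree"].sum() == 22
        sources = set(deg.index[deg["role"] == "source-like"])
        sinks = set(deg.index[deg["role"] == "sink-like"])
        assert {"PHG.L", "PHG.R", "CAU.L", "CAU.R", "REC.R", "PUT.L"} <= sources
        assert {"CC1.R", "PCUN.L", "TPOmid.L", "ITG.L"} <= sinks
        assert deg["transition_flag"].sum() == 1
        assert deg.loc["TPOmid.L", "transition_flag"]

    def test_reference_degrees_are_deterministic(self):
        a = compute_degrees(network_from_edge_table(load_reference_edges()))
        b = compute_degrees(network_from_edge_table(load_reference_edges()))
        pd.testing.assert_frame_equal(a, b, check_exact=True)

    def test_empty_network_all_balanced(self):
        deg = compute_degrees(DirectedNetwork(nodes=["A", "B"], edges=[],
                                              threshold_used=0.39))
        assert (deg["role"] == "balanced").all()
        assert (deg[["out_degree", "in_degree", "out_in"]] == 0).all().all()

    @given(st.integers(0, 10_000))
    def test_degree_conservation_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 10))
        nodes = [f"N{i}" for i in range(n)]
        adj = rng.random((n, n)) < 0.3
        np.fill_diagonal(adj, False)
        edges = [
            Edge(nodes[i], nodes[j], float(rng.choice([-1, 1]) * 0.5), 0.0)
            for i in range(n)
            for j in range(n)
            if adj[i, j]
        ]
        deg = compute_degrees(DirectedNetwork(nodes=nodes, edges=edges,
                                              threshold_used=0.39))
        assert deg["out_degree"].sum() == deg["in_degree"].sum() == adj.sum()
        # independent oracle: adjacency row/column sums
        assert deg.loc[nodes, "out_degree"].to_numpy().tolist() \
            == adj.sum(axis=1).tolist()
        assert deg.loc[nodes, "in_degree"].to_numpy().tolist() \
            == adj.sum(axis=0).tolist()
        assert (deg["out_in"] == deg["out_degree"] - deg["in_degree"]).all()


class TestMultivariate:
    def test_two_rois_reduce_to_bivariate(self):
        config = SimConfig(roi_names=("A", "B"), planted_edges=(("A", "B", 1.5),),
                           rng_seed=5)
        series, cov = _series(config)
        net_bv = build_roi_network(series, cov)
        net_mv, _, _ = multivariate_robustness(series, cov)
        bv = {(e.source, e.target): e.gc for e in net_bv.edges}
        mv = {(e.source, e.target): e.gc for e in net_mv.edges}
        assert bv.keys() == mv.keys()
        for k in bv:
            assert bv[k] == pytest.approx(mv[k], abs=1e-10)

    def test_chain_indirect_edge_suppressed(self):
        out = chain_robustness_experiment(n_replicates=40, seed=8)
        assert out["multivariate_indirect_rate"] < out["bivariate_indirect_rate"]

    def test_star_roles_recovered_by_both_analyses(self):
        hub_ok_bv, hub_ok_mv, sink_bv, sink_mv = [], [], [], []
        for s in range(10):
            config = SimConfig(
                roi_names=("HUB", "S1", "S2", "S3", "S4"),
                planted_edges=tuple(("HUB", f"S{i}", 2.0) for i in range(1, 5)),
                noise_sd=0.3,
                rng_seed=300 + s,
            )
            series, cov = _series(config)
            deg_bv = compute_degrees(build_roi_network(series, cov))
            _, deg_mv, _ = multivariate_robustness(series, cov)
            hub_ok_bv.append(deg_bv.loc["HUB", "out_in"] > 0)
            hub_ok_mv.append(deg_mv.loc["HUB", "out_in"] > 0)
            sink_bv += [deg_bv.loc[f"S{i}", "out_in"] < 0 for i in range(1, 5)]
            sink_mv += [deg_mv.loc[f"S{i}", "out_in"] < 0 for i in range(1, 5)]
        assert np.mean(hub_ok_bv) >= 0.9
        assert np.mean(hub_ok_mv) >= 0.9
        assert np.mean(sink_bv) >= 0.7
        assert np.mean(sink_mv) >= 0.7

    def test_too_many_rois_refused(self, rng):
        df = pd.DataFrame(rng.standard_normal((12, 8)),
                          columns=[f"R{i}" for i in range(8)])
        with pytest.raises(ValueError, match="reduce the ROI count"):
            multivariate_robustness(df)


def test_recovery_experiment_smoke():
    """Abbreviated planted-recovery run; full scale lives in acceptance."""
    res = roi_recovery_experiment(n_replicates=15, seed=42)
    assert res.recall >= 0.8
    assert res.false_edge_rate <= 0.1
    assert res.sign_accuracy == 1.0
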