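"""Sliding-window networks, decomposition, consensus, and pathway extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tegrn.dynet import (EDGE_COLUMNS, OneToManyView, TransferNetwork, Window,
                         aggregate_window, decompose_one_to_many,
                         extract_pathways, n_windows, significance_periods,
                         windowed_networks, write_network, read_network)


def _view(p_out, windows=None):
    """Single-neighbor view with a given outgoing p series."""
    p = np.asarray(p_out, dtype=float)[None, :]
    n_w = p.shape[1]
    wins = windows or [
        Window(i, i + 1, f"{7 + i // 20:02d}:{(i * 3) % 60:02d}",
               f"{7 + i // 20:02d}:{(i * 3) % 60:02d}", 0)
        for i in range(n_w)
    ]
    z = np.zeros_like(p)
    return OneToManyView("c", ["n"], wins, z, z, p, np.ones_like(p))


class TestWindowArithmetic:
    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.integers(10, 2000), st.integers(10, 500), st.integers(1, 50))
    def test_window_count_formula(self, t, w, s):
        if w > t:
            with pytest.raises(ValueError):
                n_windows(t, w, s)
        else:
            assert n_windows(t, w, s) == (t - w) // s + 1

    def test_spec_design_counts(self):
        assert n_windows(480, 40, 1) == 441
        # a 2-hour clock window at 3-minute cadence spans 40 samples
        assert 120 / 3 == 40


@pytest.fixture(scope="module")
def nets():
    from tegrn.simulate import (GroundTruthEdge, Oscillation, SimConfig,
                                simulate_panel)

    cfg = SimConfig(
        genes=("a", "b", "c", "d"),
        n_timepoints=160,
        couplings=(GroundTruthEdge("a", "b", 1, 0.85, ("08:00", "10:00")),),
        baseline={g: Oscillation(30, 15, 3 * i) for i, g in
                  enumerate(("a", "b", "c", "d"))},
        seed=21,
    )
    m, _ = simulate_panel(cfg)
    return windowed_networks(m, window_len=40, stride=10,
                             n_surrogates=49, seed=2), m


class TestWindowedNetworks:

    def test_count_and_structure(self, nets):
        nets, m = nets
        assert len(nets) == (160 - 40) // 10 + 1
        for net in nets:
            assert len(net.edges) == 6  # C(4,2)
            assert list(net.edges.columns) == EDGE_COLUMNS
            assert net.window.length == 40

    def test_edges_use_only_window_samples(self, nets):
        nets, m = nets
        # recompute the first window from the slice alone and compare TE values
        from tegrn.tecore import detrend_linear, pairwise_te_series

        sub = {g: detrend_linear(np.log1p(m.series(g)[0:40])) for g in m.gene_ids}
        ref = pairwise_te_series(sub, n_bins=3, n_surrogates=None)
        got = nets[0].edges
        assert np.allclose(got["te_ab"], ref["te_ab"])
        assert np.allclose(got["te_ba"], ref["te_ba"])

    def test_active_window_carries_higher_te(self, nets):
        nets, m = nets
        # coupling active 08:00-10:00 → samples 20..60
        te_by_window = []
        for net in nets:
            row = net.edges[(net.edges["gene_a"] == "a") & (net.edges["gene_b"] == "b")]
            te_by_window.append(float(row["te_ab"].iloc[0]))
        inside = te_by_window[2:4]   # windows [20,60) and [30,70)
        outside = [te_by_window[i] for i in (8, 9, 10, 11, 12)]
        assert min(inside) > max(outside)

    def test_window_len_larger_than_series(self, nets):
        _, m = nets
        with pytest.raises(ValueError, match="exceeds"):
            windowed_networks(m, window_len=500)

    def test_clock_labels_attached(self, nets):
        nets, _ = nets
        assert nets[0].window.start_clock == "07:00"
        assert nets[0].window.end_clock == "09:00"


class TestDecomposition:
    def test_neighbor_count_24_genes(self):
        from tegrn.simulate import default_scenario, simulate_panel
        from tegrn.tecore import pairwise_te

        m, _ = simulate_panel(default_scenario(seed=4))
        net = TransferNetwork(panel=m.gene_ids,
                              edges=pairwise_te(m, n_surrogates=None))
        view = decompose_one_to_many(net, "Aanat")
        assert len(view.neighbors) == 23

    def test_two_gene_views_mirror(self, small_matrix):
        from tegrn.tecore import pairwise_te
        from tegrn.exprio import ExpressionMatrix

        m = ExpressionMatrix(small_matrix.data.iloc[:2], small_matrix.cadence_minutes)
        net = TransferNetwork(panel=m.gene_ids, edges=pairwise_te(m, n_surrogates=None))
        va = decompose_one_to_many(net, m.gene_ids[0])
        vb = decompose_one_to_many(net, m.gene_ids[1])
        assert len(va.neighbors) == len(vb.neighbors) == 1
        assert va.te_out[0, 0] == vb.te_in[0, 0]
        assert va.te_in[0, 0] == vb.te_out[0, 0]

    def test_edge_conservation_over_all_centers(self, small_matrix):
        from tegrn.tecore import pairwise_te

        net = TransferNetwork(panel=small_matrix.gene_ids,
                              edges=pairwise_te(small_matrix, n_surrogates=None))
        total_out = total_in = 0.0
        covered = 0
        for center in net.panel:
            v = decompose_one_to_many(net, center)
            covered += len(v.neighbors)
            total_out += v.te_out.sum()
            total_in += v.te_in.sum()
        assert covered == 2 * len(net.edges)
        assert total_out == pytest.approx(total_in, abs=1e-12)

    def test_absent_center_errors(self, small_matrix):
        from tegrn.tecore import pairwise_te

        net = TransferNetwork(panel=small_matrix.gene_ids,
                              edges=pairwise_te(small_matrix, n_surrogates=None))
        with pytest.raises(KeyError):
            decompose_one_to_many(net, "nope")


class TestSignificancePeriods:
    def test_all_insignificant_empty(self):
        view = _view(np.ones(50))
        assert significance_periods(view) == []

    def test_single_block_span(self):
        p = np.ones(200)
        p[100:141] = 0.01
        blocks = significance_periods(_view(p), min_run=5)
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.start_window, b.end_window) == (100, 140)
        assert b.direction == "outgoing"

    def test_short_runs_dropped_and_gaps_merged(self):
        p = np.ones(60)
        p[10:12] = 0.01            # too short
        p[30:34] = 0.01            # 4 long ...
        p[35:38] = 0.01            # ... merged across the 1-window gap: span 8
        blocks = significance_periods(_view(p), min_run=5, gap_tolerance=1)
        assert [(b.start_window, b.end_window) for b in blocks] == [(30, 37)]

    def test_null_series_produce_no_blocks(self, rng):
        """Independent series + BH adjustment: no spurious multi-window blocks."""
        import pandas as pd
        from tegrn.exprio import ExpressionMatrix, clock_labels

        n_t = 160
        df = pd.DataFrame(
            rng.lognormal(3, 0.4, size=(5, n_t)),
            index=pd.Index([f"g{i}" for i in range(5)], name="gene"),
            columns=clock_labels("07:00", n_t, 3.0),
        )
        nets = windowed_networks(ExpressionMatrix(df, 3.0), window_len=40,
                                 stride=10, n_surrogates=49, adjust="bh", seed=9)
        blocks = []
        for g in df.index:
            blocks += significance_periods(decompose_one_to_many(nets, g), min_run=5)
        assert blocks == []


def _consensus_fixture():
    """Hand-built two-window network list with a known significant edge."""
    def net(p_ab, start, clock, center_min):
        edges = pd.DataFrame(
            {
                "gene_a": ["A", "A", "B"], "gene_b": ["B", "C", "C"],
                "te_ab": [0.5, 0.1, 0.1], "te_ba": [0.1, 0.1, 0.1],
                "td": [0.4, 0.0, 0.0],
                "p_ab": [p_ab, 0.8, 0.9], "p_ba": [0.7, 0.6, 0.5],
                "padj_ab": [p_ab, 0.8, 0.9], "padj_ba": [0.7, 0.6, 0.5],
                "max_te": [0.5, 0.1, 0.1],
            }
        )
        return TransferNetwork(panel=["A", "B", "C"], edges=edges,
                               window=Window(start, start + 40, clock, clock, center_min))

    return [net(0.01, 0, "14:00", 15 * 60), net(0.01, 10, "14:30", 15 * 60 + 30)]


class TestAggregateWindow:
    def test_single_window_consensus_equals_its_edges(self):
        nets = _consensus_fixture()[:1]
        cons = aggregate_window(nets, "14:00", "16:00")
        assert len(cons.directed) == 1
        row = cons.directed.iloc[0]
        assert (row["source"], row["target"]) == ("A", "B")
        assert row["n_windows"] == 1

    def test_no_significance_empty_consensus(self):
        nets = _consensus_fixture()
        for n in nets:
            n.edges["padj_ab"] = 1.0
            n.edges["padj_ba"] = 1.0
        cons = aggregate_window(nets, "14:00", "16:00")
        assert len(cons.directed) == 0

    def test_majority_rule(self):
        nets = _consensus_fixture()
        nets[1].edges.loc[0, "padj_ab"] = 0.9  # 1 of 2 significant → keeps (≥ half)
        cons = aggregate_window(nets, "14:00", "16:00")
        assert len(cons.directed) == 1

    def test_empty_clock_range_errors(self):
        with pytest.raises(ValueError, match="no windows"):
            aggregate_window(_consensus_fixture(), "02:00", "03:00")

    def test_median_te_summary(self):
        nets = _consensus_fixture()
        nets[1].edges.loc[0, "te_ab"] = 0.7
        cons = aggregate_window(nets, "14:00", "16:00")
        assert cons.directed.iloc[0]["te"] == pytest.approx(0.6)


class TestExtractPathways:
    def _net(self, edges, panel=None):
        rows = [{"source": u, "target": v, "te": 0.3, "te_rev": 0.1,
                 "td": 0.2, "p": 0.01, "n_sig": 2, "n_windows": 2}
                for u, v in edges]
        directed = pd.DataFrame(
            rows, columns=["source", "target", "te", "te_rev", "td", "p",
                           "n_sig", "n_windows"])
        panel = panel or sorted({g for e in edges for g in e})
        return TransferNetwork(panel=panel, edges=pd.DataFrame(columns=EDGE_COLUMNS),
                               directed=directed)

    def test_toy_chain(self):
        net = self._net([("A", "B"), ("B", "C")])
        paths = extract_pathways(net, {"A"}, "C", max_len=4)
        assert [p.genes for p in paths] == [("A", "B", "C")]
        assert paths[0].step_te == (0.3, 0.3)

    def test_unreachable_sink_empty(self):
        net = self._net([("A", "B")], panel=["A", "B", "Z"])
        assert extract_pathways(net, {"A"}, "Z") == []

    def test_max_len_caps_path_genes(self):
        net = self._net([("A", "B"), ("B", "C"), ("C", "D")])
        assert [p.genes for p in extract_pathways(net, {"A"}, "D", max_len=4)] == [
            ("A", "B", "C", "D")
        ]
        assert extract_pathways(net, {"A"}, "D", max_len=3) == []

    def test_matches_brute_force_enumeration(self, rng):
        # random sparse DAG on 10 nodes vs exhaustive DFS
        nodes = [f"n{i}" for i in range(10)]
        edges = [
            (nodes[i], nodes[j])
            for i in range(10) for j in range(i + 1, 10)
            if rng.random() < 0.3
        ]
        if not edges:
            edges = [("n0", "n9")]
        net = self._net(edges, panel=nodes)

        def dfs(path, adj, sink, max_genes, acc):
            if path[-1] == sink:
                acc.add(tuple(path))
                return
            if len(path) == max_genes:
                return
            for nxt in adj.get(path[-1], []):
                if nxt not in path:
                    dfs(path + [nxt], adj, sink, max_genes, acc)

        adj: dict = {}
        for u, v in edges:
            adj.setdefault(u, []).append(v)
        expected: set = set()
        for src in ("n0", "n1"):
            dfs([src], adj, "n9", 5, expected)
        got = {p.genes for p in extract_pathways(net, {"n0", "n1"}, "n9", max_len=5)}
        assert got == expected

    def test_lexicographic_order(self):
        net = self._net([("B", "C"), ("A", "C"), ("A", "B")])
        paths = extract_pathways(net, {"A", "B"}, "C", max_len=3)
        assert [p.genes for p in paths] == sorted(p.genes for p in paths)


class TestNetworkIO:
    def test_consensus_round_trip(self, tmp_path):
        nets = _consensus_fixture()
        cons = aggregate_window(nets, "14:00", "16:00")
        p = tmp_path / "net.tsv"
        write_network(cons, p)
        back = read_network(p)
        assert list(back.directed["source"]) == list(cons.directed["source"])

    def test_gene_order_invariance(self, small_matrix):
        """Permuting panel rows changes no TE value, block, or path set."""
        from tegrn.exprio import ExpressionMatrix
        from tegrn.tecore import pairwise_te

        perm = small_matrix.data.iloc[::-1]
        t1 = pairwise_te(small_matrix, n_surrogates=None)
        t2 = pairwise_te(ExpressionMatrix(perm, 3.0), n_surrogates=None)
        def canon(t):
            return {
                frozenset((r["gene_a"], r["gene_b"])): (round(r["max_te"], 12),
                                                        round(abs(r["td"]), 12))
                for _, r in t.iterrows()
            }
        assert canon(t1) == canon(t2)
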