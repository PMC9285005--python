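"""SVG renderers: determinism and numeric fidelity of the encodings."""

import math
import xml.etree.ElementTree as ET

import numpy as np
import pandas as pd
import pytest

from tegrn.dynet import (EDGE_COLUMNS, OneToManyView, Pathway,
                         SignificanceBlock, TransferNetwork, Window)
from tegrn.viz import (RenderSpec, render, render_circular,
                       render_edge_glyph_network, render_flow_graph,
                       render_force_network, render_sankey)

NS = {"svg": "http://www.w3.org/2000/svg"}


def _parse(data: bytes) -> ET.Element:
    return ET.fromstring(data.decode())


def _pair_net(te_ab=0.4, te_ba=0.1) -> TransferNetwork:
    edges = pd.DataFrame(
        [{"gene_a": "X", "gene_b": "Y", "te_ab": te_ab, "te_ba": te_ba,
          "td": te_ab - te_ba, "p_ab": 0.01, "p_ba": 0.4,
          "padj_ab": 0.01, "padj_ba": 0.4, "max_te": max(te_ab, te_ba)}],
        columns=EDGE_COLUMNS,
    )
    return TransferNetwork(panel=["X", "Y"], edges=edges)


def _many_view(n_nb=23, n_w=12, seed=0) -> OneToManyView:
    r = np.random.default_rng(seed)
    wins = [Window(i, i + 40, "07:00", "09:00", 480) for i in range(n_w)]
    return OneToManyView(
        center="B",
        neighbors=[f"n{i}" for i in range(n_nb)],
        windows=wins,
        te_out=r.uniform(0, 0.5, (n_nb, n_w)),
        te_in=r.uniform(0, 0.5, (n_nb, n_w)),
        p_out=r.uniform(0, 1, (n_nb, n_w)),
        p_in=r.uniform(0, 1, (n_nb, n_w)),
    )


class TestEdgeGlyph:
    def test_red_blue_span_ratio(self):
        root = _parse(render_edge_glyph_network(_pair_net(0.4, 0.1)))
        glyph = root.find(".//svg:g[@class='edge-glyph']", NS)
        red, blue = glyph.findall("svg:line", NS)
        def seg_len(l):
            return math.hypot(float(l.get("x2")) - float(l.get("x1")),
                              float(l.get("y2")) - float(l.get("y1")))
        assert seg_len(red) / seg_len(blue) == pytest.approx(4.0, rel=1e-9)
        # arrowhead present, pointing at the blue (Y) end since TD > 0
        assert glyph.find("svg:polygon", NS) is not None

    def test_stroke_width_encodes_sum(self):
        spec = RenderSpec("edge_glyph_network", stroke_scale=10.0)
        root = _parse(render_edge_glyph_network(_pair_net(0.4, 0.1), spec))
        line = root.find(".//svg:g[@class='edge-glyph']/svg:line", NS)
        assert float(line.get("stroke-width")) == pytest.approx(5.0)

    def test_tied_edge_dashed_no_arrow(self):
        root = _parse(render_edge_glyph_network(_pair_net(0.25, 0.25)))
        glyph = root.find(".//svg:g[@class='edge-glyph']", NS)
        assert glyph.find("svg:polygon", NS) is None
        for line in glyph.findall("svg:line", NS):
            assert line.get("stroke-dasharray")

    def test_glyph_count_matches_edge_rows(self):
        from tegrn.simulate import default_scenario, simulate_panel
        from tegrn.tecore import pairwise_te

        m, _ = simulate_panel(default_scenario(seed=6))
        edges = pairwise_te(m, n_surrogates=None)
        edges["padj_ab"] = edges["padj_ba"] = 1.0
        net = TransferNetwork(panel=m.gene_ids, edges=edges)
        root = _parse(render_edge_glyph_network(net))
        drawn = root.findall(".//svg:g[@class='edge-glyph']", NS)
        expect = (edges["te_ab"] + edges["te_ba"] > 0).sum()
        assert len(drawn) == expect

    def test_empty_network_rejected(self):
        net = TransferNetwork(panel=[], edges=pd.DataFrame(columns=EDGE_COLUMNS))
        with pytest.raises(ValueError, match="empty"):
            render_edge_glyph_network(net)


class TestFlowGraph:
    def test_stacked_height_equals_te_sum(self):
        view = _many_view(5, 8)
        spec = RenderSpec("flow_graph", te_scale=60.0)
        root = _parse(render_flow_graph(view, spec))
        axis_y = float(root.get("data-axis-y"))
        scale = float(root.get("data-te-scale"))
        bands = root.findall(".//svg:polygon[@data-direction='outgoing']", NS)
        assert len(bands) == 5
        # the top boundary of the last band at the first timepoint
        top = bands[-1]
        first_pt = top.get("points").split()[0]
        x0, y0 = map(float, first_pt.split(","))
        recovered = (axis_y - y0) / scale
        assert recovered == pytest.approx(view.te_out[:, 0].sum(), abs=1e-9)

    def test_all_zero_view_flat(self):
        view = _many_view(3, 6)
        view.te_out[:] = 0
        view.te_in[:] = 0
        root = _parse(render_flow_graph(view))
        axis_y = float(root.get("data-axis-y"))
        for poly in root.findall(".//svg:polygon", NS):
            for pt in poly.get("points").split():
                _, y = map(float, pt.split(","))
                assert y == pytest.approx(axis_y, abs=1e-9)
        assert root.findall(".//svg:rect", NS) == []

    def test_constant_band_height(self):
        view = _many_view(1, 6)
        view.te_out[:] = 0.3
        view.te_in[:] = 0.0
        spec = RenderSpec("flow_graph", te_scale=100.0)
        root = _parse(render_flow_graph(view, spec))
        band = root.find(".//svg:polygon[@data-direction='outgoing']", NS)
        ys = [float(pt.split(",")[1]) for pt in band.get("points").split()]
        axis_y = float(root.get("data-axis-y"))
        assert set(round(axis_y - y, 6) for y in ys) == {0.0, 30.0}

    def test_significance_blocks_drawn(self):
        view = _many_view(2, 10)
        view.blocks = [SignificanceBlock("n0", "outgoing", 2, 6, "07:00", "09:00"),
                       SignificanceBlock("n1", "incoming", 1, 4, "07:00", "09:00")]
        root = _parse(render_flow_graph(view))
        rects = root.findall(".//svg:rect[@class='sig-block']", NS)
        assert {r.get("data-direction") for r in rects} == {"outgoing", "incoming"}

    def test_single_window_rejected(self):
        with pytest.raises(ValueError, match="2 windows"):
            render_flow_graph(_many_view(2, 1))


class TestCircular:
    def test_23_neighbors_equal_spacing(self):
        view = _many_view(23, 4)
        root = _parse(render_circular(view, 0))
        assert float(root.get("data-spacing-deg")) == pytest.approx(360 / 23)
        discs = root.findall(".//svg:circle[@class='neighbor-disc']", NS)
        assert len(discs) == 23
        cx, cy = 400.0, 400.0
        angles = sorted(
            math.atan2(float(d.get("cy")) - cy, float(d.get("cx")) - cx)
            for d in discs
        )
        gaps = np.diff(angles)
        assert np.allclose(gaps, 2 * math.pi / 23, atol=1e-9)

    def test_direction_colors(self):
        view = _many_view(2, 3)
        view.te_out[0, 1], view.te_in[0, 1] = 0.5, 0.1   # center drives n0 → red
        view.te_out[1, 1], view.te_in[1, 1] = 0.1, 0.5   # n1 drives center → blue
        view.p_out[:], view.p_in[:] = 0.04, 0.04
        root = _parse(render_circular(view, 1))
        discs = root.findall(".//svg:circle[@class='neighbor-disc']", NS)
        fills = {d.get("data-neighbor"): d.get("fill") for d in discs}
        assert fills["n0"].lower() in {"#f1948a", "#e74c3c", "#922b21"}
        assert fills["n1"].lower() in {"#85c1e9", "#3498db", "#1a5276"}

    def test_darker_for_smaller_p(self):
        view = _many_view(2, 1)
        view.te_out[:, 0], view.te_in[:, 0] = 0.5, 0.1
        view.p_out[0, 0], view.p_out[1, 0] = 0.04, 0.0005
        root = _parse(render_circular(view, 0))
        discs = {d.get("data-neighbor"): d.get("fill")
                 for d in root.findall(".//svg:circle[@class='neighbor-disc']", NS)}
        assert discs["n0"] == "#f1948a"
        assert discs["n1"] == "#922b21"

    def test_radius_encodes_te(self):
        view = _many_view(1, 1)
        view.te_out[0, 0], view.te_in[0, 0] = 0.8, 0.2
        spec = RenderSpec("circular_one_to_many", te_scale=100.0)
        root = _parse(render_circular(view, 0, spec))
        disc = root.find(".//svg:circle[@class='neighbor-disc']", NS)
        assert float(disc.get("r")) == pytest.approx(0.8 * 25.0)


class TestSankey:
    def _paths(self):
        return [
            Pathway(("Rel", "E2f6", "Aanat"), (0.3, 0.2), (0.3, 0.2), (0.01, 0.01)),
            Pathway(("Srebf1", "E2f6", "Aanat"), (0.25, 0.2), (0.25, 0.2), (0.01, 0.01)),
        ]

    def test_single_path_counts(self):
        p = Pathway(("A", "B", "C"), (0.3, 0.2), (0.3, 0.2), (0.01, 0.02))
        root = _parse(render_sankey([p]))
        assert len(root.findall(".//svg:path[@class='sankey-link']", NS)) == 2
        assert len(root.findall(".//svg:rect[@class='sankey-node']", NS)) == 3

    def test_links_deduplicated_across_paths(self):
        root = _parse(render_sankey(self._paths()))
        links = root.findall(".//svg:path[@class='sankey-link']", NS)
        got = {(l.get("data-source"), l.get("data-target")) for l in links}
        assert got == {("Rel", "E2f6"), ("Srebf1", "E2f6"), ("E2f6", "Aanat")}

    def test_link_thickness_proportional_to_te(self):
        spec = RenderSpec("sankey", te_scale=80.0)
        root = _parse(render_sankey(self._paths(), spec))
        widths = {
            (l.get("data-source"), l.get("data-target")): float(l.get("stroke-width"))
            for l in root.findall(".//svg:path[@class='sankey-link']", NS)
        }
        assert widths[("Rel", "E2f6")] == pytest.approx(0.3 * 20.0)

    def test_empty_pathways_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            render_sankey([])

    def test_html_wrapper(self):
        data = render_sankey(self._paths(), html=True)
        assert data.startswith(b"<!DOCTYPE html>")
        assert b"<svg" in data


class TestForceNetwork:
    def _net(self, n=24):
        rows = [{"source": f"g{i}", "target": f"g{(i + 1) % n}", "te": 0.2,
                 "te_rev": 0.1, "td": 0.1, "p": 0.01, "n_sig": 1, "n_windows": 1}
                for i in range(n)]
        return TransferNetwork(
            panel=[f"g{i}" for i in range(n)],
            edges=pd.DataFrame(columns=EDGE_COLUMNS),
            directed=pd.DataFrame(rows),
        )

    def test_same_seed_byte_identical(self):
        net = self._net(10)
        spec = RenderSpec("force_network", seed=3)
        assert render_force_network(net, spec) == render_force_network(net, spec)

    def test_different_seed_differs(self):
        net = self._net(10)
        a = render_force_network(net, RenderSpec("force_network", seed=3))
        b = render_force_network(net, RenderSpec("force_network", seed=4))
        assert a != b

    def test_min_separation_enforced(self):
        net = self._net(24)
        spec = RenderSpec("force_network", min_separation=36.0)
        root = _parse(render_force_network(net, spec))
        pts = [
            (float(c.get("cx")), float(c.get("cy")))
            for c in root.findall(".//svg:circle[@class='node']", NS)
        ]
        assert len(pts) == 24
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                d = math.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1])
                assert d >= 36.0 - 1e-6

    def test_single_node_network(self):
        net = TransferNetwork(panel=["only"], edges=pd.DataFrame(columns=EDGE_COLUMNS))
        root = _parse(render_force_network(net))
        assert len(root.findall(".//svg:circle[@class='node']", NS)) == 1
        assert root.findall(".//svg:line", NS) == []


class TestDispatch:
    def test_render_dispatch_and_determinism(self):
        net = _pair_net()
        spec = RenderSpec("edge_glyph_network", seed=5)
        assert render(net, spec) == render(net, spec)

    def test_unknown_encoding_rejected(self):
        with pytest.raises(ValueError, match="encoding"):
            RenderSpec("pie_chart")
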