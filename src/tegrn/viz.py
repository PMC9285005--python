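"""Deterministic SVG renderings of transfer networks and their decompositions.

Five encodings:

* ``edge_glyph_network`` — every gene pair as a bicolor segment: the red
  span is proportional to TE(X→Y), the blue span to TE(Y→X), the stroke
  width to their sum, and an arrowhead points from the red end to the blue
  end when TD(X,Y) > 0 (and the reverse when TD < 0); exact ties are drawn
  dashed with no arrowhead.
* ``flow_graph`` — a center gene's outgoing TE streams stacked above the
  time axis and incoming streams below, with significant transfer periods
  overlaid as red (outgoing) / blue (incoming) blocks.
* ``circular_one_to_many`` — the center gene surrounded by a ring of
  neighbors; disc radius encodes TE magnitude, red/blue the direction of
  the dominant transfer, darker shades more significant p-values.
* ``sankey`` — staged promoter→…→receptor pathway flows with link
  thickness proportional to step TE.
* ``force_network`` — seeded force-directed node-link layout with overlap
  resolution, directed edges arrowed.

All renderers are pure functions of (input object, spec): a fixed layout
seed yields byte-identical SVG.  Proportionality constants are embedded as
``data-*`` attributes on the root element so rendered geometry can be read
back numerically.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .dynet import OneToManyView, Pathway, TransferNetwork

__all__ = [
    "RenderSpec",
    "ENCODINGS",
    "render_edge_glyph_network",
    "render_flow_graph",
    "render_circular",
    "render_sankey",
    "render_force_network",
    "render",
]

ENCODINGS = (
    "edge_glyph_network",
    "flow_graph",
    "circular_one_to_many",
    "sankey",
    "force_network",
)

# darkness ladders: light → dark for p ≤ .05, ≤ .01, ≤ .001
_REDS = ("#f1948a", "#e74c3c", "#922b21")
_BLUES = ("#85c1e9", "#3498db", "#1a5276")
_GREY = "#999999"
_NODE_FILL = "#f4f1ea"


@dataclass(frozen=True)
class RenderSpec:
    """Rendering parameters shared by all encodings."""

    encoding: str = "edge_glyph_network"
    width: int = 800
    height: int = 800
    seed: int = 7
    stroke_scale: float = 12.0   # px per bit for glyph stroke width
    te_scale: float = 60.0       # px per bit for flow/disc magnitudes
    min_separation: float = 36.0  # px between node centers (force layout)

    def __post_init__(self) -> None:
        if self.encoding not in ENCODINGS:
            raise ValueError(f"unknown encoding {self.encoding!r}")


# ---------------------------------------------------------------------------
# SVG plumbing
# ---------------------------------------------------------------------------

def _f(v: float) -> str:
    return format(float(v), ".12g")


def _root(spec: RenderSpec, **data: float | str) -> ET.Element:
    el = ET.Element(
        "svg",
        xmlns="http://www.w3.org/2000/svg",
        width=str(spec.width),
        height=str(spec.height),
        viewBox=f"0 0 {spec.width} {spec.height}",
    )
    el.set("data-encoding", spec.encoding)
    for k, v in data.items():
        el.set(f"data-{k.replace('_', '-')}", _f(v) if isinstance(v, (int, float)) else str(v))
    return el


def _text(parent: ET.Element, x: float, y: float, s: str, size: int = 11,
          anchor: str = "middle", fill: str = "#222222") -> None:
    t = ET.SubElement(
        parent, "text", x=_f(x), y=_f(y),
        **{"font-size": str(size), "text-anchor": anchor, "fill": fill,
           "font-family": "sans-serif"},
    )
    t.text = s


def _line(parent: ET.Element, x1, y1, x2, y2, stroke, width, dashed=False, **extra):
    at = {
        "x1": _f(x1), "y1": _f(y1), "x2": _f(x2), "y2": _f(y2),
        "stroke": stroke, "stroke-width": _f(width),
    }
    if dashed:
        at["stroke-dasharray"] = "6,4"
    at.update({k.replace("_", "-"): v for k, v in extra.items()})
    return ET.SubElement(parent, "line", at)


def _arrowhead(parent: ET.Element, x: float, y: float, angle: float,
               size: float, fill: str) -> None:
    pts = []
    for dx, dy in ((0.0, 0.0), (-size, size * 0.45), (-size, -size * 0.45)):
        px = x + dx * math.cos(angle) - dy * math.sin(angle)
        py = y + dx * math.sin(angle) + dy * math.cos(angle)
        pts.append(f"{_f(px)},{_f(py)}")
    ET.SubElement(parent, "polygon", points=" ".join(pts), fill=fill)


def _shade(p: float, ladder: tuple[str, str, str]) -> str:
    if p <= 0.001:
        return ladder[2]
    if p <= 0.01:
        return ladder[1]
    return ladder[0]


def to_bytes(root: ET.Element) -> bytes:
    body = ET.tostring(root, encoding="unicode")
    return ("<?xml version='1.0' encoding='utf-8'?>\n" + body + "\n").encode()


def _ring_positions(n: int, cx: float, cy: float, r: float) -> list[tuple[float, float]]:
    out = []
    for i in range(n):
        a = -math.pi / 2 + 2 * math.pi * i / n
        out.append((cx + r * math.cos(a), cy + r * math.sin(a)))
    return out


# ---------------------------------------------------------------------------
# 1. vector-encoded edge glyph network
# ---------------------------------------------------------------------------

def render_edge_glyph_network(net: TransferNetwork, spec: RenderSpec | None = None) -> bytes:
    """Bicolor-segment encoding of every pair's directed transfer.

    The segment between genes X and Y is split at TE(X→Y)/(TE(X→Y)+TE(Y→X)):
    the red part sits at the X end, the blue part at the Y end, stroke width
    is ``stroke_scale`` px per bit of total transfer, and the arrowhead
    marks the receiving end of the dominant direction.
    """
    spec = spec or RenderSpec(encoding="edge_glyph_network")
    if len(net.edges) == 0:
        raise ValueError("empty network: nothing to render")
    root = _root(spec, stroke_scale=spec.stroke_scale)
    genes = net.panel
    cx, cy = spec.width / 2, spec.height / 2
    r = min(cx, cy) - 70
    pos = dict(zip(genes, _ring_positions(len(genes), cx, cy, r)))

    glyphs = ET.SubElement(root, "g", {"class": "edge-glyphs"})
    for _, e in net.edges.iterrows():
        a, b = e["gene_a"], e["gene_b"]
        te_ab, te_ba = float(e["te_ab"]), float(e["te_ba"])
        total = te_ab + te_ba
        if total <= 0:
            continue
        (x1, y1), (x2, y2) = pos[a], pos[b]
        frac = te_ab / total
        xm, ym = x1 + frac * (x2 - x1), y1 + frac * (y2 - y1)
        w = spec.stroke_scale * total
        td = te_ab - te_ba
        g = ET.SubElement(glyphs, "g", {
            "class": "edge-glyph",
            "data-gene-a": str(a), "data-gene-b": str(b),
            "data-te-fwd": _f(te_ab), "data-te-rev": _f(te_ba), "data-td": _f(td),
        })
        dashed = td == 0
        _line(g, x1, y1, xm, ym, _REDS[1], w, dashed=dashed)
        _line(g, xm, ym, x2, y2, _BLUES[1], w, dashed=dashed)
        if td != 0:
            # arrow at the receiving end: red→blue when TD > 0
            tx, ty = (x2, y2) if td > 0 else (x1, y1)
            fx, fy = (x1, y1) if td > 0 else (x2, y2)
            ang = math.atan2(ty - fy, tx - fx)
            # pull the tip off the node disc
            tipx, tipy = tx - 16 * math.cos(ang), ty - 16 * math.sin(ang)
            _arrowhead(g, tipx, tipy, ang, 10 + w / 2, "#333333")

    nodes = ET.SubElement(root, "g", {"class": "nodes"})
    for gname in genes:
        x, y = pos[gname]
        ET.SubElement(nodes, "circle", cx=_f(x), cy=_f(y), r="14",
                      fill=_NODE_FILL, stroke="#555555")
        _text(nodes, x, y + 3, gname, size=9)

    legend = ET.SubElement(root, "g", {"class": "legend"})
    _line(legend, 20, spec.height - 30, 60, spec.height - 30, _REDS[1], 4)
    _text(legend, 130, spec.height - 26, "TE(X→Y)  red span")
    _line(legend, 20, spec.height - 12, 60, spec.height - 12, _BLUES[1], 4)
    _text(legend, 130, spec.height - 8, "TE(Y→X)  blue span")
    return to_bytes(root)


# ---------------------------------------------------------------------------
# 2. flow graph of a one-to-many view
# ---------------------------------------------------------------------------

def render_flow_graph(view: OneToManyView, spec: RenderSpec | None = None) -> bytes:
    """Stacked-stream flow graph of one center gene's transfer over time.

    Outgoing TE to each neighbor is stacked above the time axis in fixed
    neighbor order, incoming TE below; the vertical extent of each band is
    ``te_scale`` px per bit.  Significance blocks from ``view.blocks`` are
    overlaid red (outgoing) / blue (incoming) across their window spans.
    """
    spec = spec or RenderSpec(encoding="flow_graph")
    n_w = view.te_out.shape[1]
    if n_w < 2:
        raise ValueError("flow graph needs a view covering at least 2 windows")
    axis_y = spec.height / 2
    x0, x1 = 60.0, spec.width - 20.0
    xs = np.linspace(x0, x1, n_w)
    root = _root(spec, te_scale=spec.te_scale, axis_y=axis_y, x0=x0, x1=x1,
                 center=view.center)

    bands = ET.SubElement(root, "g", {"class": "bands"})
    palette = ["#b23a2e", "#d35400", "#c58917", "#7d6608", "#7b241c", "#a04000"]
    palette_in = ["#1f618d", "#2874a6", "#117864", "#6c3483", "#1b4f72", "#148f77"]

    for sign, series, pal, cls in (
        (-1.0, view.te_out, palette, "outgoing"),   # above axis: y decreases
        (+1.0, view.te_in, palette_in, "incoming"),
    ):
        cum = np.zeros(n_w)
        for i, nb in enumerate(view.neighbors):
            lo = cum.copy()
            cum = cum + series[i]
            ys_lo = axis_y + sign * lo * spec.te_scale
            ys_hi = axis_y + sign * cum * spec.te_scale
            pts = [f"{_f(x)},{_f(y)}" for x, y in zip(xs, ys_hi)]
            pts += [f"{_f(x)},{_f(y)}" for x, y in zip(xs[::-1], ys_lo[::-1])]
            ET.SubElement(
                bands, "polygon",
                {"points": " ".join(pts), "fill": pal[i % len(pal)],
                 "fill-opacity": "0.85", "class": f"band {cls}",
                 "data-neighbor": nb, "data-direction": cls},
            )

    blocks = ET.SubElement(root, "g", {"class": "significance-blocks"})
    for b in view.blocks:
        xa, xb = xs[b.start_window], xs[b.end_window]
        if b.direction == "outgoing":
            y, h, fill = axis_y - 14, 10.0, _REDS[1]
        else:
            y, h, fill = axis_y + 4, 10.0, _BLUES[1]
        ET.SubElement(
            blocks, "rect",
            {"x": _f(xa), "y": _f(y), "width": _f(max(xb - xa, 1.0)),
             "height": _f(h), "fill": fill, "fill-opacity": "0.6",
             "class": "sig-block", "data-neighbor": b.neighbor,
             "data-direction": b.direction},
        )

    _line(root, x0, axis_y, x1, axis_y, "#222222", 1.2)
    _text(root, x0 - 30, axis_y + 4, view.center, size=12)
    for w in (0, n_w - 1):
        _text(root, xs[w], axis_y + (28 if w == 0 else 28),
              view.windows[w].start_clock, size=9)
    return to_bytes(root)


# ---------------------------------------------------------------------------
# 3. circular one-to-many diagram
# ---------------------------------------------------------------------------

def render_circular(view: OneToManyView, window: int = 0,
                    spec: RenderSpec | None = None) -> bytes:
    """Ring diagram of one center gene's pairwise transfer at one window.

    Neighbors sit equally spaced on a circle around the center gene; each
    neighbor's disc radius is ``te_scale``/4 px per bit of the dominant
    pairwise TE, red when the center drives the neighbor (TD > 0), blue
    when it is driven, grey on an exact tie; darker shades mark smaller
    p-values.
    """
    spec = spec or RenderSpec(encoding="circular_one_to_many")
    if not view.neighbors:
        raise ValueError("circular diagram needs at least one neighbor")
    if not 0 <= window < view.te_out.shape[1]:
        raise ValueError(f"window {window} out of range")
    root = _root(spec, disc_scale=spec.te_scale / 4.0,
                 spacing_deg=360.0 / len(view.neighbors))
    cx, cy = spec.width / 2, spec.height / 2
    ring_r = min(cx, cy) - 90
    pos = _ring_positions(len(view.neighbors), cx, cy, ring_r)

    ET.SubElement(root, "circle", cx=_f(cx), cy=_f(cy), r="22",
                  fill=_NODE_FILL, stroke="#333333")
    _text(root, cx, cy + 4, view.center, size=11)

    discs = ET.SubElement(root, "g", {"class": "neighbor-discs"})
    for i, nb in enumerate(view.neighbors):
        out_te, in_te = float(view.te_out[i, window]), float(view.te_in[i, window])
        td = out_te - in_te
        mag = max(out_te, in_te)
        if td > 0:
            fill = _shade(float(view.p_out[i, window]), _REDS)
        elif td < 0:
            fill = _shade(float(view.p_in[i, window]), _BLUES)
        else:
            fill = _GREY
        x, y = pos[i]
        r = max(spec.te_scale / 4.0 * mag, 2.0)
        ET.SubElement(
            discs, "circle",
            {"cx": _f(x), "cy": _f(y), "r": _f(r), "fill": fill,
             "stroke": "#444444", "stroke-width": "0.8",
             "class": "neighbor-disc", "data-neighbor": nb,
             "data-te-out": _f(out_te), "data-te-in": _f(in_te), "data-td": _f(td)},
        )
        _text(discs, x, y - r - 6, nb, size=9)
    return to_bytes(root)


# ---------------------------------------------------------------------------
# 4. Sankey pathway diagram
# ---------------------------------------------------------------------------

def _stages(pathways: list[Pathway]) -> dict[str, int]:
    stage: dict[str, int] = {}
    for p in pathways:
        for i, g in enumerate(p.genes):
            stage[g] = max(stage.get(g, 0), i)
    last = max(stage.values())
    for p in pathways:  # the receptor always sits in the last column
        stage[p.genes[-1]] = last
    return stage


def render_sankey(pathways: list[Pathway], spec: RenderSpec | None = None,
                  html: bool = False) -> bytes:
    """Staged flow diagram of promoter→…→receptor pathways.

    Genes are laid out in columns by their pathway depth (promoters left,
    the receptor right); each distinct step becomes one ribbon whose
    thickness is ``te_scale``/4 px per bit of step TE.
    """
    spec = spec or RenderSpec(encoding="sankey")
    if not pathways:
        raise ValueError("empty pathway list: nothing to render")
    stage = _stages(pathways)
    links: dict[tuple[str, str], float] = {}
    for p in pathways:
        for i in range(len(p.genes) - 1):
            links.setdefault((p.genes[i], p.genes[i + 1]), p.step_te[i])
    thick = spec.te_scale / 4.0
    n_cols = max(stage.values()) + 1
    cols: list[list[str]] = [[] for _ in range(n_cols)]
    for g in sorted(stage):
        cols[stage[g]].append(g)

    node_w, gap = 14.0, 26.0
    x_of = {g: 80.0 + stage[g] * (spec.width - 180.0) / max(n_cols - 1, 1)
            for g in stage}
    flow = {g: max(
        sum(t for (u, v), t in links.items() if u == g),
        sum(t for (u, v), t in links.items() if v == g),
    ) for g in stage}
    y_of: dict[str, tuple[float, float]] = {}
    for col in cols:
        total_h = sum(max(flow[g] * thick, 8.0) for g in col) + gap * (len(col) - 1)
        y = (spec.height - total_h) / 2
        for g in col:
            h = max(flow[g] * thick, 8.0)
            y_of[g] = (y, h)
            y += h + gap

    root = _root(spec, link_scale=thick)
    ribbons = ET.SubElement(root, "g", {"class": "links"})
    offs_out = {g: 0.0 for g in stage}
    offs_in = {g: 0.0 for g in stage}
    for (u, v) in sorted(links):
        t = links[(u, v)]
        h = max(t * thick, 1.5)
        x1 = x_of[u] + node_w
        y1 = y_of[u][0] + offs_out[u] + h / 2
        x2 = x_of[v]
        y2 = y_of[v][0] + offs_in[v] + h / 2
        offs_out[u] += h
        offs_in[v] += h
        mx = (x1 + x2) / 2
        d = f"M {_f(x1)} {_f(y1)} C {_f(mx)} {_f(y1)}, {_f(mx)} {_f(y2)}, {_f(x2)} {_f(y2)}"
        ET.SubElement(
            ribbons, "path",
            {"d": d, "stroke": "#b08968", "stroke-opacity": "0.55",
             "stroke-width": _f(h), "fill": "none", "class": "sankey-link",
             "data-source": u, "data-target": v, "data-te": _f(t)},
        )
    boxes = ET.SubElement(root, "g", {"class": "nodes"})
    for g in stage:
        y, h = y_of[g]
        ET.SubElement(
            boxes, "rect",
            {"x": _f(x_of[g]), "y": _f(y), "width": _f(node_w), "height": _f(h),
             "fill": "#5d4037", "class": "sankey-node", "data-gene": g},
        )
        _text(boxes, x_of[g] + node_w / 2, y - 5, g, size=10)
    svg = to_bytes(root)
    if html:
        return (
            b"<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
            b"<title>pathway sankey</title></head><body>\n"
            + svg
            + b"</body></html>\n"
        )
    return svg


# ---------------------------------------------------------------------------
# 5. force-directed network
# ---------------------------------------------------------------------------

def _resolve_overlaps(pos: dict[str, np.ndarray], min_sep: float) -> None:
    nodes = sorted(pos)
    for _ in range(200):
        moved = False
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                d = pos[b] - pos[a]
                dist = float(np.hypot(*d))
                if dist < 1e-9:
                    ang = (hash(a) % 360) * math.pi / 180.0
                    d = np.array([math.cos(ang), math.sin(ang)])
                    dist = 1e-9
                if dist < min_sep:
                    push = (min_sep - dist) / 2 * d / dist
                    pos[a] -= push
                    pos[b] += push
                    moved = True
        if not moved:
            break


def render_force_network(net: TransferNetwork, spec: RenderSpec | None = None) -> bytes:
    """Seeded force-directed node-link rendering with no node overlap.

    A fixed-iteration spring layout from a seeded initialization is
    followed by deterministic pairwise overlap resolution enforcing
    ``min_separation`` px between node centers; directed edges carry
    arrowheads.
    """
    spec = spec or RenderSpec(encoding="force_network")
    g = nx.DiGraph()
    if net.directed is not None and len(net.directed):
        for _, r in net.directed.iterrows():
            g.add_edge(r["source"], r["target"], te=float(r["te"]))
        g.add_nodes_from(net.panel)
    else:
        g.add_nodes_from(net.panel)
        for _, e in net.edges.iterrows():
            td = float(e["td"])
            if td > 0:
                g.add_edge(e["gene_a"], e["gene_b"], te=float(e["te_ab"]))
            elif td < 0:
                g.add_edge(e["gene_b"], e["gene_a"], te=float(e["te_ba"]))
    if g.number_of_nodes() == 0:
        raise ValueError("empty network: nothing to render")

    raw = nx.spring_layout(g, seed=spec.seed, iterations=80)
    pos = {n: np.asarray(p, dtype=float) for n, p in raw.items()}
    xs = np.array([p[0] for p in pos.values()])
    ys = np.array([p[1] for p in pos.values()])
    span = max(float(np.ptp(xs)), float(np.ptp(ys)), 1e-9)
    margin = 60.0
    scale = (min(spec.width, spec.height) - 2 * margin) / span
    for n in pos:
        pos[n] = np.array(
            [
                margin + (pos[n][0] - xs.min()) * scale,
                margin + (pos[n][1] - ys.min()) * scale,
            ]
        )
    _resolve_overlaps(pos, spec.min_separation)

    root = _root(spec, min_separation=spec.min_separation)
    edges_el = ET.SubElement(root, "g", {"class": "edges"})
    for u, v, data in sorted(g.edges(data=True)):
        p1, p2 = pos[u], pos[v]
        ang = math.atan2(p2[1] - p1[1], p2[0] - p1[0])
        tip = p2 - 16 * np.array([math.cos(ang), math.sin(ang)])
        _line(edges_el, p1[0], p1[1], p2[0], p2[1], "#777777",
              1.0 + 3.0 * data.get("te", 0.2), **{"class": "edge",
              "data_source": u, "data_target": v})
        _arrowhead(edges_el, tip[0], tip[1], ang, 8, "#555555")
    nodes_el = ET.SubElement(root, "g", {"class": "nodes"})
    for n in sorted(pos):
        x, y = pos[n]
        ET.SubElement(nodes_el, "circle",
                      {"cx": _f(x), "cy": _f(y), "r": "14", "fill": _NODE_FILL,
                       "stroke": "#444444", "class": "node", "data-gene": str(n)})
        _text(nodes_el, x, y + 3, str(n), size=9)
    return to_bytes(root)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def render(obj, spec: RenderSpec, **kwargs) -> bytes:
    """Render ``obj`` with the encoding named in ``spec``."""
    fn = {
        "edge_glyph_network": render_edge_glyph_network,
        "flow_graph": render_flow_graph,
        "circular_one_to_many": render_circular,
        "sankey": render_sankey,
        "force_network": render_force_network,
    }[spec.encoding]
    return fn(obj, spec=spec, **kwargs)
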