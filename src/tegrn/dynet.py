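"""Time-resolved transfer networks, their decomposition, and pathway extraction.

Transfer entropy is undefined at a single instant, so a "network per timing
sample" is realized as a sliding window (default 40 samples = 2 h at 3-min
cadence, stride 1): each window yields one all-pairs transfer network whose
edges carry both directed TE values, their difference, and surrogate
p-values.  Windows are labeled with wall-clock ranges, a many-to-many
network is decomposed into per-gene one-to-many views, runs of consecutive
significant windows become significance periods, named clock windows
(e.g. 14:00–16:00) are aggregated into consensus networks, and simple
directed paths from designated promoter genes to a receptor gene are
extracted from the consensus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exprio import ExpressionMatrix, parse_clock
from .tecore import EmbeddingConfig, detrend_linear, pairwise_te_series

__all__ = [
    "Window",
    "TransferNetwork",
    "OneToManyView",
    "SignificanceBlock",
    "Pathway",
    "n_windows",
    "windowed_networks",
    "decompose_one_to_many",
    "significance_periods",
    "aggregate_window",
    "extract_pathways",
    "write_network",
    "read_network",
    "write_pathways",
]

EDGE_COLUMNS = [
    "gene_a", "gene_b", "te_ab", "te_ba", "td",
    "p_ab", "p_ba", "padj_ab", "padj_ba", "max_te",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Window:
    """A half-open sample range [start, stop) with its clock labels."""

    start: int
    stop: int
    start_clock: str
    end_clock: str
    center_minutes: int

    @property
    def length(self) -> int:
        return self.stop - self.start


@dataclass
class TransferNetwork:
    """All-pairs transfer estimates over one window (or one consensus range).

    ``edges`` has one row per unordered pair (columns ``EDGE_COLUMNS``); a
    consensus network additionally carries ``directed`` — one row per
    retained directed edge (source, target, te, te_rev, td, p, n_sig,
    n_windows).
    """

    panel: list[str]
    edges: pd.DataFrame
    window: Window | None = None
    directed: pd.DataFrame | None = None


@dataclass
class SignificanceBlock:
    """A maximal run of windows where one neighbor's transfer is significant."""

    neighbor: str
    direction: str  # "outgoing" (center drives) or "incoming"
    start_window: int
    end_window: int  # inclusive
    start_clock: str
    end_clock: str


@dataclass
class OneToManyView:
    """A center gene's transfer to/from every other panel gene over time.

    Outgoing series are meant to be stacked above the time axis, incoming
    below; ``blocks`` marks significant transfer periods per neighbor.
    """

    center: str
    neighbors: list[str]
    windows: list[Window]
    te_out: np.ndarray  # (n_neighbors, n_windows)
    te_in: np.ndarray
    p_out: np.ndarray   # adjusted p-values, same shape
    p_in: np.ndarray
    blocks: list[SignificanceBlock] = field(default_factory=list)


@dataclass(frozen=True)
class Pathway:
    """A simple directed path from a promoter gene to the receptor gene."""

    genes: tuple[str, ...]
    step_te: tuple[float, ...]
    step_td: tuple[float, ...]
    step_p: tuple[float, ...]

    def __str__(self) -> str:
        return " -> ".join(self.genes)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def n_windows(n_timepoints: int, window_len: int, stride: int) -> int:
    """floor((T − W)/stride) + 1 sliding windows."""
    if window_len > n_timepoints:
        raise ValueError(
            f"window_len {window_len} exceeds series length {n_timepoints}"
        )
    if stride < 1:
        raise ValueError("stride must be ≥ 1")
    return (n_timepoints - window_len) // stride + 1


def _make_window(
    start: int, window_len: int, start_label: str, cadence: float
) -> Window:
    start_min = parse_clock(start_label)
    end_min = int(round(start_min + window_len * cadence)) % (24 * 60)
    center = int(round(start_min + window_len * cadence / 2.0)) % (24 * 60)
    return Window(
        start=start,
        stop=start + window_len,
        start_clock=f"{start_min // 60:02d}:{start_min % 60:02d}",
        end_clock=f"{end_min // 60:02d}:{end_min % 60:02d}",
        center_minutes=center,
    )


def _adjust(edges: pd.DataFrame, method: str) -> pd.DataFrame:
    """Attach padj_ab/padj_ba columns, correcting across all directed tests."""
    edges = edges.copy()
    if edges[["p_ab", "p_ba"]].isna().any().any() or method == "none":
        edges["padj_ab"] = edges["p_ab"]
        edges["padj_ba"] = edges["p_ba"]
        return edges[EDGE_COLUMNS]
    if method != "bh":
        raise ValueError(f"unknown adjustment {method!r}")
    flat = np.concatenate([edges["p_ab"].to_numpy(), edges["p_ba"].to_numpy()])
    adj = multipletests(flat, method="fdr_bh")[1]
    k = len(edges)
    edges["padj_ab"] = adj[:k]
    edges["padj_ba"] = adj[k:]
    return edges[EDGE_COLUMNS]


def windowed_networks(
    m: ExpressionMatrix,
    window_len: int = 40,
    stride: int = 1,
    emb: EmbeddingConfig = EmbeddingConfig(),
    n_bins: int = 3,
    n_surrogates: int | None = 99,
    adjust: str = "none",
    detrend: bool = True,
    seed: int = 0,
) -> list[TransferNetwork]:
    """One transfer network per sliding window.

    Each network's edges are computed only from the samples inside its
    window: series are taken to the log1p scale, linearly detrended within
    the window by default (a 24-h baseline is locally a trend that would
    otherwise dominate the bins), and discretized window-locally with 3
    bins (a 2-h window holds ~40 samples; 3 bins keep the triplet table
    populated).  ``adjust`` chooses the multiple-testing correction applied
    within each window across all directed tests ("none" keeps the raw
    surrogate p-values, "bh" applies Benjamini–Hochberg).
    """
    if window_len < 10:
        raise ValueError("window_len must be at least 10 samples for TE")
    total = n_windows(m.n_timepoints, window_len, stride)
    rng = np.random.default_rng(seed)
    window_seeds = rng.integers(0, 2**31 - 1, size=total)
    labels = m.time_labels
    log_vals = {g: np.log1p(m.series(g)) for g in m.gene_ids}
    nets: list[TransferNetwork] = []
    for w in range(total):
        s = w * stride
        sub = {}
        for g, v in log_vals.items():
            seg = v[s : s + window_len]
            sub[g] = detrend_linear(seg) if detrend else seg
        edges = pairwise_te_series(
            sub,
            emb=emb,
            n_bins=n_bins,
            n_surrogates=n_surrogates,
            seed=int(window_seeds[w]),
        )
        edges = _adjust(edges, adjust)
        win = _make_window(s, window_len, labels[s], m.cadence_minutes)
        nets.append(TransferNetwork(panel=m.gene_ids, edges=edges, window=win))
    return nets


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def decompose_one_to_many(
    nets: list[TransferNetwork] | TransferNetwork, center: str
) -> OneToManyView:
    """Split many-to-many networks into one center gene's view of the rest.

    For each window, ``te_out[i, w]`` is TE(center → neighbor_i) and
    ``te_in[i, w]`` is TE(neighbor_i → center).  Re-assembling the views of
    every center covers each undirected pair exactly twice.
    """
    if isinstance(nets, TransferNetwork):
        nets = [nets]
    if not nets:
        raise ValueError("no networks to decompose")
    panel = nets[0].panel
    if center not in panel:
        raise KeyError(f"center gene {center!r} not in panel")
    neighbors = [g for g in panel if g != center]
    idx = {g: i for i, g in enumerate(neighbors)}
    n_nb, n_w = len(neighbors), len(nets)
    te_out = np.zeros((n_nb, n_w))
    te_in = np.zeros((n_nb, n_w))
    p_out = np.ones((n_nb, n_w))
    p_in = np.ones((n_nb, n_w))
    for w, net in enumerate(nets):
        e = net.edges
        a_is_center = e["gene_a"] == center
        b_is_center = e["gene_b"] == center
        for _, r in e[a_is_center].iterrows():
            i = idx[r["gene_b"]]
            te_out[i, w] = r["te_ab"]
            te_in[i, w] = r["te_ba"]
            p_out[i, w] = r["padj_ab"] if "padj_ab" in e else r["p_ab"]
            p_in[i, w] = r["padj_ba"] if "padj_ba" in e else r["p_ba"]
        for _, r in e[b_is_center].iterrows():
            i = idx[r["gene_a"]]
            te_out[i, w] = r["te_ba"]
            te_in[i, w] = r["te_ab"]
            p_out[i, w] = r["padj_ba"] if "padj_ba" in e else r["p_ba"]
            p_in[i, w] = r["padj_ab"] if "padj_ab" in e else r["p_ab"]
    windows = [n.window for n in nets if n.window is not None]
    if len(windows) != n_w:  # windowless (e.g. consensus) networks: synthesize indices
        windows = [
            n.window or Window(w, w + 1, "00:00", "00:00", 0)
            for w, n in enumerate(nets)
        ]
    return OneToManyView(
        center=center,
        neighbors=neighbors,
        windows=windows,
        te_out=te_out,
        te_in=te_in,
        p_out=np.nan_to_num(p_out, nan=1.0),
        p_in=np.nan_to_num(p_in, nan=1.0),
    )


# ---------------------------------------------------------------------------
# significance periods
# ---------------------------------------------------------------------------

def _runs(sig: np.ndarray, min_run: int, gap_tolerance: int) -> list[tuple[int, int]]:
    """Maximal runs of True, merging gaps of ≤ gap_tolerance, kept if span ≥ min_run."""
    idx = np.flatnonzero(sig)
    if idx.size == 0:
        return []
    runs: list[tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        if i - prev <= gap_tolerance + 1:
            prev = int(i)
        else:
            runs.append((start, prev))
            start = prev = int(i)
    runs.append((start, prev))
    return [(a, b) for a, b in runs if b - a + 1 >= min_run]


def significance_periods(
    view: OneToManyView,
    alpha: float = 0.05,
    min_run: int = 5,
    gap_tolerance: int = 1,
) -> list[SignificanceBlock]:
    """Per neighbor and direction, maximal runs of significant windows.

    A block requires ≥ ``min_run`` consecutive windows with p ≤ alpha; runs
    separated by at most ``gap_tolerance`` non-significant windows are
    merged first, stabilizing the blocks against surrogate noise.  The
    result is also stored on ``view.blocks``.
    """
    blocks: list[SignificanceBlock] = []
    for i, nb in enumerate(view.neighbors):
        for direction, p in (("outgoing", view.p_out[i]), ("incoming", view.p_in[i])):
            for a, b in _runs(p <= alpha, min_run, gap_tolerance):
                blocks.append(
                    SignificanceBlock(
                        neighbor=nb,
                        direction=direction,
                        start_window=a,
                        end_window=b,
                        start_clock=view.windows[a].start_clock,
                        end_clock=view.windows[b].end_clock,
                    )
                )
    view.blocks = blocks
    return blocks


# ---------------------------------------------------------------------------
# consensus over a named clock window
# ---------------------------------------------------------------------------

def _in_clock_range(minutes: int, lo: str, hi: str) -> bool:
    a, b = parse_clock(lo), parse_clock(hi)
    m = minutes % (24 * 60)
    if a == b:
        return True
    if a < b:
        return a <= m < b
    return m >= a or m < b


def aggregate_window(
    nets: list[TransferNetwork],
    start_clock: str,
    end_clock: str,
    alpha: float = 0.05,
) -> TransferNetwork:
    """Consensus network over the windows centered inside a clock range.

    A directed edge is retained iff its direction is significant (adjusted
    p ≤ alpha) in at least half of the covered windows AND those
    significant windows form a contiguous run (single-window gaps
    tolerated) spanning at least half of the range.  Overlapping sliding
    windows make isolated false positives persist across scattered window
    subsets; genuine couplings are significant in one unbroken block, so
    the contiguity requirement removes the former without touching the
    latter.  TE and TD are summarized by their medians across covered
    windows.  When both directions qualify, the median TD's sign picks the
    direction; exact TD ties are dropped.
    """
    covered = [
        n for n in nets
        if n.window is not None
        and _in_clock_range(n.window.center_minutes, start_clock, end_clock)
    ]
    if not covered:
        raise ValueError(f"no windows centered in {start_clock}–{end_clock}")
    panel = covered[0].panel
    n_cov = len(covered)
    need = math.ceil(n_cov / 2)

    key = covered[0].edges[["gene_a", "gene_b"]]
    te_ab = np.vstack([n.edges["te_ab"].to_numpy() for n in covered])
    te_ba = np.vstack([n.edges["te_ba"].to_numpy() for n in covered])
    td = np.vstack([n.edges["td"].to_numpy() for n in covered])
    padj_ab = np.vstack([n.edges["padj_ab"].to_numpy() for n in covered])
    padj_ba = np.vstack([n.edges["padj_ba"].to_numpy() for n in covered])

    sig_ab = np.sum(padj_ab <= alpha, axis=0)
    sig_ba = np.sum(padj_ba <= alpha, axis=0)

    def _contiguous(col: np.ndarray) -> bool:
        runs = _runs(col, min_run=need, gap_tolerance=1)
        return bool(runs)
    med_ab = np.median(te_ab, axis=0)
    med_ba = np.median(te_ba, axis=0)
    med_td = np.median(td, axis=0)

    summary = pd.DataFrame(
        {
            "gene_a": key["gene_a"],
            "gene_b": key["gene_b"],
            "te_ab": med_ab,
            "te_ba": med_ba,
            "td": med_td,
            "p_ab": np.median(padj_ab, axis=0),
            "p_ba": np.median(padj_ba, axis=0),
            "padj_ab": np.median(padj_ab, axis=0),
            "padj_ba": np.median(padj_ba, axis=0),
            "max_te": np.maximum(med_ab, med_ba),
        }
    )

    rows = []
    for i in range(len(key)):
        a, b = key.iloc[i]["gene_a"], key.iloc[i]["gene_b"]
        ab_ok = sig_ab[i] >= need and _contiguous(padj_ab[:, i] <= alpha)
        ba_ok = sig_ba[i] >= need and _contiguous(padj_ba[:, i] <= alpha)
        if ab_ok and ba_ok:
            if med_td[i] > 0:
                ba_ok = False
            elif med_td[i] < 0:
                ab_ok = False
            else:
                continue  # exact tie: undirected, dropped
        for ok, src, dst, te, te_rev, d, p, nsig in (
            (ab_ok, a, b, med_ab[i], med_ba[i], med_td[i],
             np.median(padj_ab[:, i]), sig_ab[i]),
            (ba_ok, b, a, med_ba[i], med_ab[i], -med_td[i],
             np.median(padj_ba[:, i]), sig_ba[i]),
        ):
            if ok:
                rows.append(
                    {
                        "source": src, "target": dst, "te": te, "te_rev": te_rev,
                        "td": d, "p": p, "n_sig": int(nsig), "n_windows": n_cov,
                    }
                )
    directed = pd.DataFrame(
        rows,
        columns=["source", "target", "te", "te_rev", "td", "p", "n_sig", "n_windows"],
    )
    first, last = covered[0].window, covered[-1].window
    win = Window(
        start=first.start,
        stop=last.stop,
        start_clock=start_clock,
        end_clock=end_clock,
        center_minutes=first.center_minutes,
    )
    return TransferNetwork(panel=panel, edges=summary, window=win, directed=directed)


# ---------------------------------------------------------------------------
# pathways
# ---------------------------------------------------------------------------

def extract_pathways(
    net: TransferNetwork,
    sources: list[str] | set[str],
    sink: str,
    max_len: int = 4,
) -> list[Pathway]:
    """All simple directed paths source→…→sink in a consensus network.

    Only retained (significant) directed edges are walked; ``max_len`` caps
    the number of genes in a path (so max_len = 4 allows up to three steps).
    An unreachable sink yields an empty list.  Paths are returned in
    lexicographic order of their gene sequences.
    """
    if net.directed is None:
        raise ValueError("pathway extraction needs a consensus network with directed edges")
    if sink not in net.panel:
        raise KeyError(f"sink gene {sink!r} not in panel")
    if max_len < 2:
        raise ValueError("max_len must be at least 2 genes")
    g = nx.DiGraph()
    g.add_nodes_from(net.panel)
    for _, r in net.directed.iterrows():
        g.add_edge(r["source"], r["target"], te=r["te"], td=r["td"], p=r["p"])
    paths: set[tuple[str, ...]] = set()
    for src in sorted(set(sources)):
        if src not in g or src == sink:
            continue
        for p in nx.all_simple_paths(g, src, sink, cutoff=max_len - 1):
            paths.add(tuple(p))
    out = []
    for genes in sorted(paths):
        steps = [g.edges[genes[i], genes[i + 1]] for i in range(len(genes) - 1)]
        out.append(
            Pathway(
                genes=genes,
                step_te=tuple(float(s["te"]) for s in steps),
                step_td=tuple(float(s["td"]) for s in steps),
                step_p=tuple(float(s["p"]) for s in steps),
            )
        )
    return out


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def write_network(net: TransferNetwork, path: str) -> None:
    """Edge-list TSV; consensus networks write their directed edges."""
    label = "" if net.window is None else f"{net.window.start_clock}-{net.window.end_clock}"
    if net.directed is not None:
        df = net.directed.copy()
    else:
        df = net.edges.copy()
    df["window"] = label
    df.to_csv(path, sep="\t", index=False)


def read_network(path: str) -> TransferNetwork:
    """Read a consensus edge-list TSV back into a TransferNetwork."""
    df = pd.read_csv(path, sep="\t")
    if "source" in df.columns:
        panel = sorted(set(df["source"]) | set(df["target"]))
        return TransferNetwork(
            panel=panel, edges=pd.DataFrame(columns=EDGE_COLUMNS),
            directed=df.drop(columns=["window"], errors="ignore"),
        )
    panel = sorted(set(df["gene_a"]) | set(df["gene_b"]))
    return TransferNetwork(
        panel=panel, edges=df.drop(columns=["window"], errors="ignore")
    )


def write_pathways(pathways: list[Pathway], path: str) -> None:
    """Pathway TSV: arrow-joined chain, min step TE, max step p."""
    df = pd.DataFrame(
        {
            "pathway": [str(p) for p in pathways],
            "n_steps": [len(p.genes) - 1 for p in pathways],
            "min_step_te": [min(p.step_te) if p.step_te else 0.0 for p in pathways],
            "max_step_p": [max(p.step_p) if p.step_p else 1.0 for p in pathways],
        }
    )
    df.to_csv(path, sep="\t", index=False)
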