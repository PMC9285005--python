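"""End-to-end orchestration: simulate/ingest → filter → panel → pairwise TE
→ windowed networks → decomposition → significance → consensus → pathways
→ renderings, driven by a single config, with a JSON run manifest.

Every stage writes its artifact as a plain-text table (TSV) or SVG under
the run directory; the manifest records the config (and its hash), the
seed, package versions, and per-stage row counts, so a rerun with an
identical config reproduces every non-log output byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exprio import (ExpressionMatrix, PanelSelection, filter_expressed,
                     read_matrix, select_panel, write_matrix)
from .simulate import (GroundTruthEdge, Oscillation, SimConfig,
                       default_scenario, simulate_panel, write_ground_truth)
from .tecore import EmbeddingConfig, pairwise_te
from .dynet import (aggregate_window, decompose_one_to_many, extract_pathways,
                    significance_periods, windowed_networks, write_network,
                    write_pathways)
from .viz import (RenderSpec, render_circular, render_edge_glyph_network,
                  render_flow_graph, render_force_network, render_sankey)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger("tegrn")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one pipeline run needs; YAML-serializable."""

    matrix: str | None = None          # input TSV/CSV; None → simulate
    simulate: str | dict | None = "default"
    reference: str = "Aanat"
    min_fpkm: float = 1.0
    panel_enabled: bool = False
    panel_threshold: float = 0.6
    smoothing_window: int = 21
    bins: int = 4
    k: int = 1
    l: int = 1
    log_base: float = 2.0
    surrogates: int = 199
    window_len: int = 40
    stride: int = 1
    window_bins: int = 3
    window_surrogates: int = 99
    adjust: str = "none"
    detrend: bool = True
    alpha: float = 0.05
    clock_windows: list = field(
        default_factory=lambda: [["14:00", "16:00"], ["18:00", "20:00"], ["20:00", "22:00"]]
    )
    sources: list = field(default_factory=lambda: ["Rel", "Polr2A", "Mafk", "Srebf1"])
    sink: str = "Aanat"
    max_len: int = 4
    center: str = "Zmiz1"
    seed: int = 7
    out_dir: str = "tegrn_run"

    def to_dict(self) -> dict:
        return asdict(self)

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def load_config(path: str, **overrides) -> RunConfig:
    """Read a YAML config; keyword overrides (CLI flags) take precedence."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = RunConfig.__dataclass_fields__
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**raw)


def _sim_config(cfg: RunConfig) -> SimConfig:
    if cfg.simulate == "default" or cfg.simulate is None:
        return default_scenario(seed=cfg.seed)
    spec = dict(cfg.simulate)
    spec.setdefault("seed", cfg.seed)
    if "couplings" in spec:
        spec["couplings"] = tuple(
            GroundTruthEdge(
                source=e["source"], target=e["target"],
                lag=int(e.get("lag", 1)), strength=float(e.get("strength", 0.8)),
                active_window=tuple(e.get("active_window", ["00:00", "00:00"])),
            )
            for e in spec["couplings"]
        )
    if "baseline" in spec:
        spec["baseline"] = {
            g: Oscillation(**b) for g, b in spec["baseline"].items()
        }
    if "genes" in spec:
        spec["genes"] = tuple(spec["genes"])
    return SimConfig(**spec)


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage, returning the run directory.

    On failure the partial outputs are kept and a ``FAILED`` marker file
    names the offending stage; the exception is re-raised as
    :class:`PipelineError`.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    manifest: dict = {
        "package": "tegrn",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "artifacts": [],
        "counts": {},
    }

    def artifact(name: str, rows: int | None = None) -> Path:
        manifest["artifacts"].append(name)
        if rows is not None:
            manifest["counts"][name] = rows
        return out / name

    stage = "ingest"
    try:
        # ---- ingest or simulate ------------------------------------------
        if config.matrix:
            m = read_matrix(config.matrix)
            truth = None
            log.info("read matrix %s: %d genes x %d timepoints",
                     config.matrix, m.n_genes, m.n_timepoints)
        else:
            sim = _sim_config(config)
            m, truth = simulate_panel(sim)
            write_ground_truth(truth, artifact("ground_truth.tsv", len(truth)))
            log.info("simulated %d genes x %d timepoints", m.n_genes, m.n_timepoints)
        write_matrix(m, artifact("matrix.tsv", m.n_genes))

        # ---- expression filter -------------------------------------------
        stage = "filter"
        m = filter_expressed(m, config.min_fpkm)
        write_matrix(m, artifact("filtered.tsv", m.n_genes))
        log.info("expression filter (min %s): %d genes kept", config.min_fpkm, m.n_genes)

        # ---- panel selection ---------------------------------------------
        stage = "panel"
        if config.panel_enabled:
            sel = select_panel(
                m,
                PanelSelection(
                    reference_gene=config.reference,
                    threshold=config.panel_threshold,
                    smoothing_window=config.smoothing_window,
                ),
            )
            sel.to_frame().to_csv(
                artifact("panel.tsv", len(sel.selected)), sep="\t", index=False
            )
            m = ExpressionMatrix(m.data.loc[sel.selected], m.cadence_minutes)
            log.info("panel selection around %s: %d genes", config.reference, m.n_genes)

        emb = EmbeddingConfig(k=config.k, l=config.l, log_base=config.log_base)

        # ---- global pairwise TE ------------------------------------------
        stage = "pairwise"
        table = pairwise_te(
            m, emb=emb, n_bins=config.bins,
            n_surrogates=config.surrogates, seed=config.seed,
        )
        table.to_csv(artifact("pairwise_te.tsv", len(table)), sep="\t", index=False)
        log.info("global pairwise TE: %d pairs", len(table))

        # ---- windowed networks -------------------------------------------
        stage = "dynet"
        nets = windowed_networks(
            m, window_len=config.window_len, stride=config.stride, emb=emb,
            n_bins=config.window_bins, n_surrogates=config.window_surrogates,
            adjust=config.adjust, detrend=config.detrend, seed=config.seed,
        )
        all_edges = []
        for i, net in enumerate(nets):
            e = net.edges.copy()
            e.insert(0, "window", i)
            e.insert(1, "start_clock", net.window.start_clock)
            all_edges.append(e)
        pd.concat(all_edges, ignore_index=True).to_csv(
            artifact("windowed_edges.tsv", sum(len(e) for e in all_edges)),
            sep="\t", index=False,
        )
        log.info("windowed networks: %d windows", len(nets))

        # ---- one-to-many view of the center gene -------------------------
        stage = "decompose"
        center = config.center if config.center in m.gene_ids else m.gene_ids[0]
        view = decompose_one_to_many(nets, center)
        blocks = significance_periods(view, alpha=config.alpha)
        pd.DataFrame(
            {
                "neighbor": [b.neighbor for b in blocks],
                "direction": [b.direction for b in blocks],
                "start_window": [b.start_window for b in blocks],
                "end_window": [b.end_window for b in blocks],
                "start_clock": [b.start_clock for b in blocks],
                "end_clock": [b.end_clock for b in blocks],
            }
        ).to_csv(artifact("significance_blocks.tsv", len(blocks)), sep="\t", index=False)
        log.info("one-to-many view of %s: %d significance blocks", center, len(blocks))

        # ---- consensus clock windows and pathways ------------------------
        stage = "consensus"
        consensus = {}
        for lo, hi in config.clock_windows:
            cons = aggregate_window(nets, lo, hi, alpha=config.alpha)
            tag = f"{lo.replace(':', '')}-{hi.replace(':', '')}"
            write_network(cons, artifact(f"consensus_{tag}.tsv", len(cons.directed)))
            consensus[(lo, hi)] = cons
            log.info("consensus %s-%s: %d directed edges", lo, hi, len(cons.directed))

        stage = "pathways"
        all_paths = []
        for (lo, hi), cons in consensus.items():
            sources = [s for s in config.sources if s in cons.panel]
            if not sources or config.sink not in cons.panel:
                continue
            paths = extract_pathways(cons, sources, config.sink, config.max_len)
            tag = f"{lo.replace(':', '')}-{hi.replace(':', '')}"
            write_pathways(paths, artifact(f"pathways_{tag}.tsv", len(paths)))
            all_paths.append(((lo, hi), paths))
            log.info("pathways %s-%s: %d", lo, hi, len(paths))

        # ---- renderings ---------------------------------------------------
        stage = "viz"
        first_cons = next(iter(consensus.values()))
        artifact("glyph_network.svg").write_bytes(
            render_edge_glyph_network(first_cons, RenderSpec("edge_glyph_network", seed=config.seed))
        )
        if len(nets) >= 2:
            artifact("flow_graph.svg").write_bytes(
                render_flow_graph(view, RenderSpec("flow_graph", seed=config.seed))
            )
            artifact("circular.svg").write_bytes(
                render_circular(view, len(nets) // 2,
                                RenderSpec("circular_one_to_many", seed=config.seed))
            )
        for (lo, hi), paths in all_paths:
            if paths:
                tag = f"{lo.replace(':', '')}-{hi.replace(':', '')}"
                artifact(f"sankey_{tag}.html").write_bytes(
                    render_sankey(paths, RenderSpec("sankey", seed=config.seed), html=True)
                )
        artifact("force_network.svg").write_bytes(
            render_force_network(first_cons, RenderSpec("force_network", seed=config.seed))
        )

        stage = "manifest"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        log.info("run complete: %d artifacts in %s", len(manifest["artifacts"]), out)
        return out
    except Exception as exc:  # noqa: BLE001 — every stage failure aborts the run
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc
    finally:
        log.removeHandler(fh)
        fh.close()
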