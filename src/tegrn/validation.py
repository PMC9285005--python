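"""Self-validation benchmarks: estimator correctness, calibration, and
ground-truth recovery, each recomputed from scratch on synthetic data.

These functions back both the acceptance test suite and the
``scripts/acceptance.py`` report.  Every quantity is measured at run time;
nothing is cached or looked up.
"""

from __future__ import annotations

import numpy as np

from .dynet import (aggregate_window, decompose_one_to_many, extract_pathways,
                    n_windows, windowed_networks)
from .exprio import clock_labels
from .simulate import (CoupledBinaryProcess, DEFAULT_PANEL, PROMOTER_GENES,
                       RATE_LIMITING_GENE, analytic_te_copy, default_scenario,
                       simulate_coupled_binary, simulate_panel,
                       two_gene_config)
from .tecore import (DiscreteSeries, EmbeddingConfig, brute_force_te,
                     estimate_pair, surrogate_pvalues, transfer_entropy)

__all__ = [
    "design_counts",
    "oracle_max_abs_diff",
    "copy_process_estimates",
    "antisymmetry_and_nonnegativity",
    "direction_recovery_rate",
    "type1_rejection_rate",
    "scenario_recovery",
    "structural_conservation",
]

_EMB = EmbeddingConfig()


def design_counts() -> tuple[int, int]:
    """(timepoints of a 24-h design at 3-min cadence, panel size).

    Both recomputed: the label generator is asked for a full cycle and the
    shipped panel is counted.
    """
    labels = clock_labels("07:00", int(24 * 60 / 3), 3.0)
    assert labels[0] == "07:00"
    return len(labels), len(DEFAULT_PANEL)


def oracle_max_abs_diff(n_fixtures: int = 1000, seed: int = 0) -> float:
    """Worst |plug-in TE − brute-force TE| over random discrete fixtures."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        n = int(rng.integers(8, 60))
        sx, sy = int(rng.integers(2, 4)), int(rng.integers(2, 4))
        k, l = int(rng.integers(1, 3)), int(rng.integers(1, 3))
        if n < max(k, l) + 2:
            continue
        emb = EmbeddingConfig(k=k, l=l)
        x = DiscreteSeries(rng.integers(0, sx, n), sx)
        y = DiscreteSeries(rng.integers(0, sy, n), sy)
        worst = max(worst, abs(transfer_entropy(x, y, emb) - brute_force_te(x, y, emb)))
    return worst


def copy_process_estimates(
    eps: float = 0.1, n: int = 10_000, seed: int = 0
) -> dict[str, float]:
    """Plug-in TE of the binary copy process vs its closed form."""
    x, y = simulate_coupled_binary(CoupledBinaryProcess(eps, n, seed))
    dx, dy = DiscreteSeries(x, 2), DiscreteSeries(y, 2)
    return {
        "forward": transfer_entropy(dx, dy, _EMB),
        "reverse": transfer_entropy(dy, dx, _EMB),
        "analytic": analytic_te_copy(eps),
    }


def antisymmetry_and_nonnegativity(
    n_fixtures: int = 200, seed: int = 0
) -> dict[str, float]:
    """max |TD(X,Y)+TD(Y,X)| and min TE over random fixtures (both directions)."""
    rng = np.random.default_rng(seed)
    worst_sum, min_te = 0.0, np.inf
    for _ in range(n_fixtures):
        n = int(rng.integers(10, 120))
        sx, sy = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        x = DiscreteSeries(rng.integers(0, sx, n), sx)
        y = DiscreteSeries(rng.integers(0, sy, n), sy)
        te_xy = transfer_entropy(x, y, _EMB)
        te_yx = transfer_entropy(y, x, _EMB)
        td_xy = te_xy - te_yx
        td_yx = te_yx - te_xy
        worst_sum = max(worst_sum, abs(td_xy + td_yx))
        min_te = min(min_te, te_xy, te_yx)
    return {"max_abs_td_sum": worst_sum, "min_te": float(min_te)}


def direction_recovery_rate(n_reps: int = 200, seed: int = 0) -> float:
    """Fraction of strongly coupled simulated pairs with TD > 0 toward the target.

    Each replicate simulates a 2-gene panel (strength 0.8, lag 1, n = 480)
    and checks the sign of the transfer-entropy difference.
    """
    rng = np.random.default_rng(seed)
    base = int(rng.integers(0, 2**31 - 10 * n_reps))
    hits = 0
    for r in range(n_reps):
        m, _ = simulate_panel(two_gene_config(seed=base + r))
        est = estimate_pair(m.series("Src"), m.series("Tgt"), n_surrogates=None)
        hits += est.td > 0
    return hits / n_reps


def type1_rejection_rate(
    n_reps: int = 500,
    n: int = 480,
    n_surrogates: int = 199,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the surrogate test on independent iid Gaussian pairs."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        est = estimate_pair(x, y, n_surrogates=n_surrogates, seed=rng)
        rejections += est.p_xy <= alpha
    return rejections / n_reps


def surrogate_power_rate(
    eps: float = 0.1, n: int = 480, n_reps: int = 100,
    n_surrogates: int = 199, alpha: float = 0.05, seed: int = 0,
) -> float:
    """Detection rate of the surrogate test on the coupled copy process."""
    rng = np.random.default_rng(seed)
    hits = 0
    for r in range(n_reps):
        x, y = simulate_coupled_binary(
            CoupledBinaryProcess(eps, n, int(rng.integers(0, 2**31)))
        )
        est = surrogate_pvalues(DiscreteSeries(x, 2), DiscreteSeries(y, 2),
                                _EMB, n_surrogates=n_surrogates, seed=rng)
        hits += est.p_xy <= alpha
    return hits / n_reps


def scenario_recovery(
    seed: int = 1,
    stride: int = 1,
    n_surrogates: int = 99,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Recover the default two-stage scenario from its own simulation.

    Runs the full windowed analysis (2-h windows) on the shipped scenario,
    aggregates the 14:00–16:00 and 18:00–20:00 consensus networks, and
    measures: the fraction of 14:00–16:00 consensus out-edges whose source
    is one of the four designated promoter genes, how many of the four
    promoters appear as sources, and the fraction of extracted
    promoter→…→Aanat pathway steps that are ground-truth couplings.
    """
    m, truth = simulate_panel(default_scenario(seed=seed))
    true_edges = {(e.source, e.target) for e in truth}
    nets = windowed_networks(
        m, window_len=40, stride=stride, n_surrogates=n_surrogates, seed=seed + 1
    )
    early = aggregate_window(nets, "14:00", "16:00", alpha=alpha)
    n_out = len(early.directed)
    from_promoters = sum(
        1 for _, r in early.directed.iterrows() if r["source"] in PROMOTER_GENES
    )
    late = aggregate_window(nets, "18:00", "20:00", alpha=alpha)
    paths = extract_pathways(late, PROMOTER_GENES, RATE_LIMITING_GENE, max_len=4)
    n_steps = sum(len(p.genes) - 1 for p in paths)
    good_steps = sum(
        1 for p in paths for i in range(len(p.genes) - 1)
        if (p.genes[i], p.genes[i + 1]) in true_edges
    )
    return {
        "out_edges": n_out,
        "out_edge_promoter_fraction": from_promoters / n_out if n_out else 0.0,
        "promoters_recovered": len(
            set(early.directed["source"]) & set(PROMOTER_GENES)
        ),
        "n_pathways": len(paths),
        "pathway_step_consistency": good_steps / n_steps if n_steps else 1.0,
    }


def structural_conservation(seed: int = 0) -> dict[str, float]:
    """Decomposition double-coverage and the sliding-window count formula."""
    from .tecore import pairwise_te
    from .dynet import TransferNetwork

    m, _ = simulate_panel(default_scenario(seed=seed))
    net = TransferNetwork(panel=m.gene_ids, edges=pairwise_te(m, n_surrogates=None))
    covered = sum(
        len(decompose_one_to_many(net, c).neighbors) for c in net.panel
    )
    coverage_ratio = covered / len(net.edges)

    rng = np.random.default_rng(seed)
    ok = 0
    trials = 200
    for _ in range(trials):
        t = int(rng.integers(10, 2000))
        w = int(rng.integers(10, t + 1))
        s = int(rng.integers(1, 50))
        expected = (t - w) // s + 1
        ok += n_windows(t, w, s) == expected
    return {
        "decomposition_coverage_ratio": coverage_ratio,
        "window_formula_ok_fraction": ok / trials,
    }
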