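"""Synthetic circadian expression panels with known directed couplings.

The generator emulates a dense one-day expression time course: a panel of
genes sampled at a fixed cadence over a full 24-h cycle (default 24 genes ×
480 timepoints at 3-min cadence starting 07:00), each gene following a
cosine baseline on the log scale with AR(1) residual noise, and a set of
ground-truth directed couplings that are active only inside stated clock
windows.

The coupling model is first-order Markov by construction, matching the
k = l = 1 embedding of the estimator: inside its active window, a target's
log-expression at time t is a convex combination of its own mean-reverting
autoregressive term and the source's lagged log-expression, plus Gaussian
log-noise.  Expression is floored at 0 after exponentiation.

A coupled binary copy process with an analytic transfer-entropy value
(1 − h(ε) bits toward the target, 0 in reverse) serves as the closed-form
oracle for estimator validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exprio import ExpressionMatrix, clock_labels, clock_to_hours, parse_clock

__all__ = [
    "Oscillation",
    "GroundTruthEdge",
    "SimConfig",
    "CoupledBinaryProcess",
    "simulate_panel",
    "simulate_coupled_binary",
    "analytic_te_copy",
    "binary_entropy",
    "default_scenario",
    "two_gene_config",
    "write_ground_truth",
    "read_ground_truth",
    "DEFAULT_PANEL",
    "PROMOTER_GENES",
    "INTERMEDIATE_GENES",
    "RATE_LIMITING_GENE",
]

# The 24-gene circadian panel of the rat pineal system: the melatonin
# rate-limiting enzyme gene Aanat plus 23 co-cycling regulators.
DEFAULT_PANEL: tuple[str, ...] = (
    "Aanat", "Gli2", "Hif1a", "Rel", "Clock", "Per1", "Per2", "Tef-1",
    "Fos", "Nfkb1", "Arid3A", "Atf1", "Bach1", "E2f6", "Egr1", "Stat3",
    "Hdac1", "Mafk", "Mxi1", "Phf8", "Polr2A", "Rcor1", "Srebf1", "Zmiz1",
)

PROMOTER_GENES: tuple[str, ...] = ("Rel", "Polr2A", "Mafk", "Srebf1")
INTERMEDIATE_GENES: tuple[str, ...] = ("Hif1a", "Bach1", "Clock", "E2f6", "Per2")
RATE_LIMITING_GENE = "Aanat"


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Oscillation:
    """One gene's 24-h cosine baseline on the FPKM scale.

    Expected expression is ``mesor + amplitude · cos(2π (h − phase_hours)/24)``,
    peaking at ``phase_hours`` o'clock; amplitude ≤ mesor keeps it nonnegative.
    """

    mesor: float = 30.0
    amplitude: float = 15.0
    phase_hours: float = 0.0

    def __post_init__(self) -> None:
        if self.mesor < 0 or self.amplitude < 0:
            raise ValueError("mesor and amplitude must be nonnegative")
        if self.amplitude > self.mesor:
            raise ValueError(
                "amplitude exceeds mesor: expected expression would go negative"
            )

    def value(self, hours: np.ndarray) -> np.ndarray:
        return self.mesor + self.amplitude * np.cos(
            2 * math.pi * (hours - self.phase_hours) / 24.0
        )


@dataclass(frozen=True)
class GroundTruthEdge:
    """A directed coupling active inside a clock window.

    ``strength`` in [0, 1] is the convex weight on the lagged source in the
    target's update; ``lag`` is in sampling steps; ``active_window`` is a
    pair of HH:MM labels (start inclusive, end exclusive; may wrap midnight).
    """

    source: str
    target: str
    lag: int = 1
    strength: float = 0.8
    active_window: tuple[str, str] = ("00:00", "00:00")  # whole day

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("self-coupling not allowed")
        if self.lag < 1:
            raise ValueError("lag must be a positive integer number of steps")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")
        for lab in self.active_window:
            parse_clock(lab)  # raises on invalid labels

    def active_at(self, clock_minutes: int) -> bool:
        lo = parse_clock(self.active_window[0])
        hi = parse_clock(self.active_window[1])
        if lo == hi:  # whole day
            return True
        m = clock_minutes % (24 * 60)
        if lo < hi:
            return lo <= m < hi
        return m >= lo or m < hi  # wraps midnight


@dataclass(frozen=True)
class SimConfig:
    """Full description of a synthetic panel.

    ``noise_sd`` is the standard deviation of the Gaussian innovation on the
    log scale (multiplicative noise on the FPKM scale); ``ar_coef`` is the
    mean-reversion weight of the residual AR(1).
    """

    genes: tuple[str, ...] = DEFAULT_PANEL
    n_timepoints: int = 480
    cadence_minutes: float = 3.0
    start_clock: str = "07:00"
    couplings: tuple[GroundTruthEdge, ...] = ()
    baseline: dict[str, Oscillation] = field(default_factory=dict)
    noise_sd: float = 0.25
    ar_coef: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("need at least 2 genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene names")
        if self.n_timepoints < 10:
            raise ValueError("need at least 10 timepoints")
        if self.cadence_minutes <= 0:
            raise ValueError(f"cadence must be positive, got {self.cadence_minutes}")
        parse_clock(self.start_clock)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValueError("ar_coef must lie in [0, 1)")
        for e in self.couplings:
            if e.source not in self.genes or e.target not in self.genes:
                raise ValueError(f"coupling references unknown gene: {e.source}->{e.target}")
        for g in self.baseline:
            if g not in self.genes:
                raise ValueError(f"baseline for unknown gene {g!r}")


@dataclass(frozen=True)
class CoupledBinaryProcess:
    """Driver X of iid uniform bits; Y copies X with one-step lag, flipped w.p. ε."""

    flip_prob: float = 0.1
    length: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_prob <= 0.5:
            raise ValueError("flip_prob must lie in [0, 0.5]")
        if self.length < 2:
            raise ValueError("length must be at least 2")


# ---------------------------------------------------------------------------
# panel simulation
# ---------------------------------------------------------------------------

def simulate_panel(config: SimConfig) -> tuple[ExpressionMatrix, list[GroundTruthEdge]]:
    """Simulate a genes × timepoints FPKM-like panel with known couplings.

    Dynamics on the log1p scale z_i(t):

    * uncoupled: z_i(t) = λ_i(t) + φ·(z_i(t−1) − λ_i(t−1)) + σξ, a
      mean-reverting AR(1) around the log baseline λ_i(t);
    * with active in-edges: a convex combination of the target's own noisy
      update and the lagged sources,
      (1 − S)·(own + σξ) + Σ_e (w_e/Σw)·S·z_src(t − lag_e),
      with total coupling S = min(Σ w_e, 0.95).  The innovation sits inside
      the combination so that ``strength`` is the fraction of the target's
      next-step variability handed over to the sources: strength → 1
      approaches a noiseless copy, the same limit the binary copy-process
      oracle realizes at ε → 0.

    Expression is expm1(z) floored at 0, so identical seeds give bit-identical
    nonnegative matrices.
    """
    rng = np.random.default_rng(config.seed)
    genes = list(config.genes)
    n_g, n_t = len(genes), config.n_timepoints
    labels = clock_labels(config.start_clock, n_t, config.cadence_minutes)
    start_h = clock_to_hours(config.start_clock)
    hours = start_h + np.arange(n_t) * config.cadence_minutes / 60.0

    osc = {g: config.baseline.get(g, Oscillation()) for g in genes}
    lam = np.vstack([np.log1p(osc[g].value(hours)) for g in genes])

    # noise drawn in one fixed-shape block: determinism is independent of couplings
    noise = rng.normal(0.0, config.noise_sd, size=(n_g, n_t)) if config.noise_sd > 0 \
        else np.zeros((n_g, n_t))

    gi = {g: i for i, g in enumerate(genes)}
    in_edges: list[list[GroundTruthEdge]] = [[] for _ in genes]
    for e in config.couplings:
        in_edges[gi[e.target]].append(e)
    start_min = parse_clock(config.start_clock)
    clock_min = [
        int(round(start_min + t * config.cadence_minutes)) % (24 * 60)
        for t in range(n_t)
    ]

    z = np.empty((n_g, n_t))
    z[:, 0] = lam[:, 0] + noise[:, 0]
    phi = config.ar_coef
    for t in range(1, n_t):
        own = lam[:, t] + phi * (z[:, t - 1] - lam[:, t - 1]) + noise[:, t]
        zt = own.copy()
        for i in range(n_g):
            active = [
                e for e in in_edges[i]
                if e.active_at(clock_min[t]) and t - e.lag >= 0 and e.strength > 0
            ]
            if not active:
                continue
            wsum = sum(e.strength for e in active)
            total = min(wsum, 0.95)
            drive = sum(
                (e.strength / wsum) * z[gi[e.source], t - e.lag] for e in active
            )
            zt[i] = (1.0 - total) * own[i] + total * drive
        z[:, t] = zt

    values = np.maximum(np.expm1(z), 0.0)
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=labels)
    return ExpressionMatrix(df, config.cadence_minutes), list(config.couplings)


def default_scenario(seed: int = 0) -> SimConfig:
    """The shipped two-stage circadian scenario on the 24-gene panel.

    Four promoter genes (Rel, Polr2A, Mafk, Srebf1) drive five intermediates
    (Hif1a, Bach1, Clock, E2f6, Per2) from 14:00 to 20:00 at strength 0.8;
    the intermediates drive the late-peaking rate-limiting gene Aanat from
    17:00 to 20:00 with E2f6 as the dominant input, so
    information reaches Aanat only in the evening and its transcript peaks
    near midnight.  All couplings use lag 1 step.
    """
    stage1 = [
        GroundTruthEdge("Rel", "Clock", 1, 0.8, ("14:00", "20:00")),
        GroundTruthEdge("Rel", "Per2", 1, 0.8, ("14:00", "20:00")),
        GroundTruthEdge("Polr2A", "Hif1a", 1, 0.8, ("14:00", "20:00")),
        GroundTruthEdge("Mafk", "Bach1", 1, 0.8, ("14:00", "20:00")),
        GroundTruthEdge("Srebf1", "E2f6", 1, 0.8, ("14:00", "20:00")),
    ]
    stage2_strength = {"E2f6": 0.75, "Hif1a": 0.1, "Clock": 0.05, "Bach1": 0.03, "Per2": 0.02}
    stage2 = [
        GroundTruthEdge(g, RATE_LIMITING_GENE, 1, stage2_strength[g], ("17:00", "20:00"))
        for g in INTERMEDIATE_GENES
    ]
    rng = np.random.default_rng(20221107)  # fixed: baselines are part of the scenario
    baseline: dict[str, Oscillation] = {}
    for g in DEFAULT_PANEL:
        mesor = float(rng.uniform(20.0, 60.0))
        baseline[g] = Oscillation(
            mesor=mesor,
            amplitude=0.5 * mesor,
            phase_hours=float(rng.uniform(0.0, 24.0)),
        )
    # the rate-limiting gene peaks near midnight with a deep rhythm
    baseline[RATE_LIMITING_GENE] = Oscillation(mesor=40.0, amplitude=32.0, phase_hours=0.0)
    # promoters peak mid-afternoon, intermediates early evening
    for i, g in enumerate(PROMOTER_GENES):
        m = 30.0 + 5.0 * i
        baseline[g] = Oscillation(mesor=m, amplitude=0.5 * m, phase_hours=15.0 + 0.5 * i)
    for i, g in enumerate(INTERMEDIATE_GENES):
        m = 25.0 + 4.0 * i
        baseline[g] = Oscillation(mesor=m, amplitude=0.5 * m, phase_hours=18.5 + 0.4 * i)
    return SimConfig(
        genes=DEFAULT_PANEL,
        couplings=tuple(stage1 + stage2),
        baseline=baseline,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# binary copy oracle
# ---------------------------------------------------------------------------

def simulate_coupled_binary(p: CoupledBinaryProcess) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the copy process: X iid uniform bits, Y_{t+1} = X_t ⊕ Bern(ε)."""
    rng = np.random.default_rng(p.seed)
    x = rng.integers(0, 2, size=p.length).astype(np.int64)
    flips = (rng.random(p.length) < p.flip_prob).astype(np.int64)
    y = np.empty(p.length, dtype=np.int64)
    y[0] = rng.integers(0, 2)
    y[1:] = x[:-1] ^ flips[1:]
    return x, y


def binary_entropy(eps: float) -> float:
    """h(ε) = −ε log2 ε − (1−ε) log2(1−ε), with h(0) = h(1) = 0."""
    if eps in (0.0, 1.0):
        return 0.0
    return float(-eps * math.log2(eps) - (1 - eps) * math.log2(1 - eps))


def analytic_te_copy(eps: float, direction: str = "forward") -> float:
    """Closed-form TE of the copy process, in bits.

    Toward the target the uncertainty reduction is 1 − h(ε): the target's
    next bit is the driver's current bit through a binary symmetric channel
    and its own past is useless.  In reverse the driver is iid, so nothing
    is transferred.
    """
    if not 0.0 <= eps <= 0.5:
        raise ValueError("eps must lie in [0, 0.5]")
    if direction == "forward":
        return 1.0 - binary_entropy(eps)
    if direction == "reverse":
        return 0.0
    raise ValueError(f"direction must be 'forward' or 'reverse', got {direction!r}")


# ---------------------------------------------------------------------------
# ground-truth IO
# ---------------------------------------------------------------------------

def write_ground_truth(edges: list[GroundTruthEdge], path: str) -> None:
    """Edge list as 5-column TSV: source, target, lag, strength, window."""
    df = pd.DataFrame(
        {
            "source": [e.source for e in edges],
            "target": [e.target for e in edges],
            "lag": [e.lag for e in edges],
            "strength": [e.strength for e in edges],
            "window": [f"{e.active_window[0]}-{e.active_window[1]}" for e in edges],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_ground_truth(path: str) -> list[GroundTruthEdge]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = []
    for _, r in df.iterrows():
        lo, hi = str(r["window"]).split("-")
        out.append(
            GroundTruthEdge(
                source=r["source"],
                target=r["target"],
                lag=int(r["lag"]),
                strength=float(r["strength"]),
                active_window=(lo, hi),
            )
        )
    return out


def two_gene_config(
    strength: float = 0.8,
    lag: int = 1,
    noise_sd: float = 0.25,
    n_timepoints: int = 480,
    seed: int = 0,
) -> SimConfig:
    """A minimal driver→target pair, coupled all day: the recovery benchmark."""
    return SimConfig(
        genes=("Src", "Tgt"),
        n_timepoints=n_timepoints,
        couplings=(GroundTruthEdge("Src", "Tgt", lag, strength, ("00:00", "00:00")),),
        baseline={
            "Src": Oscillation(30.0, 15.0, 15.0),
            "Tgt": Oscillation(30.0, 15.0, 18.0),
        },
        noise_sd=noise_sd,
        seed=seed,
    )
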