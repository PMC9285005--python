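"""Plug-in transfer entropy, transfer-entropy difference, and surrogate tests.

Transfer entropy (TE) from a source series X to a target series Y is the
reduction in Shannon uncertainty about the target's next value obtained by
knowing the source's past beyond what the target's own past provides:

    TE(X→Y) = Σ p(y_{n+1}, y_n^{(l)}, x_n^{(k)})
                · log [ p(y_{n+1} | y_n^{(l)}, x_n^{(k)}) / p(y_{n+1} | y_n^{(l)}) ]

with source order ``k`` and target order ``l`` both defaulting to 1 (a
first-order Markov embedding).  Probabilities are maximum-likelihood plug-in
frequencies of the discretized series; 0·log 0 terms contribute 0.  The
transfer-entropy difference TD(X,Y) = TE(X→Y) − TE(Y→X) assigns the dominant
direction of influence: TD > 0 means X drives Y.

Significance is assessed with circular-shift surrogates of the *source*
series, which preserve its marginal distribution and (periodic)
autocorrelation — essential for rhythmic data — while destroying any
cross-coupling at a fixed lag.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exprio import ExpressionMatrix

__all__ = [
    "DiscreteSeries",
    "EmbeddingConfig",
    "JointCounts",
    "TEEstimate",
    "discretize",
    "joint_counts",
    "transfer_entropy",
    "transfer_difference",
    "brute_force_te",
    "surrogate_pvalues",
    "estimate_pair",
    "pairwise_te",
    "pairwise_te_series",
    "detrend_linear",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class DiscreteSeries:
    """An integer-valued series on the state space {0, …, n_states−1}."""

    states: np.ndarray
    n_states: int
    bin_edges: np.ndarray | None = None
    origin: str | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1:
            raise ValueError("states must be one-dimensional")
        if self.states.size and (
            self.states.min() < 0 or self.states.max() >= self.n_states
        ):
            raise ValueError("state out of range [0, n_states)")

    def __len__(self) -> int:
        return self.states.size


@dataclass(frozen=True)
class EmbeddingConfig:
    """Markov embedding orders and logarithm base.

    ``k`` past source steps and ``l`` past target steps condition the
    target's next value; both default to 1.  ``log_base`` 2 gives bits,
    ``math.e`` gives nats.
    """

    k: int = 1
    l: int = 1
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.k < 1 or self.l < 1:
            raise ValueError("embedding orders k and l must be positive integers")
        if self.log_base <= 1:
            raise ValueError("log_base must exceed 1")


@dataclass
class JointCounts:
    """Counts over triplets (future target state, target past block, source past block).

    ``counts`` has shape (n_y, n_y**l, n_x**k); past blocks are encoded as
    base-``n_states`` integers, most recent step last.
    """

    counts: np.ndarray
    total: int
    n_y: int
    n_x: int
    emb: EmbeddingConfig


@dataclass
class TEEstimate:
    """Directed transfer entropies for one gene pair, their difference, and p-values."""

    te_xy: float
    te_yx: float
    n_effective: int
    p_xy: float | None = None
    p_yx: float | None = None

    @property
    def td(self) -> float:
        return self.te_xy - self.te_yx


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def discretize(
    series: np.ndarray, n_bins: int = 4, strategy: str = "quantile", origin: str | None = None
) -> DiscreteSeries:
    """Bin a continuous series into integer states.

    ``quantile`` (default) places bin edges at equal-frequency quantiles, so
    occupancies are near-uniform regardless of the measurement scale;
    ``uniform`` uses equal-width bins.  Duplicate edges (heavily tied data)
    collapse, so the realized number of states can be smaller than
    ``n_bins``; a constant series collapses to a single state with a warning.
    """
    x = np.asarray(series, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("series contains non-finite values")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    if np.ptp(x) == 0:
        warnings.warn("constant series: collapsing to a single state", stacklevel=2)
        return DiscreteSeries(np.zeros(x.size, dtype=np.int64), 1, None, origin)
    if strategy == "quantile":
        if x.size < n_bins:
            raise ValueError("series shorter than n_bins for quantile strategy")
        qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
        edges = np.unique(qs)
    elif strategy == "uniform":
        edges = np.linspace(x.min(), x.max(), n_bins + 1)[1:-1]
    else:
        raise ValueError(f"unknown binning strategy {strategy!r}")
    states = np.searchsorted(edges, x, side="right")
    n_states = int(states.max()) + 1
    return DiscreteSeries(states.astype(np.int64), n_states, edges, origin)


def detrend_linear(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares straight line from a series.

    Used on short analysis windows, where a slowly varying 24-h baseline
    appears as a near-linear trend that would otherwise dominate quantile
    bins and mask (or mimic) genuine transfer.
    """
    x = np.asarray(series, dtype=float)
    t = np.arange(x.size, dtype=float)
    t = t - t.mean()
    denom = float(t @ t)
    if denom == 0:
        return x - x.mean()
    slope = float(t @ (x - x.mean())) / denom
    return x - x.mean() - slope * t


# ---------------------------------------------------------------------------
# counting and plug-in TE
# ---------------------------------------------------------------------------

def _block_codes(states: np.ndarray, order: int, n_states: int, t0: int, t1: int) -> np.ndarray:
    """Encode length-``order`` past blocks ending at t for t in [t0, t1) as integers."""
    code = np.zeros(t1 - t0, dtype=np.int64)
    for j in range(order):
        code = code * n_states + states[t0 - j : t1 - j]
    return code


def _triplet_codes(
    x: DiscreteSeries, y: DiscreteSeries, emb: EmbeddingConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """(future y, y past-block code, x past-block code) for every full triplet."""
    n = len(y)
    if len(x) != n:
        raise ValueError("series length mismatch")
    m = max(emb.k, emb.l)
    if n < m + 1:
        raise ValueError(f"series too short for embedding: need ≥ {m + 1} points")
    t0, t1 = m - 1, n - 1  # past block ends at t, future at t+1
    y1 = y.states[t0 + 1 : t1 + 1]
    yp = _block_codes(y.states, emb.l, y.n_states, t0, t1)
    xp = _block_codes(x.states, emb.k, x.n_states, t0, t1)
    return y1, yp, xp, n - m


def joint_counts(x: DiscreteSeries, y: DiscreteSeries, emb: EmbeddingConfig = EmbeddingConfig()) -> JointCounts:
    """Count all (y_{n+1}, y-past block, x-past block) triplets."""
    y1, yp, xp, total = _triplet_codes(x, y, emb)
    n_y, n_x = y.n_states, x.n_states
    n_yp, n_xp = n_y**emb.l, n_x**emb.k
    flat = (y1 * n_yp + yp) * n_xp + xp
    counts = np.bincount(flat, minlength=n_y * n_yp * n_xp).reshape(n_y, n_yp, n_xp)
    return JointCounts(counts, total, n_y, n_x, emb)


def _te_from_counts(counts: np.ndarray, base: float) -> float:
    """Plug-in TE from a (future, target-past, source-past) count array."""
    total = counts.sum()
    if total == 0:
        return 0.0
    n_ypxp = counts.sum(axis=0)            # (yp, xp)
    n_y1yp = counts.sum(axis=2)            # (y1, yp)
    n_yp = counts.sum(axis=(0, 2))         # (yp,)
    nz = counts > 0
    c = counts[nz].astype(float)
    iy1, iyp, ixp = np.nonzero(nz)
    ratio = (c * n_yp[iyp]) / (n_ypxp[iyp, ixp] * n_y1yp[iy1, iyp])
    te = float(np.sum(c * np.log(ratio))) / total / math.log(base)
    return te


def transfer_entropy(
    x: DiscreteSeries, y: DiscreteSeries, emb: EmbeddingConfig = EmbeddingConfig()
) -> float:
    """Plug-in TE(X→Y) of the empirical triplet distribution.

    Nonnegative up to floating-point rounding (it is a conditional mutual
    information of the empirical law); exactly 0 when the source past takes
    a single value.
    """
    return _te_from_counts(joint_counts(x, y, emb).counts.astype(float), emb.log_base)


def transfer_difference(
    x: DiscreteSeries, y: DiscreteSeries, emb: EmbeddingConfig = EmbeddingConfig()
) -> TEEstimate:
    """Both directed TEs and their difference TD = TE(X→Y) − TE(Y→X)."""
    te_xy = transfer_entropy(x, y, emb)
    te_yx = transfer_entropy(y, x, emb)
    m = max(emb.k, emb.l)
    return TEEstimate(te_xy=te_xy, te_yx=te_yx, n_effective=len(x) - m)


def brute_force_te(
    x: DiscreteSeries, y: DiscreteSeries, emb: EmbeddingConfig = EmbeddingConfig()
) -> float:
    """TE(X→Y) by explicit enumeration of every triplet value combination.

    Independent oracle for :func:`transfer_entropy`: loops over all possible
    (future value, target past block, source past block) combinations,
    counting occurrences by scanning the series, and accumulates the
    defining sum with plain Python arithmetic.  Intended for short series.
    """
    n = len(y)
    m = max(emb.k, emb.l)
    if len(x) != n or n < m + 1:
        raise ValueError("series too short or mismatched")
    xs, ys = [int(v) for v in x.states], [int(v) for v in y.states]
    positions = list(range(m - 1, n - 1))  # past block ends at t, future at t+1
    total = len(positions)

    def y_block(t):
        return tuple(ys[t - emb.l + 1 : t + 1])

    def x_block(t):
        return tuple(xs[t - emb.k + 1 : t + 1])

    te = 0.0
    for y1 in range(y.n_states):
        for yp in itertools.product(range(y.n_states), repeat=emb.l):
            for xp in itertools.product(range(x.n_states), repeat=emb.k):
                n_joint = sum(
                    1
                    for t in positions
                    if ys[t + 1] == y1 and y_block(t) == yp and x_block(t) == xp
                )
                if n_joint == 0:
                    continue
                n_ypxp = sum(
                    1 for t in positions if y_block(t) == yp and x_block(t) == xp
                )
                n_y1yp = sum(
                    1 for t in positions if ys[t + 1] == y1 and y_block(t) == yp
                )
                n_yp = sum(1 for t in positions if y_block(t) == yp)
                p_joint = n_joint / total
                cond_full = n_joint / n_ypxp
                cond_marg = n_y1yp / n_yp
                te += p_joint * math.log(cond_full / cond_marg, emb.log_base)
    return te


# ---------------------------------------------------------------------------
# surrogate significance
# ---------------------------------------------------------------------------

def _te_circular_shift_batch(
    x: DiscreteSeries,
    y: DiscreteSeries,
    emb: EmbeddingConfig,
    shifts: np.ndarray,
) -> np.ndarray:
    """TE(X_shifted→Y) for a batch of circular shifts of the source, vectorized.

    Only the source past-block codes change with the shift; the target
    marginals N(y1, yp) and N(yp) are shift-invariant and computed once.
    """
    n = len(y)
    m = max(emb.k, emb.l)
    t0, t1 = m - 1, n - 1
    y1 = y.states[t0 + 1 : t1 + 1]
    yp = _block_codes(y.states, emb.l, y.n_states, t0, t1)
    n_y, n_x = y.n_states, x.n_states
    n_yp_states, n_xp_states = n_y**emb.l, n_x**emb.k
    t_idx = np.arange(t0, t1)

    # source past-block codes under each shift: x_s[t] = x[(t - s) mod n]
    codes = np.zeros((shifts.size, t_idx.size), dtype=np.int64)
    for j in range(emb.k):
        idx = (t_idx[None, :] - j - shifts[:, None]) % n
        codes = codes * n_x + x.states[idx]

    yy = y1 * n_yp_states + yp  # shift-invariant part of the cell code
    flat = yy[None, :] * n_xp_states + codes
    n_cells = n_y * n_yp_states * n_xp_states
    offsets = np.arange(shifts.size)[:, None] * n_cells
    counts = np.bincount(
        (flat + offsets).ravel(), minlength=shifts.size * n_cells
    ).reshape(shifts.size, n_y, n_yp_states, n_xp_states)

    total = t_idx.size
    n_ypxp = counts.sum(axis=1)                      # (S, yp, xp)
    n_y1yp = np.bincount(yy, minlength=n_y * n_yp_states).reshape(n_y, n_yp_states)
    n_yp = n_y1yp.sum(axis=0)                        # (yp,)

    c = counts.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (c * n_yp[None, None, :, None]) / (
            n_ypxp[:, None, :, :] * n_y1yp[None, :, :, None]
        )
        terms = np.where(c > 0, c * np.log(ratio), 0.0)
    return terms.sum(axis=(1, 2, 3)) / total / math.log(emb.log_base)


def _draw_shifts(rng: np.random.Generator, n: int, order: int, n_surrogates: int) -> np.ndarray:
    """Uniform circular shifts that move the source by at least ``order + 1`` steps."""
    lo = order + 1
    hi = n - lo  # inclusive upper bound keeps a symmetric exclusion zone
    if hi < lo:
        raise ValueError("series too short for circular-shift surrogates")
    return rng.integers(lo, hi + 1, size=n_surrogates)


def surrogate_pvalues(
    x: DiscreteSeries,
    y: DiscreteSeries,
    emb: EmbeddingConfig = EmbeddingConfig(),
    n_surrogates: int = 199,
    method: str = "circular_shift",
    seed: int | np.random.Generator = 0,
) -> TEEstimate:
    """Two-sided-direction surrogate test for an ordered pair.

    For each direction the *source* series is circularly shifted by a
    uniform random offset of at least k+1 steps; the p-value uses the
    add-one convention p = (1 + #{surrogate TE ≥ observed}) / (n_surrogates
    + 1), so the smallest attainable p is 1/(n_surrogates+1).
    """
    if n_surrogates < 19:
        raise ValueError("n_surrogates must be at least 19")
    if method != "circular_shift":
        raise ValueError(f"unknown surrogate method {method!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(x)

    te_xy = transfer_entropy(x, y, emb)
    te_yx = transfer_entropy(y, x, emb)

    shifts_x = _draw_shifts(rng, n, emb.k, n_surrogates)
    sur_xy = _te_circular_shift_batch(x, y, emb, shifts_x)
    p_xy = (1 + int(np.sum(sur_xy >= te_xy))) / (n_surrogates + 1)

    shifts_y = _draw_shifts(rng, n, emb.k, n_surrogates)
    sur_yx = _te_circular_shift_batch(y, x, emb, shifts_y)
    p_yx = (1 + int(np.sum(sur_yx >= te_yx))) / (n_surrogates + 1)

    m = max(emb.k, emb.l)
    return TEEstimate(
        te_xy=te_xy, te_yx=te_yx, n_effective=n - m, p_xy=p_xy, p_yx=p_yx
    )


def estimate_pair(
    xs: np.ndarray,
    ys: np.ndarray,
    emb: EmbeddingConfig = EmbeddingConfig(),
    n_bins: int = 4,
    strategy: str = "quantile",
    n_surrogates: int | None = 199,
    seed: int | np.random.Generator = 0,
) -> TEEstimate:
    """Discretize two continuous series and estimate TE/TD (and p-values)."""
    x = discretize(xs, n_bins, strategy)
    y = discretize(ys, n_bins, strategy)
    if n_surrogates is None:
        return transfer_difference(x, y, emb)
    return surrogate_pvalues(x, y, emb, n_surrogates=n_surrogates, seed=seed)


# ---------------------------------------------------------------------------
# all-pairs table
# ---------------------------------------------------------------------------

def pairwise_te(
    m: ExpressionMatrix,
    emb: EmbeddingConfig = EmbeddingConfig(),
    n_bins: int = 4,
    strategy: str = "quantile",
    n_surrogates: int | None = 199,
    seed: int = 0,
) -> pd.DataFrame:
    """TE/TD (and surrogate p-values) for every unordered gene pair.

    Returns one row per pair with both directed estimates, their difference,
    both p-values (NaN when surrogates are disabled), and the summary weight
    ``max_te`` = max(TE(a→b), TE(b→a)) — the retained pair statistic.
    """
    return pairwise_te_series(
        {g: m.series(g) for g in m.gene_ids},
        emb=emb,
        n_bins=n_bins,
        strategy=strategy,
        n_surrogates=n_surrogates,
        seed=seed,
    )


def pairwise_te_series(
    series: dict[str, np.ndarray],
    emb: EmbeddingConfig = EmbeddingConfig(),
    n_bins: int = 4,
    strategy: str = "quantile",
    n_surrogates: int | None = 199,
    seed: int = 0,
) -> pd.DataFrame:
    """As :func:`pairwise_te`, but on a mapping of already-extracted series.

    Accepts arbitrary real-valued series (e.g. detrended log expression),
    which the matrix container deliberately does not.
    """
    genes = list(series)
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes collapse to one state
        disc = {g: discretize(series[g], n_bins, strategy, origin=g) for g in genes}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(genes) * (len(genes) - 1) // 2)
    rows = []
    pair_i = 0
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if n_surrogates is None:
                est = transfer_difference(disc[a], disc[b], emb)
            else:
                est = surrogate_pvalues(
                    disc[a],
                    disc[b],
                    emb,
                    n_surrogates=n_surrogates,
                    seed=np.random.default_rng(children[pair_i]),
                )
            rows.append(
                {
                    "gene_a": a,
                    "gene_b": b,
                    "te_ab": est.te_xy,
                    "te_ba": est.te_yx,
                    "td": est.td,
                    "p_ab": np.nan if est.p_xy is None else est.p_xy,
                    "p_ba": np.nan if est.p_yx is None else est.p_yx,
                    "max_te": max(est.te_xy, est.te_yx),
                }
            )
            pair_i += 1
    return pd.DataFrame(rows)
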