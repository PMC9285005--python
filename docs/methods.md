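# Methods

## The estimation problem

`tegrn` infers *directed* regulatory relations among a panel of co-cycling
genes from a single dense expression time course — the motivating design is
a circadian panel sampled every 3 minutes over one 24-h cycle (480
timepoints), FPKM-scale values, with the melatonin rate-limiting enzyme
gene *Aanat* as the biological readout. With only one cycle and no
perturbations, directionality has to come from temporal asymmetry, which is
what transfer entropy measures.

## Transfer entropy and the transfer-entropy difference

For discretized series X (source) and Y (target), the plug-in transfer
entropy with source order *k* and target order *l* is

    TE(X→Y) = Σ p̂(y_{n+1}, y_n^{(l)}, x_n^{(k)})
              · log[ p̂(y_{n+1} | y_n^{(l)}, x_n^{(k)}) / p̂(y_{n+1} | y_n^{(l)}) ]

summed over every full triplet, with maximum-likelihood (frequency)
probabilities and 0·log 0 = 0. Defaults are k = l = 1 — a first-order
Markov embedding — and base-2 logs (bits). TE is a conditional mutual
information of the empirical law, hence nonnegative up to rounding, exactly
zero when the source past is constant, and invariant to relabeling of the
discrete states. The direction of an edge is assigned by the
transfer-entropy difference TD(X,Y) = TE(X→Y) − TE(Y→X): TD > 0 reads "X
drives Y". TD(X,Y) = −TD(Y,X) holds exactly by construction; TD = 0 is
reported as a tie, drawn undirected and excluded from pathway search.

A brute-force implementation (`brute_force_te`) evaluates the same sum by
explicit enumeration of every triplet value combination with plain Python
arithmetic. It shares no code with the vectorized estimator and serves as
the correctness oracle (agreement to 1e−12 across random fixtures).

### Discretization

Continuous series are binned by equal-frequency (quantile) bins — scale-free
and entropy-maximizing per bin — with 4 bins by default for full-length
(≈480-sample) series. Duplicate quantile edges collapse; a constant series
collapses to a single state with a warning. Equal-width binning is
available.

### Significance

Observed TE is compared against circular-shift surrogates of the *source*
series: a uniformly random rotation of at least k+1 steps preserves the
source's marginal distribution and its (periodic) autocorrelation — which
matters for circadian series, whose full-cycle rotation is nearly
stationary — while destroying any fixed-lag cross-coupling. P-values use
the add-one convention p = (1 + #{TE_surrogate ≥ TE_observed})/(S + 1), so
the smallest attainable p with S surrogates is 1/(S+1); S defaults to 199
for full-length series. On independent series the rejection rate at
α = 0.05 is calibrated (checked against the binomial 99% band over 500
replicates).

## Sliding-window dynamic networks

TE is undefined at a single instant, so "a network per timing sample" is a
sliding window: default 40 samples (2 h at 3-min cadence, the reporting
granularity of the windowed analyses), stride 1. Within each window, every
gene's series is taken to the log1p scale and linearly detrended before
binning: over 2 h a 24-h baseline is locally a near-linear trend that would
otherwise dominate quantile bins, masking genuine transfer and
mis-calibrating the circular-shift surrogates (a rotated trend acquires a
wrap discontinuity). Window-local estimation uses 3 bins — 3³ = 27 triplet
cells against ~39 triplets; 4 bins (64 cells) leaves the table too sparse —
and 99 surrogates per window, a cost/resolution compromise at half a
million window-pair tests per run.

Multiple testing: raw surrogate p-values are compared to α = 0.05 by
default. Benjamini–Hochberg within each window across all directed tests is
implemented (`adjust="bh"`), but with add-one p-values floored at 1/(S+1)
and ~550 directed tests per 24-gene window, BH at α = 0.05 can only ever
reject if dozens of tests sit at the floor; with feasible surrogate counts
it silences everything, so it is not the default.

### One-to-many decomposition and significance periods

Each windowed network is decomposed around a center gene into its outgoing
and incoming TE to all other panel genes; reassembling all centers' views
covers every pair exactly twice. Significance periods are maximal runs of
at least `min_run` = 5 consecutive windows (15 min) with p ≤ α per neighbor
and direction; runs separated by a single non-significant window are merged
(gap tolerance 1), stabilizing blocks against surrogate noise.

### Clock-window consensus

A named clock range (e.g. 14:00–16:00) aggregates the windows whose centers
fall inside it. A directed edge enters the consensus iff it is significant
in at least half of the covered windows *and* those significances form one
gap-tolerant contiguous run spanning at least half the range. The
contiguity condition exists because adjacent sliding windows share almost
all their samples: a single lucky fluctuation stays "significant" across a
scattered subset of overlapping windows and can reach the one-half count by
itself, whereas a genuinely active coupling is significant in one unbroken
block. Consensus TE/TD are medians across covered windows; if both
directions qualify, the median TD's sign decides, and exact ties are
dropped.

### Pathways

On a consensus network, pathway extraction enumerates all simple directed
paths from designated promoter genes to a receptor gene (default cap: 4
genes per path), walking only retained (significant) directed edges,
returned in lexicographic order. A brute-force DFS enumeration backs the
implementation in the tests.

## The synthetic-data generator

Real pineal time courses are not regenerable at desk scale, so the
simulator stands in for the study design: 24 named panel genes × 480
timepoints at 3-min cadence starting 07:00. Each gene follows a cosine
baseline on the FPKM scale, `mesor + amplitude·cos(2π(h − phase)/24)`
(amplitude ≤ mesor keeps it nonnegative), log1p-transformed to λ_i(t). The
uncoupled dynamic is mean-reverting AR(1) around the baseline:

    z_i(t) = λ_i(t) + φ·(z_i(t−1) − λ_i(t−1)) + σξ_t,

with φ = 0.6 and log-scale innovation σ = 0.25 (≈25% multiplicative noise,
a realistic CV for expression measurements). A directed coupling with
strength s, lag ℓ (steps), active inside a clock window, replaces the
target's update by the convex combination

    z_tgt(t) = (1 − S)·(own + σξ) + Σ_e (w_e/Σw)·S·z_src(t − ℓ_e),
    S = min(Σ_e w_e, 0.95).

The innovation sits *inside* the combination so that strength means "the
fraction of the target's next-step variability handed to the source":
s → 1 approaches a noiseless copy, the same limit the binary copy-process
oracle reaches at ε → 0. Expression is expm1(z) floored at 0; identical
seeds give bit-identical matrices. The update is first-order Markov,
matching the estimator's k = l = 1 embedding.

The shipped scenario mirrors a two-stage evening cascade: four promoter
genes (Rel, Polr2A, Mafk, Srebf1) drive five intermediates (Hif1a, Bach1,
Clock, E2f6, Per2) at strength 0.8 from 14:00 to 20:00; the intermediates
drive the late-peaking *Aanat* from 17:00 to 20:00 with E2f6 dominant
(strength 0.75) and the rest minor (0.02–0.1). Two design constraints shape
the numbers: (i) stage 2 starts at 17:00 so that no 2-h window centered
before 16:00 overlaps it — the 14:00–16:00 consensus then contains only
promoter out-edges — while windows centered in 18:00–20:00 overlap it by
well over half; (ii) with several equal-strength inputs to one target, each
source's unique contribution is the total divided by the input count and
becomes undetectable in 40-sample windows for *any* pairwise estimator, so
a realistic recoverable cascade needs a dominant driver, exactly as the
first stage of the modeled biology has E2f6 as *Aanat*'s sole input.

### The analytic oracle

The coupled binary copy process — X iid uniform bits, Y_{t+1} = X_t flipped
with probability ε — has closed-form TE(X→Y) = 1 − h(ε) bits (h the binary
entropy) and TE(Y→X) = 0. It anchors the estimator's consistency
(|estimate − analytic| shrinking in n, within 0.02 bits at n = 10⁴ for
ε = 0.1) and the surrogate test's power.

### What the simulator does not emulate

Counts noise at low expression, unequal per-gene noise, non-sinusoidal
waveforms, transcription–translation delays longer than a few samples,
common technical batch structure, and real regulatory topology. Passing
tests therefore demonstrate that the estimators recover the *stated*
generative couplings under realistic rhythm + noise conditions — not that
the method's biological claims hold on tissue data.

## Panel selection and filtering

"Genes co-trending with the reference" is operationalized as Spearman rank
correlation ≥ 0.6 between moving-average-smoothed series (centered window,
21 points ≈ 1 h), robust to the FPKM scale and invariant to positive affine
rescaling; the reference gene is always selected. The expression filter
drops genes whose maximum over timepoints is below 1 FPKM (the strictest
reading of "completely not expressed"; a mean-based variant is available).

## Visual encodings

All renderers emit deterministic SVG (fixed layout seed ⇒ identical bytes)
with proportionality constants embedded as `data-*` attributes: the
bicolor edge-glyph network (red span ∝ TE(X→Y), blue span ∝ TE(Y→X),
width ∝ sum, arrow from red to blue when TD > 0); the stacked flow graph of
a center gene with red/blue significance blocks; the circular one-to-many
diagram (disc radius ∝ TE, red = center drives, blue = driven, darker =
more significant at p ≤ 0.05 / 0.01 / 0.001); the staged Sankey of
promoter→receptor pathways (link thickness ∝ step TE); and a force-directed
network laid out by a seeded spring embedding followed by deterministic
overlap resolution (minimum node separation enforced).

## Problem sizes used in validation

The validation suite measures: oracle agreement on 1,000 random fixtures;
copy-process consistency at n = 10⁴; direction recovery over 200 simulated
pairs at n = 480; type-I calibration over 500 independent pairs (199
surrogates each); and full scenario recovery on the 24 × 480 panel with
2-h windows at stride 1 (441 windows, 99 surrogates per window-pair
direction). These sizes keep a full validation run in a few minutes on one
core while leaving the binomial/recovery bands tight enough to be
informative.

## Known limitations

Pairwise TE does not condition on third genes: common-driver and chain
motifs can produce genuine (not artifactual) indirect edges, which is
inherent to the method, and the pathway lists should be read accordingly.
Plug-in TE at 40-sample windows is strongly biased upward; the surrogate
comparison absorbs the bias but absolute windowed TE values are not
comparable across window lengths or bin counts. Significance granularity is
floored at 1/(S+1). Higher-order embeddings (k, l > 1) are supported by the
counting machinery but untuned; continuous (kernel/KSG) estimators and
conditional TE are out of scope.
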