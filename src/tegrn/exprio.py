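"""Expression-matrix input/output, expression filtering, and panel selection.

The unit of analysis is a genes × timepoints matrix of nonnegative,
FPKM-scale expression values sampled at a fixed cadence over a circadian
cycle.  Columns carry wall-clock labels ("07:00", "07:03", ...) that wrap
past midnight; chronological order is the column order, never the lexical
order of the labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "PanelSelection",
    "MatrixParseError",
    "clock_labels",
    "parse_clock",
    "clock_to_hours",
    "read_matrix",
    "write_matrix",
    "filter_expressed",
    "select_panel",
]


class MatrixParseError(ValueError):
    """A malformed expression-matrix file (ragged row, duplicate gene, negative value)."""


# ---------------------------------------------------------------------------
# clock labels
# ---------------------------------------------------------------------------

def parse_clock(label: str) -> int:
    """Parse an ``HH:MM`` label to minutes after midnight.

    Raises :class:`ValueError` for anything that is not a valid 24-h time.
    """
    parts = str(label).strip().split(":")
    if len(parts) != 2:
        raise ValueError(f"invalid clock label {label!r}: expected HH:MM")
    try:
        hh, mm = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise ValueError(f"invalid clock label {label!r}: expected HH:MM") from exc
    if not (0 <= hh < 24 and 0 <= mm < 60):
        raise ValueError(f"invalid clock label {label!r}: out of range")
    return 60 * hh + mm


def clock_to_hours(label: str) -> float:
    """Clock label as fractional hours after midnight (07:30 → 7.5)."""
    return parse_clock(label) / 60.0


def clock_labels(start_clock: str, n: int, cadence_minutes: float) -> list[str]:
    """Generate ``n`` HH:MM labels from ``start_clock`` at a fixed cadence.

    Labels wrap past midnight; a 480-point series at 3-min cadence starting
    07:00 ends at 06:57 the next day.
    """
    if cadence_minutes <= 0:
        raise ValueError(f"cadence must be positive, got {cadence_minutes}")
    start = parse_clock(start_clock)
    out = []
    for i in range(n):
        m = int(round(start + i * cadence_minutes)) % (24 * 60)
        out.append(f"{m // 60:02d}:{m % 60:02d}")
    return out


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes × ordered timepoints of nonnegative expression with clock labels.

    Parameters
    ----------
    data:
        DataFrame indexed by gene symbol with one column per timepoint,
        column labels being HH:MM clock strings in chronological order.
    cadence_minutes:
        Sampling interval between consecutive columns, in minutes.
    """

    data: pd.DataFrame
    cadence_minutes: float = 3.0

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise MatrixParseError(f"duplicate gene ids: {dups}")
        vals = self.data.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise MatrixParseError("non-finite expression values present")
        if (vals < 0).any():
            g, t = np.argwhere(vals < 0)[0]
            raise MatrixParseError(
                f"negative expression at gene {self.data.index[g]!r}, "
                f"column {self.data.columns[t]!r}"
            )
        if self.cadence_minutes <= 0:
            raise ValueError(f"cadence must be positive, got {self.cadence_minutes}")
        for lab in self.data.columns:
            parse_clock(lab)  # validates

    # -- convenience accessors ------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time_labels(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def series(self, gene: str) -> np.ndarray:
        return self.data.loc[gene].to_numpy(dtype=float)

    def time_hours(self) -> np.ndarray:
        """Monotone time axis in hours since the first sample (unwrapped)."""
        return np.arange(self.n_timepoints) * self.cadence_minutes / 60.0

    def window(self, start: int, stop: int) -> "ExpressionMatrix":
        """Column slice [start, stop) as a new matrix."""
        return ExpressionMatrix(self.data.iloc[:, start:stop], self.cadence_minutes)

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (
            self.cadence_minutes == other.cadence_minutes
            and self.data.equals(other.data)
        )


@dataclass
class PanelSelection:
    """Result of trend-similarity panel selection around a reference gene."""

    reference_gene: str
    method: str = "spearman"
    threshold: float = 0.6
    smoothing_window: int = 21
    scores: dict[str, float] = field(default_factory=dict)
    selected: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        sel = set(self.selected)
        return pd.DataFrame(
            {
                "gene": list(self.scores),
                "score": [self.scores[g] for g in self.scores],
                "selected": [g in sel for g in self.scores],
            }
        )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _sniff_delimiter(path: str) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_matrix(
    path: str, dialect: str = "auto", cadence_minutes: float | None = None
) -> ExpressionMatrix:
    """Read a genes × timepoints expression table (TSV or CSV).

    The first column holds gene symbols; the header row holds HH:MM clock
    labels.  Cadence defaults to the spacing of the first two labels.
    """
    sep = {"auto": None, "tsv": "\t", "csv": ","}.get(dialect, dialect)
    if sep is None:
        sep = _sniff_delimiter(path)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise MatrixParseError(f"ragged row in {path}: {exc}") from exc
    if df.isna().any().any():
        row = int(np.argwhere(df.isna().any(axis=1).to_numpy())[0][0]) + 2
        raise MatrixParseError(f"ragged or missing values near row {row} of {path}")
    try:
        num = df.astype(float)
    except ValueError as exc:
        raise MatrixParseError(f"non-numeric expression value in {path}: {exc}") from exc
    if cadence_minutes is None:
        labels = [parse_clock(c) for c in num.columns[:2]]
        if len(labels) == 2:
            cadence_minutes = float((labels[1] - labels[0]) % (24 * 60)) or 3.0
        else:
            cadence_minutes = 3.0
    num.index.name = "gene"
    return ExpressionMatrix(num, cadence_minutes)


def write_matrix(m: ExpressionMatrix, path: str) -> None:
    """Write as TSV: header ``gene`` + clock labels, one gene per row.

    Floats are written with ``repr`` precision, so write → read → write is
    byte-stable and read(write(m)) reproduces ``m`` exactly.
    """
    df = m.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# filtering and panel selection
# ---------------------------------------------------------------------------

def filter_expressed(
    m: ExpressionMatrix, min_level: float = 1.0, statistic: str = "max"
) -> ExpressionMatrix:
    """Drop genes whose expression never (default) reaches ``min_level``.

    A gene counted as "completely not expressed" is one whose per-gene
    summary (max over timepoints by default, mean optionally) falls below
    ``min_level`` — on FPKM data the conventional floor is 1.
    """
    if min_level < 0:
        raise ValueError("min_level must be nonnegative")
    if statistic == "max":
        keep = m.data.max(axis=1) >= min_level
    elif statistic == "mean":
        keep = m.data.mean(axis=1) >= min_level
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    if not keep.any():
        warnings.warn("expression filter removed every gene", stacklevel=2)
    return ExpressionMatrix(m.data.loc[keep], m.cadence_minutes)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    return (
        pd.Series(x).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def select_panel(m: ExpressionMatrix, sel: PanelSelection) -> PanelSelection:
    """Score every gene's trend similarity to the reference and select.

    Both the reference series and each candidate are moving-average smoothed
    (centered window, default 21 points ≈ 1 h at 3-min cadence) before a
    Spearman rank correlation is taken; genes scoring at or above the
    threshold are selected.  The reference gene is always selected.
    """
    if sel.reference_gene not in m.data.index:
        raise KeyError(f"reference gene {sel.reference_gene!r} not in matrix")
    if sel.smoothing_window < 1 or sel.smoothing_window % 2 == 0:
        raise ValueError("smoothing_window must be an odd positive integer")
    if sel.method != "spearman":
        raise ValueError(f"unknown similarity method {sel.method!r}")
    ref = _smooth(m.series(sel.reference_gene), sel.smoothing_window)
    scores: dict[str, float] = {}
    selected: list[str] = []
    for gene in m.gene_ids:
        g = _smooth(m.series(gene), sel.smoothing_window)
        if np.ptp(g) == 0 or np.ptp(ref) == 0:
            rho = 1.0 if gene == sel.reference_gene else 0.0
        else:
            rho = float(stats.spearmanr(ref, g).statistic)
        scores[gene] = rho
        if gene == sel.reference_gene or rho >= sel.threshold:
            selected.append(gene)
    return PanelSelection(
        reference_gene=sel.reference_gene,
        method=sel.method,
        threshold=sel.threshold,
        smoothing_window=sel.smoothing_window,
        scores=scores,
        selected=selected,
    )
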