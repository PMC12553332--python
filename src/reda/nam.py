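"""Neighborhood abundance matrix (NAM) via random walk with restart.

Each cell's soft neighborhood is defined by a finite-step random walk with
restart on the SNN graph: with ``r0 = I`` and row-stochastic ``W = D^-1 A``,

    r_s = (1 - alpha) * W @ r_{s-1} + alpha * I

so ``r_s[i, j]`` is the probability mass started at cell i that sits on cell
j after s steps.  Summing rows over the cells of each sample gives the raw
abundance matrix ``R[n, j] = sum_{i in C(n)} r_s[i, j]``; row-normalizing R
gives the NAM ``Q`` (each sample's abundance profile over cell
neighborhoods).

The walk length s is chosen adaptively: neighborhoods are expanded until the
median excess kurtosis of the NAM columns (across samples) either drops by
less than 3 in one step or falls below 8 — the point where neighborhoods stop
being dominated by cells from a few samples while staying as local as
possible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.stats import kurtosis as _kurtosis

from .graph import SnnGraph
from .io import SampleTable

logger = logging.getLogger(__name__)

__all__ = [
    "WalkState",
    "Nam",
    "walk_matrix",
    "rwr_step",
    "nam_from_walk",
    "select_steps",
]

DEFAULT_ALPHA = 0.3
DEFAULT_S_MAX = 50
KURTOSIS_DROP = 3.0
KURTOSIS_FLOOR = 8.0


@dataclass
class WalkState:
    """The M×M restart-walk matrix r_s with its step count and restart prob."""

    r: np.ndarray
    s: int
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"restart probability alpha={self.alpha} outside [0, 1]")
        rowsum = self.r.sum(axis=1)
        if np.abs(rowsum - 1.0).max() > 1e-10:
            raise ValueError("walk matrix rows do not sum to 1")


@dataclass
class Nam:
    """N-samples × M-cells abundance matrix Q (rows sum to 1) plus raw R."""

    Q: np.ndarray
    R_raw: np.ndarray
    sample_ids: list[str]
    cell_barcodes: list[str]
    s_selected: int
    alpha: float
    kurtosis_trace: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.abs(self.Q.sum(axis=1) - 1.0).max() > 1e-10:
            raise ValueError("NAM rows do not sum to 1")
        if self.Q.min() < 0:
            raise ValueError("NAM has negative entries")


def walk_matrix(graph: SnnGraph) -> sp.csr_matrix:
    """Row-stochastic transition matrix W = D^-1 A of the SNN graph."""
    a = graph.adjacency
    deg = np.asarray(a.sum(axis=1)).ravel()
    if np.any(deg <= 0):
        raise ValueError("zero-degree cell: cannot row-normalize")
    return sp.diags(1.0 / deg) @ a


def rwr_step(state: WalkState, W: sp.spmatrix) -> WalkState:
    """One application of the restart-walk recursion (dense r, small graphs)."""
    r_next = (1.0 - state.alpha) * (W @ state.r)
    idx = np.arange(r_next.shape[0])
    r_next[idx, idx] += state.alpha
    return WalkState(r=r_next, s=state.s + 1, alpha=state.alpha)


def _sample_indicator(samples: SampleTable, barcodes: list[str]) -> sp.csr_matrix:
    """N×M indicator: entry (n, i) = 1 iff cell i belongs to sample n."""
    cell_sample = samples.sample_index_of_cells(barcodes)
    counts = np.bincount(cell_sample, minlength=samples.n_samples)
    if np.any(counts == 0):
        empty = [samples.sample_ids[i] for i in np.flatnonzero(counts == 0)]
        raise ValueError(f"samples with zero cells: {empty}")
    m = len(barcodes)
    return sp.csr_matrix(
        (np.ones(m), (cell_sample, np.arange(m))), shape=(samples.n_samples, m)
    )


def nam_from_walk(
    state: WalkState, samples: SampleTable, cell_barcodes: list[str]
) -> Nam:
    """Aggregate a walk matrix into the sample-by-cell NAM.

    R[n, j] sums row i of r over the cells i of sample n; since r is
    row-stochastic the row sums of R equal the sample cell counts, which is
    asserted, and Q is R with rows normalized to 1.
    """
    S = _sample_indicator(samples, cell_barcodes)
    R = np.asarray(S @ state.r)
    cell_counts = np.asarray(S.sum(axis=1)).ravel()
    if np.abs(R.sum(axis=1) - cell_counts).max() > 1e-8:
        raise AssertionError("NAM row sums do not match sample cell counts")
    Q = R / R.sum(axis=1, keepdims=True)
    return Nam(
        Q=Q,
        R_raw=R,
        sample_ids=list(samples.sample_ids),
        cell_barcodes=list(cell_barcodes),
        s_selected=state.s,
        alpha=state.alpha,
    )


def _median_column_kurtosis(Q: np.ndarray, convention: str = "fisher") -> float:
    """Median kurtosis of NAM columns across samples; zero-variance skipped."""
    variances = Q.var(axis=0)
    cols = Q[:, variances > 0]
    if cols.shape[1] == 0:
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        k = _kurtosis(cols, axis=0, fisher=(convention == "fisher"), bias=True)
    return float(np.nanmedian(k))


def select_steps(
    W: sp.spmatrix,
    samples: SampleTable,
    cell_barcodes: list[str],
    alpha: float = DEFAULT_ALPHA,
    s_max: int = DEFAULT_S_MAX,
    kurtosis_convention: str = "fisher",
    return_walk: bool = False,
) -> tuple[WalkState | None, Nam]:
    """Run the restart walk with the kurtosis-based automatic stop.

    After each step the NAM is formed and the median kurtosis of its columns
    (across the N samples) recorded; the walk stops at the first step s where
    the median kurtosis dropped by less than ``KURTOSIS_DROP`` relative to
    step s-1, or is below ``KURTOSIS_FLOOR``.  If neither fires by ``s_max``
    the walk stops there with a warning.

    The recursion is run on the N-row sample-indicator block
    ``R_s = (1-alpha) R_{s-1} W + alpha S`` — algebraically identical to
    aggregating the full M×M walk matrix, at O(N·nnz) per step.  Pass
    ``return_walk=True`` to also materialize the dense M×M walk state
    (small graphs only).

    Requires at least 4 samples (column kurtosis is degenerate below that).
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside (0, 1]")
    if s_max < 1:
        raise ValueError("s_max must be >= 1")
    if samples.n_samples < 4:
        raise ValueError(
            f"need at least 4 samples for the kurtosis stopping rule, got "
            f"{samples.n_samples}"
        )
    S = _sample_indicator(samples, cell_barcodes).toarray()
    cell_counts = S.sum(axis=1)
    W = sp.csr_matrix(W)

    trace: list[tuple[int, float]] = []
    R = S.copy()
    prev_kurt = None
    s_selected = None
    for s in range(1, s_max + 1):
        R = (1.0 - alpha) * (R @ W) + alpha * S
        Q = R / cell_counts[:, None]
        kurt = _median_column_kurtosis(Q, kurtosis_convention)
        trace.append((s, kurt))
        if kurt < KURTOSIS_FLOOR or (
            prev_kurt is not None and prev_kurt - kurt < KURTOSIS_DROP
        ):
            s_selected = s
            break
        prev_kurt = kurt
    if s_selected is None:
        s_selected = s_max
        logger.warning(
            "kurtosis stopping rule did not fire by s_max=%d; using s_max", s_max
        )

    nam = Nam(
        Q=R / R.sum(axis=1, keepdims=True),
        R_raw=R,
        sample_ids=list(samples.sample_ids),
        cell_barcodes=list(cell_barcodes),
        s_selected=s_selected,
        alpha=alpha,
        kurtosis_trace=trace,
    )
    state = None
    if return_walk:
        m = W.shape[0]
        state = WalkState(r=np.eye(m), s=0, alpha=alpha)
        for _ in range(s_selected):
            state = rwr_step(state, W)
    return state, nam
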