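"""Association testing between NAM neighborhoods and a sample phenotype.

The framework follows the covarying-neighborhood-analysis structure: PCA of
the (residualized) NAM across samples, a selection-aware permutation global
test picking the NAM-PC rank k, per-cell neighborhood coefficients through
the rank-k subspace, and an empirical FDR computed by re-running the
coefficient pipeline on phenotype permutations.

Rank selection uses a min-p (Westfall–Young style) statistic: for each
candidate rank k the permutation p-value of R²(y ~ first k PC scores) is
computed, the observed statistic is the minimum of these p-values over k,
and the same minimization is applied within every permutation so the global
p-value accounts for the selection.  A plain max-over-k of R² would be
degenerate — R² is non-decreasing in k and reaches 1 at k = N-1 for any
phenotype — whereas min-p weighs each rank by its own null distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .io import SampleTable
from .nam import Nam
from .util import stage_rng

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationResult",
    "residualize",
    "nam_pca",
    "global_test",
    "local_coefficients",
    "empirical_fdr",
    "association_test",
]

DEFAULT_N_PERM = 1000
DEFAULT_FDR = 0.05
FDR_GRID_SIZE = 50


@dataclass
class AssociationResult:
    """Global p-value, selected rank, per-cell coefficients and FDR table."""

    global_p: float
    k_selected: int
    coefficients: np.ndarray
    fdr_table: list[tuple[float, float]]
    fdr_threshold: float | None
    passing_cells: list[str]
    cell_barcodes: list[str]
    n_permutations: int
    seed: int
    per_k_r2: np.ndarray | None = None
    per_k_p: np.ndarray | None = None
    s_selected: int | None = None
    alpha: float | None = None
    approximate_knn: bool = False
    config: dict | None = None
    kurtosis_trace: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 < self.global_p <= 1.0:
            raise ValueError("global_p outside (0, 1]")
        if np.abs(self.coefficients).max(initial=0.0) > 1.0 + 1e-9:
            raise ValueError("neighborhood coefficients outside [-1, 1]")


def _design_matrix(
    covariates: np.ndarray | None, batch: np.ndarray | None, n_samples: int
) -> np.ndarray | None:
    """Covariates plus one-hot batch (first level dropped), no intercept col."""
    blocks = []
    if covariates is not None:
        blocks.append(np.atleast_2d(np.asarray(covariates, float)).reshape(n_samples, -1))
    if batch is not None:
        levels = np.unique(batch)
        for lv in levels[1:]:
            blocks.append((np.asarray(batch) == lv).astype(float)[:, None])
    if not blocks:
        return None
    return np.hstack(blocks)


def residualize(
    nam: Nam | np.ndarray,
    covariates: np.ndarray | None = None,
    batch: np.ndarray | None = None,
) -> np.ndarray:
    """Center, covariate-residualize, and unit-variance-scale the NAM columns.

    Each column of Q is centered across samples; if covariates (and/or a
    batch label, one-hot encoded) are given, the column is replaced by its
    residual from an OLS fit with intercept.  Columns are then scaled to unit
    variance; zero-variance columns are left at zero.
    """
    Q = nam.Q if isinstance(nam, Nam) else np.asarray(nam, float)
    n = Q.shape[0]
    Qt = Q - Q.mean(axis=0, keepdims=True)
    X = _design_matrix(covariates, batch, n)
    if X is not None:
        Xc = X - X.mean(axis=0, keepdims=True)
        rank = np.linalg.matrix_rank(np.hstack([np.ones((n, 1)), X]))
        if rank < X.shape[1] + 1:
            raise ValueError(
                "covariate design is rank-deficient (collinear with the "
                "intercept or each other); drop redundant columns"
            )
        beta, *_ = np.linalg.lstsq(Xc, Qt, rcond=None)
        Qt = Qt - Xc @ beta
    sd = Qt.std(axis=0, ddof=0)
    nonzero = sd > 1e-12
    Qt[:, nonzero] /= sd[nonzero]
    Qt[:, ~nonzero] = 0.0
    return Qt


def nam_pca(Qt: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thin SVD of the residualized NAM: sample scores U·S, loadings V, S.

    Keeps min(N-1, M) components.  Signs are fixed by making the
    largest-magnitude loading of each component positive, so the
    decomposition is deterministic.
    """
    n, m = Qt.shape
    k = min(n - 1, m)
    u, s, vt = np.linalg.svd(Qt, full_matrices=False)
    u, s, vt = u[:, :k], s[:k], vt[:k]
    n_live = int(np.sum(s > 1e-12 * max(s[0], 1e-300)))
    if n_live == 0:
        raise ValueError("residualized NAM has no non-degenerate components")
    if n_live < 2:
        logger.warning("only one non-degenerate NAM principal component")
    v = vt.T
    flip = np.sign(v[np.abs(v).argmax(axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    v = v * flip
    u = u * flip
    return u * s, v, s


def _center_y(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, float)
    yc = y - y.mean()
    if np.linalg.norm(yc) < 1e-12:
        raise ValueError("phenotype has no variation")
    return yc


def _permute_within_batch(
    y: np.ndarray, batch: np.ndarray | None, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """(n_perm, N) matrix of phenotype permutations, stratified by batch."""
    n = y.size
    perms = np.empty((n_perm, n))
    if batch is None:
        for b in range(n_perm):
            perms[b] = y[rng.permutation(n)]
        return perms
    batch = np.asarray(batch)
    groups = [np.flatnonzero(batch == lv) for lv in np.unique(batch)]
    for g in groups:
        if g.size == 1:
            logger.warning(
                "batch level with a single sample: that sample is unpermutable"
            )
    for b in range(n_perm):
        row = y.copy()
        for g in groups:
            row[g] = y[g][rng.permutation(g.size)]
        perms[b] = row
    return perms


def _r2_per_k(yc_rows: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """R² of each (centered) row of yc_rows on the first k orthonormal basis
    columns, for every k; returns (rows, k_max)."""
    norms = np.linalg.norm(yc_rows, axis=1, keepdims=True)
    proj = yc_rows @ basis
    return np.cumsum(proj**2, axis=1) / norms**2


def _score_basis(scores: np.ndarray, k_max: int) -> np.ndarray:
    """Orthonormal basis of the score columns (they are U·S, so this just
    rescales; QR guards against user-supplied non-orthogonal scores)."""
    q, r = np.linalg.qr(scores[:, :k_max])
    # keep direction aligned with the original columns
    q = q * np.sign(np.diag(r) + (np.diag(r) == 0))
    return q


def global_test(
    scores: np.ndarray,
    y: np.ndarray,
    batch: np.ndarray | None = None,
    k_max: int | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> tuple[float, int, np.ndarray, dict]:
    """Selection-aware permutation test of phenotype vs NAM-PC sample scores.

    Returns ``(global_p, k_selected, per_k_r2, details)`` where details
    carries the per-k permutation p-values and the permutation pool used
    (so the empirical-FDR step can reuse the identical null).
    """
    scores = np.asarray(scores, float)
    n = scores.shape[0]
    if n < 4:
        raise ValueError(f"need at least 4 samples for the permutation test, got {n}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    yc = _center_y(y)
    if k_max is None:
        k_max = min(scores.shape[1], 10)
    k_max = min(k_max, scores.shape[1])
    basis = _score_basis(scores, k_max)

    rng = stage_rng(seed, "global-test-permutations")
    perms = _permute_within_batch(yc, batch, n_perm, rng)
    r2_obs = _r2_per_k(yc[None, :], basis)[0]           # (k_max,)
    r2_perm = _r2_per_k(perms, basis)                   # (n_perm, k_max)

    # permutation p-value per k, and the same quantity for each permutation
    # against the pool (rank-based, counting >= including self)
    p_obs_k = (1 + (r2_perm >= r2_obs[None, :] - 1e-12).sum(axis=0)) / (1 + n_perm)
    # null analogue, counted against the same pool with the same +1 for the
    # pseudo-observed draw, so observed and null p-values share one scale and
    # the observed min-p can attain the 1/(n_perm+1) floor
    counts_ge = rankdata(-r2_perm, axis=0, method="max")
    p_perm_k = (1 + counts_ge) / (1 + n_perm)

    minp_obs = p_obs_k.min()
    minp_perm = p_perm_k.min(axis=1)
    global_p = float((1 + (minp_perm <= minp_obs + 1e-12).sum()) / (1 + n_perm))
    k_selected = int(np.argmin(p_obs_k)) + 1
    details = {
        "per_k_p": p_obs_k,
        "perms": perms,
        "p_perm_k": p_perm_k,
        "basis": basis,
        "k_max": k_max,
    }
    return global_p, k_selected, r2_obs, details


def local_coefficients(
    Qt: np.ndarray,
    V: np.ndarray,
    svals: np.ndarray,
    y: np.ndarray,
    k_selected: int,
) -> np.ndarray:
    """Per-cell neighborhood coefficients through the rank-k PC subspace.

    Coefficient of cell i is the Pearson correlation, across samples, between
    the centered phenotype and the rank-k reconstruction of column i of the
    residualized NAM (the column projected onto the top-k PC subspace).  The
    projection filters the per-cell restart self-mass, which otherwise acts
    as own-sample indicator noise in every raw column.  Cells whose
    reconstructed column has no variance get coefficient 0.
    """
    if k_selected > svals.size:
        raise ValueError(
            f"k_selected={k_selected} exceeds available components ({svals.size})"
        )
    yc = _center_y(y)
    k = k_selected
    us = Qt @ V[:, :k]                                   # (N, k) = U_k * S_k
    numer = (yc @ us) @ V[:, :k].T                       # y^T P_k Qt, (M,)
    recon_norms = np.sqrt((V[:, :k] ** 2 * svals[:k] ** 2).sum(axis=1))
    denom = np.linalg.norm(yc) * recon_norms
    coefs = np.zeros(Qt.shape[1])
    ok = denom > 1e-12
    coefs[ok] = numer[ok] / denom[ok]
    return np.clip(coefs, -1.0, 1.0)


def _null_coefficients(
    perms: np.ndarray,
    k_per_perm: np.ndarray,
    scores: np.ndarray,
    V: np.ndarray,
    svals: np.ndarray,
) -> np.ndarray:
    """Null coefficient vectors, one per permutation, each at its own rank.

    Mirrors :func:`local_coefficients` exactly, vectorized over permutations
    grouped by their selected rank."""
    n_perm, _ = perms.shape
    m = V.shape[0]
    out = np.empty((n_perm, m))
    proj = perms @ scores  # (n_perm, K); col j is y^T U_j S_j
    y_norms = np.linalg.norm(perms, axis=1)
    for k in np.unique(k_per_perm):
        rows = np.flatnonzero(k_per_perm == k)
        numer = proj[rows, :k] @ V[:, :k].T
        recon_norms = np.sqrt((V[:, :k] ** 2 * svals[:k] ** 2).sum(axis=1))
        denom = y_norms[rows, None] * recon_norms[None, :]
        block = np.zeros((rows.size, m))
        ok = np.broadcast_to((recon_norms > 1e-12)[None, :], denom.shape)
        np.divide(numer, denom, out=block, where=ok)
        out[rows] = np.clip(block, -1.0, 1.0)
    return out


def empirical_fdr(
    coefficients: np.ndarray,
    Qt: np.ndarray,
    V: np.ndarray,
    svals: np.ndarray,
    y: np.ndarray,
    batch: np.ndarray | None = None,
    k_max: int | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    fdr: float = DEFAULT_FDR,
    _details: dict | None = None,
) -> tuple[list[tuple[float, float]], float | None, np.ndarray]:
    """Empirical FDR table, threshold t*, and boolean mask of passing cells.

    For each phenotype permutation the full pipeline from rank selection to
    local coefficients is re-run, giving null coefficient vectors.  On a grid
    of 50 thresholds at the quantiles of |observed coefficients|, FDR(t) is
    the permutation-mean null exceedance count over the observed exceedance
    count (at-least-one denominator), clipped to [0, 1] and monotonized by a
    running minimum from the largest threshold down.  t* is the smallest
    threshold with FDR <= ``fdr``; if none qualifies the passing set is empty
    (reported, not an error).

    ``_details`` lets the caller pass the permutation pool of
    :func:`global_test` so both stages share the identical null.
    """
    coefficients = np.asarray(coefficients, float)
    yc = _center_y(y)
    us = Qt @ V  # scores U*S
    if _details is None:
        _, _, _, _details = global_test(
            us, yc, batch=batch, k_max=k_max, n_perm=n_perm, seed=seed
        )
    perms = _details["perms"]
    k_per_perm = np.argmin(_details["p_perm_k"], axis=1) + 1
    null = _null_coefficients(perms, k_per_perm, us, V, svals)

    abs_obs = np.abs(coefficients)
    qs = np.linspace(0.0, 1.0, FDR_GRID_SIZE)
    grid = np.unique(np.quantile(abs_obs, qs))
    abs_null = np.abs(null)
    fdr_vals = np.empty(grid.size)
    for i, t in enumerate(grid):
        null_count = (abs_null >= t).sum(axis=1).mean()
        obs_count = max(1, int((abs_obs >= t).sum()))
        fdr_vals[i] = min(1.0, null_count / obs_count)
    # enforce that a stricter threshold never reports a worse FDR
    fdr_vals = np.minimum.accumulate(fdr_vals)

    table = list(zip(grid.tolist(), fdr_vals.tolist()))
    passing = np.zeros(coefficients.size, bool)
    t_star = None
    ok = np.flatnonzero(fdr_vals <= fdr)
    if ok.size:
        t_star = float(grid[ok[0]])
        passing = abs_obs >= t_star
    else:
        logger.info("no threshold achieves FDR <= %.3g; empty passing set", fdr)
    return table, t_star, passing


def association_test(
    nam: Nam,
    samples: SampleTable,
    k_max: int | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    fdr: float = DEFAULT_FDR,
) -> AssociationResult:
    """Run the full NAM→phenotype association pipeline on one dataset."""
    if samples.n_samples < 4:
        raise ValueError(
            f"association testing needs at least 4 samples, got {samples.n_samples}"
        )
    y = samples.phenotype_vector()
    batch = samples.batch_vector()
    Qt = residualize(nam, covariates=samples.covariate_matrix(), batch=batch)
    scores, V, svals = nam_pca(Qt)
    global_p, k_selected, r2, details = global_test(
        scores, y, batch=batch, k_max=k_max, n_perm=n_perm, seed=seed
    )
    coefs = local_coefficients(Qt, V, svals, y, k_selected)
    table, t_star, passing = empirical_fdr(
        coefs, Qt, V, svals, y, batch=batch, k_max=k_max,
        n_perm=n_perm, seed=seed, fdr=fdr, _details=details,
    )
    if global_p > 0.05:
        # hierarchical testing: localize neighborhoods only when the global
        # association is significant; bounds the null discovery rate by the
        # global test's level
        logger.info(
            "global test not significant (p=%.3g): reporting empty passing set",
            global_p,
        )
        t_star = None
        passing = np.zeros_like(passing)
    barcodes = list(nam.cell_barcodes)
    return AssociationResult(
        global_p=global_p,
        k_selected=k_selected,
        coefficients=coefs,
        fdr_table=table,
        fdr_threshold=t_star,
        passing_cells=[barcodes[i] for i in np.flatnonzero(passing)],
        cell_barcodes=barcodes,
        n_permutations=n_perm,
        seed=seed,
        per_k_r2=r2,
        per_k_p=details["per_k_p"],
        s_selected=nam.s_selected,
        alpha=nam.alpha,
        kurtosis_trace=list(nam.kurtosis_trace),
    )
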