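"""End-to-end pipeline: counts → LSI embedding → SNN graph → NAM → association.

This is the library entry point the CLI wraps.  Every stage logs its
dimensions; a precomputed embedding (e.g. batch-corrected externally) or a
prebuilt SNN graph can be supplied to bypass the corresponding stages.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass

import numpy as np

from . import assoc, graph as graph_mod, nam as nam_mod, preprocess
from .io import CountMatrix, SampleTable
from .util import stage_seed

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    """All pipeline tunables; serialized verbatim into the output JSON."""

    alpha: float = nam_mod.DEFAULT_ALPHA
    k_neighbors: int = graph_mod.DEFAULT_K
    prune: float = graph_mod.DEFAULT_PRUNE
    lsi_components: int = 30
    lsi_drop_first: bool = True
    binarize: bool = True
    s_max: int = nam_mod.DEFAULT_S_MAX
    s_forced: int | None = None  # ablation: skip the kurtosis rule, walk s steps
    kurtosis_convention: str = "fisher"
    n_perm: int = assoc.DEFAULT_N_PERM
    fdr: float = assoc.DEFAULT_FDR
    k_max: int | None = None
    seed: int = 0


def run(
    counts: CountMatrix | None,
    samples: SampleTable,
    config: RunConfig | None = None,
    embedding: np.ndarray | None = None,
    graph: graph_mod.SnnGraph | None = None,
    cell_barcodes: list[str] | None = None,
) -> assoc.AssociationResult:
    """Run the full differential-abundance pipeline on one dataset.

    Either ``counts`` or a precomputed ``embedding`` (cells × d, barcode
    order) must be given; passing ``graph`` additionally skips graph
    construction.  Returns the association result with per-cell
    neighborhood coefficients and the empirical-FDR passing set.
    """
    cfg = config or RunConfig()
    if counts is not None:
        cell_barcodes = list(counts.cell_barcodes)
    if cell_barcodes is None:
        raise ValueError("cell_barcodes required when counts is not given")

    if graph is None:
        if embedding is None:
            if counts is None:
                raise ValueError("need counts, an embedding, or a graph")
            t0 = time.time()
            tf = preprocess.tfidf(counts, binarize=cfg.binarize)
            emb = preprocess.lsi(
                tf,
                n_components=cfg.lsi_components,
                drop_first=cfg.lsi_drop_first,
                random_state=stage_seed(cfg.seed, "lsi"),
            )
            embedding = emb.coords
            logger.info(
                "preprocess: %d peaks x %d cells -> %d dims (%.1fs)",
                tf.shape[0], tf.shape[1], embedding.shape[1], time.time() - t0,
            )
        else:
            logger.info("preprocess: skipped (precomputed embedding provided)")
        t0 = time.time()
        nbrs = graph_mod.knn(embedding, k=cfg.k_neighbors)
        graph = graph_mod.snn_from_knn(nbrs, prune=cfg.prune)
        logger.info(
            "graph: %d cells, %d edges (%.1fs)",
            graph.n_cells, graph.adjacency.nnz // 2, time.time() - t0,
        )
    else:
        logger.info("graph: skipped (prebuilt graph provided)")

    t0 = time.time()
    W = nam_mod.walk_matrix(graph)
    if cfg.s_forced is not None:
        # ablation arm: bypass the kurtosis rule, walk exactly s_forced steps
        nam = _walk_exactly(W, samples, cell_barcodes, cfg.alpha, cfg.s_forced)
    else:
        _, nam = nam_mod.select_steps(
            W, samples, cell_barcodes, alpha=cfg.alpha, s_max=cfg.s_max,
            kurtosis_convention=cfg.kurtosis_convention,
        )
    logger.info("nam: selected s=%d (%.1fs)", nam.s_selected, time.time() - t0)

    t0 = time.time()
    result = assoc.association_test(
        nam, samples, k_max=cfg.k_max, n_perm=cfg.n_perm,
        seed=stage_seed(cfg.seed, "assoc"), fdr=cfg.fdr,
    )
    result.approximate_knn = graph.approximate
    result.config = asdict(cfg)
    logger.info(
        "assoc: global_p=%.4g k=%d, %d/%d cells pass FDR %.2g (%.1fs)",
        result.global_p, result.k_selected, len(result.passing_cells),
        len(cell_barcodes), cfg.fdr, time.time() - t0,
    )
    return result


def _walk_exactly(W, samples, cell_barcodes, alpha, s):
    """NAM after exactly s walk steps, bypassing the kurtosis stopping rule."""
    from .nam import Nam, _sample_indicator

    S = _sample_indicator(samples, cell_barcodes).toarray()
    R = S.copy()
    for _ in range(s):
        R = (1.0 - alpha) * (R @ W) + alpha * S
    return Nam(
        Q=R / R.sum(axis=1, keepdims=True),
        R_raw=R,
        sample_ids=list(samples.sample_ids),
        cell_barcodes=list(cell_barcodes),
        s_selected=s,
        alpha=alpha,
    )
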