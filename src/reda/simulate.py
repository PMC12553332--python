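"""Synthetic multi-sample scATAC-seq with planted differential abundance.

The generator emulates the statistical structure the differential-abundance
test faces in practice: near-binary sparse counts (1–10% of peaks detected
per cell), a handful of latent cell populations, and sample-level variation
in population composition, where exactly one population's abundance differs
between two conditions by a known fold-change.  Ground-truth labels are
recorded so detections can be scored as TPR/FPR.

Model: each population p has a Gaussian cluster center in a latent space;
a cell's latent position is its population center plus isotropic noise.  A
random peak-loading matrix maps latent positions to per-peak Bernoulli
logits, with a global intercept calibrated by bisection so the mean per-cell
detection fraction hits ``target_sparsity``.  Counts are Bernoulli draws
(optionally with Poisson bursts on detected peaks).  Per-sample population
mixing weights differ between conditions only for ``da_population``, whose
weight is multiplied by ``da_effect`` in condition 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .io import CountMatrix, SampleTable, write_count_matrix
from .util import stage_rng

__all__ = ["SimConfig", "SimTruth", "simulate_dataset", "evaluate", "write_dataset"]

LATENT_DIM = 10
CLUSTER_SEPARATION = 4.0  # distance scale between population centers


@dataclass
class SimConfig:
    """Parameters of the synthetic benchmark generator (defaults = the
    standard two-condition benchmark: 2×5 samples, 400 cells each, 3000
    peaks, 4 populations with the DA population at 15% baseline abundance
    and a 3-fold abundance shift, 5% mean detection)."""

    n_samples_per_condition: int = 5
    cells_per_sample: int = 400
    n_peaks: int = 3000
    n_populations: int = 4
    da_population: int = 0
    da_effect: float = 3.0
    da_baseline_weight: float = 0.15
    target_sparsity: float = 0.05
    noise_sd: float = 1.0
    burst_rate: float = 0.0  # expected extra Poisson counts on detected peaks
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.target_sparsity < 1.0:
            raise ValueError("target_sparsity must lie in (0, 1)")
        if not 0 <= self.da_population < self.n_populations:
            raise ValueError("da_population must index a population")
        if self.da_effect < 1.0:
            raise ValueError("da_effect must be >= 1 (fold-change)")
        if self.n_peaks * self.target_sparsity < 1.0:
            raise ValueError(
                f"target_sparsity={self.target_sparsity} unattainable with "
                f"{self.n_peaks} peaks (expected detections per cell < 1)"
            )


@dataclass
class SimTruth:
    """Ground-truth labels: per-cell population, DA membership, condition."""

    cell_population: np.ndarray
    is_da_cell: np.ndarray
    condition_per_sample: dict[str, int]
    cell_barcodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.array_equal(
            self.is_da_cell, self.cell_population == self.da_population
        ):
            raise ValueError("DA flags inconsistent with population labels")

    @property
    def da_population(self) -> int:
        pops = np.unique(self.cell_population[self.is_da_cell])
        return int(pops[0]) if pops.size else -1


def _mixing_weights(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Population weights for condition 0 and 1; only the DA population's
    weight changes (by factor da_effect), then both are renormalized."""
    base = np.full(cfg.n_populations, (1.0 - cfg.da_baseline_weight) / (cfg.n_populations - 1))
    base[cfg.da_population] = cfg.da_baseline_weight
    shifted = base.copy()
    shifted[cfg.da_population] *= cfg.da_effect
    return base / base.sum(), shifted / shifted.sum()


def _calibrate_intercept(logits: np.ndarray, target: float) -> float:
    """Bisection on the global intercept so mean sigmoid hits the target.

    Calibrated on a deterministic strided subsample of cells, which is ample
    for a mean over millions of entries."""
    step = max(1, logits.shape[0] // 500)
    logits = logits[::step]
    lo, hi = -30.0, 30.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        mean = float(np.mean(1.0 / (1.0 + np.exp(-(logits + mid)))))
        if mean < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_dataset(config: SimConfig) -> tuple[CountMatrix, SampleTable, SimTruth]:
    """Generate one synthetic dataset; fixed seed gives a byte-identical
    dataset."""
    cfg = config
    rng = stage_rng(cfg.seed, "simulate")
    n_samples = 2 * cfg.n_samples_per_condition
    m = n_samples * cfg.cells_per_sample

    centers = rng.normal(size=(cfg.n_populations, LATENT_DIM)) * CLUSTER_SEPARATION
    loadings = rng.normal(size=(cfg.n_peaks, LATENT_DIM)) / np.sqrt(LATENT_DIM)

    w0, w1 = _mixing_weights(cfg)
    sample_ids = [f"s{idx + 1}" for idx in range(n_samples)]
    condition = {
        s: (0 if idx < cfg.n_samples_per_condition else 1)
        for idx, s in enumerate(sample_ids)
    }

    populations = np.empty(m, dtype=int)
    cell_sample = np.empty(m, dtype=int)
    for idx, s in enumerate(sample_ids):
        lo = idx * cfg.cells_per_sample
        w = w0 if condition[s] == 0 else w1
        populations[lo : lo + cfg.cells_per_sample] = rng.choice(
            cfg.n_populations, size=cfg.cells_per_sample, p=w
        )
        cell_sample[lo : lo + cfg.cells_per_sample] = idx

    latent = centers[populations] + cfg.noise_sd * rng.normal(size=(m, LATENT_DIM))
    logits = latent @ loadings.T  # cells x peaks
    intercept = _calibrate_intercept(logits, cfg.target_sparsity)
    probs = 1.0 / (1.0 + np.exp(-(logits + intercept)))
    detected = rng.random(size=probs.shape) < probs
    # guarantee every cell detects at least one peak (empty droplets would be
    # removed by upstream QC and the pipeline rejects zero-count cells)
    empty = np.flatnonzero(~detected.any(axis=1))
    if empty.size:
        detected[empty, probs[empty].argmax(axis=1)] = True
    counts = detected.astype(np.int64)
    if cfg.burst_rate > 0:
        counts[detected] += rng.poisson(cfg.burst_rate, size=int(detected.sum()))

    barcodes = [f"cell{i + 1:05d}" for i in range(m)]
    peaks = [("chr1", 1000 * p, 1000 * p + 500) for p in range(cfg.n_peaks)]
    count_matrix = CountMatrix(sp.csr_matrix(counts.T), peaks, barcodes)

    table = SampleTable(
        cell_to_sample={b: sample_ids[cell_sample[i]] for i, b in enumerate(barcodes)},
        sample_phenotype={s: float(condition[s]) for s in sample_ids},
        sample_ids=sample_ids,
    )
    truth = SimTruth(
        cell_population=populations,
        is_da_cell=populations == cfg.da_population,
        condition_per_sample=condition,
        cell_barcodes=barcodes,
    )
    return count_matrix, table, truth


def evaluate(predicted_passing: set[str], truth: SimTruth) -> tuple[float, float]:
    """TPR and FPR of a predicted set of DA cell barcodes against the truth.

    TPR = |pred ∩ DA| / |DA|, FPR = |pred ∩ notDA| / |notDA|.  An empty DA
    set yields TPR = NaN with a warning.
    """
    pred = np.array([b in predicted_passing for b in truth.cell_barcodes])
    da = truth.is_da_cell
    n_da = int(da.sum())
    n_not = int((~da).sum())
    if n_da == 0:
        import warnings

        warnings.warn("no ground-truth DA cells: TPR undefined (NaN)")
        tpr = float("nan")
    else:
        tpr = float((pred & da).sum() / n_da)
    fpr = float((pred & ~da).sum() / n_not) if n_not else 0.0
    return tpr, fpr


def write_dataset(
    counts: CountMatrix, samples: SampleTable, truth: SimTruth, out_dir: str | Path
) -> None:
    """Write the MTX/TSV triplet, the two metadata tables, and truth labels."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_count_matrix(counts, out)
    with open(out / "cells.csv", "w") as fh:
        fh.write("barcode,sample\n")
        for b in counts.cell_barcodes:
            fh.write(f"{b},{samples.cell_to_sample[b]}\n")
    with open(out / "samples.csv", "w") as fh:
        fh.write("sample,phenotype\n")
        for s in samples.sample_ids:
            fh.write(f"{s},{samples.sample_phenotype[s]:g}\n")
    with open(out / "truth.tsv", "w") as fh:
        fh.write("barcode\tpopulation\tis_da_cell\n")
        for b, p, d in zip(
            counts.cell_barcodes, truth.cell_population, truth.is_da_cell
        ):
            fh.write(f"{b}\t{p}\t{str(bool(d)).lower()}\n")
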