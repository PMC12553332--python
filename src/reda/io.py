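"""Readers, writers and validation for the cell–sample–phenotype data model.

The canonical on-disk interchange is the 10x-style triplet: a Matrix Market
peak-by-cell count matrix plus a barcodes TSV and a peaks BED/TSV.  Sample
metadata comes as two small tables: one mapping cell barcodes to sample ids,
one mapping sample ids to a numeric phenotype (plus optional covariates and a
batch label).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "SampleTable",
    "FormatError",
    "ValidationError",
    "read_count_matrix",
    "read_dense_matrix",
    "read_sample_table",
    "read_embedding",
    "write_count_matrix",
    "write_results",
    "read_coefficients",
]


class FormatError(ValueError):
    """A file could not be parsed as the expected format."""


class ValidationError(ValueError):
    """Parsed data violates an invariant of the data model."""


@dataclass
class CountMatrix:
    """Sparse non-negative peak-by-cell counts with peak and barcode labels.

    ``counts`` has one row per peak and one column per cell; ``peak_ids`` are
    (chrom, start, end) tuples in 0-based half-open convention, treated as
    opaque labels by the downstream algorithm.
    """

    counts: sp.csr_matrix
    peak_ids: list[tuple[str, int, int]]
    cell_barcodes: list[str]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape[0] != len(self.peak_ids):
            raise ValidationError(
                f"count matrix has {self.counts.shape[0]} rows but "
                f"{len(self.peak_ids)} peaks"
            )
        if self.counts.shape[1] != len(self.cell_barcodes):
            raise ValidationError(
                f"count matrix has {self.counts.shape[1]} columns but "
                f"{len(self.cell_barcodes)} barcodes"
            )
        if len(set(self.cell_barcodes)) != len(self.cell_barcodes):
            raise ValidationError("duplicate cell barcodes")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative count entries")

    @property
    def n_peaks(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]


@dataclass
class SampleTable:
    """Cell→sample assignment and per-sample phenotype/covariates/batch.

    ``sample_ids`` fixes the sample ordering used for every sample-indexed
    matrix downstream (the NAM rows, the phenotype vector y, ...).
    """

    cell_to_sample: dict[str, str]
    sample_phenotype: dict[str, float]
    sample_covariates: dict[str, np.ndarray] | None = None
    sample_batch: dict[str, str] | None = None
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sample_ids:
            self.sample_ids = sorted(self.sample_phenotype)
        missing = set(self.cell_to_sample.values()) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"cells assigned to unknown samples: {sorted(missing)}")
        phen = [self.sample_phenotype[s] for s in self.sample_ids]
        if len(set(phen)) < 2:
            raise ValidationError("phenotype has no variation")
        if self.sample_covariates is not None:
            dims = {np.atleast_1d(v).size for v in self.sample_covariates.values()}
            if len(dims) > 1:
                raise ValidationError("ragged covariate vectors across samples")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def phenotype_vector(self) -> np.ndarray:
        return np.array([self.sample_phenotype[s] for s in self.sample_ids], float)

    def covariate_matrix(self) -> np.ndarray | None:
        if self.sample_covariates is None:
            return None
        return np.vstack(
            [np.atleast_1d(np.asarray(self.sample_covariates[s], float)) for s in self.sample_ids]
        )

    def batch_vector(self) -> np.ndarray | None:
        if self.sample_batch is None:
            return None
        return np.array([self.sample_batch[s] for s in self.sample_ids])

    def sample_index_of_cells(self, barcodes: list[str]) -> np.ndarray:
        """Integer sample index (into sample_ids) for each barcode, in order."""
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[self.cell_to_sample[b]] for b in barcodes], int)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise ValidationError(f"cell barcode without sample assignment: {exc}") from exc


def _read_lines(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip()]


def _parse_peaks(path: str | Path) -> list[tuple[str, int, int]]:
    peaks = []
    for ln, line in enumerate(_read_lines(path), 1):
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 3:
            raise FormatError(f"{path}: line {ln} has fewer than 3 columns")
        try:
            peaks.append((parts[0], int(parts[1]), int(parts[2])))
        except ValueError as exc:
            raise FormatError(f"{path}: line {ln}: non-integer coordinate") from exc
    return peaks


def read_count_matrix(
    mtx_path: str | Path, barcodes_path: str | Path, peaks_path: str | Path
) -> CountMatrix:
    """Read a Matrix Market peak-by-cell matrix with its barcode/peak sidecars."""
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:
        raise FormatError(f"{mtx_path}: not valid Matrix Market: {exc}") from exc
    mat = sp.csr_matrix(mat)
    barcodes = _read_lines(barcodes_path)
    peaks = _parse_peaks(peaks_path)
    if mat.shape[0] != len(peaks):
        raise FormatError(
            f"{peaks_path}: {len(peaks)} peaks but matrix {mtx_path} has {mat.shape[0]} rows"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"{barcodes_path}: {len(barcodes)} barcodes but matrix {mtx_path} has "
            f"{mat.shape[1]} columns"
        )
    return CountMatrix(mat, peaks, barcodes)


def read_dense_matrix(
    tsv_path: str | Path, barcodes_path: str | Path, peaks_path: str | Path
) -> CountMatrix:
    """Dense-TSV loader for tiny fixtures; rows are peaks, columns cells."""
    dense = np.loadtxt(tsv_path, ndmin=2)
    return CountMatrix(sp.csr_matrix(dense), _parse_peaks(peaks_path), _read_lines(barcodes_path))


def write_count_matrix(counts: CountMatrix, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(counts.counts), field="integer")
    (out / "barcodes.tsv").write_text("".join(b + "\n" for b in counts.cell_barcodes))
    (out / "peaks.bed").write_text(
        "".join(f"{c}\t{s}\t{e}\n" for c, s, e in counts.peak_ids)
    )


def read_sample_table(cells_csv: str | Path, samples_csv: str | Path) -> SampleTable:
    """Read cell→sample and sample→phenotype(+covariates,batch) tables.

    ``cells_csv`` needs columns ``barcode,sample``; ``samples_csv`` needs
    ``sample,phenotype`` and may add a ``batch`` column plus any number of
    numeric covariate columns.
    """
    cells = pd.read_csv(cells_csv, sep=None, engine="python")
    samples = pd.read_csv(samples_csv, sep=None, engine="python")
    for col in ("barcode", "sample"):
        if col not in cells.columns:
            raise FormatError(f"{cells_csv}: missing column '{col}'")
    for col in ("sample", "phenotype"):
        if col not in samples.columns:
            raise FormatError(f"{samples_csv}: missing column '{col}'")
    sample_ids = [str(s) for s in samples["sample"]]
    phen = dict(zip(sample_ids, samples["phenotype"].astype(float)))
    batch = None
    if "batch" in samples.columns:
        batch = dict(zip(sample_ids, samples["batch"].astype(str)))
    cov_cols = [c for c in samples.columns if c not in ("sample", "phenotype", "batch")]
    cov = None
    if cov_cols:
        cov = {
            s: np.asarray(row, float)
            for s, row in zip(sample_ids, samples[cov_cols].to_numpy())
        }
    cell_to_sample = dict(zip(cells["barcode"].astype(str), cells["sample"].astype(str)))
    table = SampleTable(cell_to_sample, phen, cov, batch, sample_ids)
    return table


def read_embedding(tsv_path: str | Path, n_cells: int | None = None) -> np.ndarray:
    """Headerless TSV embedding, one row per cell in barcode order."""
    coords = np.loadtxt(tsv_path, ndmin=2)
    if n_cells is not None and coords.shape[0] != n_cells:
        raise FormatError(
            f"{tsv_path}: {coords.shape[0]} rows but dataset has {n_cells} cells"
        )
    if not np.all(np.isfinite(coords)):
        raise ValidationError(f"{tsv_path}: embedding contains NaN/Inf")
    return coords


def write_results(result, out_dir: str | Path) -> dict[str, Path]:
    """Write per-cell coefficients TSV, global-summary JSON, and FDR table TSV.

    Returns the paths written.  ``result`` is an
    :class:`reda.assoc.AssociationResult`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "coefficients": out / "coefficients.tsv",
        "summary": out / "summary.json",
        "fdr_table": out / "fdr_table.tsv",
    }
    passing = set(result.passing_cells)
    with open(paths["coefficients"], "w") as fh:
        fh.write("barcode\tcoefficient\tpasses_fdr_05\n")
        for bc, coef in zip(result.cell_barcodes, result.coefficients):
            fh.write(f"{bc}\t{coef:.17g}\t{str(bc in passing).lower()}\n")
    summary = {
        "global_p": result.global_p,
        "k_selected": int(result.k_selected),
        "s_selected": None if result.s_selected is None else int(result.s_selected),
        "alpha": result.alpha,
        "n_permutations": int(result.n_permutations),
        "seed": int(result.seed),
        "fdr_threshold": result.fdr_threshold,
        "n_passing": len(result.passing_cells),
        "approximate_knn": bool(getattr(result, "approximate_knn", False)),
        "config": getattr(result, "config", None),
    }
    paths["summary"].write_text(json.dumps(summary, indent=2) + "\n")
    with open(paths["fdr_table"], "w") as fh:
        fh.write("threshold\tfdr\n")
        for t, f in result.fdr_table:
            fh.write(f"{t:.17g}\t{f:.17g}\n")
    return paths


def read_coefficients(tsv_path: str | Path) -> pd.DataFrame:
    """Round-trip reader for the per-cell coefficients TSV."""
    return pd.read_csv(tsv_path, sep="\t")
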