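import numpy as np
import pytest
import scipy.sparse as sp

import reda
from reda.io import CountMatrix, SampleTable


@pytest.fixture(scope="session")
def small_sim():
    """A reduced two-condition dataset (10 samples x 60 cells, 500 peaks)."""
    cfg = reda.SimConfig(cells_per_sample=60, n_peaks=500, seed=7)
    return reda.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_nam(small_sim):
    """NAM of the reduced dataset at default walk parameters."""
    counts, samples, _ = small_sim
    tf = reda.preprocess.tfidf(counts)
    emb = reda.preprocess.lsi(tf, n_components=20, random_state=0)
    nbrs = reda.graph.knn(emb.coords, k=10)
    g = reda.graph.snn_from_knn(nbrs)
    W = reda.walk_matrix(g)
    _, nam = reda.select_steps(W, samples, counts.cell_barcodes)
    return W, nam


@pytest.fixture()
def toy_counts():
    """3 peaks x 4 cells with simple integer counts."""
    mat = sp.csr_matrix(
        np.array([[1, 0, 2, 0], [1, 1, 0, 1], [0, 3, 1, 1]], dtype=np.int64)
    )
    peaks = [("chr1", 0, 100), ("chr1", 200, 300), ("chr2", 0, 50)]
    return CountMatrix(mat, peaks, ["c1", "c2", "c3", "c4"])


@pytest.fixture()
def toy_samples():
    return SampleTable(
        cell_to_sample={"c1": "s1", "c2": "s1", "c3": "s2", "c4": "s2"},
        sample_phenotype={"s1": 0.0, "s2": 1.0},
        sample_ids=["s1", "s2"],
    )


def two_cell_walk(alpha=0.3, steps=2):
    """The hand-checked 2-cell chain: W = [[0,1],[1,0]]."""
    W = sp.csr_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
    state = reda.WalkState(r=np.eye(2), s=0, alpha=alpha)
    for _ in range(steps):
        state = reda.nam.rwr_step(state, W)
    return W, state
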