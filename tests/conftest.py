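import os

os.environ.setdefault("MPLBACKEND", "Agg")

import numpy as np
import pytest
import scipy.sparse as sp

from crossclust import ClusterLabels, CountMatrix, normalize_log


@pytest.fixture
def toy_counts() -> CountMatrix:
    """3 genes x 4 cells, deterministic."""
    counts = np.array([[3, 0, 1, 2],
                       [0, 5, 0, 1],
                       [1, 1, 1, 1]])
    return CountMatrix(genes=["gA", "gB", "gC"], cells=["c1", "c2", "c3", "c4"],
                       counts=sp.csr_matrix(counts), species="test")


@pytest.fixture
def two_cluster_norm():
    """30 + 30 cells, 20 genes; gene 'gM' drawn with 4x mean in cluster A."""
    rng = np.random.default_rng(42)
    n_a, n_b, n_genes = 30, 30, 20
    lam = rng.uniform(0.5, 2.0, size=n_genes)
    counts = rng.poisson(lam[:, None], size=(n_genes, n_a + n_b))
    counts[0, :n_a] = rng.poisson(4 * lam[0], size=n_a)  # gM boosted in A
    genes = ["gM"] + [f"g{i:02d}" for i in range(1, n_genes)]
    cells = [f"c{i:03d}" for i in range(n_a + n_b)]
    cm = CountMatrix(genes=genes, cells=cells, counts=sp.csr_matrix(counts))
    labels = ClusterLabels(assignment={c: ("A" if i < n_a else "B")
                                       for i, c in enumerate(cells)})
    return normalize_log(cm), labels
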