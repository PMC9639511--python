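"""Library-size normalization and log transform.

x'_{gc} = ln(1 + x_{gc} * s / sum_g x_{gc}) with scale factor s
(default 10,000).  The sparsity pattern is preserved: a normalized value
is zero iff the underlying count is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io_formats import CountMatrix

DEFAULT_SCALE_FACTOR = 1e4


@dataclass
class NormMatrix:
    """Log-normalized expression, same gene/cell order as the source counts."""

    genes: list[str]
    cells: list[str]
    values: sp.csr_matrix  # genes x cells, non-negative reals
    scale_factor: float = DEFAULT_SCALE_FACTOR

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale factor must be positive")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError("normalized matrix shape does not match identifier lists")


def normalize_log(counts: CountMatrix, scale_factor: float = DEFAULT_SCALE_FACTOR) -> NormMatrix:
    """Per-cell library-size normalization followed by log1p.

    Raises ``ValueError`` listing the offending cell identifiers if any
    cell has a zero total count (silently dropping would desynchronize
    the label files).
    """
    if scale_factor <= 0:
        raise ValueError("scale factor must be positive")
    totals = np.asarray(counts.counts.sum(axis=0), dtype=float).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [counts.cells[i] for i in zero[:10]]
        raise ValueError(f"cells with zero total counts: {names}")
    x = counts.counts.tocsc().astype(np.float64)
    x = x.multiply(scale_factor / totals).tocsr()
    x.data = np.log1p(x.data)
    return NormMatrix(genes=list(counts.genes), cells=list(counts.cells),
                      values=x, scale_factor=scale_factor)
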