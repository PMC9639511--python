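"""Source x target homology matrix, best-match calls and rendering.

Every (source cluster, target cluster) pair must be accounted for,
either by an enrichment result or by an explicit rejection marker with
a reason code.  The match rule — per target cluster, the maximal
positive NES among cells with padj <= alpha — is this artifact's
formalization of reading the heatmap; it is labeled as such in the
report metadata.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .enrichment import EnrichmentResult, Rejection

__all__ = ["HomologyMatrix", "MatchCall", "assemble_matrix", "best_matches",
           "render_heatmap", "write_matrix_tsv", "write_matrix_json",
           "write_match_calls_tsv"]

DEFAULT_ALPHA = 0.05

UNASSIGNED = "unassigned"


@dataclass
class HomologyMatrix:
    source_clusters: list[str]
    target_clusters: list[str]
    cells: dict[tuple[str, str], EnrichmentResult | Rejection]

    def nes_grid(self) -> np.ndarray:
        """NES per (source, target); nan where rejected or NES undefined."""
        grid = np.full((len(self.source_clusters), len(self.target_clusters)), math.nan)
        for i, s in enumerate(self.source_clusters):
            for j, t in enumerate(self.target_clusters):
                cell = self.cells[(s, t)]
                if isinstance(cell, EnrichmentResult):
                    grid[i, j] = cell.nes
        return grid


@dataclass
class MatchCall:
    target_cluster: str
    best_source: str  # cluster id or "unassigned"
    nes: float | None
    padj: float | None
    runner_up: str | None
    margin: float


def assemble_matrix(results: Sequence[EnrichmentResult], rejections: Sequence[Rejection],
                    source_clusters: Sequence[str],
                    target_clusters: Sequence[str]) -> HomologyMatrix:
    """Build the complete grid; duplicates and uncovered pairs are errors."""
    cells: dict[tuple[str, str], EnrichmentResult | Rejection] = {}
    for item in [*results, *rejections]:
        key = (item.source_cluster, item.target_cluster)
        if key in cells:
            raise ValueError(f"duplicate cell for pair {key}")
        cells[key] = item
    missing = [(s, t) for s in source_clusters for t in target_clusters
               if (s, t) not in cells]
    if missing:
        raise ValueError(f"pairs without result or rejection: {missing[:5]}")
    extra = set(cells) - {(s, t) for s in source_clusters for t in target_clusters}
    if extra:
        raise ValueError(f"results for unknown pairs: {sorted(extra)[:5]}")
    return HomologyMatrix(source_clusters=list(source_clusters),
                          target_clusters=list(target_clusters), cells=cells)


def best_matches(matrix: HomologyMatrix, alpha: float = DEFAULT_ALPHA) -> list[MatchCall]:
    """Per target cluster: best source = maximal NES among padj <= alpha, NES > 0."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    source_index = {s: i for i, s in enumerate(matrix.source_clusters)}
    calls: list[MatchCall] = []
    for t in matrix.target_clusters:
        candidates: list[EnrichmentResult] = []
        for s in matrix.source_clusters:
            cell = matrix.cells[(s, t)]
            if isinstance(cell, EnrichmentResult) and not math.isnan(cell.nes) \
                    and cell.padj <= alpha and cell.nes > 0:
                candidates.append(cell)
        if not candidates:
            calls.append(MatchCall(t, UNASSIGNED, None, None, None, 0.0))
            continue
        candidates.sort(key=lambda r: (-r.nes, source_index[r.source_cluster]))
        best = candidates[0]
        runner = candidates[1] if len(candidates) > 1 else None
        margin = best.nes - runner.nes if runner is not None else 0.0
        calls.append(MatchCall(t, best.source_cluster, best.nes, best.padj,
                               runner.source_cluster if runner else None, margin))
    return calls


def _fmt(x: float | None) -> str:
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "NA"
    return repr(float(x))


def write_matrix_tsv(matrix: HomologyMatrix, path: Path | str) -> None:
    """NES grid, rows = source clusters, columns = target clusters; NA for rejected."""
    grid = matrix.nes_grid()
    with open(path, "w") as fh:
        fh.write("source_cluster\t" + "\t".join(matrix.target_clusters) + "\n")
        for i, s in enumerate(matrix.source_clusters):
            fh.write(s + "\t" + "\t".join(_fmt(v) for v in grid[i]) + "\n")


def write_matrix_json(matrix: HomologyMatrix, path: Path | str) -> None:
    cells = []
    for (s, t), cell in matrix.cells.items():
        if isinstance(cell, EnrichmentResult):
            cells.append({
                "source_cluster": s, "target_cluster": t, "status": "tested",
                "set_size": cell.set_size, "ES": cell.es,
                "NES": None if math.isnan(cell.nes) else cell.nes,
                "pval": cell.p, "padj": cell.padj,
                "n_perm_used": cell.n_perm_used,
                "leading_edge": cell.leading_edge,
            })
        else:
            cells.append({"source_cluster": s, "target_cluster": t,
                          "status": "rejected", "reason": cell.reason})
    payload = {"source_clusters": matrix.source_clusters,
               "target_clusters": matrix.target_clusters, "cells": cells}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_match_calls_tsv(calls: Sequence[MatchCall], path: Path | str) -> None:
    with open(path, "w") as fh:
        fh.write("target_cluster\tbest_source\tNES\tpadj\trunner_up\tmargin\n")
        for c in calls:
            fh.write("\t".join([
                c.target_cluster, c.best_source, _fmt(c.nes), _fmt(c.padj),
                c.runner_up if c.runner_up is not None else "NA", _fmt(c.margin),
            ]) + "\n")


def render_heatmap(matrix: HomologyMatrix, image_path: Path | str,
                   tsv_path: Path | str | None = None) -> None:
    """Diverging heatmap centered at 0 (positive red, negative blue).

    Rejected cells are drawn hatched over grey, never as 0.  The plotted
    values are also written as a TSV twin (defaults to the image path
    with a .tsv suffix) that matches the assembled NES grid exactly.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import Normalize

    grid = matrix.nes_grid()
    masked = np.ma.masked_invalid(grid)
    vmax = float(np.nanmax(np.abs(grid))) if np.isfinite(grid).any() else 1.0
    vmax = vmax if vmax > 0 else 1.0
    fig, ax = plt.subplots(
        figsize=(1.5 + 0.5 * len(matrix.target_clusters),
                 1.5 + 0.5 * len(matrix.source_clusters)))
    cmap = plt.get_cmap("RdBu_r").copy()
    cmap.set_bad("#d9d9d9")
    im = ax.imshow(masked, cmap=cmap, norm=Normalize(-vmax, vmax), aspect="auto")
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            if not np.isfinite(grid[i, j]):
                ax.add_patch(plt.Rectangle((j - 0.5, i - 0.5), 1, 1, fill=False,
                                           hatch="////", edgecolor="grey", linewidth=0))
    ax.set_xticks(range(len(matrix.target_clusters)), matrix.target_clusters,
                  rotation=90, fontsize=8)
    ax.set_yticks(range(len(matrix.source_clusters)), matrix.source_clusters, fontsize=8)
    ax.set_xlabel("target cluster")
    ax.set_ylabel("source cluster")
    fig.colorbar(im, ax=ax, label="NES")
    fig.tight_layout()
    fig.savefig(image_path, dpi=150)
    plt.close(fig)
    if tsv_path is None:
        tsv_path = Path(image_path).with_suffix(".tsv")
    write_matrix_tsv(matrix, tsv_path)
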