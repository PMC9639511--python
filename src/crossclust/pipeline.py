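"""In-memory orchestration of the full analysis.

normalize -> markers (source filtered-mode, target full-mode) ->
ortholog-mapped gene sets -> signed-p ranked lists -> size filter ->
per-pair enrichment -> BH -> homology matrix -> best-match calls.
The CLI wraps this with file I/O; tests and the acceptance suite call
it directly on in-memory objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import crossmap, enrichment, homology, markers, preprocess
from .io_formats import ClusterLabels, CountMatrix, GeneSetCollection, OrthologTable, RankedList

logger = logging.getLogger(__name__)


@dataclass
class AnalysisOutput:
    source_markers: pd.DataFrame
    target_markers: pd.DataFrame
    gene_sets: GeneSetCollection
    ranked_lists: dict[str, RankedList]
    results: list[enrichment.EnrichmentResult]
    rejections: list[enrichment.Rejection]
    matrix: homology.HomologyMatrix
    calls: list[homology.MatchCall]
    omitted_source_clusters: list[str] = field(default_factory=list)


def analyze(source_counts: CountMatrix, source_labels: ClusterLabels,
            target_counts: CountMatrix, target_labels: ClusterLabels,
            orthologs: OrthologTable, *,
            scale_factor: float = preprocess.DEFAULT_SCALE_FACTOR,
            min_pct: float = markers.DEFAULT_MIN_PCT,
            logfc_threshold: float = markers.DEFAULT_LOGFC_THRESHOLD,
            fc_base: str = "e",
            top_n: int = crossmap.DEFAULT_TOP_N,
            map_during_selection: bool = True,
            metric: str = "signedP",
            p_floor: float = crossmap.DEFAULT_P_FLOOR,
            n_perm: int = enrichment.DEFAULT_N_PERM,
            seed: int = 0,
            min_size: int = enrichment.DEFAULT_MIN_SIZE,
            max_size: int = enrichment.DEFAULT_MAX_SIZE,
            weight: float = enrichment.DEFAULT_WEIGHT,
            bh_scope: str = "per_target",
            alpha: float = homology.DEFAULT_ALPHA) -> AnalysisOutput:
    source_labels.validate_with(source_counts)
    target_labels.validate_with(target_counts)

    logger.info("[stage:normalize] %d+%d cells", len(source_counts.cells),
                len(target_counts.cells))
    src_norm = preprocess.normalize_log(source_counts, scale_factor)
    tgt_norm = preprocess.normalize_log(target_counts, scale_factor)

    logger.info("[stage:markers] source filtered-mode, target full-mode")
    src_markers = markers.find_all_markers(src_norm, source_labels, min_pct=min_pct,
                                           logfc_threshold=logfc_threshold,
                                           mode="filtered", base=fc_base)
    tgt_markers = markers.find_all_markers(tgt_norm, target_labels, mode="full",
                                           base=fc_base)

    logger.info("[stage:crossmap] %d ortholog pairs, top_n=%d", len(orthologs), top_n)
    gene_sets = crossmap.build_gene_sets(src_markers, orthologs, top_n,
                                         map_during_selection=map_during_selection)
    omitted = [c for c in source_labels.clusters if c not in gene_sets.sets]
    ranked_lists = {
        str(cluster): crossmap.build_ranked_list(table, metric=metric, p_floor=p_floor)
        for cluster, table in tgt_markers.groupby("cluster", sort=False)
    }
    # keep the declared target cluster order
    ranked_lists = {t: ranked_lists[t] for t in target_labels.clusters}

    logger.info("[stage:enrichment] %d sets x %d ranked lists, n_perm=%d",
                len(gene_sets), len(ranked_lists), n_perm)
    results, rejections = enrichment.run_enrichment(
        gene_sets, ranked_lists, n_perm=n_perm, seed=seed, min_size=min_size,
        max_size=max_size, weight=weight, bh_scope=bh_scope)
    for c in omitted:
        for t in target_labels.clusters:
            rejections.append(enrichment.Rejection(c, t, "source_set_omitted"))

    logger.info("[stage:homology] %d results, %d rejections", len(results),
                len(rejections))
    matrix = homology.assemble_matrix(results, rejections, source_labels.clusters,
                                      target_labels.clusters)
    calls = homology.best_matches(matrix, alpha)
    return AnalysisOutput(source_markers=src_markers, target_markers=tgt_markers,
                          gene_sets=gene_sets, ranked_lists=ranked_lists,
                          results=results, rejections=rejections, matrix=matrix,
                          calls=calls, omitted_source_clusters=omitted)
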