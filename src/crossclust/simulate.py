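"""Paired source/target count simulator with planted cluster homology.

A pool of shared ortholog-linked genes carries one marker program per
cluster "identity": every source cluster has a program, and each target
cluster either re-expresses a source program (a planted correspondence)
or carries a private program of its own.  Gene baselines are log-normal
and shared between species for ortholog pairs; counts are negative
binomial (variance = mu + phi * mu^2) with per-cell log-normal library
factors, which yields dropout-like sparsity at single-cell means without
explicit zero inflation.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .io_formats import (ClusterLabels, CountMatrix, OrthologTable,
                         write_cluster_labels, write_count_matrix,
                         write_ortholog_table)

__all__ = ["SimParams", "SyntheticTruth", "SimResult",
           "generate_paired_datasets", "write_dataset", "paper_shape_params"]


@dataclass
class SimParams:
    n_source_clusters: int = 10
    n_target_clusters: int = 18
    n_shared_orthologs: int = 3000
    n_private_genes: int = 200        # per species, outside the ortholog table
    markers_per_program: int = 100
    marker_fold: float = 4.0          # theta, multiplicative effect on marker means
    baseline_log_mean: float = -1.8   # mu0 of LogNormal baseline
    baseline_log_sd: float = 1.0      # sigma0
    dispersion: float = 0.5           # phi; variance = mu + phi mu^2
    cells_per_cluster: int | Sequence[int] = 300
    library_log_sd: float = 0.25
    n_matched: int | None = None      # planted correspondences; default min(Ks, Kt)
    decoy_fraction: float = 0.05      # extra one-to-many ortholog rows
    seed: int = 0

    def __post_init__(self) -> None:
        # theta = 1 is tolerated so a no-signal null dataset can be generated
        if self.marker_fold < 1:
            raise ValueError("marker_fold must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_matched is None:
            self.n_matched = min(self.n_source_clusters, self.n_target_clusters)
        if self.n_matched > min(self.n_source_clusters, self.n_target_clusters):
            raise ValueError("more correspondences than clusters")
        n_programs = self.n_source_clusters + self.n_target_clusters - self.n_matched
        if n_programs * self.markers_per_program > self.n_shared_orthologs:
            raise ValueError(
                f"{n_programs} programs x {self.markers_per_program} markers "
                f"exhaust the {self.n_shared_orthologs} shared genes")

    def cluster_sizes(self, n_clusters: int) -> list[int]:
        if isinstance(self.cells_per_cluster, int):
            return [self.cells_per_cluster] * n_clusters
        sizes = list(self.cells_per_cluster)
        if len(sizes) != n_clusters:
            raise ValueError("cells_per_cluster list length must match cluster count")
        return sizes


@dataclass
class SyntheticTruth:
    """Planted correspondences plus everything needed to regenerate the data."""

    correspondence: dict[str, str]                  # source cluster -> target cluster
    programs: dict[str, dict[str, list[str]]]       # cluster -> marker genes per namespace
    params: dict
    seed: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(**d)


@dataclass
class SimResult:
    source_counts: CountMatrix
    source_labels: ClusterLabels
    target_counts: CountMatrix
    target_labels: ClusterLabels
    orthologs: OrthologTable
    truth: SyntheticTruth


def paper_shape_params(seed: int = 0, **overrides) -> SimParams:
    """10 x 18 clusters with 6,146 / 12,073 cells split across clusters.

    The published shape; too large for routine testing, intended for
    manual runs.  Cell totals are spread as evenly as possible.
    """
    def split(total: int, k: int) -> list[int]:
        base = total // k
        return [base + (1 if i < total % k else 0) for i in range(k)]

    kwargs = dict(n_source_clusters=10, n_target_clusters=18,
                  n_shared_orthologs=4000, seed=seed)
    kwargs.update(overrides)
    params = SimParams(**kwargs)
    params._source_sizes = split(6146, params.n_source_clusters)  # type: ignore[attr-defined]
    params._target_sizes = split(12073, params.n_target_clusters)  # type: ignore[attr-defined]
    return params


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mean))


def _simulate_species(rng: np.random.Generator, prefix: str, cluster_ids: list[str],
                      sizes: list[int], base_means: np.ndarray,
                      program_markers: dict[str, np.ndarray],
                      params: SimParams) -> tuple[sp.csr_matrix, list[str], ClusterLabels]:
    n_genes = base_means.size
    blocks = []
    cells: list[str] = []
    assignment: dict[str, str] = {}
    cell_no = 0
    for cid, n_c in zip(cluster_ids, sizes):
        mu = base_means.copy()
        marked = program_markers.get(cid)
        if marked is not None:
            mu[marked] *= params.marker_fold
        lib = rng.lognormal(mean=0.0, sigma=params.library_log_sd, size=n_c)
        counts = _nb_counts(rng, np.outer(mu, lib), params.dispersion)
        blocks.append(sp.csr_matrix(counts))
        for _ in range(n_c):
            name = f"{prefix}_cell_{cell_no:06d}"
            cells.append(name)
            assignment[name] = cid
            cell_no += 1
    matrix = sp.hstack(blocks, format="csr")
    return matrix, cells, ClusterLabels(assignment=assignment, clusters=list(cluster_ids))


def generate_paired_datasets(params: SimParams) -> SimResult:
    """Generate source + target counts, labels, ortholog table and truth."""
    rng = np.random.default_rng(params.seed)
    g_o, g_p = params.n_shared_orthologs, params.n_private_genes
    m = params.markers_per_program

    src_clusters = [f"mC{i + 1:02d}" for i in range(params.n_source_clusters)]
    tgt_clusters = [f"hC{i + 1:02d}" for i in range(params.n_target_clusters)]
    correspondence = {src_clusters[i]: tgt_clusters[i] for i in range(params.n_matched)}
    unmatched_targets = tgt_clusters[params.n_matched:]

    src_shared = [f"mGene{i + 1:05d}" for i in range(g_o)]
    tgt_shared = [f"hGene{i + 1:05d}" for i in range(g_o)]
    src_private = [f"mPriv{i + 1:05d}" for i in range(g_p)]
    tgt_private = [f"hPriv{i + 1:05d}" for i in range(g_p)]

    # disjoint marker blocks carved from the shared pool, one per program
    owners = src_clusters + unmatched_targets
    program_idx = {owner: np.arange(i * m, (i + 1) * m) for i, owner in enumerate(owners)}

    shared_means = rng.lognormal(params.baseline_log_mean, params.baseline_log_sd, g_o)
    src_priv_means = rng.lognormal(params.baseline_log_mean, params.baseline_log_sd, g_p)
    tgt_priv_means = rng.lognormal(params.baseline_log_mean, params.baseline_log_sd, g_p)

    # decoy one-to-many rows: a shared source gene additionally maps to an
    # extra target-only gene with its own background baseline
    n_decoy = int(round(params.decoy_fraction * g_o))
    decoy_src_idx = np.sort(rng.choice(g_o, size=n_decoy, replace=False)) if n_decoy else np.array([], int)
    decoy_names = [f"hDecoy{i + 1:05d}" for i in range(n_decoy)]
    decoy_means = rng.lognormal(params.baseline_log_mean, params.baseline_log_sd, n_decoy)

    src_genes = src_shared + src_private
    tgt_genes = tgt_shared + tgt_private + decoy_names
    src_base = np.concatenate([shared_means, src_priv_means])
    tgt_base = np.concatenate([shared_means, tgt_priv_means, decoy_means])

    src_programs = {c: program_idx[c] for c in src_clusters}
    tgt_programs: dict[str, np.ndarray] = {}
    for s, t in correspondence.items():
        tgt_programs[t] = program_idx[s]  # same shared indices -> ortholog partners
    for t in unmatched_targets:
        tgt_programs[t] = program_idx[t]

    src_sizes = getattr(params, "_source_sizes", None) or params.cluster_sizes(params.n_source_clusters)
    tgt_sizes = getattr(params, "_target_sizes", None) or params.cluster_sizes(params.n_target_clusters)

    src_mat, src_cells, src_labels = _simulate_species(
        rng, "m", src_clusters, src_sizes, src_base, src_programs, params)
    tgt_mat, tgt_cells, tgt_labels = _simulate_species(
        rng, "h", tgt_clusters, tgt_sizes, tgt_base, tgt_programs, params)

    pairs = list(zip(src_shared, tgt_shared))
    pairs += [(src_shared[i], decoy_names[j]) for j, i in enumerate(decoy_src_idx)]
    orthologs = OrthologTable(pairs=pairs)

    programs = {}
    for owner in owners:
        idx = program_idx[owner]
        programs[owner] = {"source_genes": [src_shared[i] for i in idx],
                           "target_genes": [tgt_shared[i] for i in idx]}
    truth = SyntheticTruth(correspondence=correspondence, programs=programs,
                           params=asdict(params), seed=params.seed)

    return SimResult(
        source_counts=CountMatrix(src_genes, src_cells, src_mat, species="source"),
        source_labels=src_labels,
        target_counts=CountMatrix(tgt_genes, tgt_cells, tgt_mat, species="target"),
        target_labels=tgt_labels,
        orthologs=orthologs,
        truth=truth,
    )


#: file names emitted by write_dataset / consumed by the CLI
DATASET_FILES = {
    "source_counts": "source_counts.mtx",
    "source_genes": "source_genes.tsv",
    "source_cells": "source_cells.tsv",
    "source_labels": "source_labels.tsv",
    "target_counts": "target_counts.mtx",
    "target_genes": "target_genes.tsv",
    "target_cells": "target_cells.tsv",
    "target_labels": "target_labels.tsv",
    "orthologs": "orthologs.tsv",
    "truth": "truth.json",
}


def write_dataset(result: SimResult, outdir: Path | str) -> dict[str, Path]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / v for k, v in DATASET_FILES.items()}
    write_count_matrix(result.source_counts, paths["source_counts"],
                       paths["source_genes"], paths["source_cells"])
    write_cluster_labels(result.source_labels, paths["source_labels"])
    write_count_matrix(result.target_counts, paths["target_counts"],
                       paths["target_genes"], paths["target_cells"])
    write_cluster_labels(result.target_labels, paths["target_labels"])
    write_ortholog_table(result.orthologs, paths["orthologs"])
    paths["truth"].write_text(result.truth.to_json())
    return paths
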