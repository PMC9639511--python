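"""From-scratch preranked gene-set enrichment.

The statistic is the weighted Kolmogorov-Smirnov running sum: walking
the ranked list, hits add |score|^w / N_R (N_R = sum of |score|^w over
set members in the universe) and misses subtract 1 / (N - k).  The
enrichment score ES is the deviation of maximal absolute value, with
ties resolved to the smallest rank index.  Significance comes from a
gene-permutation null (uniform random k-subsets of the universe) with
the add-one estimator, and NES divides ES by the mean magnitude of the
same-sign null scores.

This deliberately substitutes plain gene permutation for adaptive
multilevel p-value refinement; the permutation count is configurable
and recorded with every result.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io_formats import RankedList

__all__ = [
    "EnrichmentResult",
    "Rejection",
    "filter_gene_set",
    "enrichment_score",
    "permutation_null",
    "nes_and_pvalue",
    "bh_adjust",
    "pair_rng",
    "run_enrichment",
]

DEFAULT_MIN_SIZE = 15
DEFAULT_MAX_SIZE = 500
DEFAULT_WEIGHT = 1.0
DEFAULT_N_PERM = 10_000


@dataclass
class EnrichmentResult:
    source_cluster: str
    target_cluster: str
    set_size: int  # after intersection with the ranked universe
    es: float
    nes: float  # nan when the same-sign null subset is empty
    p: float
    padj: float = math.nan
    leading_edge: list[str] = field(default_factory=list)
    n_perm_used: int = 0


@dataclass
class Rejection:
    """A (source, target) pair not tested, with a reason code."""

    source_cluster: str
    target_cluster: str
    reason: str


def filter_gene_set(gene_set: Sequence[str], universe: Iterable[str],
                    min_size: int = DEFAULT_MIN_SIZE,
                    max_size: int = DEFAULT_MAX_SIZE) -> list[str] | None:
    """Intersect a set with the ranked universe and apply the size window.

    Returns the effective member list (set order preserved) or ``None``
    if the effective size falls outside [min_size, max_size].  Rejection
    is an expected outcome, not an error.
    """
    if min_size > max_size:
        raise ValueError(f"min_size {min_size} exceeds max_size {max_size}")
    uni = set(universe)
    effective = [g for g in gene_set if g in uni]
    if not min_size <= len(effective) <= max_size:
        return None
    return effective


def enrichment_score(ranked: RankedList, gene_set: Sequence[str],
                     weight: float = DEFAULT_WEIGHT) -> tuple[float, list[str]]:
    """Weighted running-sum enrichment score and leading edge.

    Requires 1 <= k < N where k is the effective set size.  If all
    member scores are zero the weights fall back to uniform (|s|^0).
    """
    genes = ranked.genes
    scores = ranked.scores
    n = len(genes)
    members = set(gene_set)
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=n)
    k = int(hit.sum())
    if k == 0:
        raise ValueError("empty intersection between gene set and ranked universe")
    if k == n:
        raise ValueError("set equals universe (miss denominator zero)")
    absw = np.abs(scores) ** weight
    n_r = float(absw[hit].sum())
    if n_r == 0.0:
        absw = np.ones(n)
        n_r = float(k)
    p_hit = np.cumsum(np.where(hit, absw, 0.0)) / n_r
    p_miss = np.cumsum(~hit) / (n - k)
    dev = p_hit - p_miss
    j = int(np.argmax(np.abs(dev)))  # first occurrence = smallest index
    es = float(dev[j])
    if es > 0:
        leading = [g for i, g in enumerate(genes) if hit[i] and i <= j]
    elif es < 0:
        leading = [g for i, g in enumerate(genes) if hit[i] and i >= j]
    else:
        leading = []
    return es, leading


def _es_batch(absw: np.ndarray, positions: np.ndarray, n: int) -> np.ndarray:
    """ES for many hit-position sets at once.

    ``positions`` is (B, k), each row the sorted 0-based ranks of the k
    hits.  Between hits the deviation declines strictly, so its extrema
    lie at hit indices or just before them; candidates are evaluated in
    rank order so that first-max selection matches the smallest-index
    tie rule of :func:`enrichment_score`.
    """
    b, k = positions.shape
    wh = absw[positions].astype(float)
    n_r = wh.sum(axis=1, keepdims=True)
    zero = n_r[:, 0] == 0.0
    if zero.any():
        wh[zero] = 1.0
        n_r = wh.sum(axis=1, keepdims=True)
    wh = wh / n_r
    cum = np.cumsum(wh, axis=1)
    idx = np.arange(1, k + 1)
    denom = n - k
    d_hit = cum - (positions + 1 - idx) / denom
    d_pre = cum - wh - (positions - (idx - 1)) / denom
    cand = np.empty((b, 2 * k))
    cand[:, 0::2] = d_pre
    cand[:, 1::2] = d_hit
    j = np.argmax(np.abs(cand), axis=1)
    return cand[np.arange(b), j]


def permutation_null(ranked: RankedList, k: int, n_perm: int,
                     seed: int | np.random.Generator = 0,
                     weight: float = DEFAULT_WEIGHT) -> np.ndarray:
    """ES values for ``n_perm`` uniformly random k-subsets of the universe."""
    n = len(ranked)
    if not 1 <= k < n:
        raise ValueError(f"need 1 <= k < N, got k={k}, N={n}")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    absw = np.abs(ranked.scores) ** weight
    rand = rng.random((n_perm, n))
    positions = np.sort(np.argpartition(rand, k - 1, axis=1)[:, :k], axis=1)
    return _es_batch(absw, positions, n)


def nes_and_pvalue(es_obs: float, null: Sequence[float]) -> tuple[float, float]:
    """Normalized ES and add-one permutation p against the same-sign null.

    NES = ES / mean(|same-sign null|); p = (1 + #{|e| >= |ES|}) / (1 + |Q|).
    ES of exactly 0 gives (0, 1).  An empty same-sign subset yields
    NES = nan with p = 1 / (len(null) + 1).
    """
    null_arr = np.asarray(null, dtype=float)
    if null_arr.size == 0:
        raise ValueError("null distribution is empty")
    if es_obs == 0.0:
        return 0.0, 1.0
    q = null_arr[np.sign(null_arr) == np.sign(es_obs)]
    if q.size == 0:
        return math.nan, 1.0 / (null_arr.size + 1)
    abs_q = np.abs(q)
    nes = float(es_obs / abs_q.mean())
    p = float((1 + np.count_nonzero(abs_q >= abs(es_obs))) / (1 + q.size))
    return nes, p


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up, values returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(n)
    out[order] = q
    return out


def _stable_hash(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:8], "big")


def pair_rng(master_seed: int, target_id: str, source_id: str) -> np.random.Generator:
    """Deterministic per-(target, source) stream, independent of evaluation order."""
    ss = np.random.SeedSequence([master_seed, _stable_hash(target_id), _stable_hash(source_id)])
    return np.random.default_rng(ss)


def run_enrichment(gene_sets, ranked_lists: dict[str, RankedList], *,
                   n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                   min_size: int = DEFAULT_MIN_SIZE, max_size: int = DEFAULT_MAX_SIZE,
                   weight: float = DEFAULT_WEIGHT,
                   bh_scope: str = "per_target") -> tuple[list[EnrichmentResult], list[Rejection]]:
    """Score every (source set, target ranked list) pair.

    ``bh_scope`` is either ``per_target`` (adjust across the source sets
    of each ranked list, one enrichment call per list) or ``global``
    (one adjustment across the whole matrix).
    """
    if bh_scope not in ("per_target", "global"):
        raise ValueError(f"unknown bh_scope {bh_scope!r}")
    results: list[EnrichmentResult] = []
    rejections: list[Rejection] = []
    for target_id, ranked in ranked_lists.items():
        universe = ranked.genes
        batch: list[EnrichmentResult] = []
        for source_id, members in gene_sets.sets.items():
            effective = filter_gene_set(members, universe, min_size, max_size)
            if effective is None:
                k_eff = len(set(members) & set(universe))
                rejections.append(Rejection(source_id, target_id,
                                            f"size_filtered:effective={k_eff}"))
                continue
            es, leading = enrichment_score(ranked, effective, weight)
            rng = pair_rng(seed, target_id, source_id)
            null = permutation_null(ranked, len(effective), n_perm, rng, weight)
            nes, p = nes_and_pvalue(es, null)
            batch.append(EnrichmentResult(
                source_cluster=source_id, target_cluster=target_id,
                set_size=len(effective), es=es, nes=nes, p=p,
                leading_edge=leading, n_perm_used=n_perm))
        if bh_scope == "per_target" and batch:
            for res, q in zip(batch, bh_adjust([r.p for r in batch])):
                res.padj = float(q)
        results.extend(batch)
    if bh_scope == "global" and results:
        for res, q in zip(results, bh_adjust([r.p for r in results])):
            res.padj = float(q)
    return results, rejections
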