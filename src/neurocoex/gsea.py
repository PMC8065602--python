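"""Preranked gene-set enrichment with a permutation null.

The enrichment score is the weighted Kolmogorov-Smirnov walk (exponent 1):
stepping down the ranked list, hits add |metric| / sum of hit |metric|,
misses subtract 1/(N - N_hits); ES is the signed extremum of the running
sum, which by construction returns to zero at the end of the list.  The
null is gene-label permutation — B random same-size sets drawn from the
ranked universe — matching preranked GSEA practice; NES normalizes ES by
the mean |ES| of same-sign permutations, and the nominal p honors the
(r + 1)/(B + 1) floor, so B = 10,000 bottoms out at "p < 1e-4".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coexnet import ModulePartition, UNASSIGNED
from .diffexpr import ModeratedStats
from .enrich import bh_adjust
from .io import GeneSetCollection

__all__ = ["RankedList", "GseaResult", "rank_genes", "enrichment_score",
           "gsea_preranked", "module_gsea", "compare_nes"]


@dataclass
class RankedList:
    """Genes in descending metric order with deterministic tie-breaking."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        self.metric = np.asarray(self.metric, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")
        if len(self.genes) != self.metric.size:
            raise ValueError("genes and metric lengths differ")
        if np.any(np.diff(self.metric) > 0):
            raise ValueError("metric must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GseaResult:
    name: str
    size: int
    es: float
    nes: float
    p: float
    p_adj: float = np.nan
    leading_edge: list[str] = field(default_factory=list)
    n_permutations: int = 0
    n_same_sign: int = 0  # permutations sharing the observed ES sign
    seed: int | None = None


def rank_genes(stats_: ModeratedStats, contrast: str) -> RankedList:
    """Rank genes by descending logFC; ties break lexicographically."""
    if contrast not in stats_.tables:
        raise ValueError(f"no contrast {contrast!r} in the fitted statistics")
    tab = stats_.tables[contrast]
    order = sorted(tab.index, key=lambda g: (-tab.at[g, "logFC"], g))
    return RankedList(order, tab.loc[order, "logFC"].to_numpy())


def _es_from_positions(pos: np.ndarray, absmetric: np.ndarray,
                       n: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized signed-extremum ES for rows of sorted hit positions.

    ``pos`` is (B, s) with each row the 0-based hit positions in ascending
    order.  Returns (ES values, extremum candidate index) per row; the
    extremum index k encodes "after hit k" for k >= 0 and "before hit
    -k-1" for negative entries.
    """
    B, s = pos.shape
    w = absmetric[pos]
    W = w.sum(axis=1, keepdims=True)
    uniform = (W == 0).ravel()
    if uniform.any():
        w[uniform] = 1.0
        W = w.sum(axis=1, keepdims=True)
    cumw = np.cumsum(w, axis=1) / W
    miss = 1.0 / (n - s)
    ks = np.arange(s)
    after = cumw - (pos - ks) * miss          # misses so far: pos_k - k
    before = np.concatenate([np.zeros((B, 1)), cumw[:, :-1]], axis=1) \
        - (pos - ks) * miss
    cand = np.concatenate([after, before], axis=1)
    mx, mn = cand.max(axis=1), cand.min(axis=1)
    es = np.where(mx >= -mn - 1e-12, mx, mn)  # positive extremum wins |ties|
    return es, np.argmax(np.abs(cand), axis=1)


def enrichment_score(ranked: RankedList, gene_set
                     ) -> tuple[float, np.ndarray, list[str]]:
    """ES, full running sum and leading edge of one gene set.

    The running sum ends at zero (up to floating error); the leading edge
    is the hits up to the positive extremum (or from the negative
    extremum onward for a negative ES).
    """
    members = set(gene_set)
    n = len(ranked)
    hit = np.fromiter((g in members for g in ranked.genes), bool, n)
    nh = int(hit.sum())
    if nh == 0:
        raise ValueError("gene set is disjoint from the ranked list")
    absm = np.abs(ranked.metric)
    w = np.where(hit, absm, 0.0)
    W = w.sum()
    if W == 0:
        w = hit.astype(float)
        W = float(nh)
    if nh == n:
        running = np.cumsum(w / W)
        return 1.0, running, [g for g in ranked.genes]
    steps = np.where(hit, w / W, -1.0 / (n - nh))
    running = np.cumsum(steps)
    i_max, i_min = int(np.argmax(running)), int(np.argmin(running))
    es = (float(running[i_max])
          if running[i_max] >= -running[i_min] - 1e-12 else float(running[i_min]))
    if es >= 0:
        leading = [g for g, h in zip(ranked.genes[:i_max + 1], hit[:i_max + 1]) if h]
    else:
        leading = [g for g, h in zip(ranked.genes[i_min:], hit[i_min:]) if h]
    return es, running, leading


def gsea_preranked(ranked: RankedList, sets: GeneSetCollection,
                   n_permutations: int = 10_000, min_size: int = 20,
                   max_size: int = 500, seed: int | None = None,
                   alpha: float = 0.05) -> list[GseaResult]:
    """Permutation GSEA over a gene-set collection.

    Sets are intersected with the ranked universe and size-filtered before
    testing; sets sharing a size share one batch of B random same-size
    null sets.  BH correction runs across all tested sets.
    """
    universe = set(ranked.genes)
    tested: list[tuple[str, list[str]]] = []
    for name, (_, members) in sets.items():
        inter = [g for g in dict.fromkeys(members) if g in universe]
        if min_size <= len(inter) <= max_size:
            tested.append((name, inter))
    if not tested:
        warnings.warn("no gene set survives the size filter", stacklevel=2)
        return []
    rng = np.random.default_rng(seed)
    absm = np.abs(ranked.metric)
    n = len(ranked)
    null_cache: dict[int, np.ndarray] = {}
    results = []
    for name, members in tested:
        s = len(members)
        if s not in null_cache:
            keys = rng.random((n_permutations, n))
            pos = np.sort(np.argpartition(keys, s - 1, axis=1)[:, :s], axis=1)
            null_cache[s], _ = _es_from_positions(pos, absm, n)
        null = null_cache[s]
        es, _, leading = enrichment_score(ranked, members)
        same_sign = null >= 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        r = int((np.abs(null[same_sign]) >= abs(es)).sum())
        p = (r + 1) / (n_same + 1)  # tail proportion among same-sign perms
        denom_pool = np.abs(null[same_sign]) if same_sign.any() else np.abs(null)
        denom = float(denom_pool.mean())
        nes = es / denom if denom > 0 else 0.0
        results.append(GseaResult(name=name, size=s, es=float(es),
                                  nes=float(nes), p=float(p),
                                  leading_edge=leading,
                                  n_permutations=n_permutations,
                                  n_same_sign=n_same, seed=seed))
    adj = bh_adjust([r.p for r in results])
    for r_, q in zip(results, adj):
        r_.p_adj = float(q)
    return results


def module_gsea(ranked: RankedList, partition: ModulePartition,
                n_permutations: int = 10_000, min_size: int = 20,
                seed: int | None = None) -> list[GseaResult]:
    """Run each coexpression module's gene list through the GSEA engine."""
    sets = {}
    universe = set(ranked.genes)
    for module in partition.module_names():
        genes = [g for g in partition.genes_of(module) if g in universe]
        if len(genes) < min_size:
            warnings.warn(f"{module}: only {len(genes)} genes in the ranked "
                          "universe; skipped", stacklevel=2)
            continue
        sets[module] = ("coexpression module", genes)
    if not sets:
        return []
    return gsea_preranked(ranked, GeneSetCollection(sets),
                          n_permutations=n_permutations, min_size=min_size,
                          max_size=len(ranked), seed=seed)


def compare_nes(results_a: list[GseaResult],
                results_b: list[GseaResult]) -> dict:
    """Pearson correlation of NES over the commonly tested sets."""
    nes_a = {r.name: r.nes for r in results_a}
    nes_b = {r.name: r.nes for r in results_b}
    shared = sorted(set(nes_a) & set(nes_b))
    if len(shared) < 3:
        raise ValueError("need at least 3 commonly tested sets")
    va = np.array([nes_a[s] for s in shared])
    vb = np.array([nes_b[s] for s in shared])
    r = float(np.corrcoef(va, vb)[0, 1])
    return {"correlation": r, "n_shared": len(shared), "sets": shared}
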