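"""Gene Set Enrichment Analysis with a gene-set-permutation null.

The statistic is the classical weighted running-sum enrichment score.
Genes are ranked by a differential-expression metric (signal-to-noise by
default); walking the ranked list, each gene that belongs to the query set
("hit") increments the running sum by ``|metric|**p / sum_hits |metric|**p``
and each miss decrements it by ``1 / (N - N_hits)``.  The enrichment score
(ES) is the running-sum value of maximal absolute deviation, so ES lies in
[-1, 1]: positive when the set concentrates at the top of the ranking
(enriched in group 1), negative at the bottom.  With ``weight_p=0`` the
statistic reduces to a Kolmogorov-Smirnov comparison of hit positions
against uniform placement.

Because the designs this pipeline targets have very few phenotype samples
(3 vs 3), the null model permutes *gene sets*, not phenotype labels: null
scores come from random same-size gene sets drawn uniformly without
replacement from the ranked universe.  The nominal p-value and the
normalised enrichment score (NES) are computed against null scores of the
same sign as the observed ES, with an add-one correction keeping p > 0:

    p   = (1 + #{|null| >= |ES|, same sign}) / (1 + #{null, same sign})
    NES = ES / mean(|null|, same sign)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection, GroupLabels

__all__ = [
    "RankedList",
    "GseaResult",
    "rank_genes",
    "enrichment_score",
    "permutation_test",
    "run_gsea",
    "gsea_table",
]

log = logging.getLogger(__name__)

# Broad-convention variance floor for the signal-to-noise metric
SD_FLOOR_FRACTION = 0.2
SD_FLOOR_ABSOLUTE = 0.2


@dataclass
class RankedList:
    """Genes ordered by descending metric (ties broken by gene id ascending)."""

    genes: np.ndarray
    metric: np.ndarray
    metric_name: str
    groups: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric lengths differ")
        if len(np.unique(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in ranked list")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GseaResult:
    """One gene set's enrichment against one ranked list."""

    set_name: str
    set_size: int            # after restriction to the ranked universe
    es: float
    running_sum: np.ndarray
    leading_edge: list[str]
    n_perm: int
    nominal_p: float
    nes: float
    seed: int
    weight_p: float = 1.0


def _adjusted_sd(sd: np.ndarray, mean: np.ndarray) -> np.ndarray:
    floor = SD_FLOOR_FRACTION * np.abs(mean)
    adj = np.maximum(sd, floor)
    return np.where(adj == 0.0, SD_FLOOR_ABSOLUTE, adj)


def rank_genes(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    metric: str = "signal_to_noise",
) -> RankedList:
    """Rank all genes by differential expression between the two groups.

    ``signal_to_noise`` is ``(mu1 - mu2) / (sd1_adj + sd2_adj)`` with sample
    standard deviations (n-1 denominator) floored at 20% of the absolute
    group mean (0.2 if that floor is itself zero); it needs >= 2 samples per
    group.  ``log2_fc`` is the plain difference of group means and works for
    single-sample groups.
    """
    g1, g2 = labels.two_groups()
    s1 = [s for s in matrix.sample_ids if labels.assignments.get(s) == g1]
    s2 = [s for s in matrix.sample_ids if labels.assignments.get(s) == g2]
    if not s1 or not s2:
        raise ValueError(f"groups {g1!r}/{g2!r} absent from matrix samples")
    v1 = matrix.values[s1].to_numpy(dtype=float)
    v2 = matrix.values[s2].to_numpy(dtype=float)
    mu1, mu2 = v1.mean(axis=1), v2.mean(axis=1)
    if metric == "signal_to_noise":
        if len(s1) < 2 or len(s2) < 2:
            raise ValueError(
                "signal_to_noise needs >= 2 samples per group; use metric='log2_fc'"
            )
        sd1 = v1.std(axis=1, ddof=1)
        sd2 = v2.std(axis=1, ddof=1)
        scores = (mu1 - mu2) / (_adjusted_sd(sd1, mu1) + _adjusted_sd(sd2, mu2))
    elif metric == "log2_fc":
        scores = mu1 - mu2
    else:
        raise ValueError(f"unknown metric {metric!r}")

    genes = np.asarray([str(g) for g in matrix.values.index])
    # descending metric; ties broken by gene id ascending (lexsort: last key primary)
    order = np.lexsort((genes, -scores))
    return RankedList(
        genes=genes[order], metric=scores[order], metric_name=metric, groups=(g1, g2)
    )


def _hit_mask(ranked: RankedList, members) -> np.ndarray:
    member_set = {str(m) for m in members}
    return np.fromiter((g in member_set for g in ranked.genes), dtype=bool, count=len(ranked))


def _running_sum(hit: np.ndarray, absw: np.ndarray) -> np.ndarray:
    """Running enrichment profile for one hit mask (1-D) over |metric|**p weights."""
    n = hit.size
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValueError("no set member present in the ranked universe")
    if n_hit == n:
        raise ValueError("gene set equals the whole universe (miss denominator zero)")
    w = np.where(hit, absw, 0.0)
    denom = w.sum()
    if denom == 0.0:
        # all hit metrics are exactly zero: fall back to equal hit weights
        incr = hit / n_hit
    else:
        incr = w / denom
    steps = incr - (~hit) / (n - n_hit)
    return np.cumsum(steps)


def enrichment_score(
    ranked: RankedList,
    members,
    weight_p: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted running-sum enrichment score of ``members`` in ``ranked``.

    Members absent from the ranked universe are dropped first.  Returns
    ``(es, running_sum, leading_edge)``; the extremum position is the first
    index attaining the maximal absolute deviation, and the leading edge is
    the hit genes at or before it (strictly after it, for negative ES).
    """
    hit = _hit_mask(ranked, members)
    running = _running_sum(hit, np.abs(ranked.metric) ** weight_p)
    i = int(np.argmax(np.abs(running)))
    es = float(running[i])
    if es >= 0:
        edge_mask = hit & (np.arange(len(ranked)) <= i)
    else:
        edge_mask = hit & (np.arange(len(ranked)) > i)
    leading = [str(g) for g in ranked.genes[edge_mask]]
    return es, running, leading


def _batch_null_es(
    absw: np.ndarray,
    n_hit: int,
    n_perm: int,
    rng: np.random.Generator,
    chunk: int = 256,
) -> np.ndarray:
    """ES values of ``n_perm`` random size-``n_hit`` gene sets (vectorised)."""
    n = absw.size
    out = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # random k-subsets: first k entries of row-wise permutations
        keys = rng.random((m, n))
        idx = np.argpartition(keys, n_hit - 1, axis=1)[:, :n_hit]
        hit = np.zeros((m, n), dtype=bool)
        np.put_along_axis(hit, idx, True, axis=1)
        w = np.where(hit, absw[None, :], 0.0)
        denom = w.sum(axis=1, keepdims=True)
        incr = np.where(denom > 0, w / np.where(denom == 0, 1.0, denom), hit / n_hit)
        steps = incr - (~hit) / (n - n_hit)
        running = np.cumsum(steps, axis=1)
        pos = np.argmax(np.abs(running), axis=1)
        out[done : done + m] = running[np.arange(m), pos]
        done += m
    return out


def permutation_test(
    ranked: RankedList,
    members,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    set_name: str = "",
) -> GseaResult:
    """Gene-set-permutation significance of one set's enrichment.

    Null scores come from ``n_perm`` random same-size gene sets; p and NES
    use the same-sign convention described in the module docstring.  If no
    null score shares the observed sign the NES is NaN and p is 1.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    hit = _hit_mask(ranked, members)
    n_hit = int(hit.sum())
    if n_hit > len(ranked):
        raise ValueError("set size exceeds the ranked universe")
    es, running, leading = enrichment_score(ranked, members, weight_p=weight_p)

    rng = np.random.default_rng(seed)
    absw = np.abs(ranked.metric) ** weight_p
    null = _batch_null_es(absw, n_hit, n_perm, rng)

    sign = 1.0 if es >= 0 else -1.0
    same = null * sign > 0
    n_same = int(same.sum())
    n_extreme = int((np.abs(null[same]) >= abs(es)).sum())
    nominal_p = (1 + n_extreme) / (1 + n_same)
    nes = float(es / np.abs(null[same]).mean()) if n_same else float("nan")
    return GseaResult(
        set_name=set_name,
        set_size=n_hit,
        es=es,
        running_sum=running,
        leading_edge=leading,
        n_perm=n_perm,
        nominal_p=nominal_p,
        nes=nes,
        seed=seed,
        weight_p=weight_p,
    )


def run_gsea(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    metric: str = "signal_to_noise",
    weight_p: float = 1.0,
    min_size: int = 5,
) -> list[GseaResult]:
    """Enrichment of every collection set against one ranked comparison.

    Sets with fewer than ``min_size`` members in the ranked universe are
    skipped (logged).  Every set's permutation test uses the same seed, so a
    single-set collection reproduces a direct :func:`permutation_test` call
    exactly.  Results are sorted by descending |NES|.
    """
    if len(collection) == 0:
        raise ValueError("empty gene set collection")
    ranked = rank_genes(matrix, labels, metric=metric)
    universe = set(ranked.genes.tolist())
    results: list[GseaResult] = []
    for name in collection.names:
        members = [m for m in collection[name] if m in universe]
        if len(members) < min_size:
            log.info("run_gsea: skipping %r (%d members in universe)", name, len(members))
            continue
        results.append(
            permutation_test(
                ranked, members, n_perm=n_perm, seed=seed, weight_p=weight_p, set_name=name
            )
        )
    results.sort(key=lambda r: (-(abs(r.nes) if np.isfinite(r.nes) else -1.0), r.set_name))
    return results


def gsea_table(results: list[GseaResult]) -> pd.DataFrame:
    """Summary DataFrame (one row per set) of a list of results."""
    return pd.DataFrame(
        {
            "set_name": [r.set_name for r in results],
            "set_size": [r.set_size for r in results],
            "es": [r.es for r in results],
            "nes": [r.nes for r in results],
            "nominal_p": [r.nominal_p for r in results],
            "n_perm": [r.n_perm for r in results],
            "leading_edge_size": [len(r.leading_edge) for r in results],
        }
    ).set_index("set_name")
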