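"""Cross-species fold-change concordance statistics.

Homologous gene pairs carry one fold-change per species.  Restricting to
pairs strong in both species (|linear fold| above a threshold), each pair
falls into one of four quadrants by the sign pattern of its two deltas:
up/up, up/down, down/up, down/down.  Association between the two species'
directions is tested by Fisher's exact test on the 2x2 quadrant table
(species-A direction x species-B direction); the concordant fraction is
(up/up + down/down) / n.

The Fisher p-value is the classical two-sided point-probability rule: the
sum of the probabilities of all tables with the observed margins whose
point probability does not exceed the observed one (with a 1e-7 relative
tolerance for floating-point ties).  Rank association is measured by a
Spearman correlation restricted — as in the comparative screens this
module serves — to pairs strong in *one* designated species only.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .homology import HomologPairSet
from .signatures import FoldChangeTable

__all__ = [
    "PairedFC",
    "ConcordanceResult",
    "CorrelationResult",
    "pair_fold_changes",
    "quadrant_concordance",
    "fisher_exact_2x2",
    "restricted_spearman",
    "spearman_rho_p",
]

log = logging.getLogger(__name__)

FISHER_TIE_RTOL = 1e-7
SPEARMAN_EXACT_MAX_N = 10


@dataclass
class PairedFC:
    """Per-homolog-pair fold-changes in two species.

    ``table`` has columns ``gene_a``, ``gene_b``, ``delta_a``, ``delta_b``
    (log2 group differences); ``n_universe`` is the number of pairs offered,
    ``n_dropped`` how many were missing from either fold-change table.
    """

    table: pd.DataFrame
    n_universe: int
    n_dropped: int

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class ConcordanceResult:
    """Quadrant counts and association statistics over strong pairs."""

    counts: dict[str, int]          # keys up_up, up_down, down_up, down_down
    n_overlap: int
    concordant_fraction: float
    fisher_p: float | None
    odds_ratio: float
    min_fold: float

    def quadrant_table(self) -> list[list[int]]:
        c = self.counts
        return [[c["up_up"], c["up_down"]], [c["down_up"], c["down_down"]]]


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p_value: float
    restriction: str


def pair_fold_changes(
    fc_a: FoldChangeTable,
    fc_b: FoldChangeTable,
    pairs: HomologPairSet,
) -> PairedFC:
    """Join two species' fold-change tables over the 1:1 homolog pairs.

    Pairs whose gene is missing from either table are dropped and counted.
    An empty intersection is an error.
    """
    pa = pairs.pairs
    in_a = pa["gene_a"].isin(fc_a.table.index)
    in_b = pa["gene_b"].isin(fc_b.table.index)
    kept = pa[in_a & in_b]
    n_dropped = len(pa) - len(kept)
    if kept.empty:
        raise ValueError("no homolog pair is present in both fold-change tables")
    if n_dropped:
        log.info("pair_fold_changes: %d pairs missing from a table", n_dropped)
    table = pd.DataFrame(
        {
            "gene_a": kept["gene_a"].to_numpy(),
            "gene_b": kept["gene_b"].to_numpy(),
            "delta_a": fc_a.table.loc[kept["gene_a"], "delta_log2"].to_numpy(),
            "delta_b": fc_b.table.loc[kept["gene_b"], "delta_log2"].to_numpy(),
        }
    )
    return PairedFC(table=table, n_universe=len(pa), n_dropped=n_dropped)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on the table [[a, b], [c, d]].

    Enumerates the full hypergeometric support at the observed margins and
    sums the probabilities of tables whose point probability is at most the
    observed one (relative tolerance 1e-7).  Returns ``(p, odds_ratio)``
    with the sample odds ratio ``a*d / (b*c)`` (``inf`` when ``b*c == 0``
    and ``a*d > 0``, ``nan`` for 0/0).
    """
    for v in (a, b, c, d):
        if not isinstance(v, (int, np.integer)) or v < 0:
            raise ValueError("cell counts must be nonnegative integers")
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero contingency table")
    row1, col1 = a + b, a + c
    kmin = max(0, row1 + col1 - n)
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[support == a][0]
    p = float(pmf[pmf <= p_obs * (1.0 + FISHER_TIE_RTOL)].sum())
    p = min(p, 1.0)
    if b * c == 0:
        odds = float("nan") if a * d == 0 else float("inf")
    else:
        odds = (a * d) / (b * c)
    return p, odds


def quadrant_concordance(
    paired: PairedFC,
    min_fold_both: float = 2.0,
) -> ConcordanceResult:
    """Quadrant analysis over pairs strong in BOTH species.

    Pairs with |linear fold| >= ``min_fold_both`` in each species (zero
    deltas always excluded) are classified by the sign pattern of their two
    deltas.  When no pair survives, counts are zero and the Fisher p is
    ``None``.
    """
    if min_fold_both < 1:
        raise ValueError("min_fold_both must be >= 1")
    thr = math.log2(min_fold_both)
    da = paired.table["delta_a"].to_numpy()
    db = paired.table["delta_b"].to_numpy()
    strong = (np.abs(da) >= thr) & (np.abs(db) >= thr) & (da != 0) & (db != 0)
    da, db = da[strong], db[strong]
    counts = {
        "up_up": int(((da > 0) & (db > 0)).sum()),
        "up_down": int(((da > 0) & (db < 0)).sum()),
        "down_up": int(((da < 0) & (db > 0)).sum()),
        "down_down": int(((da < 0) & (db < 0)).sum()),
    }
    n = int(strong.sum())
    if n == 0:
        log.warning("quadrant_concordance: no pair passes the threshold")
        return ConcordanceResult(
            counts=counts,
            n_overlap=0,
            concordant_fraction=float("nan"),
            fisher_p=None,
            odds_ratio=float("nan"),
            min_fold=min_fold_both,
        )
    fraction = (counts["up_up"] + counts["down_down"]) / n
    p, odds = fisher_exact_2x2(
        counts["up_up"], counts["up_down"], counts["down_up"], counts["down_down"]
    )
    return ConcordanceResult(
        counts=counts,
        n_overlap=n,
        concordant_fraction=fraction,
        fisher_p=p,
        odds_ratio=odds,
        min_fold=min_fold_both,
    )


def _rank_average(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman_rho_p(x, y, exact_max_n: int = SPEARMAN_EXACT_MAX_N) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and its p-value.

    For n <= ``exact_max_n`` the p-value is the exact permutation tail
    (two-sided, |rho| at least as extreme, over all n! pairings); above
    that, the usual t approximation ``t = rho * sqrt((n-2) / (1-rho^2))``
    with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("length mismatch")
    if n < 3:
        raise ValueError("need n >= 3 for a Spearman p-value")
    rx, ry = _rank_average(x), _rank_average(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise ValueError("constant vector: Spearman correlation undefined")
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= exact_max_n:
        # exact null: all pairings of the observed rank vectors
        sx = (rx - rx.mean()) / rx.std()
        sy = (ry - ry.mean()) / ry.std()
        target = abs(rho) - 1e-12
        count = 0
        total = 0
        perms = itertools.permutations(range(n))
        chunk: list[tuple[int, ...]] = []
        for perm in perms:
            chunk.append(perm)
            if len(chunk) == 50000:
                rhos = (sx[np.array(chunk)] * sy[None, :]).mean(axis=1)
                count += int((np.abs(rhos) >= target).sum())
                total += len(chunk)
                chunk = []
        if chunk:
            rhos = (sx[np.array(chunk)] * sy[None, :]).mean(axis=1)
            count += int((np.abs(rhos) >= target).sum())
            total += len(chunk)
        p = count / total
    else:
        denom = 1.0 - rho * rho
        if denom <= 0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / denom)
            p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def restricted_spearman(
    paired: PairedFC,
    restrict_species: str = "B",
    min_fold: float = 2.0,
    strict_greater: bool = False,
) -> CorrelationResult:
    """Spearman correlation of paired log2 fold-changes, restricted one-sided.

    Only pairs with |linear fold| >= ``min_fold`` (or strictly greater with
    ``strict_greater``) in ``restrict_species`` ("A" or "B") enter the
    correlation; both species' deltas are then correlated over that subset.
    """
    if restrict_species not in ("A", "B"):
        raise ValueError("restrict_species must be 'A' or 'B'")
    thr = math.log2(min_fold)
    d = paired.table[f"delta_{restrict_species.lower()}"].to_numpy()
    mask = np.abs(d) > thr if strict_greater else np.abs(d) >= thr
    if min_fold == 1.0 and not strict_greater:
        mask = mask & (d != 0)
    sub = paired.table[mask]
    if len(sub) < 3:
        raise ValueError(f"restriction leaves n={len(sub)} < 3 pairs")
    rho, p = spearman_rho_p(sub["delta_a"].to_numpy(), sub["delta_b"].to_numpy())
    cmp = ">" if strict_greater else ">="
    return CorrelationResult(
        rho=rho,
        n=len(sub),
        p_value=p,
        restriction=f"|fold_{restrict_species}| {cmp} {min_fold:g}",
    )
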