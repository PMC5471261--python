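"""Group fold-changes and fold-change-derived gene signatures.

The fold-change between two phenotype groups is the difference of
arithmetic mean log2 intensities (i.e. the log2 ratio of geometric-mean
intensities, the standard quantity for RMA data), carried both as
``delta_log2`` and as a signed linear fold ``sign(delta) * 2**|delta|`` so
that a 2-fold change reads as +2.0 / -2.0 rather than +-1.0.

Signature constructions mirror the comparative screens this pipeline
serves:

* ``threshold_signature`` — genes at >= *f*-fold in one comparison;
* ``intersection_signature`` — genes at >= *f*-fold, same direction, in two
  comparisons (e.g. subset-1 vs NK *and* subset-2 vs NK);
* ``recurrence_classes`` — for cross-species pairs strong in species A, in
  how many species-B tissues the homolog recurs ("blue" = all tissues,
  "green" = all but one);
* ``two_platform_screen`` — genes from a candidate list (e.g. transcription
  factors) changed >= *f*-fold in the same direction on two array
  platforms, ordered by mean linear fold.

All fold thresholds are inclusive (>=).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .collapse import _group_delta
from .homology import HomologPairSet
from .io import ExpressionMatrix, GeneSetCollection, GroupLabels

__all__ = [
    "FoldChangeTable",
    "GeneSignature",
    "fold_changes",
    "threshold_signature",
    "intersection_signature",
    "recurrence_classes",
    "two_platform_screen",
    "signatures_to_collection",
]

log = logging.getLogger(__name__)


def signed_linear_fold(delta_log2: np.ndarray) -> np.ndarray:
    """Signed linear fold: |fold| >= 1 always, sign follows delta (0 -> +1)."""
    d = np.asarray(delta_log2, dtype=float)
    return np.where(d >= 0, np.exp2(d), -np.exp2(-d))


@dataclass
class FoldChangeTable:
    """Per-gene fold-change between two groups of one comparison.

    ``table`` is indexed by gene id with columns ``mean_log2_group1``,
    ``mean_log2_group2``, ``delta_log2`` (group1 minus group2) and
    ``linear_fold``.
    """

    table: pd.DataFrame
    group1: str
    group2: str
    species: str = ""

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.table["delta_log2"].to_numpy())):
            raise ValueError("non-finite delta_log2")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def delta(self, gene: str) -> float:
        return float(self.table.loc[gene, "delta_log2"])


@dataclass
class GeneSignature:
    """A named, species-tagged gene list plus the rule that produced it."""

    name: str
    species: str
    members: list[str]
    rule: str = "manual"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate members in signature {self.name!r}")

    def __len__(self) -> int:
        return len(self.members)


def fold_changes(
    matrix: ExpressionMatrix,
    labels: GroupLabels,
) -> FoldChangeTable:
    """Per-feature fold-change table, group1 minus group2 of ``labels``.

    Requires exactly two groups; a group with a single sample is permitted
    with a warning (means are still well-defined).
    """
    g1, g2 = labels.two_groups()
    s1 = [s for s in matrix.sample_ids if labels.assignments.get(s) == g1]
    s2 = [s for s in matrix.sample_ids if labels.assignments.get(s) == g2]
    if not s1 or not s2:
        raise ValueError(f"groups {g1!r}/{g2!r} absent from matrix samples")
    if len(s1) < 2 or len(s2) < 2:
        log.warning("fold_changes: a group has a single sample")
    m1 = matrix.values[s1].mean(axis=1)
    m2 = matrix.values[s2].mean(axis=1)
    delta = m1 - m2
    table = pd.DataFrame(
        {
            "mean_log2_group1": m1,
            "mean_log2_group2": m2,
            "delta_log2": delta,
            "linear_fold": signed_linear_fold(delta.to_numpy()),
        }
    )
    table.index = table.index.astype(str)
    table.index.name = "gene_id"
    return FoldChangeTable(table=table, group1=g1, group2=g2, species=matrix.species)


def _direction_mask(fc: FoldChangeTable, min_fold: float, direction: str) -> pd.Series:
    if min_fold < 1:
        raise ValueError("min_fold must be >= 1")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    delta = fc.table["delta_log2"]
    lin = fc.table["linear_fold"]
    if direction == "up":
        return (delta > 0) & (lin >= min_fold)
    return (delta < 0) & (lin <= -min_fold)


def threshold_signature(
    fc: FoldChangeTable,
    min_fold: float = 2.0,
    direction: str = "up",
    name: str | None = None,
) -> GeneSignature:
    """Genes changed >= ``min_fold`` in ``direction`` (inclusive threshold).

    With ``min_fold=1`` this returns every gene with a nonzero delta in the
    stated direction.
    """
    mask = _direction_mask(fc, min_fold, direction)
    members = fc.table.index[mask].tolist()
    return GeneSignature(
        name=name or f"{fc.group1}_vs_{fc.group2}_{direction}_{min_fold:g}x",
        species=fc.species,
        members=members,
        rule="threshold",
        params={"min_fold": min_fold, "direction": direction,
                "comparison": f"{fc.group1}_vs_{fc.group2}"},
    )


def intersection_signature(
    fc1: FoldChangeTable,
    fc2: FoldChangeTable,
    min_fold: float = 2.0,
    direction: str = "up",
    name: str | None = None,
) -> GeneSignature:
    """Genes passing the threshold in the same direction in both comparisons.

    Operates on the intersection of the two gene universes; disjoint
    universes yield an empty signature with a warning.
    """
    common = fc1.table.index.intersection(fc2.table.index)
    if len(common) == 0:
        log.warning("intersection_signature: disjoint gene universes")
    m1 = _direction_mask(fc1, min_fold, direction).reindex(common, fill_value=False)
    m2 = _direction_mask(fc2, min_fold, direction).reindex(common, fill_value=False)
    members = common[m1 & m2].tolist()
    return GeneSignature(
        name=name or f"intersection_{direction}_{min_fold:g}x",
        species=fc1.species,
        members=members,
        rule="intersection",
        params={
            "min_fold": min_fold,
            "direction": direction,
            "comparisons": [
                f"{fc1.group1}_vs_{fc1.group2}",
                f"{fc2.group1}_vs_{fc2.group2}",
            ],
        },
    )


def recurrence_classes(
    fc_a: FoldChangeTable,
    fc_b_by_tissue: dict[str, FoldChangeTable],
    pairs: HomologPairSet,
    min_fold: float = 2.0,
    class_labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Multi-tissue recurrence of species-A fold-changes in species B.

    For each homolog pair whose species-A gene passes ``min_fold``, count
    the species-B tissues in which the homolog passes ``min_fold`` in the
    same direction (a tissue table missing the homolog counts as not
    passing).  By default a pair recurring in all tissues is classed
    ``"blue"`` and in all-but-one ``"green"``; other counts get ``""``.

    Returns a DataFrame with columns ``gene_a``, ``gene_b``, ``delta_a``,
    ``direction``, ``n_tissues_pass``, ``recurrence_class``.
    """
    if not fc_b_by_tissue:
        raise ValueError("at least one species-B tissue table is required")
    n_tissues = len(fc_b_by_tissue)
    if class_labels is None:
        class_labels = {n_tissues: "blue"}
        if n_tissues >= 2:
            class_labels[n_tissues - 1] = "green"
    thr = np.log2(min_fold)

    rows = []
    for _, pr in pairs.pairs.iterrows():
        ga, gb = pr["gene_a"], pr["gene_b"]
        if ga not in fc_a.table.index:
            continue
        da = fc_a.delta(ga)
        if abs(da) < thr or da == 0:
            continue
        direction = "up" if da > 0 else "down"
        count = 0
        for fc_b in fc_b_by_tissue.values():
            if gb not in fc_b.table.index:
                continue
            db = fc_b.delta(gb)
            if abs(db) >= thr and np.sign(db) == np.sign(da) and db != 0:
                count += 1
        rows.append((ga, gb, da, direction, count, class_labels.get(count, "")))
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "delta_a", "direction", "n_tissues_pass", "recurrence_class"],
    )


def two_platform_screen(
    fc_p1: FoldChangeTable,
    fc_p2: FoldChangeTable,
    gene_list: list[str],
    min_fold: float = 2.0,
    name: str = "two_platform",
) -> tuple[GeneSignature, pd.DataFrame]:
    """Candidate genes changed >= ``min_fold`` in the same direction on both platforms.

    Returns the signature plus a per-gene table (``fold_p1``, ``fold_p2``,
    ``mean_fold`` — the arithmetic mean of the two signed linear folds),
    ordered by descending |mean fold|.
    """
    if not gene_list:
        raise ValueError("gene_list must be non-empty")
    rows = []
    for g in gene_list:
        if g not in fc_p1.table.index or g not in fc_p2.table.index:
            continue
        f1 = float(fc_p1.table.loc[g, "linear_fold"])
        f2 = float(fc_p2.table.loc[g, "linear_fold"])
        if abs(f1) < min_fold or abs(f2) < min_fold:
            continue
        if np.sign(f1) != np.sign(f2):
            continue
        rows.append((g, f1, f2, (f1 + f2) / 2.0))
    report = pd.DataFrame(rows, columns=["gene_id", "fold_p1", "fold_p2", "mean_fold"])
    report = report.reindex(
        report["mean_fold"].abs().sort_values(ascending=False, kind="mergesort").index
    ).set_index("gene_id")
    sig = GeneSignature(
        name=name,
        species=fc_p1.species,
        members=report.index.tolist(),
        rule="two_platform",
        params={"min_fold": min_fold, "n_candidates": len(gene_list)},
    )
    return sig, report


def signatures_to_collection(sigs: list[GeneSignature]) -> GeneSetCollection:
    """Bundle non-empty signatures into a GMT-style collection."""
    sets = {s.name: list(s.members) for s in sigs if s.members}
    descriptions = {s.name: s.rule for s in sigs if s.members}
    return GeneSetCollection(sets=sets, descriptions=descriptions)
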