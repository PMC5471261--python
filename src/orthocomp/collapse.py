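"""Collapse a probeset-level matrix to one representative probeset per gene.

Selection is lexicographic over annotated criteria, in priority order:

1. lack of cross-reactivity,
2. recognition of coding regions,
3. larger absolute log2 fold-change between the two phenotype groups,
4. lexicographically smallest probeset id (determinism tie-break).

Three-valued annotation: an *unknown* flag never penalises a probeset — it
is grouped with the favoured side (not cross-reactive / coding), so a
criterion only discriminates where the information was actually annotated.
The chosen probeset's sample values are carried to the gene level unchanged
(no averaging or model-based summarisation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GroupLabels, ProbesetAnnotation

__all__ = ["CollapseRecord", "collapse"]

log = logging.getLogger(__name__)

CRITERIA = ("single_candidate", "cross_reactivity", "coding", "fold_change", "id_tiebreak")


@dataclass
class CollapseRecord:
    """Per-gene record of the collapse decision.

    ``table`` is indexed by gene id with columns ``probeset_id`` (the chosen
    representative), ``n_candidates`` and ``criterion`` (which rule decided).
    ``n_unmatched`` counts annotation probesets absent from the matrix.
    """

    table: pd.DataFrame
    n_unmatched: int = 0


def _group_delta(values: pd.DataFrame, labels: GroupLabels) -> np.ndarray:
    """Row-wise mean log2 difference, group1 minus group2."""
    g1, g2 = labels.two_groups()
    s1 = [s for s in values.columns if labels.assignments.get(str(s)) == g1]
    s2 = [s for s in values.columns if labels.assignments.get(str(s)) == g2]
    if not s1 or not s2:
        raise ValueError("both groups must be present among the matrix samples")
    return values[s1].mean(axis=1).to_numpy() - values[s2].mean(axis=1).to_numpy()


def collapse(
    matrix: ExpressionMatrix,
    annotation: ProbesetAnnotation,
    labels: GroupLabels,
) -> tuple[ExpressionMatrix, CollapseRecord]:
    """Reduce ``matrix`` to one row per annotated gene.

    Probesets present in the annotation but absent from the matrix are
    ignored (counted in the record); genes with no probeset in the matrix
    produce no output row.  An empty intersection yields an empty gene
    matrix with a warning rather than an error.
    """
    if matrix.level != "probeset":
        raise ValueError("collapse expects a probeset-level matrix")

    ann = annotation.table
    present = ann.index.astype(str).isin(matrix.values.index.astype(str))
    n_unmatched = int((~present).sum())
    if n_unmatched:
        log.info("collapse: %d annotated probesets absent from matrix", n_unmatched)
    ann = ann.loc[present]
    if ann.empty:
        log.warning("collapse: no annotated probesets present in matrix")
        empty = ExpressionMatrix(
            values=pd.DataFrame(columns=matrix.values.columns),
            level="gene",
            species=matrix.species,
        )
        rec = CollapseRecord(
            table=pd.DataFrame(columns=["probeset_id", "n_candidates", "criterion"]),
            n_unmatched=n_unmatched,
        )
        return empty, rec

    sub = matrix.values.loc[ann.index]
    absfc = np.abs(_group_delta(sub, labels))

    cand = pd.DataFrame(
        {
            "probeset_id": ann.index.astype(str),
            "gene_id": ann["gene_id"].astype(str).to_numpy(),
            # unknown flags never penalise: rank 1 only on annotated bad values
            "cr_rank": np.array([1 if v is True else 0 for v in ann["cross_reactive"]]),
            "coding_rank": np.array([1 if v is False else 0 for v in ann["coding"]]),
            "absfc": absfc,
        }
    )
    # lexicographic selection, ascending on every key (absfc negated)
    cand = cand.assign(neg_absfc=-cand["absfc"]).sort_values(
        ["gene_id", "cr_rank", "coding_rank", "neg_absfc", "probeset_id"],
        kind="mergesort",
    )
    chosen = cand.groupby("gene_id", sort=True).head(1).set_index("gene_id")

    grp = cand.groupby("gene_id", sort=True)
    n_cand = grp.size()
    surv1 = grp["cr_rank"].transform("min") == cand["cr_rank"]
    n1 = cand[surv1].groupby("gene_id", sort=True).size()
    c2 = cand[surv1]
    surv2 = c2.groupby("gene_id", sort=True)["coding_rank"].transform("min") == c2["coding_rank"]
    n2 = c2[surv2].groupby("gene_id", sort=True).size()
    c3 = c2[surv2]
    surv3 = c3.groupby("gene_id", sort=True)["absfc"].transform("max") == c3["absfc"]
    n3 = c3[surv3].groupby("gene_id", sort=True).size()

    criterion = pd.Series("id_tiebreak", index=n_cand.index)
    criterion[n3 == 1] = "fold_change"
    criterion[n2 == 1] = "coding"
    criterion[n1 == 1] = "cross_reactivity"
    criterion[n_cand == 1] = "single_candidate"

    record = pd.DataFrame(
        {
            "probeset_id": chosen["probeset_id"],
            "n_candidates": n_cand,
            "criterion": criterion,
        }
    )
    record.index.name = "gene_id"

    gene_values = matrix.values.loc[chosen["probeset_id"].to_numpy()].copy()
    gene_values.index = pd.Index(chosen.index, name="gene_id")
    gene_matrix = ExpressionMatrix(values=gene_values, level="gene", species=matrix.species)
    return gene_matrix, CollapseRecord(table=record, n_unmatched=n_unmatched)
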