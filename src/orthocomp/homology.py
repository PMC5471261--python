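"""1:1 cross-species gene pairing from a Homologene-style table.

A homology group yields a pair exactly when it contains a single gene from
each of the two requested taxa (strict 1:1 policy); groups with a missing
taxon or with within-species paralogs are dropped and logged, so deviations
from an expected pair count are diagnosable from the drop log.  Manual
override pairs (the hand-curated kind, e.g. pairing a gene the database
does not match) are carried separately and excluded from the default pair
count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import HomologyTable

__all__ = ["HomologPairSet", "build_pairs", "translate_signature"]

log = logging.getLogger(__name__)


@dataclass
class HomologPairSet:
    """1:1 gene pairs between two taxa.

    ``pairs`` has columns ``gene_a``, ``gene_b``, ``group_id``, ``manual``;
    ``dropped`` logs rejected groups with columns ``group_id``, ``reason``
    (``absent_species``, ``multi_mapping`` or ``duplicate_gene``).
    """

    taxon_a: str
    taxon_b: str
    pairs: pd.DataFrame
    dropped: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["group_id", "reason"])
    )

    @property
    def n_pairs(self) -> int:
        """Database-derived pair count (manual overrides excluded)."""
        return int((~self.pairs["manual"]).sum())

    def a_to_b(self, include_manual: bool = True) -> dict[str, str]:
        sub = self.pairs if include_manual else self.pairs[~self.pairs["manual"]]
        return dict(zip(sub["gene_a"], sub["gene_b"]))

    def b_to_a(self, include_manual: bool = True) -> dict[str, str]:
        sub = self.pairs if include_manual else self.pairs[~self.pairs["manual"]]
        return dict(zip(sub["gene_b"], sub["gene_a"]))


def build_pairs(
    table: HomologyTable,
    taxon_a: str,
    taxon_b: str,
    overrides: list[tuple[str, str]] | None = None,
) -> HomologPairSet:
    """Build strict 1:1 pairs between ``taxon_a`` and ``taxon_b``.

    Groups containing one of the two taxa but not the other are dropped with
    reason ``absent_species``; groups with more than one gene in either
    taxon with reason ``multi_mapping``.  A gene may appear in at most one
    pair: a later group re-using an already-paired gene is dropped with
    reason ``duplicate_gene``.  Overrides referencing an already-paired gene
    raise a conflict error.
    """
    taxon_a, taxon_b = str(taxon_a), str(taxon_b)
    df = table.table.astype(str)
    relevant = df[df["taxon_id"].isin([taxon_a, taxon_b])]
    if relevant.empty or set(relevant["taxon_id"]) != {taxon_a, taxon_b}:
        raise ValueError(f"homology table must contain both taxa {taxon_a} and {taxon_b}")

    pair_rows: list[tuple[str, str, str, bool]] = []
    drop_rows: list[tuple[str, str]] = []
    used_a: set[str] = set()
    used_b: set[str] = set()
    for group_id, grp in relevant.groupby("group_id", sort=True):
        in_a = grp.loc[grp["taxon_id"] == taxon_a, "gene_id"].tolist()
        in_b = grp.loc[grp["taxon_id"] == taxon_b, "gene_id"].tolist()
        if not in_a or not in_b:
            drop_rows.append((group_id, "absent_species"))
            continue
        if len(in_a) > 1 or len(in_b) > 1:
            drop_rows.append((group_id, "multi_mapping"))
            continue
        ga, gb = in_a[0], in_b[0]
        if ga in used_a or gb in used_b:
            drop_rows.append((group_id, "duplicate_gene"))
            continue
        used_a.add(ga)
        used_b.add(gb)
        pair_rows.append((ga, gb, group_id, False))

    for ga, gb in overrides or []:
        ga, gb = str(ga), str(gb)
        if ga in used_a or gb in used_b:
            raise ValueError(f"override ({ga}, {gb}) conflicts with an existing pair")
        used_a.add(ga)
        used_b.add(gb)
        pair_rows.append((ga, gb, "", True))

    pairs = pd.DataFrame(pair_rows, columns=["gene_a", "gene_b", "group_id", "manual"])
    dropped = pd.DataFrame(drop_rows, columns=["group_id", "reason"])
    if len(dropped):
        log.info(
            "build_pairs: %d pairs, %d groups dropped (%s)",
            len(pairs),
            len(dropped),
            dropped["reason"].value_counts().to_dict(),
        )
    return HomologPairSet(taxon_a=taxon_a, taxon_b=taxon_b, pairs=pairs, dropped=dropped)


def translate_signature(sig, pairs: HomologPairSet, target_taxon: str):
    """Map a gene signature into the homologous genes of ``target_taxon``.

    Members without a 1:1 partner are dropped (the drop count is recorded in
    the result's parameters); a signature already in the target taxon is
    returned unchanged with a drop count of zero.  An empty translation is a
    warning, not an error.
    """
    from .signatures import GeneSignature  # local import to avoid a cycle

    target_taxon = str(target_taxon)
    if sig.species == target_taxon:
        return GeneSignature(
            name=sig.name,
            species=target_taxon,
            members=list(sig.members),
            rule=sig.rule,
            params={**sig.params, "translated_from": sig.species, "n_dropped": 0},
        )
    if target_taxon == pairs.taxon_a:
        mapping = pairs.b_to_a()
    elif target_taxon == pairs.taxon_b:
        mapping = pairs.a_to_b()
    else:
        raise ValueError(f"target taxon {target_taxon!r} not covered by the pair set")
    mapped = [mapping[m] for m in sig.members if m in mapping]
    n_dropped = len(sig.members) - len(mapped)
    if not mapped:
        log.warning("translate_signature: signature %r maps to no genes", sig.name)
    return GeneSignature(
        name=sig.name,
        species=target_taxon,
        members=mapped,
        rule=sig.rule,
        params={**sig.params, "translated_from": sig.species, "n_dropped": n_dropped},
    )
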