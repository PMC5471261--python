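"""Seeded two-species microarray-like data with planted differential signatures.

The generator emulates the study design the downstream pipeline was built
for: two species (nominally human, taxon 9606, and mouse, taxon 10090), two
sorted cell subsets per species, three biological replicates per subset, RMA
log2-scale intensities with independent Gaussian noise, several probesets
per gene (a fraction of which are cross-reactive), and a partial 1:1
homology map in the real Homologene flat-file layout so the same reader
serves synthetic and real data.

Planted signatures specify gene sets with a known log2 effect between the
two subsets; for ``species="both"`` the effect is mirrored onto the homolog
in the second species with the same sign (``concordant=True``) or the
opposite sign (``concordant=False``).  At ``noise_sd=0`` every downstream
fold-change estimate equals its planted effect exactly, which the test
suite exploits as ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GroupLabels,
    HomologyTable,
    ProbesetAnnotation,
    write_class_labels,
    write_expression,
    write_homologene,
    write_probeset_annotation,
)

__all__ = [
    "PlantedSignature",
    "SimConfig",
    "TruthRecord",
    "SyntheticDataset",
    "generate_dataset",
    "write_dataset",
]

# weight of the contaminating gene's signal in a cross-reactive probeset
CROSS_REACTIVE_MIX = 0.5


class ConfigurationError(ValueError):
    """Raised for an internally inconsistent simulation configuration."""


@dataclass
class PlantedSignature:
    """A named gene set with a known differential effect.

    ``gene_ids`` refer to species-A genes when ``species`` is ``"A"`` or
    ``"both"`` and to species-B genes when ``species`` is ``"B"``.  For
    ``"both"`` the genes must lie in the homologous subset; the effect is
    copied to the species-B partner with matching (``concordant=True``) or
    flipped (``concordant=False``) sign.
    """

    name: str
    species: str  # "A" | "B" | "both"
    gene_ids: list[str]
    log2_effect: float
    concordant: bool = True

    def __post_init__(self) -> None:
        if self.species not in ("A", "B", "both"):
            raise ConfigurationError(f"signature species must be A/B/both, got {self.species!r}")
        if not np.isfinite(self.log2_effect):
            raise ConfigurationError("log2_effect must be finite")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ConfigurationError(f"duplicate gene ids in signature {self.name!r}")


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic two-species dataset.

    Defaults mirror the emulated design: 3 samples per subset, log2-scale
    Gaussian noise, baseline log2 intensities uniform on [6, 12].
    """

    seed: int
    n_genes_per_species: int = 1000
    frac_homologous: float = 0.8
    probesets_per_gene: tuple[int, int] = (1, 3)
    frac_cross_reactive: float = 0.2
    n_samples_per_group: int = 3
    noise_sd: float = 0.5
    planted_signatures: list[PlantedSignature] = field(default_factory=list)
    baseline_mean_range: tuple[float, float] = (6.0, 12.0)
    taxon_a: str = "9606"
    taxon_b: str = "10090"
    group_names_a: tuple[str, str] = ("CD56bright", "CD56dim")
    group_names_b: tuple[str, str] = ("ILC1", "NK")

    def __post_init__(self) -> None:
        if not (0.0 <= self.frac_homologous <= 1.0):
            raise ConfigurationError("frac_homologous must lie in [0, 1]")
        if not (0.0 <= self.frac_cross_reactive <= 1.0):
            raise ConfigurationError("frac_cross_reactive must lie in [0, 1]")
        if self.n_genes_per_species < 1 or self.n_samples_per_group < 1:
            raise ConfigurationError("counts must be >= 1")
        lo, hi = self.probesets_per_gene
        if lo < 1 or hi < lo:
            raise ConfigurationError("probesets_per_gene must be a range with 1 <= lo <= hi")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        lo, hi = self.baseline_mean_range
        if hi < lo:
            raise ConfigurationError("baseline_mean_range must satisfy lo <= hi")
        for sig in self.planted_signatures:
            if len(sig.gene_ids) > self.n_genes_per_species:
                raise ConfigurationError(
                    f"signature {sig.name!r} has more genes than the universe"
                )


@dataclass
class TruthRecord:
    """Ground truth behind one synthetic dataset (JSON-serialisable).

    ``group_means`` holds each gene's noiseless log2 group means per species;
    ``homology_pairs`` the 1:1 pairs (gene_a, gene_b, group_id);
    ``signatures`` the resolved per-species membership and effect of every
    planted signature.
    """

    group_means: dict[str, dict[str, dict[str, float]]]
    homology_pairs: list[tuple[str, str, str]]
    probeset_genes: dict[str, dict[str, str]]
    cross_reactive: dict[str, list[str]]
    signatures: dict[str, dict]

    def effect(self, species: str, gene_id: str) -> float:
        """Planted group1-minus-group2 log2 effect for one gene."""
        means = self.group_means[species][gene_id]
        g1, g2 = list(means)
        return means[g1] - means[g2]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        with open(path) as fh:
            raw = json.load(fh)
        raw["homology_pairs"] = [tuple(p) for p in raw["homology_pairs"]]
        return cls(**raw)


@dataclass
class SyntheticDataset:
    expression: dict[str, ExpressionMatrix]       # "A" / "B"
    annotation: dict[str, ProbesetAnnotation]
    labels: dict[str, GroupLabels]
    homology: HomologyTable
    truth: TruthRecord
    config: SimConfig


def _gene_ids(species: str, n: int) -> list[str]:
    base = 100000 if species == "A" else 200000
    return [str(base + i) for i in range(1, n + 1)]


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate one seeded synthetic dataset.

    The draw order is fixed, so an identical config (including seed) yields
    bit-identical output.  The first ``round(frac_homologous * n)`` genes of
    each species form the 1:1 homologous subset (pair *i* links gene *i* of
    each species).  Each gene's first probeset is always clean; additional
    probesets are cross-reactive with probability ``frac_cross_reactive``,
    in which case the stored signal is an equal-weight mixture of the gene's
    own noiseless signal and that of a random contaminant gene, before the
    per-cell Gaussian noise is added.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_genes_per_species
    n_hom = int(round(config.frac_homologous * n))
    genes = {"A": _gene_ids("A", n), "B": _gene_ids("B", n)}
    group_names = {"A": config.group_names_a, "B": config.group_names_b}
    lo, hi = config.baseline_mean_range

    baselines = {
        "A": rng.uniform(lo, hi, size=n),
        "B": rng.uniform(lo, hi, size=n),
    }

    # planted effects: group1-minus-group2 log2 difference per gene
    effects = {"A": np.zeros(n), "B": np.zeros(n)}
    index_of = {sp: {g: i for i, g in enumerate(genes[sp])} for sp in ("A", "B")}
    for sig in config.planted_signatures:
        primary = "B" if sig.species == "B" else "A"
        for gid in sig.gene_ids:
            if gid not in index_of[primary]:
                raise ConfigurationError(
                    f"signature {sig.name!r}: gene {gid!r} not in species-{primary} universe"
                )
            i = index_of[primary][gid]
            effects[primary][i] = sig.log2_effect
            if sig.species == "both":
                if i >= n_hom:
                    raise ConfigurationError(
                        f"signature {sig.name!r}: gene {gid!r} is not homologous, "
                        "cannot plant a two-species effect"
                    )
                effects["B"][i] = sig.log2_effect if sig.concordant else -sig.log2_effect

    group_means = {
        sp: {
            genes[sp][i]: {
                group_names[sp][0]: float(baselines[sp][i] + effects[sp][i] / 2.0),
                group_names[sp][1]: float(baselines[sp][i] - effects[sp][i] / 2.0),
            }
            for i in range(n)
        }
        for sp in ("A", "B")
    }

    expression: dict[str, ExpressionMatrix] = {}
    annotation: dict[str, ProbesetAnnotation] = {}
    labels: dict[str, GroupLabels] = {}
    probeset_genes: dict[str, dict[str, str]] = {"A": {}, "B": {}}
    cross_reactive: dict[str, list[str]] = {"A": [], "B": []}

    for sp in ("A", "B"):
        g1, g2 = group_names[sp]
        reps = config.n_samples_per_group
        sample_ids = [f"{sp}_{g1}_{r + 1}" for r in range(reps)] + [
            f"{sp}_{g2}_{r + 1}" for r in range(reps)
        ]
        sample_group = [g1] * reps + [g2] * reps
        # noiseless per-gene signal per sample
        signal = np.empty((n, 2 * reps))
        for j, grp in enumerate(sample_group):
            col = baselines[sp] + np.where(grp == g1, 0.5, -0.5) * effects[sp]
            signal[:, j] = col

        plo, phi = config.probesets_per_gene
        counts = rng.integers(plo, phi + 1, size=n)
        rows = []
        row_gene_idx = []
        annot_rows = []
        for i, gid in enumerate(genes[sp]):
            for j in range(counts[i]):
                pid = f"{gid}_ps{j + 1}"
                if j == 0:
                    cr = False
                    coding: bool | None = True
                else:
                    cr = bool(rng.random() < config.frac_cross_reactive)
                    coding = [True, False, None][int(rng.integers(0, 3))]
                contaminant = -1
                if cr:
                    contaminant = int(rng.integers(0, n - 1))
                    if contaminant >= i:
                        contaminant += 1  # never self
                    cross_reactive[sp].append(pid)
                rows.append((pid, i, contaminant))
                row_gene_idx.append(i)
                probeset_genes[sp][pid] = gid
                annot_rows.append((pid, gid, f"G{sp}{i + 1}", cr, coding))

        values = np.empty((len(rows), 2 * reps))
        for r, (pid, i, contaminant) in enumerate(rows):
            if contaminant < 0:
                base = signal[i]
            else:
                base = (1 - CROSS_REACTIVE_MIX) * signal[i] + CROSS_REACTIVE_MIX * signal[contaminant]
            values[r] = base
        if config.noise_sd > 0:
            values = values + rng.normal(0.0, config.noise_sd, size=values.shape)

        df = pd.DataFrame(
            values, index=pd.Index([r[0] for r in rows], name="feature_id"), columns=sample_ids
        )
        expression[sp] = ExpressionMatrix(
            values=df, level="probeset", species=config.taxon_a if sp == "A" else config.taxon_b
        )
        annot = pd.DataFrame(
            {
                "gene_id": [a[1] for a in annot_rows],
                "gene_symbol": [a[2] for a in annot_rows],
                "cross_reactive": [a[3] for a in annot_rows],
                "coding": [a[4] for a in annot_rows],
            },
            index=pd.Index([a[0] for a in annot_rows], name="probeset_id"),
        )
        annotation[sp] = ProbesetAnnotation(table=annot)
        labels[sp] = GroupLabels(
            assignments=dict(zip(sample_ids, sample_group)), group_order=[g1, g2]
        )

    pairs = [
        (genes["A"][i], genes["B"][i], str(i + 1)) for i in range(n_hom)
    ]
    hom_rows = []
    for ga, gb, grp in pairs:
        ia, ib = index_of["A"][ga], index_of["B"][gb]
        hom_rows.append((grp, config.taxon_a, ga, f"GA{ia + 1}"))
        hom_rows.append((grp, config.taxon_b, gb, f"GB{ib + 1}"))
    homology = HomologyTable(
        table=pd.DataFrame(
            hom_rows, columns=["group_id", "taxon_id", "gene_id", "gene_symbol"]
        )
    )

    sig_truth: dict[str, dict] = {}
    pair_a_to_b = {ga: gb for ga, gb, _ in pairs}
    for sig in config.planted_signatures:
        members = {"A": [], "B": []}
        if sig.species in ("A", "both"):
            members["A"] = list(sig.gene_ids)
        if sig.species == "B":
            members["B"] = list(sig.gene_ids)
        if sig.species == "both":
            members["B"] = [pair_a_to_b[g] for g in sig.gene_ids]
        sig_truth[sig.name] = {
            "species": sig.species,
            "members": members,
            "log2_effect": sig.log2_effect,
            "concordant": sig.concordant,
        }

    truth = TruthRecord(
        group_means=group_means,
        homology_pairs=pairs,
        probeset_genes=probeset_genes,
        cross_reactive=cross_reactive,
        signatures=sig_truth,
    )
    return SyntheticDataset(
        expression=expression,
        annotation=annotation,
        labels=labels,
        homology=homology,
        truth=truth,
        config=config,
    )


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, str]:
    """Write every table of a synthetic dataset; returns a role -> filename manifest.

    Files are the formats the readers consume: expression and annotation TSVs
    per species, a six-column Homologene-format table, two-column label TSVs
    and the truth record as JSON.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    for sp in ("A", "B"):
        f = f"expression_{sp}.tsv"
        write_expression(dataset.expression[sp], directory / f)
        manifest[f"expression_{sp}"] = f
        f = f"annotation_{sp}.tsv"
        write_probeset_annotation(dataset.annotation[sp], directory / f)
        manifest[f"annotation_{sp}"] = f
        f = f"labels_{sp}.tsv"
        write_class_labels(dataset.labels[sp], directory / f)
        manifest[f"labels_{sp}"] = f
    write_homologene(dataset.homology, directory / "homologene.data")
    manifest["homology"] = "homologene.data"
    dataset.truth.to_json(directory / "truth.json")
    manifest["truth"] = "truth.json"
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
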