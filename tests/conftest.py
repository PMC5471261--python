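import numpy as np
import pandas as pd
import pytest

from orthocomp.io import ExpressionMatrix, GroupLabels, ProbesetAnnotation
from orthocomp.simulate import PlantedSignature, SimConfig, generate_dataset


def gene_ids_a(indices):
    """Species-A synthetic gene ids for 1-based gene indices."""
    return [str(100000 + i) for i in indices]


@pytest.fixture(scope="session")
def zero_noise_dataset():
    """Deterministic two-species dataset, no noise, one planted up-signature.

    20 homologous genes carry a concordant +2 log2 effect (4-fold) in both
    species; everything else is flat.  Multiple probesets per gene, some
    cross-reactive, so the collapse step has real work to do.
    """
    cfg = SimConfig(
        seed=7,
        n_genes_per_species=200,
        frac_homologous=0.8,
        probesets_per_gene=(1, 3),
        frac_cross_reactive=0.3,
        noise_sd=0.0,
        planted_signatures=[
            PlantedSignature("planted_up", "both", gene_ids_a(range(1, 21)), 2.0)
        ],
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def concordance_fixture_dataset():
    """Zero-noise dataset planting the 26-strong-pair quadrant layout:

    10 concordant up, 10 concordant down, 3 discordant each way — so the
    strong-in-both overlap is exactly 26 pairs of which 20 agree in
    direction.
    """
    cfg = SimConfig(
        seed=13,
        n_genes_per_species=200,
        frac_homologous=0.8,
        probesets_per_gene=(1, 1),
        frac_cross_reactive=0.0,
        noise_sd=0.0,
        planted_signatures=[
            PlantedSignature("conc_up", "both", gene_ids_a(range(1, 11)), 2.0, True),
            PlantedSignature("conc_down", "both", gene_ids_a(range(11, 21)), -2.0, True),
            PlantedSignature("disc_up", "both", gene_ids_a(range(21, 24)), 2.0, False),
            PlantedSignature("disc_down", "both", gene_ids_a(range(24, 27)), -2.0, False),
        ],
    )
    return generate_dataset(cfg)


def toy_matrix(values: dict[str, list[float]], groups=("g1", "g1", "g1", "g2", "g2", "g2"),
               level="probeset"):
    """Small matrix + labels from a feature -> per-sample values mapping."""
    samples = [f"s{i + 1}" for i in range(len(groups))]
    df = pd.DataFrame(values, index=samples).T
    matrix = ExpressionMatrix(values=df, level=level)
    labels = GroupLabels(assignments=dict(zip(samples, groups)))
    return matrix, labels


def toy_annotation(rows: dict[str, tuple]):
    """Annotation from probeset -> (gene_id, cross_reactive, coding)."""
    table = pd.DataFrame(
        {
            "gene_id": [r[0] for r in rows.values()],
            "gene_symbol": [f"SYM_{r[0]}" for r in rows.values()],
            "cross_reactive": [r[1] for r in rows.values()],
            "coding": [r[2] for r in rows.values()],
        },
        index=pd.Index(rows.keys(), name="probeset_id"),
    )
    return ProbesetAnnotation(table=table)
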