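"""End-to-end orchestration: simulate/load -> collapse -> pairs -> signatures
-> GSEA -> cross-species concordance, from one structured configuration.

A run is fully determined by its config (including the single top-level
seed): the simulator consumes the seed directly and the GSEA stage uses
``seed + 1`` — the only two consumers of randomness.  Outputs are written
under the run directory together with a JSON manifest and a report of
row counts at every stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as oio
from .collapse import collapse
from .concordance import pair_fold_changes, quadrant_concordance, restricted_spearman
from .gsea import gsea_table, run_gsea
from .homology import build_pairs, translate_signature
from .signatures import (
    fold_changes,
    signatures_to_collection,
    threshold_signature,
)
from .simulate import PlantedSignature, SimConfig, generate_dataset, write_dataset

__all__ = ["RunConfig", "run_all"]

log = logging.getLogger(__name__)

GSEA_SEED_OFFSET = 1


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    Exactly one of ``simulate`` (a :class:`SimConfig`) or ``inputs`` (a dict
    of file paths: expression_A/B, annotation_A/B, labels_A/B, homology)
    must be provided.
    """

    outdir: str
    seed: int = 0
    simulate: SimConfig | None = None
    inputs: dict[str, str] | None = None
    min_fold: float = 2.0
    secondary_min_fold: float = 1.5
    gsea: dict = field(
        default_factory=lambda: {
            "metric": "signal_to_noise",
            "n_perm": 999,
            "weight_p": 1.0,
            "min_size": 5,
        }
    )
    taxon_a: str = "9606"
    taxon_b: str = "10090"

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("provide exactly one of 'simulate' or 'inputs'")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = dict(sim)
            sigs = [
                PlantedSignature(**s) for s in sim.pop("planted_signatures", [])
            ]
            sim.setdefault("seed", raw.get("seed", 0))
            for key in ("probesets_per_gene", "baseline_mean_range",
                        "group_names_a", "group_names_b"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            sim = SimConfig(planted_signatures=sigs, **sim)
        return cls(simulate=sim, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _load_inputs(inputs: dict[str, str], taxon_a: str, taxon_b: str):
    ex = {
        "A": oio.read_expression(inputs["expression_A"], species=taxon_a),
        "B": oio.read_expression(inputs["expression_B"], species=taxon_b),
    }
    ann = {
        "A": oio.read_probeset_annotation(inputs["annotation_A"]),
        "B": oio.read_probeset_annotation(inputs["annotation_B"]),
    }
    lab = {
        "A": oio.read_class_labels(inputs["labels_A"]),
        "B": oio.read_class_labels(inputs["labels_B"]),
    }
    hom = oio.read_homologene(inputs["homology"])
    return ex, ann, lab, hom


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the run report (also written to disk).

    The report carries per-stage row counts, the seeds used and the output
    manifest.  Any stage failure propagates with its stage name attached.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    manifest: dict[str, str] = {}

    stage = "simulate" if config.simulate is not None else "load"
    try:
        if config.simulate is not None:
            ds = generate_dataset(config.simulate)
            data_manifest = write_dataset(ds, outdir / "data")
            manifest.update({k: f"data/{v}" for k, v in data_manifest.items()})
            expression, annotation, labels, homology = (
                ds.expression, ds.annotation, ds.labels, ds.homology,
            )
            taxon_a, taxon_b = config.simulate.taxon_a, config.simulate.taxon_b
            report["stages"][stage] = {
                "n_probesets": {sp: expression[sp].n_features for sp in ("A", "B")},
                "n_samples": {sp: expression[sp].n_samples for sp in ("A", "B")},
            }
        else:
            expression, annotation, labels, homology = _load_inputs(
                config.inputs, config.taxon_a, config.taxon_b
            )
            taxon_a, taxon_b = config.taxon_a, config.taxon_b
            report["stages"][stage] = {
                "n_probesets": {sp: expression[sp].n_features for sp in ("A", "B")},
            }

        stage = "collapse"
        gene_matrix = {}
        for sp in ("A", "B"):
            gm, rec = collapse(expression[sp], annotation[sp], labels[sp])
            gene_matrix[sp] = gm
            path = f"gene_matrix_{sp}.tsv"
            oio.write_expression(gm, outdir / path)
            manifest[f"gene_matrix_{sp}"] = path
            rec.table.to_csv(outdir / f"collapse_report_{sp}.tsv", sep="\t")
            manifest[f"collapse_report_{sp}"] = f"collapse_report_{sp}.tsv"
            report["stages"].setdefault(stage, {})[sp] = {
                "n_genes": gm.n_features,
                "n_unmatched_probesets": rec.n_unmatched,
            }

        stage = "pairs"
        pairs = build_pairs(homology, taxon_a, taxon_b)
        pairs.pairs.to_csv(outdir / "pairs.tsv", sep="\t", index=False)
        pairs.dropped.to_csv(outdir / "pairs_dropped.tsv", sep="\t", index=False)
        manifest["pairs"] = "pairs.tsv"
        manifest["pairs_dropped"] = "pairs_dropped.tsv"
        report["stages"][stage] = {
            "n_pairs": pairs.n_pairs,
            "n_dropped_groups": len(pairs.dropped),
        }

        stage = "fold_changes"
        fc = {sp: fold_changes(gene_matrix[sp], labels[sp]) for sp in ("A", "B")}
        for sp in ("A", "B"):
            fc[sp].table.to_csv(outdir / f"fold_changes_{sp}.tsv", sep="\t")
            manifest[f"fold_changes_{sp}"] = f"fold_changes_{sp}.tsv"

        stage = "signatures"
        sigs_b = [
            threshold_signature(fc["B"], config.min_fold, "up", name="B_up"),
            threshold_signature(fc["B"], config.min_fold, "down", name="B_down"),
        ]
        translated = [translate_signature(s, pairs, taxon_a) for s in sigs_b]
        collection = signatures_to_collection(translated)
        oio.write_gmt(collection, outdir / "signatures.gmt")
        manifest["signatures"] = "signatures.gmt"
        provenance = {
            s.name: {"rule": s.rule, "species": s.species, "size": len(s), **s.params}
            for s in translated
        }
        with open(outdir / "signatures.json", "w") as fh:
            json.dump(provenance, fh, indent=1)
        manifest["signatures_provenance"] = "signatures.json"
        report["stages"][stage] = {s.name: len(s) for s in translated}

        stage = "gsea"
        gsea_seed = config.seed + GSEA_SEED_OFFSET
        if len(collection.sets) == 0:
            log.warning("run_all: all signatures empty, skipping GSEA")
            results = []
        else:
            results = run_gsea(
                gene_matrix["A"],
                labels["A"],
                collection,
                n_perm=int(config.gsea.get("n_perm", 999)),
                seed=gsea_seed,
                metric=config.gsea.get("metric", "signal_to_noise"),
                weight_p=float(config.gsea.get("weight_p", 1.0)),
                min_size=int(config.gsea.get("min_size", 5)),
            )
        table = gsea_table(results)
        table.to_csv(outdir / "gsea_results.tsv", sep="\t")
        manifest["gsea_results"] = "gsea_results.tsv"
        for r in results:
            prof = outdir / f"gsea_running_sum_{r.set_name}.tsv"
            np.savetxt(prof, r.running_sum, fmt="%.10g")
            manifest[f"gsea_running_sum_{r.set_name}"] = prof.name
        report["stages"][stage] = {
            "seed": gsea_seed,
            "results": {
                r.set_name: {"es": r.es, "nes": r.nes, "nominal_p": r.nominal_p}
                for r in results
            },
        }

        stage = "concordance"
        paired = pair_fold_changes(fc["A"], fc["B"], pairs)
        quad = quadrant_concordance(paired, config.min_fold)
        try:
            corr = restricted_spearman(paired, "B", config.min_fold)
            corr_block = dataclasses.asdict(corr)
        except ValueError as exc:
            corr_block = {"error": str(exc)}
        conc = {
            "n_paired": len(paired),
            "n_dropped": paired.n_dropped,
            "quadrant_counts": quad.counts,
            "n_overlap": quad.n_overlap,
            "concordant_fraction": quad.concordant_fraction,
            "fisher_p": quad.fisher_p,
            "odds_ratio": quad.odds_ratio,
            "min_fold": quad.min_fold,
            "restricted_spearman": corr_block,
        }
        with open(outdir / "concordance.json", "w") as fh:
            json.dump(conc, fh, indent=1)
        manifest["concordance"] = "concordance.json"
        report["stages"][stage] = conc
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report["manifest"] = manifest
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)
    return report
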