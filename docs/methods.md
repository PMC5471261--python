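# Methods

This note documents the models, conventions and design choices behind
`orthocomp`, in the order data flows through the pipeline.

## Scope and assumptions

The pipeline consumes **post-normalisation log2 intensity matrices**
(RMA-style); raw CEL parsing and RMA itself are out of scope. Every
differential operation assumes exactly two phenotype groups per species
(e.g. two sorted cell subsets), with ≥ 2 replicates per group for
variance-based ranking (a single-replicate group is allowed for plain
log2 fold-changes, with a warning). Gene identifiers are treated as
opaque strings; cross-species joins always go through gene **IDs** via the
homology table, never through symbols, because symbol aliasing across
species is ambiguous.

## Synthetic data generator

The generator emulates the study design the pipeline targets:

- two species (default taxa 9606 and 10090), two subsets per species,
  **3 samples per subset** (the designs this pipeline serves use three
  individuals per subset);
- per-gene baseline log2 intensity uniform on **[6, 12]** — the central
  range of typical RMA output;
- independent Gaussian noise on the log2 scale per cell (default
  `noise_sd = 0.5`, a mid-range value for between-replicate variability of
  sorted-cell microarray data); Gaussian-on-log2 is the standard
  assumption for RMA intensities;
- 1–3 probesets per gene; each gene's first probeset is always clean,
  additional probesets are cross-reactive with probability
  `frac_cross_reactive` (default 0.2). A cross-reactive probeset's signal
  is an **equal-weight (0.5/0.5) mixture** of its own gene's noiseless
  signal and that of one random contaminant gene, before noise — this
  distorts fold-changes through such probesets and makes the collapse
  priority rule consequential;
- a partial 1:1 homology map (default 80% of genes) emitted in the real
  six-column Homologene flat-file layout, so the same reader serves
  synthetic and real data;
- planted signatures: gene sets with a specified log2 effect, applied
  symmetrically around the baseline (±effect/2 per group). For
  two-species signatures the effect is mirrored onto the homolog with the
  same or opposite sign (`concordant`).

The draw order is fixed, so one seed yields bit-identical datasets. At
`noise_sd = 0` every downstream fold-change equals its planted effect
exactly, which the tests use as ground truth. What the generator does
**not** emulate: batch effects, intensity-dependent variance, spatial
array artifacts, probe-level effects, correlated genes. Passing tests
therefore demonstrate correctness of the computations under an idealised
noise model, not robustness to real-array pathologies.

## Probeset collapse

One representative probeset per gene ("pick one row", never averaging),
selected lexicographically:

1. not cross-reactive beats cross-reactive;
2. coding beats non-coding;
3. larger |log2 fold-change| between the two groups (the same two groups
   later used in differential analysis);
4. lexicographically smallest probeset id.

Annotation flags are three-valued. An *unknown* value must not
discriminate; since a literal "ties with everything" is non-transitive,
unknown is grouped with the non-penalised side (unknown cross-reactivity
counts as clean, unknown coding status as coding). The effect is that a
criterion decides only where the annotation actually carries information,
and fully unannotated candidates fall through to the fold-change rule.
Rule 4 is a pure determinism tie-break — our convention. The collapse
report records, per gene, the number of candidates and which rule decided.

## Homology pairing

A Homologene group yields a pair iff it contains **exactly one** gene from
each of the two requested taxa (strict 1:1). Groups missing a taxon or
containing within-species paralogs are dropped and logged by reason, so
any divergence between an expected and an observed pair count is
diagnosable from the drop log. A gene enters at most one pair (later
groups re-using a gene are dropped). Manual override pairs — the
hand-curated kind that pairs genes the database does not match — are
carried with a `manual` flag and excluded from the default pair count.
Signature translation maps members through the pairs, silently dropping
(but counting) members without a partner.

## Fold-changes and signatures

`Δ = mean(log2 group1) − mean(log2 group2)` — the arithmetic mean of log2
values, i.e. the log of the geometric-mean intensity ratio, the standard
quantity for RMA data. The signed linear fold `sign(Δ)·2^|Δ|` has
magnitude ≥ 1 by construction. **All fold thresholds are inclusive (≥)**,
for internal consistency, with an optional strictly-greater switch on the
restricted Spearman; a 1.5-fold analysis is the same code path with
`min_fold = 1.5`. Threshold signatures additionally require a strictly
nonzero Δ in the stated direction so that `min_fold = 1` means "any
change in that direction". No multiple-testing control is applied to
fold-change screens (they are descriptive selections, not tests).

## GSEA

- **Ranking metric**: signal-to-noise `(μ₁−μ₂)/(σ₁'+σ₂')` with
  `σ' = max(σ, 0.2·|μ|)`, and `σ' = 0.2` when that floor is itself zero —
  the convention of the reference implementation for categorical
  phenotypes. Sample standard deviations (n−1). Ties in the ranking break
  by gene id ascending, for determinism. A `log2_fc` metric is provided
  for single-replicate groups.
- **Enrichment score**: weighted running sum (weight `p = 1` default);
  hits add `|s|^p / Σ_hits|s|^p`, misses subtract `1/(N−N_hits)`; ES is
  the value at the first position of maximal |deviation|. If all hit
  metrics are exactly zero the hit increments fall back to equal weights
  `1/N_hits` (the weighted numerator is otherwise 0/0). The leading edge
  is the hit genes at or before the extremum (strictly after it for
  negative ES). A set spanning the whole universe, or with no member in
  the universe, is an error.
- **Null model**: random same-size gene sets drawn uniformly without
  replacement — *gene-set permutation*, chosen because three samples per
  phenotype cannot support phenotype permutation. p and NES are computed
  against null scores of the observed sign only, with an add-one
  correction keeping p > 0. If no null score shares the sign, p = 1 and
  NES is NaN (flagged, not hidden).
- `run_gsea` hands the same seed to every per-set test (shared-null-pool
  semantics), so a one-set collection is bit-identical to a direct
  `permutation_test` call. Sets with fewer than `min_size` (default 5)
  members in the universe are skipped and logged. Across-set FDR q-values
  are deliberately not implemented; the pipeline reports nominal p only.

## Concordance statistics

- **Quadrant analysis**: pairs with |linear fold| ≥ threshold in *both*
  species (zero deltas always excluded), classified by sign pair. The 2×2
  Fisher table is (species-A direction) × (species-B direction).
- **Fisher's exact test**: the full hypergeometric support is enumerated
  at the observed margins; the two-sided p sums the probabilities of all
  tables whose point probability is ≤ the observed one, with a 1e−7
  relative tolerance for floating-point ties. The sample odds ratio
  `ad/bc` is reported (∞ for a zero denominator with nonzero numerator,
  NaN for 0/0). The implementation is checked against an exact-Fraction
  enumeration oracle for every table with margins ≤ 12 and against
  `scipy.stats.fisher_exact` as an independent cross-check.
- **Restricted Spearman**: ρ via average ranks + Pearson, restricted to
  pairs strong in *one* designated species (the comparative screens this
  serves condition on the mouse side). The p-value is the exact
  permutation tail for n ≤ 10 (all n! pairings enumerated) and the
  t approximation `t = ρ√((n−2)/(1−ρ²))`, df = n−2, otherwise. Note that
  rank statistics are discontinuous under massive ties: on degenerate
  inputs where many deltas are numerically identical up to float error,
  ρ is ill-conditioned; the quadrant statistics are the robust summary
  there.

## Pipeline and seeding

`run_all` composes the stages from one config; all randomness flows from
the single top-level seed — the simulator consumes it directly and the
GSEA stage uses `seed + 1`; no other stage is stochastic. Every output is
written under the run directory with a JSON manifest and per-stage row
counts, and a rerun with the same config is bit-identical.

## Problem sizes

The test suite and the acceptance script run the statistical studies at
1000 genes per species, 3 vs 3 samples, 999 (calibration) or 499 (power)
permutations, 400–1000 random sets for calibration and 100 replicate
datasets for power — sizes chosen so the full studies complete in minutes
on a single CPU while keeping Monte-Carlo error well inside the asserted
intervals.

## Known limitations

- Phenotype-permutation GSEA is intentionally absent.
- The Homologene 1:1 policy discards paralog-containing groups wholesale;
  a real analysis wishing to rescue those needs manual overrides.
- The generator's idealised noise model (see above).
- Exact Spearman enumeration above n = 8 is slow (n! permutations); the
  default exact cutoff is n ≤ 10.
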