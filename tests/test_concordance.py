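import numpy as np
import pandas as pd
import pytest
from scipy import stats

from orthocomp.collapse import collapse
from orthocomp.concordance import (
    PairedFC,
    fisher_exact_2x2,
    pair_fold_changes,
    quadrant_concordance,
    restricted_spearman,
    spearman_rho_p,
)
from orthocomp.homology import HomologPairSet, build_pairs
from orthocomp.signatures import fold_changes

from _oracles import fisher_enumeration, spearman_rank_pearson


def make_pairs(names):
    return HomologPairSet(
        taxon_a="A",
        taxon_b="B",
        pairs=pd.DataFrame(
            {
                "gene_a": [f"h{n}" for n in names],
                "gene_b": [f"m{n}" for n in names],
                "group_id": [str(n) for n in names],
                "manual": False,
            }
        ),
    )


def paired_from_deltas(da, db):
    n = len(da)
    return PairedFC(
        table=pd.DataFrame(
            {
                "gene_a": [f"h{i}" for i in range(n)],
                "gene_b": [f"m{i}" for i in range(n)],
                "delta_a": np.asarray(da, dtype=float),
                "delta_b": np.asarray(db, dtype=float),
            }
        ),
        n_universe=n,
        n_dropped=0,
    )


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((3, 1, 1, 3), 34 / 70),
            ((5, 0, 0, 5), 2 / 252),
            ((2, 2, 2, 2), 1.0),
        ],
    )
    def test_frozen_enumeration_values(self, table, expected):
        p, _ = fisher_exact_2x2(*table)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_against_fraction_oracle_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 13, size=4)
            if a + b + c + d == 0:
                continue
            p, _ = fisher_exact_2x2(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(fisher_enumeration(a, b, c, d), abs=1e-10)

    def test_against_scipy_cross_check(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(0, 15, size=4))
            if a + b + c + d == 0:
                continue
            p, _ = fisher_exact_2x2(a, b, c, d)
            assert p == pytest.approx(
                stats.fisher_exact([[a, b], [c, d]])[1], rel=1e-9, abs=1e-12
            )

    def test_odds_ratio_conventions(self):
        _, odds = fisher_exact_2x2(3, 1, 1, 3)
        assert odds == 9.0
        assert fisher_exact_2x2(2, 0, 1, 3)[1] == np.inf
        assert fisher_exact_2x2(0, 2, 1, 0)[1] == 0.0
        assert np.isnan(fisher_exact_2x2(0, 1, 0, 1)[1])

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            fisher_exact_2x2(0, 0, 0, 0)

    def test_negative_or_float_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            fisher_exact_2x2(1.5, 2, 3, 4)


class TestPairFoldChanges:
    def fc(self, deltas, prefix):
        idx = [f"{prefix}{i}" for i in range(len(deltas))]
        d = pd.Series(deltas, index=idx, dtype=float)
        from orthocomp.signatures import FoldChangeTable

        table = pd.DataFrame(
            {
                "mean_log2_group1": 8 + d / 2,
                "mean_log2_group2": 8 - d / 2,
                "delta_log2": d,
                "linear_fold": np.where(d >= 0, 2.0**d, -(2.0 ** (-d))),
            }
        )
        return FoldChangeTable(table=table, group1="g1", group2="g2")

    def test_all_pairs_present(self):
        paired = pair_fold_changes(
            self.fc([1, 2, 3], "h"), self.fc([1, 2, 3], "m"), make_pairs([0, 1, 2])
        )
        assert len(paired) == 3 and paired.n_dropped == 0

    def test_missing_gene_dropped_with_count(self):
        paired = pair_fold_changes(
            self.fc([1, 2, 3], "h"), self.fc([1, 2], "m"), make_pairs([0, 1, 2])
        )
        assert len(paired) == 2 and paired.n_dropped == 1

    def test_empty_intersection_is_error(self):
        with pytest.raises(ValueError, match="no homolog pair"):
            pair_fold_changes(
                self.fc([1], "x"), self.fc([1], "y"), make_pairs([0])
            )

    def test_synthetic_truth_pairs_all_measured(self, concordance_fixture_dataset):
        ds = concordance_fixture_dataset
        pairs = build_pairs(ds.homology, "9606", "10090")
        fc = {}
        for sp in ("A", "B"):
            gm, _ = collapse(ds.expression[sp], ds.annotation[sp], ds.labels[sp])
            fc[sp] = fold_changes(gm, ds.labels[sp])
        paired = pair_fold_changes(fc["A"], fc["B"], pairs)
        assert len(paired) == len(ds.truth.homology_pairs) == 160
        assert paired.n_dropped == 0


class TestQuadrantConcordance:
    def test_all_same_sign_fraction_one(self):
        paired = paired_from_deltas([2, 3, -2], [1.5, 2.5, -3])
        res = quadrant_concordance(paired, 2.0)
        assert res.concordant_fraction == 1.0
        assert res.n_overlap == 3

    def test_planted_twenty_of_twenty_six(self, concordance_fixture_dataset):
        """Zero-noise planted fixture: 26 strong pairs, 20 concordant."""
        ds = concordance_fixture_dataset
        pairs = build_pairs(ds.homology, "9606", "10090")
        fc = {}
        for sp in ("A", "B"):
            gm, _ = collapse(ds.expression[sp], ds.annotation[sp], ds.labels[sp])
            fc[sp] = fold_changes(gm, ds.labels[sp])
        paired = pair_fold_changes(fc["A"], fc["B"], pairs)
        res = quadrant_concordance(paired, 2.0)
        assert res.n_overlap == 26
        assert res.concordant_fraction == pytest.approx(20 / 26)
        assert res.counts == {"up_up": 10, "up_down": 3, "down_up": 3, "down_down": 10}
        assert res.fisher_p == pytest.approx(
            fisher_enumeration(10, 3, 3, 10), abs=1e-12
        )

    def test_counts_sum_to_overlap(self):
        rng = np.random.default_rng(2)
        paired = paired_from_deltas(rng.normal(0, 2, 50), rng.normal(0, 2, 50))
        res = quadrant_concordance(paired, 1.5)
        assert sum(res.counts.values()) == res.n_overlap

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        paired = paired_from_deltas(rng.normal(0, 2, 200), rng.normal(0, 2, 200))
        overlaps = [
            quadrant_concordance(paired, f).n_overlap for f in (1.0, 1.5, 2.0, 3.0, 4.0)
        ]
        assert overlaps == sorted(overlaps, reverse=True)

    def test_empty_after_restriction_flagged(self):
        paired = paired_from_deltas([0.1, -0.2], [0.1, 0.3])
        res = quadrant_concordance(paired, 4.0)
        assert res.n_overlap == 0 and res.fisher_p is None
        assert np.isnan(res.concordant_fraction)


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman_rho_p([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_rho_p([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_eight_pairs_with_tie_matches_rank_pearson_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
        y = [2.1, 1.0, 3.3, 2.9, 5.0, 4.1, 6.6, 6.0]
        rho, _ = spearman_rho_p(x, y)
        assert rho == pytest.approx(spearman_rank_pearson(x, y), abs=1e-12)

    def test_matches_scipy_rho_and_large_n_p(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        rho, p = spearman_rho_p(x, y)
        s_rho, s_p = stats.spearmanr(x, y)
        assert rho == pytest.approx(s_rho, abs=1e-12)
        assert p == pytest.approx(s_p, rel=1e-9)

    def test_exact_small_n_p_is_permutation_fraction(self):
        x = [1, 2, 3, 4, 5, 6]
        y = [1, 2, 3, 4, 6, 5]
        rho, p = spearman_rho_p(x, y)
        # brute force over all 720 pairings
        import itertools

        from _oracles import spearman_rank_pearson as oracle

        rhos = [
            oracle(x, [y[i] for i in perm])
            for perm in itertools.permutations(range(6))
        ]
        exact = sum(1 for r in rhos if abs(r) >= abs(rho) - 1e-12) / len(rhos)
        assert p == pytest.approx(exact, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        rho1, _ = spearman_rho_p(x, y)
        rho2, _ = spearman_rho_p(np.exp(x), y**3)
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_restriction_is_one_sided(self):
        paired = paired_from_deltas(
            [0.1, 0.2, 3.0, -2.0, 1.5, 0.05], [2.0, -2.5, 0.8, -1.4, 3.0, 2.2]
        )
        res = restricted_spearman(paired, restrict_species="B", min_fold=2.0)
        # five pairs have |delta_b| >= log2(2) = 1; the species-A side is free
        assert res.n == 5
        assert "fold_B" in res.restriction

    def test_too_few_pairs_after_restriction(self):
        paired = paired_from_deltas([3.0, 2.0], [3.0, 2.0])
        with pytest.raises(ValueError, match="n="):
            restricted_spearman(paired, "B", 2.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho_p([1, 1, 1, 1], [1, 2, 3, 4])
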