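import itertools

import numpy as np
import pandas as pd
import pytest

from orthocomp.gsea import (
    RankedList,
    enrichment_score,
    gsea_table,
    permutation_test,
    rank_genes,
    run_gsea,
)
from orthocomp.io import ExpressionMatrix, GeneSetCollection, GroupLabels

from _oracles import brute_force_es, ks_statistic
from conftest import toy_matrix


def ranked(metrics, genes=None):
    genes = genes or [f"g{i + 1}" for i in range(len(metrics))]
    return RankedList(
        genes=np.asarray(genes),
        metric=np.asarray(metrics, dtype=float),
        metric_name="log2_fc",
        groups=("p", "q"),
    )


DECADE = ranked([5, 4, 3, 2, 1, -1, -2, -3, -4, -5])


class TestRankGenes:
    def test_signal_to_noise_with_variance_floor(self):
        """Zero-variance groups {4,4,4} vs {2,2,2}: denominator 0.2*4 + 0.2*2."""
        matrix, labels = toy_matrix({"g": [4.0, 4.0, 4.0, 2.0, 2.0, 2.0]})
        rl = rank_genes(matrix, labels)
        assert rl.metric[0] == pytest.approx(2.0 / 1.2, abs=1e-12)

    def test_identical_groups_rank_in_gene_id_order(self):
        matrix, labels = toy_matrix(
            {"b": [5.0] * 6, "a": [3.0] * 6, "c": [4.0] * 6}
        )
        rl = rank_genes(matrix, labels)
        assert np.allclose(rl.metric, 0.0)
        assert rl.genes.tolist() == ["a", "b", "c"]

    def test_swapping_groups_negates_metric(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            rng.normal(8, 1, (20, 6)),
            index=[f"g{i:02d}" for i in range(20)],
            columns=[f"s{i}" for i in range(6)],
        )
        m = ExpressionMatrix(values=df, level="gene")
        fwd = GroupLabels({f"s{i}": ("p" if i < 3 else "q") for i in range(6)})
        rev = GroupLabels(
            {f"s{i}": ("p" if i < 3 else "q") for i in range(6)}, group_order=["q", "p"]
        )
        rf, rr = rank_genes(m, fwd), rank_genes(m, rev)
        mf = pd.Series(rf.metric, index=rf.genes)
        mr = pd.Series(rr.metric, index=rr.genes)
        assert np.allclose(mf.sort_index(), -mr.sort_index(), atol=1e-12)

    def test_single_sample_group_directs_to_log2fc(self):
        matrix, labels = toy_matrix({"g": [4.0, 2.0]}, groups=("p", "q"))
        with pytest.raises(ValueError, match="log2_fc"):
            rank_genes(matrix, labels)
        rl = rank_genes(matrix, labels, metric="log2_fc")
        assert rl.metric[0] == 2.0

    def test_zero_mean_zero_sd_uses_absolute_floor(self):
        matrix, labels = toy_matrix({"g": [0.0, 0.0, 0.0, 1.2, 1.2, 1.2]})
        rl = rank_genes(matrix, labels)
        # denominator 0.2 (mu=0, sd=0) + 0.24
        assert rl.metric[0] == pytest.approx(-1.2 / 0.44, abs=1e-12)


class TestEnrichmentScore:
    def test_single_top_gene_scores_one(self):
        es, _, leading = enrichment_score(DECADE, ["g1"])
        assert es == pytest.approx(1.0)
        assert leading == ["g1"]

    def test_single_bottom_gene_scores_minus_one(self):
        es, running, leading = enrichment_score(DECADE, ["g10"])
        assert es == pytest.approx(-1.0)
        assert leading == ["g10"]
        assert running[-1] == pytest.approx(0.0, abs=1e-12)

    def test_frozen_two_hit_example(self):
        """Metrics (5..1,-1..-5), set {g1,g3}: peak 5/8 - 1/8 + 3/8 = 0.875."""
        es, running, leading = enrichment_score(DECADE, ["g1", "g3"])
        assert es == pytest.approx(0.875, abs=1e-12)
        assert leading == ["g1", "g3"]
        oracle_es, oracle_running = brute_force_es(
            DECADE.genes, DECADE.metric, ["g1", "g3"]
        )
        assert es == pytest.approx(oracle_es, abs=1e-12)
        assert np.allclose(running, oracle_running, atol=1e-12)

    def test_absent_members_dropped_before_scoring(self):
        es1, _, _ = enrichment_score(DECADE, ["g1", "g3"])
        es2, _, _ = enrichment_score(DECADE, ["g1", "g3", "missing"])
        assert es1 == es2

    def test_all_members_absent_is_an_error(self):
        with pytest.raises(ValueError, match="no set member"):
            enrichment_score(DECADE, ["nope"])

    def test_whole_universe_set_is_an_error(self):
        with pytest.raises(ValueError, match="whole universe"):
            enrichment_score(DECADE, DECADE.genes.tolist())

    def test_es_bounded_and_profile_closes_at_zero(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            n = int(rng.integers(4, 30))
            rl = ranked(rng.normal(size=n))
            k = int(rng.integers(1, n))
            members = rng.choice(rl.genes, size=k, replace=False)
            es, running, _ = enrichment_score(rl, members)
            assert abs(es) <= 1.0 + 1e-12
            assert np.all(np.abs(running) <= 1.0 + 1e-12)
            assert running[-1] == pytest.approx(0.0, abs=1e-9)

    def test_unweighted_es_equals_ks_statistic(self):
        rng = np.random.default_rng(5)
        rl = ranked(np.sort(rng.normal(size=12))[::-1])
        for k in (1, 2, 3):
            for members in itertools.combinations(rl.genes.tolist(), k):
                es, _, _ = enrichment_score(rl, members, weight_p=0.0)
                # the magnitude is the KS statistic; the sign can flip only on
                # an exact +-tie of the extremum
                assert abs(es) == pytest.approx(
                    abs(ks_statistic(rl.genes, members)), abs=1e-12
                )

    def test_all_zero_metrics_fall_back_to_equal_weights(self):
        rl = ranked([0.0] * 6)
        es, _, _ = enrichment_score(rl, ["g1", "g2"])
        assert es == pytest.approx(1.0)


class TestPermutationTest:
    def test_seeded_determinism(self):
        r1 = permutation_test(DECADE, ["g1", "g3"], n_perm=200, seed=5)
        r2 = permutation_test(DECADE, ["g1", "g3"], n_perm=200, seed=5)
        assert r1.nominal_p == r2.nominal_p and r1.nes == r2.nes
        r3 = permutation_test(DECADE, ["g1", "g3"], n_perm=200, seed=6)
        assert (r1.nominal_p, r1.nes) != (r3.nominal_p, r3.nes)

    def test_p_in_unit_interval_and_leading_edge_subset(self):
        r = permutation_test(DECADE, ["g2", "g5"], n_perm=100, seed=0)
        assert 0.0 < r.nominal_p <= 1.0
        assert set(r.leading_edge) <= {"g2", "g5"}

    def test_converges_to_exact_enumeration(self):
        """Permutation p approaches the all-subsets enumeration value."""
        rng = np.random.default_rng(8)
        rl = ranked(np.sort(rng.normal(size=8))[::-1])
        members = ["g2", "g3"]
        es_obs, _, _ = enrichment_score(rl, members)
        null = [
            enrichment_score(rl, list(c))[0]
            for c in itertools.combinations(rl.genes.tolist(), 2)
        ]
        same = [e for e in null if e * np.sign(es_obs) > 0]
        exact = sum(1 for e in same if abs(e) >= abs(es_obs)) / len(same)
        r = permutation_test(rl, members, n_perm=20000, seed=1)
        assert r.nominal_p == pytest.approx(exact, abs=0.02)


class TestRunGsea:
    def make_inputs(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.normal(8, 0.5, (n, 6)),
            index=[f"g{i:03d}" for i in range(n)],
            columns=[f"s{i}" for i in range(6)],
        )
        planted = [f"g{i:03d}" for i in range(10)]
        df.loc[planted, ["s0", "s1", "s2"]] += 2.0
        m = ExpressionMatrix(values=df, level="gene")
        labels = GroupLabels({f"s{i}": ("p" if i < 3 else "q") for i in range(6)})
        return m, labels, planted

    def test_single_set_collection_matches_direct_call(self):
        m, labels, planted = self.make_inputs()
        coll = GeneSetCollection(sets={"planted": planted})
        res = run_gsea(m, labels, coll, n_perm=300, seed=9)
        direct = permutation_test(
            rank_genes(m, labels), planted, n_perm=300, seed=9, set_name="planted"
        )
        assert res[0].nominal_p == direct.nominal_p
        assert res[0].nes == direct.nes

    def test_planted_set_outranks_random_set(self):
        m, labels, planted = self.make_inputs(seed=2)
        rng = np.random.default_rng(3)
        random_set = rng.choice(m.feature_ids, 10, replace=False).tolist()
        coll = GeneSetCollection(sets={"planted": planted, "random": random_set})
        res = run_gsea(m, labels, coll, n_perm=300, seed=4)
        assert res[0].set_name == "planted"
        assert abs(res[0].nes) >= abs(res[1].nes)

    def test_small_sets_skipped(self):
        m, labels, planted = self.make_inputs()
        coll = GeneSetCollection(sets={"tiny": planted[:2], "ok": planted})
        res = run_gsea(m, labels, coll, n_perm=50, seed=0, min_size=5)
        assert [r.set_name for r in res] == ["ok"]

    def test_summary_table_columns(self):
        m, labels, planted = self.make_inputs()
        res = run_gsea(
            m, labels, GeneSetCollection(sets={"planted": planted}), n_perm=50, seed=0
        )
        tab = gsea_table(res)
        assert list(tab.columns) == [
            "set_size", "es", "nes", "nominal_p", "n_perm", "leading_edge_size",
        ]
        assert tab.loc["planted", "set_size"] == 10
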