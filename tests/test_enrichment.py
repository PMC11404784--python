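"""Enrichment statistics against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathkit import enrichment as enr
from pathkit.errors import ValidationError
from pathkit.io import DEGTable, GeneSet, GeneSetDatabase

from .oracles import (
    bh_adjust_naive,
    gsea_running_sum,
    hypergeom_upper_tail_enum,
    hypergeom_upper_tail_sum,
)

FC_15 = math.log2(1.5)


class TestSelectDegs:
    def test_six_gene_toy_splits_as_hand_checked(self, six_gene_table):
        up, down = enr.select_degs(six_gene_table, 0.05, FC_15)
        assert up == {"g1", "g6"}
        assert down == {"g2", "g5"}

    def test_boundary_gene_included_at_exact_fc_cutoff(self):
        df = pd.DataFrame({
            "gene_id": ["g"], "log2_fc": [FC_15],
            "p_value": [0.01], "p_adjusted": [0.01],
        })
        up, down = enr.select_degs(DEGTable("t", df), 0.05, FC_15)
        assert up == {"g"} and down == set()

    def test_zero_fold_change_in_neither_direction(self):
        df = pd.DataFrame({
            "gene_id": ["g"], "log2_fc": [0.0],
            "p_value": [0.001], "p_adjusted": [0.001],
        })
        up, down = enr.select_degs(DEGTable("t", df), 0.05, FC_15)
        assert up == set() and down == set()

    def test_missing_adjusted_p_fails_loudly(self):
        df = pd.DataFrame({
            "gene_id": ["g"], "log2_fc": [1.0],
            "p_value": [0.001], "p_adjusted": [np.nan],
        })
        with pytest.raises(ValidationError, match="adjusted"):
            enr.select_degs(DEGTable("t", df), 0.05, FC_15)


class TestOraHypergeometric:
    @pytest.mark.parametrize(
        "N,K,n,k,expected",
        [
            (10, 5, 5, 5, 1 / 252),          # all marked drawn
            (20, 5, 5, 2, 0.366099),          # brute-force tail sum
            (10, 4, 3, 0, 1.0),               # P(X >= 0) = 1
        ],
    )
    def test_frozen_examples(self, N, K, n, k, expected):
        universe = [f"u{i}" for i in range(N)]
        gene_set = universe[:K]
        # query: k hits then n-k non-members
        query = gene_set[:k] + universe[K:K + n - k]
        res = enr.ora_hypergeometric(query, gene_set, universe)
        assert res.k == k and res.K == K and res.n == n and res.N == N
        assert res.p_value == pytest.approx(expected, abs=5e-7)

    def test_matches_exhaustive_enumeration_small_universes(self):
        for N in range(2, 9):
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        universe = [f"u{i}" for i in range(N)]
                        query = universe[:k] + universe[K:K + n - k]
                        res = enr.ora_hypergeometric(query, universe[:K], universe)
                        want = hypergeom_upper_tail_enum(N, K, n, k)
                        assert abs(res.p_value - want) < 1e-12

    def test_empty_query_after_universe_intersection_is_error(self):
        with pytest.raises(ValidationError):
            enr.ora_hypergeometric(["q"], ["a"], ["a", "b"])

    def test_enrichment_ratio_definition(self):
        res = enr.ora_hypergeometric(["a", "b"], ["a", "c"], list("abcd"))
        assert res.enrichment_ratio == pytest.approx((1 / 2) / (2 / 4))


class TestGenePairSignatures:
    def test_shared_gene_alone_shares_no_pair(self, toy_pair_db):
        idx = enr.build_gene_pair_signatures(toy_pair_db, 1, 100)
        assert idx.n_pairs == 6
        assert idx.pairs[frozenset("ab")] == "P1"
        assert idx.pairs[frozenset("de")] == "P2"
        assert idx.set_pair_counts == {"P1": 3, "P2": 3}

    def test_pair_in_two_sets_is_excluded(self):
        db = GeneSetDatabase([
            GeneSet("P1", "one", frozenset("abc")),
            GeneSet("P2", "two", frozenset("abd")),
        ])
        idx = enr.build_gene_pair_signatures(db, 1, 100)
        assert frozenset("ab") not in idx.pairs
        assert idx.pairs[frozenset("ac")] == "P1"
        assert idx.pairs[frozenset("bd")] == "P2"
        assert idx.n_pairs == 4

    def test_singleton_set_contributes_no_pairs(self):
        db = GeneSetDatabase([
            GeneSet("P1", "one", frozenset("a")),
            GeneSet("P2", "two", frozenset("xyz")),
        ])
        idx = enr.build_gene_pair_signatures(db, 1, 100)
        assert idx.set_pair_counts["P1"] == 0

    def test_no_retained_sets_is_error(self, toy_pair_db):
        with pytest.raises(ValidationError):
            enr.build_gene_pair_signatures(toy_pair_db, 10, 500)

    def test_pair_counts_sum_to_total(self, toy_pair_db):
        idx = enr.build_gene_pair_signatures(toy_pair_db, 1, 100)
        assert sum(idx.set_pair_counts.values()) == idx.n_pairs


class TestOraGenePairs:
    def test_toy_p_one_twentieth_vs_enumeration(self, toy_pair_db):
        """Query {a,b,c} hits all 3 of P1's pairs out of 6; p = 1/C(6,3)."""
        idx = enr.build_gene_pair_signatures(toy_pair_db, 1, 100)
        df = enr.ora_gene_pairs(["a", "b", "c"], idx)
        row = df[df.set_id == "P1"].iloc[0]
        assert (row.k, row.K, row.n, row.N) == (3, 3, 3, 6)
        assert row.p_value == pytest.approx(1 / 20, abs=1e-12)
        # independent check: enumerate all C(6,3) draws of 3 pairs
        assert row.p_value == pytest.approx(
            hypergeom_upper_tail_enum(6, 3, 3, 3), abs=1e-12
        )

    def test_query_with_no_indexed_pairs_is_empty(self, toy_pair_db):
        idx = enr.build_gene_pair_signatures(toy_pair_db, 1, 100)
        with pytest.warns(UserWarning):
            df = enr.ora_gene_pairs(["a", "d"], idx)
        assert df.empty

    def test_single_gene_query_is_empty(self, toy_pair_db):
        idx = enr.build_gene_pair_signatures(toy_pair_db, 1, 100)
        with pytest.warns(UserWarning):
            assert enr.ora_gene_pairs(["a"], idx).empty


class TestGsea:
    def test_top_pair_scores_plus_one(self):
        ranked = enr.RankedGeneList.from_pairs(
            [(f"g{i}", 5.0 - i) for i in range(1, 6)]
        )
        res = enr.gsea(ranked, {"g1", "g2"}, weight=0, n_perm=10, seed=1)
        assert res.es == pytest.approx(1.0)
        assert res.leading_edge == ("g1", "g2")

    def test_bottom_singleton_scores_minus_one(self):
        ranked = enr.RankedGeneList.from_pairs(
            [(f"g{i}", 5.0 - i) for i in range(1, 6)]
        )
        res = enr.gsea(ranked, {"g5"}, weight=0, n_perm=10, seed=1)
        assert res.es == pytest.approx(-1.0)
        assert res.leading_edge == ("g5",)

    def test_set_equal_to_universe_rejected(self):
        ranked = enr.RankedGeneList.from_pairs([("a", 2.0), ("b", 1.0)])
        with pytest.raises(ValidationError, match="universe"):
            enr.gsea(ranked, {"a", "b"}, n_perm=10)

    def test_weight_zero_matches_bruteforce_on_random_lists(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(4, 21))
            stats = np.sort(rng.normal(size=n))[::-1]
            genes = [f"g{i:02d}" for i in range(n)]
            nh = int(rng.integers(1, n))
            members = set(rng.choice(genes, size=nh, replace=False))
            ranked = enr.RankedGeneList.from_pairs(zip(genes, stats))
            res = enr.gsea(ranked, members, weight=0, n_perm=5, seed=0)
            want = gsea_running_sum(
                [g in members for g in ranked.genes], list(ranked.stats), 0.0
            )
            assert res.es == pytest.approx(want, abs=1e-12)

    def test_permutation_p_reproducible_for_fixed_seed(self):
        ranked = enr.RankedGeneList.from_pairs(
            [(f"g{i}", 10.0 - i) for i in range(10)]
        )
        a = enr.gsea(ranked, {"g0", "g1", "g3"}, n_perm=500, seed=7)
        b = enr.gsea(ranked, {"g0", "g1", "g3"}, n_perm=500, seed=7)
        assert a.p_value == b.p_value and a.nes == b.nes

    def test_tie_order_deterministic_by_gene_id(self):
        ranked = enr.RankedGeneList.from_pairs([("b", 1.0), ("a", 1.0), ("c", 0.0)])
        assert ranked.genes == ["a", "b", "c"]


class TestAdjustBH:
    def test_frozen_worked_example(self):
        got = enr.adjust_bh([0.01, 0.04, 0.03, 0.002])
        assert got == pytest.approx([0.02, 0.04, 0.04, 0.008])

    @pytest.mark.parametrize("p,expected", [([0.5], [0.5]), ([1.0, 1.0], [1.0, 1.0])])
    def test_degenerate_cases(self, p, expected):
        assert enr.adjust_bh(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            enr.adjust_bh([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_matches_naive_bh_and_stays_in_range(self, pvals):
        got = enr.adjust_bh(pvals)
        want = bh_adjust_naive(pvals)
        assert got == pytest.approx(want, abs=1e-12)
        assert all(0 <= q <= 1 for q in got)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=15),
        st.randoms(use_true_random=False),
    )
    def test_invariant_under_permutation(self, pvals, rnd):
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        base = enr.adjust_bh(pvals)
        shuffled = enr.adjust_bh([pvals[i] for i in perm])
        assert shuffled == pytest.approx([base[i] for i in perm])


class TestPathwayEnrichment:
    def _planted(self, seed=3):
        from pathkit import synth
        cfg = synth.SimulationConfig(
            seed=seed, n_genes=800, n_pathways=10, pathway_size_range=(20, 40),
            planted_sets=(synth.PlantedSet("P001", "up", 3.0, 0.9),),
        )
        db = synth.simulate_pathway_db(cfg)
        return synth.simulate_deg_table(cfg, db, "cmpA"), db

    def test_split_labels_directions_and_strata(self, six_gene_table):
        db = GeneSetDatabase([
            GeneSet("P1", "one", frozenset(["g1", "g6", "g3"])),
            GeneSet("P2", "two", frozenset(["g2", "g5", "g4"])),
        ])
        res = enr.pathway_enrichment(
            six_gene_table, db, method="ora", split=True,
            min_set_size=1, max_set_size=100,
        )
        assert set(res["direction"]) <= {"up", "down"}
        # BH applied within each (comparison, direction) stratum
        for (_, _), grp in res.groupby(["comparison", "direction"]):
            assert grp["p_adjusted"].tolist() == pytest.approx(
                enr.adjust_bh(grp["p_value"].tolist())
            )

    def test_planted_set_ranks_first_in_planted_direction(self):
        table, db = self._planted()
        res = enr.pathway_enrichment(table, db, method="ora")
        up = res[res.direction == "up"].sort_values("p_value")
        assert up.iloc[0]["set_id"] == "P001"

    def test_gsea_with_split_rejected(self, six_gene_table, toy_pair_db):
        with pytest.raises(ValidationError):
            enr.pathway_enrichment(six_gene_table, toy_pair_db,
                                   method="gsea", split=True)

    def test_empty_stratum_warns_not_errors(self):
        df = pd.DataFrame({
            "gene_id": ["g1", "g2", "g3"],
            "log2_fc": [2.0, 1.5, 0.1],
            "p_value": [0.001, 0.002, 0.9],
            "p_adjusted": [0.003, 0.006, 0.9],
        })
        db = GeneSetDatabase([GeneSet("P1", "one", frozenset(["g1", "g2"]))])
        with pytest.warns(UserWarning, match="down"):
            res = enr.pathway_enrichment(
                DEGTable("t", df), db, min_set_size=1, max_set_size=10
            )
        assert set(res["direction"]) == {"up"}

    def test_shared_schema_across_methods(self):
        table, db = self._planted()
        frames = [
            enr.pathway_enrichment(table, db, method="ora"),
            enr.pathway_enrichment(table, db, method="gene_pair_ora"),
            enr.pathway_enrichment(table, db, method="gsea", split=False,
                                   gsea_params={"n_perm": 50}),
        ]
        for f in frames:
            assert list(f.columns) == enr.ENRICHMENT_COLUMNS

    def test_two_comparisons_concatenate(self):
        t1, db = self._planted(seed=3)
        t2, _ = self._planted(seed=4)
        t2 = DEGTable("cmpB", t2.data)
        res = enr.pathway_enrichment([t1, t2], db, method="ora")
        assert set(res["comparison"]) == {"cmpA", "cmpB"}
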