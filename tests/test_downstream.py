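import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from teratoclass.downstream import (
    condition_mean_pca,
    elim_overrepresentation,
    fisher_overrepresentation,
    keep_probe_for_display,
    propagate_annotations,
    rank_top_genes,
    venn_partition,
)


def brute_force_tail(k, N, K, n):
    """Hypergeometric upper tail by explicit enumeration."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += comb(K, x, exact=True) * comb(N - K, n - x, exact=True)
    return total / comb(N, n, exact=True)


class TestConditionMeanPca:
    def _diffs(self, grids):
        return {
            (f"C{i}", "20x"): pd.DataFrame(
                np.asarray(g), index=[f"PS{j}_at" for j in range(len(g))]
            )
            for i, g in enumerate(grids)
        }

    def test_identical_conditions_zero_variance_error(self):
        grid = [[1.0, 1.0], [2.0, 2.0]]
        with pytest.raises(ValueError, match="variance"):
            condition_mean_pca(self._diffs([grid, grid]))

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError, match="2 conditions"):
            condition_mean_pca(self._diffs([[[1.0], [2.0]]]))

    def test_explained_variance_sums_to_one(self):
        rng = np.random.default_rng(0)
        grids = [rng.normal(size=(20, 3)).tolist() for _ in range(5)]
        explained, coords = condition_mean_pca(self._diffs(grids))
        assert explained.sum() == pytest.approx(1.0)
        assert coords.shape[0] == 5

    def test_dominant_axis_captured_by_pc1(self):
        rng = np.random.default_rng(1)
        direction = rng.normal(size=50)
        grids = []
        for i in range(6):
            profile = (i - 2.5) * direction + rng.normal(scale=0.01, size=50)
            grids.append(np.tile(profile[:, None], (1, 3)).tolist())
        explained, _ = condition_mean_pca(self._diffs(grids))
        assert explained[0] > 0.9

    def test_top_k_variant_restricts_probes(self):
        rng = np.random.default_rng(2)
        grids = [rng.normal(size=(30, 2)).tolist() for _ in range(4)]
        explained, _ = condition_mean_pca(self._diffs(grids), top_k=5)
        assert explained.sum() == pytest.approx(1.0)


class TestVennPartition:
    def test_three_way_split(self):
        out = venn_partition(
            {"cmpA": {"p1", "p2"}},
            {"cmpB": {"p2", "p3"}},
            {"cmpA": "teratogen", "cmpB": "teratogen"},
        )
        assert out == {"overlap": {"p2"}, "A_only": {"p1"}, "B_only": {"p3"}}

    def test_non_teratogen_exclusive_discarded(self):
        out = venn_partition(
            {"tox": {"p1"}, "neg": {"p9"}},
            {"tox": {"p1"}},
            {"tox": "teratogen", "neg": "non_teratogen"},
        )
        union = out["overlap"] | out["A_only"] | out["B_only"]
        assert "p9" not in union

    def test_identical_systems_give_empty_exclusives(self):
        sets = {"tox": {"p1", "p2"}}
        truths = {"tox": "teratogen"}
        out = venn_partition(sets, sets, truths)
        assert out["A_only"] == out["B_only"] == set()
        assert out["overlap"] == {"p1", "p2"}

    def test_partition_is_disjoint_and_covers_union(self):
        rng = np.random.default_rng(3)
        probes = [f"p{i}" for i in range(50)]
        a = {f"t{i}": set(rng.choice(probes, 12, replace=False)) for i in range(4)}
        b = {f"t{i}": set(rng.choice(probes, 12, replace=False)) for i in range(4)}
        truths = {f"t{i}": "teratogen" for i in range(4)}
        out = venn_partition(a, b, truths)
        union_a = set().union(*a.values())
        union_b = set().union(*b.values())
        parts = [out["overlap"], out["A_only"], out["B_only"]]
        for i in range(3):
            for j in range(i + 1, 3):
                assert parts[i].isdisjoint(parts[j])
        assert parts[0] | parts[1] | parts[2] == union_a | union_b


class TestRankTopGenes:
    def test_compound_count_dominates_fold_change(self):
        fcs = {
            f"cmp{i}": {"PS1_at": 0.1} for i in range(5)
        }
        for i in range(4):
            fcs[f"cmp{i}"]["PS2_at"] = 9.0
        ranked = rank_top_genes(fcs, {"PS1_at": "G1", "PS2_at": "G2"})
        assert list(ranked["gene"]) == ["G1", "G2"]

    def test_overlap_context_sums_system_counts(self):
        a = {f"a{i}": {"PS1_at": 1.0} for i in range(3)}
        b = {f"b{i}": {"PS1_at": 1.0} for i in range(4)}
        ranked = rank_top_genes(a, {"PS1_at": "G"}, second_system=b)
        assert ranked.loc[0, "n_compounds"] == 7

    def test_gene_collapse_keeps_best_probe(self):
        fcs = {
            "c1": {"PS1_at": 2.0, "PS2_at": 1.0},
            "c2": {"PS1_at": 2.0},
        }
        gene_map = {"PS1_at": "G", "PS2_at": "G"}
        ranked = rank_top_genes(fcs, gene_map)
        assert len(ranked) == 1
        assert ranked.loc[0, "probe_set"] == "PS1_at"

    def test_suffix_filter(self):
        assert keep_probe_for_display("1234_at")
        assert keep_probe_for_display("1234_a_at")
        assert keep_probe_for_display("1234_s_at")
        assert not keep_probe_for_display("1234_x_at")
        assert not keep_probe_for_display("AFFX-1234")
        fcs = {"c": {"1_at": 1.0, "2_x_at": 5.0}}
        ranked = rank_top_genes(fcs, {"1_at": "A", "2_x_at": "B"})
        assert list(ranked["probe_set"]) == ["1_at"]

    def test_unmapped_probe_flagged(self):
        ranked = rank_top_genes({"c": {"PS1_at": 1.0}}, {})
        assert ranked.loc[0, "gene"] == "PS1_at"
        assert bool(ranked.loc[0, "unmapped"])

    def test_signed_vs_absolute_means(self):
        fcs = {"c1": {"PS1_at": 2.0}, "c2": {"PS1_at": -2.0}}
        ranked_abs = rank_top_genes(fcs, {"PS1_at": "G"}, absolute_means=True)
        ranked_signed = rank_top_genes(fcs, {"PS1_at": "G"}, absolute_means=False)
        assert ranked_abs.loc[0, "mean_log2fc"] == 2.0
        assert ranked_signed.loc[0, "mean_log2fc"] == 0.0

    def test_total_order_stable(self):
        fcs = {"c": {"PS2_at": 1.0, "PS1_at": 1.0}}
        ranked = rank_top_genes(fcs, {"PS1_at": "A", "PS2_at": "B"})
        assert list(ranked["probe_set"]) == ["PS1_at", "PS2_at"]


class TestFisher:
    def test_term_equals_universe_p_one(self):
        universe = {f"p{i}" for i in range(10)}
        result = fisher_overrepresentation({"p0", "p1"}, universe, {"T": universe})
        assert result.loc[0, "p_raw"] == 1.0

    def test_closed_form_extreme_enrichment(self):
        universe = {f"p{i}" for i in range(20)}
        term = {f"p{i}" for i in range(5)}
        result = fisher_overrepresentation(term, universe, {"T": term})
        expected = 1.0 / comb(20, 5, exact=True)
        assert result.loc[0, "p_raw"] == pytest.approx(expected)

    def test_empty_sps_all_p_one(self):
        universe = {f"p{i}" for i in range(10)}
        result = fisher_overrepresentation(
            set(), universe, {"T1": {"p0"}, "T2": {"p1", "p2"}}
        )
        assert (result["p_raw"] == 1.0).all()

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(4)
        universe = {f"p{i}" for i in range(25)}
        for _ in range(20):
            term = set(rng.choice(sorted(universe), rng.integers(1, 20),
                                  replace=False))
            sps = set(rng.choice(sorted(universe), rng.integers(1, 15),
                                 replace=False))
            result = fisher_overrepresentation(sps, universe, {"T": term})
            k = len(sps & term)
            expected = brute_force_tail(k, 25, len(term), len(sps))
            assert result.loc[0, "p_raw"] == pytest.approx(expected)

    def test_sps_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            fisher_overrepresentation({"zzz"}, {"p0"}, {"T": {"p0"}})

    def test_term_outside_universe_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            result = fisher_overrepresentation(
                {"p0"}, {"p0", "p1"}, {"GOOD": {"p0"}, "EMPTY": {"zz"}}
            )
        assert list(result["term"]) == ["GOOD"]


class TestElim:
    def _toy(self):
        universe = {f"p{i}" for i in range(10)}
        term_map = {
            "child": {f"p{i}" for i in range(5)},
            "parent": {"p5", "p6", "p7"},
        }
        dag = nx.DiGraph([("child", "parent")])
        return universe, term_map, dag

    def test_flat_dag_equals_fisher(self):
        universe = {f"p{i}" for i in range(12)}
        term_map = {"A": {"p0", "p1"}, "B": {"p2", "p3", "p4"}}
        sps = {"p0", "p2", "p3"}
        flat = elim_overrepresentation(sps, universe, term_map, dag=None)
        plain = fisher_overrepresentation(sps, universe, term_map)
        merged = flat.set_index("term")["p_raw"].sort_index()
        assert np.allclose(merged, plain.set_index("term")["p_raw"].sort_index())

    def test_significant_child_empties_parent(self):
        universe, term_map, dag = self._toy()
        sps = {f"p{i}" for i in range(5)}  # all of child
        result = elim_overrepresentation(sps, universe, term_map, dag,
                                         elim_cut=0.01).set_index("term")
        child_p = 1.0 / comb(10, 5, exact=True) * comb(5, 5, exact=True)
        assert result.loc["child", "p_raw"] == pytest.approx(
            brute_force_tail(5, 10, 5, 5)
        )
        # child's probes removed: parent tested on {p5,p6,p7} with 0 hits
        assert result.loc["parent", "term_size"] == 3
        assert result.loc["parent", "p_raw"] == 1.0
        assert result.loc["parent", "p_raw"] >= result.loc["child", "p_raw"]

    def test_child_above_cut_leaves_parent_untouched(self):
        universe, term_map, dag = self._toy()
        sps = {"p0", "p5"}  # child p well above 0.01
        result = elim_overrepresentation(sps, universe, term_map, dag,
                                         elim_cut=0.01).set_index("term")
        propagated = propagate_annotations(term_map, dag)
        plain_parent = brute_force_tail(
            len(sps & propagated["parent"]), 10, len(propagated["parent"]), 2
        )
        assert result.loc["parent", "p_raw"] == pytest.approx(plain_parent)

    def test_cut_zero_equals_plain_fisher_on_propagated_map(self):
        universe, term_map, dag = self._toy()
        rng = np.random.default_rng(5)
        for _ in range(10):
            sps = set(rng.choice(sorted(universe), 4, replace=False))
            elim = elim_overrepresentation(
                sps, universe, term_map, dag, elim_cut=0.0
            ).set_index("term")["p_raw"]
            propagated = propagate_annotations(term_map, dag)
            plain = fisher_overrepresentation(
                sps, universe, propagated
            ).set_index("term")["p_raw"]
            assert np.allclose(elim.sort_index(), plain.sort_index())

    def test_cyclic_dag_rejected(self):
        universe, term_map, _ = self._toy()
        cyclic = nx.DiGraph([("child", "parent"), ("parent", "child")])
        with pytest.raises(ValueError, match="cycle"):
            elim_overrepresentation(set(), universe, term_map, cyclic)

    def test_annotations_propagate_upward(self):
        term_map = {"leaf": {"p0"}, "mid": {"p1"}, "root": set()}
        dag = nx.DiGraph([("leaf", "mid"), ("mid", "root")])
        propagated = propagate_annotations(term_map, dag)
        assert propagated["root"] == {"p0", "p1"}
        assert propagated["mid"] == {"p0", "p1"}
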