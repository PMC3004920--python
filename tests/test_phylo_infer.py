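import numpy as np
import pytest

from duxevo.io_formats import parse_newick
from duxevo.phylo_infer import (CharacterMatrix, DistanceMatrix,
                                bootstrap_consensus, classify_duplication,
                                concatenate_domains, distance_matrix, nj_tree,
                                tree_splits)

from oracles import ls_best_tree
from duxevo.benchmarks import random_additive_tree


class TestConcatenateDomains:
    def test_concatenation_is_120_residues(self):
        row = concatenate_domains("A" * 60, "C" * 60)
        assert len(row) == 120
        assert row == "A" * 60 + "C" * 60

    def test_identical_halves(self):
        row = concatenate_domains("M" * 60, "M" * 60)
        assert row[:60] == row[60:]

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            concatenate_domains("A" * 59, "C" * 60)


class TestDistanceMatrix:
    def _m(self, rows, labels=None):
        labels = labels or [f"t{i}" for i in range(len(rows))]
        return CharacterMatrix(labels, rows)

    def test_identical_rows_zero_distance(self):
        m = self._m(["A" * 60] * 3)
        d = distance_matrix(m, "p")
        assert np.allclose(d.values, 0.0)

    def test_six_differences_p_and_poisson(self):
        a = "A" * 60
        b = "C" * 6 + "A" * 54
        m = self._m([a, b, a])
        dp = distance_matrix(m, "p")
        assert dp.values[0, 1] == pytest.approx(0.1)
        dpois = distance_matrix(m, "poisson")
        assert dpois.values[0, 1] == pytest.approx(-np.log(0.9), abs=1e-9)

    def test_symmetry_on_random_matrices(self, rng):
        aas = "ACDEFGHIKLMNPQRSTVWY"
        rows = ["".join(aas[rng.integers(0, 20)] for _ in range(60))
                for _ in range(5)]
        d = distance_matrix(self._m(rows), "p")
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)

    def test_pairwise_deletion_ignores_undefined_columns(self):
        a = "A" * 59 + "X"
        b = "A" * 58 + "CC"
        m = self._m([a, b, a])
        d = distance_matrix(m, "p")
        # only 59 mutually defined columns; one mismatch
        assert d.values[0, 1] == pytest.approx(1 / 59)

    def test_saturated_pair_rejected_under_poisson(self):
        m = self._m(["A" * 60, "C" * 60, "A" * 60])
        with pytest.raises(ValueError, match="Poisson"):
            distance_matrix(m, "poisson")


class TestNjTree:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(list("ABC"),
                            np.array([[0, 4, 6], [4, 0, 8], [6, 8, 0]], float))
        tree = nj_tree(dm)
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"A": pytest.approx(1.0), "B": pytest.approx(3.0),
                           "C": pytest.approx(5.0)}

    def test_additive_matrix_recovered_exactly_vs_ls_oracle(self):
        rng = np.random.default_rng(17)
        for trial in range(10):
            n = 4 + trial % 4
            labels, D, true_splits = random_additive_tree(n, rng)
            tree = nj_tree(DistanceMatrix(labels, D))
            oracle_splits, sse = ls_best_tree(D)
            assert sse < 1e-12
            named = {frozenset(labels[i] for i in s): l
                     for s, l in oracle_splits.items()}
            internal = {s for s in named if 1 < len(s) < n - 1}
            # orient oracle splits like tree_splits (side without labels[0])
            oriented = set()
            full = frozenset(labels)
            for s in internal:
                oriented.add(full - s if labels[0] in s else s)
            assert tree_splits(tree) == oriented
            # leaf branch lengths must match the oracle's exact fit
            leaf_len = {l.taxon.label: l.edge.length
                        for l in tree.leaf_node_iter()}
            for s, ln in named.items():
                if len(s) == 1:
                    (lab,) = s
                    assert leaf_len[lab] == pytest.approx(ln, abs=1e-8)

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(23)
        labels, D, _ = random_additive_tree(6, rng)
        t1 = nj_tree(DistanceMatrix(labels, D))
        perm = list(rng.permutation(6))
        labels2 = [labels[i] for i in perm]
        D2 = D[np.ix_(perm, perm)]
        t2 = nj_tree(DistanceMatrix(labels2, D2))
        assert tree_splits(t1) == tree_splits(t2)

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(list("ABC"),
                           np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], float))


class TestBootstrapConsensus:
    def _perfect_matrix(self):
        # every column supports ab | cde and cd | abe
        rows = ["A" * 60, "A" * 60, "G" * 30 + "T" * 30, "G" * 30 + "T" * 30,
                "G" * 30 + "C" * 30]
        return CharacterMatrix(list("abcde"), rows)

    def test_perfect_signal_gives_full_support(self):
        cons = bootstrap_consensus(self._perfect_matrix(), n_reps=100, seed=1,
                                   method="p")
        sups = [node.support for node in cons.preorder_node_iter()
                if hasattr(node, "support")]
        assert sups and all(s == 100.0 for s in sups)

    def test_same_seed_identical_supports(self):
        m = self._perfect_matrix()
        a = bootstrap_consensus(m, 50, seed=3, method="p")
        b = bootstrap_consensus(m, 50, seed=3, method="p")
        assert a.as_string(schema="newick") == b.as_string(schema="newick")

    def test_consensus_keeps_only_majority_bipartitions(self, small_sim):
        rows, labels = [], []
        for (sp, fam, dom), prot in sorted(small_sim.truth.hd_proteins.items()):
            labels.append(f"{sp}_HD{dom}")
            rows.append(prot)
        m = CharacterMatrix(labels, rows)
        cons = bootstrap_consensus(m, n_reps=100, seed=7)
        for node in cons.preorder_node_iter():
            if hasattr(node, "support"):
                assert 50.0 < node.support <= 100.0

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_consensus(self._perfect_matrix(), n_reps=0, seed=1)


class TestClassifyDuplication:
    LABELS = {"A_HD1": ("A", 1), "B_HD1": ("B", 1),
              "A_HD2": ("A", 2), "B_HD2": ("B", 2)}

    def test_domain_clades_mean_pre_speciation(self):
        t = parse_newick("((A_HD1:1,B_HD1:1):1,(A_HD2:1,B_HD2:1):1,OUT:3);")
        assert classify_duplication(t, self.LABELS, "OUT") == "pre_speciation"

    def test_gene_clades_mean_post_speciation(self):
        t = parse_newick("((A_HD1:1,A_HD2:1):1,(B_HD1:1,B_HD2:1):1,OUT:3);")
        assert classify_duplication(t, self.LABELS, "OUT") == "post_speciation"

    def test_star_polytomy_unresolved(self):
        t = parse_newick("(A_HD1:1,A_HD2:1,B_HD1:1,B_HD2:1,OUT:3);")
        assert classify_duplication(t, self.LABELS, "OUT") == "unresolved"

    def test_branch_lengths_and_gene_naming_irrelevant(self):
        t = parse_newick("((B_HD1:9,A_HD1:0.01):2,(B_HD2:5,A_HD2:1):1,OUT:9);")
        assert classify_duplication(t, self.LABELS, "OUT") == "pre_speciation"

    def test_low_support_is_unresolved(self):
        t = parse_newick(
            "((A_HD1:1,B_HD1:1)40:1,(A_HD2:1,B_HD2:1)45:1,OUT:3);")
        assert classify_duplication(t, self.LABELS, "OUT",
                                    support_floor=70) == "unresolved"

    def test_missing_outgroup_rejected(self):
        t = parse_newick("((A_HD1:1,B_HD1:1):1,(A_HD2:1,B_HD2:1):1);")
        with pytest.raises(ValueError, match="outgroup"):
            classify_duplication(t, self.LABELS, "OUT")
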