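"""Dollo parsimony scoring, tree search, bootstrap, and fit statistics."""
import itertools

import numpy as np
import pytest

from mescan import (CharacterMatrix, ParsimonyStats, Tree, bootstrap,
                    brute_force_char_score, dollo_char_score,
                    enumerate_rooted_topologies, parsimony_stats,
                    search_trees, tree_score)
from mescan.errors import ConfigError, DataError


def make_matrix(taxa, columns, ancestor="ANC"):
    """columns: list of strings over taxa order (ancestor appended as 0)."""
    states = [[col[i] for col in columns] for i in range(len(taxa))]
    states.append(["0"] * len(columns))
    return CharacterMatrix(taxa=list(taxa) + [ancestor],
                           locus_ids=[f"c{i}" for i in range(len(columns))],
                           states=np.array(states, dtype="<U1"),
                           ancestor=ancestor)


class TestCharScore:
    TREE = Tree.from_newick("((A,B),(C,D));")

    @pytest.mark.parametrize("states,expected", [
        # single gain above the (A,B) cherry
        ({"A": 1, "B": 1, "C": 0, "D": 0}, 1),
        # gain at the root, two independent losses
        ({"A": 1, "B": 0, "C": 1, "D": 0}, 3),
        # no definite presence -> no gain needed
        ({"A": "?", "B": "?", "C": 0, "D": "?"}, 0),
        # missing leaves resolve cost-free
        ({"A": 1, "B": "?", "C": 1, "D": 0}, 2),
        ({"A": 1, "B": "?", "C": "?", "D": "?"}, 1),
        # presence everywhere: single gain on the root edge
        ({"A": 1, "B": 1, "C": 1, "D": 1}, 1),
    ])
    def test_worked_examples(self, states, expected):
        assert dollo_char_score(self.TREE, states) == expected
        assert brute_force_char_score(self.TREE, states) == expected

    def test_missing_leaf_raises(self):
        with pytest.raises(DataError):
            dollo_char_score(self.TREE, {"A": 1, "B": 0, "C": 0})

    def test_oracle_equivalence_small_trees(self):
        """Exhaustive sweep: the MRCA-gain scorer equals the brute-force
        minimum over Dollo-valid ancestral assignments for every rooted
        topology with <= 5 leaves and every state vector (the full <= 6 leaf
        sweep runs in the acceptance suite)."""
        for n in range(2, 6):
            leaves = [f"L{i}" for i in range(n)]
            for tup in enumerate_rooted_topologies(leaves):
                tree = Tree.from_tuples(tup)
                for combo in itertools.product("01?", repeat=n):
                    states = dict(zip(leaves, combo))
                    assert dollo_char_score(tree, states) == \
                        brute_force_char_score(tree, states), (tup, combo)

    def test_missing_data_monotonicity(self):
        """Filling in a '?' with a definite state never lowers the score."""
        rng = np.random.default_rng(0)
        leaves = [f"L{i}" for i in range(6)]
        tops = list(enumerate_rooted_topologies(leaves))
        for _ in range(200):
            tree = Tree.from_tuples(tops[rng.integers(len(tops))])
            states = {lf: rng.choice(["0", "1", "?"]) for lf in leaves}
            base = dollo_char_score(tree, states)
            for lf in leaves:
                if states[lf] == "?":
                    for v in "01":
                        filled = dict(states, **{lf: v})
                        assert dollo_char_score(tree, filled) >= base

    def test_child_order_invariance(self):
        s = {"A": 1, "B": 0, "C": 1, "D": 0}
        t1 = Tree.from_newick("((A,B),(C,D));")
        t2 = Tree.from_newick("((D,C),(B,A));")
        assert dollo_char_score(t1, s) == dollo_char_score(t2, s)


class TestTreeScore:
    def test_pattern_compression_equals_direct_sum(self):
        rng = np.random.default_rng(1)
        taxa = ["A", "B", "C", "D", "E"]
        cols = ["".join(rng.choice(list("01?"), size=5)) for _ in range(40)]
        cols = [c if "1" in c else "11000" for c in cols]
        m = make_matrix(taxa, cols)
        tree = Tree.from_newick("(ANC,((A,B),(C,(D,E))));")
        direct = sum(dollo_char_score(
            tree, dict(zip(m.taxa, m.states[:, j]))) for j in range(len(cols)))
        assert tree_score(tree, m) == direct

    def test_empty_matrix_scores_zero(self):
        m = make_matrix(["A", "B", "C"], [])
        tree = Tree.from_newick("(ANC,(A,(B,C)));")
        assert tree_score(tree, m) == 0

    def test_taxa_mismatch_raises(self):
        m = make_matrix(["A", "B", "C"], ["110"])
        with pytest.raises(DataError):
            tree_score(Tree.from_newick("(ANC,(A,(B,X)));"), m)


class TestEnumeration:
    @pytest.mark.parametrize("n,expected", [(2, 1), (3, 3), (4, 15),
                                            (5, 105), (6, 945)])
    def test_rooted_topology_counts(self, n, expected):
        """(2n-3)!! rooted binary topologies; e.g. 7 ingroup leaves + the
        ancestor = 8 total leaves give 10,395 (checked in search tests)."""
        leaves = [f"L{i}" for i in range(n)]
        tops = list(enumerate_rooted_topologies(leaves))
        assert len(tops) == expected
        # all distinct as clade sets
        clades = {frozenset(Tree.from_tuples(t).clades()) for t in tops}
        assert len(clades) == expected


class TestSearch:
    def test_exhaustive_recovers_generating_tree(self):
        taxa = ["A", "B", "C", "D", "E"]
        # characters exactly matching the clades of (((A,B),C),(D,E))
        cols = ["11000", "11100", "00011", "11000", "00011", "11100"]
        m = make_matrix(taxa, cols)
        trees, score = search_trees(m, strategy="exhaustive")
        assert score == len(cols)
        assert len(trees) == 1
        assert trees[0].same_topology(
            Tree.from_newick("(ANC,(((A,B),C),(D,E)));"))

    def test_three_ingroup_taxa_enumerates_three_trees(self):
        m = make_matrix(["A", "B", "C"], ["110"])
        trees, score = search_trees(m, strategy="exhaustive")
        assert score == 1
        assert any(t.same_topology(Tree.from_newick("(ANC,((A,B),C));"))
                   for t in trees)

    def test_exhaustive_refuses_large_trees(self):
        taxa = [f"T{i}" for i in range(9)]  # + ancestor = 10 leaves
        m = make_matrix(taxa, ["110000000"])
        with pytest.raises(ConfigError):
            search_trees(m, strategy="exhaustive")

    def test_heuristic_matches_exhaustive_minimum(self):
        rng = np.random.default_rng(7)
        taxa = ["A", "B", "C", "D", "E", "F"]
        for rep in range(5):
            cols = ["".join(rng.choice(list("01"), size=6))
                    for _ in range(25)]
            cols = [c if c.count("1") >= 2 else "110000" for c in cols]
            m = make_matrix(taxa, cols)
            _, s_ex = search_trees(m, strategy="exhaustive")
            _, s_h = search_trees(m, strategy="heuristic",
                                  n_random_addition=10, seed=rep)
            assert s_h == s_ex


class TestBootstrap:
    def test_single_repeated_pattern_gives_full_support(self):
        taxa = ["A", "B", "C", "D", "E"]
        m = make_matrix(taxa, ["11000"] * 10)
        support, tree = bootstrap(m, n_replicates=20, seed=0)
        assert support[frozenset({"A", "B"})] == 100.0

    def test_single_replicate_supports_are_binary(self):
        taxa = ["A", "B", "C", "D", "E"]
        cols = ["11000", "11100", "00011"] * 4
        m = make_matrix(taxa, cols)
        support, _ = bootstrap(m, n_replicates=1, seed=1)
        assert set(support.values()) <= {0.0, 100.0}

    def test_reproducible_under_seed(self):
        taxa = ["A", "B", "C", "D", "E"]
        cols = ["11000", "11100", "00011", "10100"] * 3
        m = make_matrix(taxa, cols)
        s1, t1 = bootstrap(m, n_replicates=30, seed=5)
        s2, t2 = bootstrap(m, n_replicates=30, seed=5)
        assert s1 == s2 and t1.to_newick() == t2.to_newick()


class TestParsimonyStats:
    def test_single_homoplastic_character(self):
        """A=C=1, B=D=0 on ((A,B),(C,D)): S=3, m=1, g=3 -> CI=1/3, RI=0."""
        m = make_matrix(["A", "B", "C", "D"], ["1010"])
        tree = Tree.from_newick("(ANC,((A,B),(C,D)));")
        st = parsimony_stats(tree, m)
        assert st.length == 3
        assert st.min_steps == 1
        assert st.max_steps == 3
        assert st.ci == pytest.approx(1 / 3)
        assert st.ri == 0.0
        assert st.hi == pytest.approx(2 / 3)
        assert st.rc == 0.0

    def test_homoplasy_free_matrix_has_ci_one(self):
        m = make_matrix(["A", "B", "C", "D"], ["1100", "0011", "1100"])
        tree = Tree.from_newick("(ANC,((A,B),(C,D)));")
        st = parsimony_stats(tree, m)
        assert st.length == 3
        assert st.ci == 1.0 and st.hi == 0.0 and st.ri == 1.0

    def test_indices_bounded_on_random_matrices(self):
        rng = np.random.default_rng(2)
        taxa = ["A", "B", "C", "D", "E"]
        for rep in range(10):
            cols = ["".join(rng.choice(list("01?"), size=5))
                    for _ in range(15)]
            cols = [c if "1" in c else "11000" for c in cols]
            m = make_matrix(taxa, cols)
            trees, _ = search_trees(m, strategy="exhaustive")
            st = parsimony_stats(trees[0], m)
            for v in (st.ci, st.ri, st.rc, st.hi):
                assert 0.0 <= v <= 1.0

    def test_all_absent_matrix_is_degenerate(self):
        m = make_matrix(["A", "B", "C", "D"], ["0000"])
        tree = Tree.from_newick("(ANC,((A,B),(C,D)));")
        st = parsimony_stats(tree, m)
        assert st.degenerate and st.length == 0 and st.ci == 1.0
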