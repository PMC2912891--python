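"""Tree model, Newick I/O, bipartitions, consensus, NJ/LNJ, distances."""

import math

import numpy as np
import pytest

from phyloga import (
    SubstitutionModel,
    bipartitions,
    lnj_tree,
    majority_consensus,
    model_distance_matrix,
    nj_tree,
    parse_newick,
    random_tree,
    reroot,
    robinson_foulds,
    tree_signature,
    write_newick,
)
from phyloga.alignment import Alignment
from phyloga.trees import TreeError, canonical_split
from util import path_distance_matrix, random_binary_tree


class TestNewick:
    def test_basic_parse(self):
        tree = parse_newick("((A:1,B:1):1,C:1,D:1);")
        assert tree.n_leaves == 4
        assert len(list(tree.internal_edges())) == 1
        assert bipartitions(tree) == frozenset({frozenset({"C", "D"})})

    def test_round_trip_preserves_topology_and_lengths(self, rng):
        tree = random_tree([f"t{i}" for i in range(20)], rng)
        back = parse_newick(write_newick(tree))
        assert bipartitions(back) == bipartitions(tree)
        assert tree_signature(back, 9) == tree_signature(tree, 9)

    def test_rooted_input_unrooted(self):
        rooted = parse_newick("(((A,B),C),D);")
        unrooted = parse_newick("((A,B),C,D);")
        assert bipartitions(rooted) == bipartitions(unrooted)

    @pytest.mark.parametrize("bad", ["((A,B);", "((A,B),C,D)", "((A,A),C,D);"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(TreeError):
            parse_newick(bad)

    def test_dendropy_agrees_on_round_trip(self, rng):
        dendropy = pytest.importorskip("dendropy")
        tree = random_tree([f"x{i}" for i in range(10)], rng)
        text = write_newick(tree)
        dt = dendropy.Tree.get(data=text, schema="newick")
        assert {lf.taxon.label for lf in dt.leaf_node_iter()} == set(tree.taxa)


class TestBipartitions:
    def test_four_taxon_single_split(self):
        tree = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert bipartitions(tree) == frozenset({frozenset({"C", "D"})})

    def test_caterpillar_count(self):
        tree = parse_newick("(A:1,(B:1,(C:1,(D:1,(E:1,F:1):1):1):1):1);")
        assert len(bipartitions(tree)) == 3  # NTax - 3

    def test_binary_tree_has_ntax_minus_3_splits(self, rng):
        for n in (5, 7, 10):
            tree = random_tree([f"t{i}" for i in range(n)], rng)
            assert len(bipartitions(tree)) == n - 3

    def test_matches_exhaustive_edge_cut_enumeration(self, rng):
        tree = random_tree([f"t{i}" for i in range(10)], rng)
        taxa = tree.taxa
        expected = set()
        for u, v, _ in tree.edges():
            side = tree.side_taxa(u, v)
            if 2 <= len(side) <= len(taxa) - 2:
                expected.add(canonical_split(side, taxa))
        assert bipartitions(tree) == frozenset(expected)


class TestRobinsonFoulds:
    def test_identical_trees_zero(self, rng):
        tree = random_tree(list("ABCDEFG"), rng)
        assert robinson_foulds(tree, tree.copy()) == 0

    def test_single_nni_distance_two(self):
        t1 = parse_newick("((A,B),(C,D),E);")
        t2 = parse_newick("((A,(C,D)),B,E);")  # B and (C,D) swapped across one edge
        assert robinson_foulds(t1, t2) == 2

    def test_conflicting_caterpillars_match_brute_force(self):
        t1 = parse_newick("(A,(B,(C,(D,(E,F)))));")
        t2 = parse_newick("(A,(D,(E,(B,(F,C)))));")
        expected = len(bipartitions(t1) ^ bipartitions(t2))
        assert robinson_foulds(t1, t2) == expected

    def test_dendropy_cross_check(self, rng):
        dendropy = pytest.importorskip("dendropy")
        from dendropy.calculate import treecompare

        for seed in range(5):
            a = random_binary_tree(list("ABCDEFGH"), seed)
            b = random_binary_tree(list("ABCDEFGH"), seed + 100)
            tns = dendropy.TaxonNamespace()
            da = dendropy.Tree.get(data=write_newick(a), schema="newick",
                                   taxon_namespace=tns)
            db = dendropy.Tree.get(data=write_newick(b), schema="newick",
                                   taxon_namespace=tns)
            da.encode_bipartitions()
            db.encode_bipartitions()
            assert robinson_foulds(a, b) == treecompare.symmetric_difference(da, db)

    def test_mismatched_taxa_rejected(self, rng):
        with pytest.raises(TreeError):
            robinson_foulds(random_tree(list("ABCD"), rng), random_tree(list("ABCE"), rng))


class TestConsensus:
    def test_identical_trees_full_support(self, rng):
        tree = random_tree(list("ABCDEF"), rng)
        cons = majority_consensus([tree.copy() for _ in range(3)])
        assert bipartitions(cons.tree) == bipartitions(tree)
        assert all(v == 1.0 for v in cons.support.values())

    def test_two_thirds_majority(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,B),(C,D));")
        t3 = parse_newick("((A,C),(B,D));")
        cons = majority_consensus([t1, t2, t3])
        split = frozenset({"C", "D"})
        assert cons.support[split] == pytest.approx(2 / 3)
        assert bipartitions(cons.tree) == frozenset({split})

    def test_conflicting_pair_gives_star(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        cons = majority_consensus([t1, t2])
        assert bipartitions(cons.tree) == frozenset()

    def test_order_invariance(self, rng):
        trees = [random_tree(list("ABCDEFG"), rng) for _ in range(5)]
        a = majority_consensus(trees)
        b = majority_consensus(trees[::-1])
        assert a.split_support == b.split_support
        assert bipartitions(a.tree) == bipartitions(b.tree)

    def test_branch_lengths_averaged(self):
        # The 4-taxon root edge merges on unrooting: internal lengths 6 and 12.
        t1 = parse_newick("((A:1,B:1):2,(C:1,D:1):4);")
        t2 = parse_newick("((A:1,B:1):4,(C:1,D:1):8);")
        cons = majority_consensus([t1, t2])
        from phyloga.trees import split_to_edge

        split = frozenset({"C", "D"})
        u, v = split_to_edge(cons.tree)[split]
        assert cons.tree.length(u, v) == pytest.approx(9.0)

    def test_empty_input_rejected(self):
        with pytest.raises(TreeError):
            majority_consensus([])


class TestNeighborJoining:
    def test_additive_matrix_recovery_with_exact_lengths(self):
        true = parse_newick("((A:1,B:2):1,(C:3,D:4):1,E:2);")
        D, taxa = path_distance_matrix(true)
        est = nj_tree(D, taxa)
        assert robinson_foulds(true, est) == 0
        assert tree_signature(est, 9) == tree_signature(true, 9)

    def test_random_additive_matrices(self):
        for seed in range(10):
            n = 5 + seed % 8
            true = random_binary_tree([f"t{i}" for i in range(n)], seed, mean=0.5)
            D, taxa = path_distance_matrix(true)
            assert robinson_foulds(true, nj_tree(D, taxa)) == 0

    def test_ultrametric_four_taxon_pairing(self):
        # ((A,B),(C,D)) with heights 1 within pairs, 3 across.
        D = np.array([[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], float)
        est = nj_tree(D, list("ABCD"))
        assert bipartitions(est) == frozenset({frozenset({"C", "D"})})

    def test_tie_break_deterministic(self):
        D = np.full((4, 4), 2.0)
        np.fill_diagonal(D, 0.0)
        a = nj_tree(D, list("ABCD"))
        b = nj_tree(D, list("ABCD"))
        assert tree_signature(a) == tree_signature(b)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1.5, 0, 1], [3, 2, 1, 0]], float)
        with pytest.raises(TreeError):
            nj_tree(D, list("ABCD"))


class TestLooseNeighborJoining:
    def test_p_zero_equals_nj(self):
        rng = np.random.default_rng(5)
        for seed in range(20):
            M = rng.random((7, 7))
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0)
            taxa = [f"x{i}" for i in range(7)]
            assert tree_signature(lnj_tree(M, taxa, 0.0, np.random.default_rng(seed))) \
                == tree_signature(nj_tree(M, taxa))

    def test_p_one_varies_across_seeds(self, rng):
        M = rng.random((8, 8))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        taxa = [f"x{i}" for i in range(8)]
        tops = {frozenset(bipartitions(lnj_tree(M, taxa, 1.0, np.random.default_rng(s))))
                for s in range(20)}
        assert len(tops) > 1

    def test_candidate_list_size_formula(self, rng):
        """First-step list size is ceil(NTax(NTax-1)p/2): 18 for NTax=10, p=0.4."""
        sizes = []

        class Probe:
            def integers(self, n):
                sizes.append(int(n))
                return 0

        M = rng.random((10, 10))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 0)
        lnj_tree(M, [f"x{i}" for i in range(10)], 0.4, Probe())
        assert sizes[0] == math.ceil(10 * 9 * 0.4 / 2) == 18
        # per-step recomputation with the shrinking cluster count m
        assert sizes[1] == math.ceil(9 * 8 * 0.4 / 2)

    def test_invalid_p_rejected(self, rng):
        M = np.zeros((4, 4))
        with pytest.raises(TreeError):
            lnj_tree(M, list("ABCD"), 1.5, rng)


class TestRandomTree:
    def test_topology_uniform_on_four_taxa(self):
        counts = {}
        for seed in range(3000):
            t = random_tree(list("ABCD"), np.random.default_rng(seed))
            key = next(iter(bipartitions(t)))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        from scipy.stats import chisquare

        _, p = chisquare(list(counts.values()))
        assert p > 1e-3

    def test_five_taxa_reach_all_fifteen_topologies(self):
        tops = {frozenset(bipartitions(random_tree(list("ABCDE"), np.random.default_rng(s))))
                for s in range(600)}
        assert len(tops) == 15

    def test_valid_binary_with_positive_lengths(self, rng):
        tree = random_tree([f"t{i}" for i in range(12)], rng)
        tree.validate_binary()
        assert tree.n_edges() == 2 * 12 - 3
        assert all(length >= 0 for _, _, length in tree.edges())


class TestReroot:
    def test_bipartitions_invariant_on_every_edge(self, rng):
        tree = random_tree(list("ABCDEF"), rng)
        reference = bipartitions(tree)
        for u, v, _ in list(tree.edges()):
            assert bipartitions(reroot(tree, (u, v))) == reference

    def test_reroot_on_leaf_edge_valid(self, rng):
        tree = random_tree(list("ABCD"), rng)
        leaf = tree.leaf_by_label("A")
        parent = next(iter(tree.adj[leaf]))
        rooted = reroot(tree, (leaf, parent))
        assert rooted.root is not None

    def test_unknown_edge_rejected(self, rng):
        tree = random_tree(list("ABCD"), rng)
        with pytest.raises(TreeError):
            reroot(tree, (998, 999))


class TestModelDistances:
    def test_identical_sequences_zero(self):
        aln = Alignment(["a", "b", "c", "d"], {t: "ACGTACGTAC" for t in "abcd"})
        D = model_distance_matrix(aln, SubstitutionModel(family="JC"))
        assert np.allclose(D, 0.0)

    def test_jc_closed_form(self):
        # 30% observed mismatch -> d = -(3/4) ln(1 - 0.4)
        a = "A" * 7 + "C" * 3
        b = "A" * 7 + "G" * 3
        aln = Alignment(["x", "y", "z", "w"], {"x": a, "y": b, "z": a, "w": a})
        D = model_distance_matrix(aln, SubstitutionModel(family="JC"))
        expected = -0.75 * np.log(1 - 4 / 3 * 0.3)
        assert D[0, 1] == pytest.approx(expected, abs=1e-5)
        assert D[0, 1] == pytest.approx(0.3831, abs=1e-3)

    def test_saturated_pair_capped(self):
        taxa = ["p", "q", "r", "s"]
        aln = Alignment(taxa, {"p": "ACGTACGTACGTACGT", "q": "CATCGATGCATGCATG",
                               "r": "ACGTACGTACGTACGT", "s": "ACGTACGTACGTACGT"})
        D = model_distance_matrix(aln, SubstitutionModel(family="JC"), cap=5.0)
        assert D[0, 1] == 5.0

    def test_symmetric_zero_diagonal(self, jc_alignment8):
        D = model_distance_matrix(jc_alignment8, SubstitutionModel(family="JC"))
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)
        assert (D >= 0).all()
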