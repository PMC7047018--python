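"""NJ tree building, outgroup rooting, canonical census and bootstrap."""

import itertools
import random

import dendropy
import numpy as np
import pytest

from panphylo.align_qc import codon_align
from panphylo.species import OUTGROUP, SPECIES_TOPOLOGY
from panphylo.synthetic_data import _evolve_branch, _random_root_cds, _seq_to_str
from panphylo.tree_topology import (
    build_tree,
    canonical_from_newick,
    canonical_topology,
    census,
    census_table,
    check_outgroup_and_root,
    jc_distance_matrix,
    neighbor_joining,
    truncate_percent,
)
from skbio import DistanceMatrix


def least_squares_quartet(d):
    """Oracle: fit all three quartet topologies by least squares and return
    the split with minimal residual.  ``d`` maps frozenset pairs to distances
    over taxa A,B,C,D."""
    taxa = "ABCD"
    pairs = list(itertools.combinations(taxa, 2))
    y = np.array([d[frozenset(p)] for p in pairs])
    best = None
    for split in ({"A", "B"}, {"A", "C"}, {"A", "D"}):
        # design: leaf edges a,b,c,d + internal edge m
        X = []
        for p in pairs:
            row = [int(t in p) for t in taxa]
            crosses = len(set(p) & split) == 1
            row.append(int(crosses))
            X.append(row)
        X = np.array(X, float)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        sse = float(((X @ coef - y) ** 2).sum())
        key = frozenset({frozenset(split), frozenset(set(taxa) - split)})
        if best is None or sse < best[0]:
            best = (sse, key)
    return best[1]


def tree_split(tree):
    """The non-trivial split of an unrooted 4-taxon tree."""
    for node in tree.preorder_internal_node_iter():
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(below) < 3:
            all_taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
            return frozenset({below, all_taxa - below})
    return None


class TestNeighborJoining:
    def test_worked_quartet_example(self):
        d = {
            frozenset("AB"): 3, frozenset("AC"): 5, frozenset("AD"): 6,
            frozenset("BC"): 6, frozenset("BD"): 7, frozenset("CD"): 7,
        }
        ids = list("ABCD")
        mat = np.zeros((4, 4))
        for i, j in itertools.combinations(range(4), 2):
            mat[i, j] = mat[j, i] = d[frozenset(ids[i] + ids[j])]
        tree = neighbor_joining(DistanceMatrix(mat, ids))
        expected = frozenset({frozenset("AB"), frozenset("CD")})
        assert tree_split(tree) == expected
        assert least_squares_quartet(d) == expected

    def test_additive_quartets_recovered_100_of_100(self):
        rng = random.Random(17)
        ids = list("ABCD")
        for _ in range(100):
            split = rng.choice([{"A", "B"}, {"A", "C"}, {"A", "D"}])
            lengths = {t: rng.uniform(0.5, 3.0) for t in ids}
            m = rng.uniform(0.5, 3.0)
            d = {}
            for p in itertools.combinations(ids, 2):
                crosses = len(set(p) & split) == 1
                d[frozenset(p)] = lengths[p[0]] + lengths[p[1]] + (m if crosses else 0.0)
            mat = np.zeros((4, 4))
            for i, j in itertools.combinations(range(4), 2):
                mat[i, j] = mat[j, i] = d[frozenset(ids[i] + ids[j])]
            expected = frozenset({frozenset(split), frozenset(set(ids) - split)})
            assert least_squares_quartet(d) == expected
            tree = neighbor_joining(DistanceMatrix(mat, ids))
            assert tree_split(tree) == expected

    def test_identical_sequences_star_tree(self):
        rng = np.random.default_rng(0)
        cds = _seq_to_str(_random_root_cds(60, rng))
        a = codon_align({t: cds for t in "ABCDE"})
        a.mask = np.arange(a.ncol - 3)
        tree = build_tree(a)
        for edge in tree.preorder_edge_iter():
            assert (edge.length or 0.0) <= 1e-9

    def test_too_few_taxa_rejected(self):
        rng = np.random.default_rng(1)
        cds = _seq_to_str(_random_root_cds(60, rng))
        a = codon_align({"A": cds, "B": cds, "C": cds})
        a.mask = np.arange(a.ncol - 3)
        with pytest.raises(ValueError):
            build_tree(a)

    def test_simulation_recovery_rate(self):
        # evolve 600-nt alignments on a fixed 5-taxon tree with long
        # branches; NJ must recover the generating topology nearly always
        newick = "((A:0.08,B:0.08):0.05,(C:0.08,(D:0.08,E:0.08):0.05):0.05);"
        tns = dendropy.TaxonNamespace()
        true_tree = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=tns)
        true_tree.encode_bipartitions()
        from dendropy.calculate import treecompare

        ok = 0
        for rep in range(100):
            rng = np.random.default_rng([5, rep])
            root = _random_root_cds(200, rng)
            seqs = {}
            node_seq = {id(true_tree.seed_node): root}
            for node in true_tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                s = _evolve_branch(node_seq[id(node.parent_node)], node.edge.length, rng)
                node_seq[id(node)] = s
                if node.is_leaf():
                    seqs[node.taxon.label] = _seq_to_str(s)
            est = neighbor_joining(jc_distance_matrix(seqs))
            est = dendropy.Tree.get(
                data=est.as_string(schema="newick"), schema="newick",
                taxon_namespace=tns,
            )
            est.is_rooted = False
            est.encode_bipartitions()
            if treecompare.symmetric_difference(true_tree, est) == 0:
                ok += 1
        assert ok >= 95


class TestOutgroupRooting:
    def test_outgroup_split_present_roots_tree(self):
        t = dendropy.Tree.get(data=SPECIES_TOPOLOGY, schema="newick")
        t.is_rooted = False
        rooted = check_outgroup_and_root(t)
        assert rooted is not None
        kids = rooted.seed_node.child_nodes()
        sides = [
            {l.taxon.label for l in k.leaf_iter()} for k in kids
        ]
        assert set(OUTGROUP) in sides

    def test_outgroup_inside_ingroup_rejected(self):
        newick = "((Oryza,Sorghum),(Brachypodium,(Zea,Setaria)));"
        t = dendropy.Tree.get(data=newick, schema="newick")
        t.is_rooted = False
        assert check_outgroup_and_root(t) is None

    def test_four_taxon_cherries(self):
        newick = "((Oryza,Brachypodium),(Sorghum,Zea));"
        t = dendropy.Tree.get(data=newick, schema="newick")
        t.is_rooted = False
        rooted = check_outgroup_and_root(t)
        assert rooted is not None
        assert canonical_topology(rooted) == "((Brachypodium,Oryza),(Sorghum,Zea))"

    def test_missing_outgroup_taxon_raises(self):
        t = dendropy.Tree.get(data="((Oryza,Sorghum),(Zea,Setaria));", schema="newick")
        with pytest.raises(ValueError):
            check_outgroup_and_root(t)


class TestCanonical:
    def test_rotation_invariance(self):
        assert canonical_from_newick("((B,A),(D,C));") == canonical_from_newick("((C,D),(A,B));")

    def test_distinct_topologies_differ(self):
        assert canonical_from_newick("((A,B),(C,D));") != canonical_from_newick("((A,C),(B,D));")

    def test_random_rotations_one_string(self):
        rng = random.Random(23)
        base = dendropy.Tree.get(data=SPECIES_TOPOLOGY, schema="newick")
        base.is_rooted = True
        strings = set()
        for _ in range(100):
            t = base.clone(depth=1)
            for node in t.preorder_internal_node_iter():
                kids = node.child_nodes()
                if rng.random() < 0.5 and len(kids) > 1:
                    for k in kids:
                        node.remove_child(k)
                    for k in reversed(kids):
                        node.add_child(k)
            strings.add(canonical_topology(t))
        assert len(strings) == 1

    def test_duplicate_labels_rejected(self):
        t = dendropy.Tree.get(
            data="((A,A),B);", schema="newick",
            suppress_internal_node_taxa=True, suppress_leaf_node_taxa=True,
        )
        t.is_rooted = True
        for leaf in t.leaf_node_iter():
            leaf.taxon = dendropy.Taxon(label=leaf.label)
        with pytest.raises(ValueError):
            canonical_topology(t)

    def test_idempotence(self):
        c1 = canonical_from_newick(SPECIES_TOPOLOGY)
        assert canonical_from_newick(c1 + ";") == c1


def rooted(newick):
    t = dendropy.Tree.get(data=newick, schema="newick")
    t.is_rooted = True
    return t


class TestCensus:
    def test_tally_and_order(self):
        trees = [
            ("g1", 1, rooted("((A,B),(C,D));")),
            ("g2", 1, rooted("((B,A),(D,C));")),
            ("g3", 1, rooted("((A,B),(C,D));")),
            ("g4", 1, rooted("((A,C),(B,D));")),
            ("g5", 1, rooted("((C,A),(B,D));")),
        ]
        out = census(trees)
        assert [t.count for t in out] == [3, 2]
        assert out[0].canonical == canonical_from_newick("((A,B),(C,D));")

    def test_percentage_truncation_convention(self):
        assert truncate_percent(291, 684) == 42.5
        assert truncate_percent(28, 684) == 4.0
        assert truncate_percent(43, 684) == 6.2
        assert truncate_percent(14159, 34211) == 41.3
        assert truncate_percent(34016, 193422) == 17.5

    def test_empty_census(self):
        assert census([]) == []
        assert census_table([]).empty

    def test_census_table_percent(self):
        trees = [("g", i, rooted("((A,B),(C,D));")) for i in range(3)]
        trees += [("h", 1, rooted("((A,C),(B,D));"))]
        tab = census_table(census(trees))
        assert list(tab["count"]) == [3, 1]
        assert list(tab["percent"]) == [75.0, 25.0]


class TestBootstrap:
    def make_alignments(self, n=3, codons=120):
        from panphylo.synthetic_data import SimConfig, build_species_tree

        tree = build_species_tree(SimConfig(branch_length=0.08))
        alns = []
        for g in range(n):
            rng = np.random.default_rng([7, g])
            root = _random_root_cds(codons, rng)
            node_seq = {id(tree.seed_node): root}
            seqs = {}
            for node in tree.preorder_node_iter():
                if node.parent_node is None:
                    continue
                s = _evolve_branch(node_seq[id(node.parent_node)], node.edge.length, rng)
                node_seq[id(node)] = s
                if node.is_leaf():
                    seqs[node.taxon.label] = _seq_to_str(s)
            a = codon_align(seqs)
            a.mask = np.arange(a.ncol - 3)
            alns.append(a)
        return alns

    def test_supports_bounded_and_deterministic(self):
        from panphylo.tree_topology import bootstrap_support

        alns = self.make_alignments()
        s1 = bootstrap_support(alns, n_trees=2, reps=10, seed=5)
        s2 = bootstrap_support(alns, n_trees=2, reps=10, seed=5)
        assert s1.keys() == s2.keys()
        for topo in s1:
            assert s1[topo] == s2[topo]
            for v in s1[topo].values():
                assert 0.0 <= v <= 100.0

    def test_single_replicate_supports_binary(self):
        from panphylo.tree_topology import bootstrap_support

        alns = self.make_alignments(n=2)
        out = bootstrap_support(alns, n_trees=2, reps=1, seed=3)
        for topo in out:
            assert set(out[topo].values()) <= {0.0, 100.0}

    def test_oversampling_rejected(self):
        from panphylo.tree_topology import bootstrap_support

        with pytest.raises(ValueError):
            bootstrap_support(self.make_alignments(n=2), n_trees=5, reps=1, seed=1)
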