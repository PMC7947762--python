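import itertools

import dendropy
import numpy as np
import pytest

from lporlab import simulate as sim
from lporlab.errors import ValidationError
from lporlab.trees import (
    TreeSet,
    bipartitions,
    clade_frequency,
    is_monophyletic,
    leaf_labels,
    majority_rule_consensus,
)


def tree_of(newick, tns=None):
    return dendropy.Tree.get(data=newick, schema="newick",
                             taxon_namespace=tns or dendropy.TaxonNamespace(),
                             preserve_underscores=True)


# -- exhaustive topology enumeration (oracle machinery) ----------------------

def enumerate_topologies(labels):
    """All unrooted binary topologies over ``labels`` as nested tuples."""
    def attach_all(node, leaf):
        if isinstance(node, str):
            yield (node, leaf)
            return
        for i, child in enumerate(node):
            for sub in attach_all(child, leaf):
                yield tuple(sub if j == i else c for j, c in enumerate(node))
            if not isinstance(child, str):
                yield tuple((child, leaf) if j == i else c
                            for j, c in enumerate(node))

    trees = [tuple(labels[:3])]
    for leaf in labels[3:]:
        trees = [t2 for t in trees for t2 in attach_all(t, leaf)]
    return trees


def oracle_splits(nested, all_labels):
    """Brute-force split enumeration by recursive subtree collection."""
    anchor = min(all_labels)
    out = set()

    def walk(node):
        if isinstance(node, str):
            return frozenset([node])
        below = frozenset()
        for child in node:
            sub = walk(child)
            below |= sub
            side = sub if anchor not in sub else frozenset(all_labels) - sub
            if 0 < len(side) < len(all_labels):
                out.add(side)
        return below

    walk(nested)
    return out


def to_newick(nested):
    def s(n):
        return n if isinstance(n, str) else "(" + ",".join(s(c) for c in n) + ")"
    return s(nested) + ";"


class TestIsMonophyletic:
    def test_simple_quartet(self):
        t = tree_of("((A,B),(C,D));")
        assert is_monophyletic(t, {"A", "B"})
        assert not is_monophyletic(t, {"A", "C"})

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            is_monophyletic(tree_of("((A,B),(C,D));"), {"A", "Z"})

    def test_agrees_with_edge_removal_oracle_on_random_trees(self):
        rng = np.random.default_rng(0)
        labels = [f"x{i}" for i in range(8)]
        for rep in range(30):
            nested = enumerate_topologies(labels)[0]  # deterministic base
            # random topology via the generator machinery instead
            ts = sim.gen_tree_set(labels, set(labels[:3]),
                                  float(rng.integers(0, 2)), 1,
                                  sim.SimConfig(seed=rep))
            t = ts.trees[0]
            splits = bipartitions(t, include_trivial=True)
            for size in (2, 3, 4):
                for clade in itertools.islice(
                        itertools.combinations(labels, size), 12):
                    taxa = frozenset(clade)
                    canon = (taxa if min(labels) not in taxa
                             else frozenset(labels) - taxa)
                    assert is_monophyletic(t, set(clade)) == (canon in splits)


class TestBipartitionsExhaustive:
    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 7])
    def test_matches_bruteforce_on_all_topologies(self, n_leaves):
        labels = [chr(ord("A") + i) for i in range(n_leaves)]
        tns = dendropy.TaxonNamespace()
        for nested in enumerate_topologies(labels):
            t = tree_of(to_newick(nested), tns)
            mine = bipartitions(t, include_trivial=True)
            assert mine == oracle_splits(nested, labels)

    def test_matches_dendropy_encoding(self):
        # independent cross-check against dendropy's own bipartition machinery
        ts = sim.gen_tree_set([f"t{i}" for i in range(9)],
                              {"t0", "t1", "t2"}, 0.5, 20,
                              sim.SimConfig(seed=3))
        for t in ts.trees:
            labels = leaf_labels(t)
            anchor = min(labels)
            t.encode_bipartitions()
            theirs = set()
            for edge in t.preorder_edge_iter():
                if edge.bipartition is None or edge.head_node.parent_node is None:
                    continue
                side = frozenset(
                    x.label for x in
                    edge.bipartition.leafset_taxa(t.taxon_namespace))
                side = side if anchor not in side else labels - side
                if 1 < len(side) < len(labels) - 1:
                    theirs.add(side)
            assert bipartitions(t) == theirs


class TestCladeFrequency:
    def test_all_trees_contain_clade(self):
        ts = TreeSet.from_strings(["((A,B),(C,D));"] * 4)
        assert clade_frequency(ts, {"A", "B"}) == (4, 1.0)

    def test_83_of_100_constructed(self):
        taxa = [f"t{i:02d}" for i in range(12)]
        ts = sim.gen_tree_set(taxa, set(taxa[:4]), 0.83, 100,
                              sim.SimConfig(seed=1))
        assert clade_frequency(ts, set(taxa[:4])) == (83, 0.83)


class TestMajorityRuleConsensus:
    def test_identical_trees_reproduce_topology_with_full_support(self):
        ts = TreeSet.from_strings(["((A,B),(C,(D,E)));"] * 5)
        cons = majority_rule_consensus(ts)
        assert bipartitions(cons) == bipartitions(ts.trees[0])
        internal = [nd.label for nd in cons.preorder_internal_node_iter()
                    if nd.parent_node is not None and nd.label]
        assert all(float(x) == 1.0 for x in internal)

    def test_two_to_one_majority_split(self):
        ts = TreeSet.from_strings(["((A,B),(C,D));", "((A,B),(C,D));",
                                   "((A,C),(B,D));"])
        cons = majority_rule_consensus(ts)
        splits = bipartitions(cons)
        taxa = frozenset("ABCD")
        assert splits == {frozenset({"C", "D"})}  # AB|CD, canonical side CD
        labels = [nd.label for nd in cons.preorder_internal_node_iter()
                  if nd.parent_node is not None]
        assert float(labels[0]) == pytest.approx(2 / 3, abs=1e-4)

    def test_even_conflict_gives_star(self):
        ts = TreeSet.from_strings(["((A,B),(C,D));", "((A,C),(B,D));"])
        cons = majority_rule_consensus(ts, threshold=0.5)
        assert bipartitions(cons) == set()

    def test_supports_match_oracle_recount_and_threshold(self):
        taxa = [f"t{i}" for i in range(8)]
        ts = sim.gen_tree_set(taxa, {"t0", "t1", "t2"}, 0.7, 20,
                              sim.SimConfig(seed=5))
        cons = majority_rule_consensus(ts)
        tally: dict = {}
        for t in ts.trees:
            for s in bipartitions(t):
                tally[s] = tally.get(s, 0) + 1
        for split in bipartitions(cons):
            assert tally[split] / len(ts) > 0.5
        for split, count in tally.items():
            if count / len(ts) > 0.5:
                assert split in bipartitions(cons)

    def test_permutation_invariance(self):
        taxa = [f"t{i}" for i in range(7)]
        ts = sim.gen_tree_set(taxa, {"t0", "t1"}, 0.8, 10, sim.SimConfig(seed=6))
        rev = TreeSet(list(reversed(ts.trees)))
        a = bipartitions(majority_rule_consensus(ts))
        b = bipartitions(majority_rule_consensus(rev))
        assert a == b

    def test_agrees_with_dendropy_consensus(self):
        taxa = [f"t{i}" for i in range(9)]
        ts = sim.gen_tree_set(taxa, {"t0", "t1", "t2", "t3"}, 0.6, 25,
                              sim.SimConfig(seed=7))
        mine = bipartitions(majority_rule_consensus(ts))
        tl = dendropy.TreeList(ts.trees,
                               taxon_namespace=ts.trees[0].taxon_namespace)
        theirs_tree = tl.consensus(min_freq=0.5)
        theirs = bipartitions(theirs_tree)
        assert mine == theirs

    def test_low_threshold_rejected(self):
        ts = TreeSet.from_strings(["((A,B),(C,D));"])
        with pytest.raises(ValidationError):
            majority_rule_consensus(ts, threshold=0.3)


def test_tree_set_label_mismatch_rejected():
    with pytest.raises(ValidationError):
        TreeSet.from_strings(["((A,B),(C,D));", "((A,B),(C,E));"])
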