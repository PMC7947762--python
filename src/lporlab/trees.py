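"""Clade support over tree collections and majority-rule consensus.

Reproduces "monophyletic in all 100 trees" / "83 out of 100 trees" style
statements: given a set of unrooted trees over one taxon set, count in how
many trees a label set forms a clade (i.e. appears as one side of an edge
bipartition), and build the majority-rule consensus containing exactly the
bipartitions occurring in more than a threshold fraction of the trees.

Trees are parsed from newick with dendropy (one tree per line; quoted
labels, branch lengths and support annotations are tolerated and ignored
for topology); bipartition extraction, counting and consensus construction
are implemented here directly so they can be checked against independent
oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy

from .errors import ValidationError

__all__ = [
    "TreeSet",
    "leaf_labels",
    "bipartitions",
    "is_monophyletic",
    "clade_frequency",
    "majority_rule_consensus",
]


@dataclass
class TreeSet:
    """A collection of trees over a shared taxon label set."""

    trees: list[dendropy.Tree]

    def __post_init__(self) -> None:
        if not self.trees:
            raise ValidationError("empty tree set")
        ref = leaf_labels(self.trees[0])
        for i, t in enumerate(self.trees[1:], start=2):
            if leaf_labels(t) != ref:
                raise ValidationError(f"tree {i} has a different taxon set")

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def taxa(self) -> frozenset[str]:
        return leaf_labels(self.trees[0])

    @classmethod
    def from_newick(cls, path) -> "TreeSet":
        tns = dendropy.TaxonNamespace()
        trees = dendropy.TreeList.get(path=str(Path(path)), schema="newick",
                                      taxon_namespace=tns,
                                      preserve_underscores=True)
        return cls(list(trees))

    @classmethod
    def from_strings(cls, newicks: list[str]) -> "TreeSet":
        tns = dendropy.TaxonNamespace()
        return cls([
            dendropy.Tree.get(data=s, schema="newick", taxon_namespace=tns,
                              preserve_underscores=True)
            for s in newicks
        ])

    def to_newick(self, path) -> None:
        with open(path, "w") as fh:
            for t in self.trees:
                fh.write(t.as_string(schema="newick",
                                     suppress_rooting=True).strip() + "\n")


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


def _canonical(side: frozenset[str], taxa: frozenset[str]) -> frozenset[str]:
    """Canonical representation of the split side|rest: the side that does
    NOT contain the anchor (lexicographically smallest label)."""
    anchor = min(taxa)
    return taxa - side if anchor in side else side


def bipartitions(tree: dendropy.Tree,
                 include_trivial: bool = False) -> set[frozenset[str]]:
    """All edge-induced leaf-set splits of the (unrooted) tree, canonicalized.

    Nontrivial splits separate >= 2 leaves on each side; trivial (single-leaf)
    splits are included on request.  Rooted input is treated as unrooted:
    the root edge contributes no split.
    """
    taxa = leaf_labels(tree)
    n = len(taxa)
    splits: set[frozenset[str]] = set()
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in
                                              node.child_nodes()))
        if node.parent_node is None:
            continue
        side = below[node]
        k = len(side)
        if k == 0 or k == n:
            continue
        if not include_trivial and (k == 1 or k == n - 1):
            continue
        splits.add(_canonical(side, taxa))
    return splits


def is_monophyletic(tree: dendropy.Tree, taxa: set[str]) -> bool:
    """True iff ``taxa`` forms one side of an edge bipartition of the
    unrooted tree."""
    clade = frozenset(taxa)
    leaves = leaf_labels(tree)
    unknown = clade - leaves
    if unknown:
        raise ValidationError(f"labels not in tree: {sorted(unknown)}")
    if not (2 <= len(clade) < len(leaves)):
        raise ValidationError("clade must have >= 2 taxa and exclude >= 1")
    return _canonical(clade, leaves) in bipartitions(tree, include_trivial=True)


def clade_frequency(trees: TreeSet, taxa: set[str]) -> tuple[int, float]:
    """(count, proportion) of trees in which ``taxa`` is monophyletic."""
    count = sum(is_monophyletic(t, taxa) for t in trees.trees)
    return count, count / len(trees)


def majority_rule_consensus(trees: TreeSet, threshold: float = 0.5
                            ) -> dendropy.Tree:
    """Majority-rule consensus: exactly the nontrivial bipartitions present
    in strictly more than ``threshold`` of the trees, each annotated with its
    frequency as the internal node label.  For threshold >= 0.5 the retained
    splits are pairwise compatible, so the consensus always exists.
    """
    if threshold < 0.5:
        raise ValidationError("threshold must be >= 0.5")
    n = len(trees)
    taxa = trees.taxa
    tally: dict[frozenset[str], int] = {}
    for t in trees.trees:
        for split in bipartitions(t):
            tally[split] = tally.get(split, 0) + 1
    kept = {s: c / n for s, c in tally.items() if c / n > threshold}

    # splits excluding the anchor with frequency > 0.5 form a laminar family:
    # build the containment tree directly
    children: dict[frozenset[str] | None, list[frozenset[str]]] = {None: []}
    for split in sorted(kept, key=len, reverse=True):
        parent = None
        changed = True
        while changed:
            changed = False
            for cand in children.get(parent, []):
                if split < cand:
                    parent = cand
                    changed = True
                    break
        children.setdefault(parent, []).append(split)
        # re-home smaller siblings that belong inside the new split
        sibs = children[parent]
        inside = [s for s in sibs if s is not split and s < split]
        for s in inside:
            sibs.remove(s)
            children.setdefault(split, []).append(s)

    def newick(group: frozenset[str] | None, members: frozenset[str]) -> str:
        subs = children.get(group, [])
        covered = frozenset().union(*subs) if subs else frozenset()
        parts = [newick(s, s) for s in subs]
        parts += sorted(_quote(x) for x in members - covered)
        label = "" if group is None else f"{kept[group]:.4g}"
        return "(" + ",".join(parts) + ")" + label

    def _quote(label: str) -> str:
        return f"'{label}'" if any(c in label for c in " ():,;[]'") else label

    text = newick(None, taxa) + ";"
    return dendropy.Tree.get(data=text, schema="newick",
                             preserve_underscores=True)
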