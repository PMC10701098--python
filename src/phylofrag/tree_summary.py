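"""Summaries of a tree set: greedy consensus, node conflict, quartet tree.

Clades are counted as rooted clusters after rooting every tree on a fixed
outgroup (the study design fixes the outgroup, and rooted clusters match
SumTrees-style summarization).  The greedy consensus accepts clades in
descending frequency order whenever they are compatible with the clades
already accepted, with no minimum-frequency cutoff; ties break
deterministically (smaller clade first, then lexicographically smallest
member).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from ._trees import (Node, as_node, bipartitions, clusters, compatible,
                     leaf_path_distances, quartet_resolution_from_distances,
                     root_on_outgroup, tree_from_laminar)


@dataclass
class CladeTable:
    """Clade (frozen leaf set) counts over a tree set.

    ``denoms`` gives, per clade, the number of trees containing all of the
    clade's members (equal to ``n_trees`` for complete tree sets), so that
    frequencies stay meaningful for pruned tree sets.
    """

    counts: dict[frozenset, int]
    n_trees: int
    denoms: dict[frozenset, int]
    outgroup: Optional[str] = None
    ingroup: frozenset = frozenset()

    def frequency(self, clade: frozenset) -> float:
        denom = self.denoms.get(clade, self.n_trees)
        return self.counts.get(clade, 0) / denom if denom else 0.0


def clade_frequencies(ts, outgroup: str) -> CladeTable:
    """Tally every nontrivial rooted clade after outgroup rooting."""
    counts: dict[frozenset, int] = {}
    leafsets: list[frozenset] = []
    ingroup: frozenset = frozenset()
    n = 0
    for t in ts:
        node = as_node(t)
        leaves = node.leaves()
        if outgroup not in leaves:
            raise ValueError(f"outgroup {outgroup!r} missing from tree {n}")
        rooted = root_on_outgroup(node, outgroup)
        ing = leaves - {outgroup}
        ingroup = ingroup | ing
        leafsets.append(ing)
        seen = set()
        for cl in clusters(rooted, nontrivial=False):
            cl = cl - {outgroup}
            if 2 <= len(cl) <= len(ing) and cl not in seen:
                seen.add(cl)
                counts[cl] = counts.get(cl, 0) + 1
        n += 1
    complete = all(ls == ingroup for ls in leafsets)
    if complete:
        denoms = {cl: n for cl in counts}
    else:
        denoms = {cl: sum(1 for ls in leafsets if cl <= ls) for cl in counts}
    return CladeTable(counts, n, denoms, outgroup, ingroup)


@dataclass
class ConsensusTree:
    """Rooted consensus with per-clade frequency support in [0, 1]."""

    tree: Node  # rooted over ingroup + outgroup
    support: dict[frozenset, float]
    outgroup: Optional[str]
    ingroup: frozenset

    def newick(self) -> str:
        return self.tree.newick(lengths=False, support=self._support_by_cluster())

    def _support_by_cluster(self) -> dict[frozenset, float]:
        # tree clusters include the outgroup-free clades directly
        return dict(self.support)

    def clades(self) -> list[frozenset]:
        return sorted(self.support, key=lambda c: (-len(c), sorted(c)))


def greedy_consensus(ct: CladeTable) -> ConsensusTree:
    """Accept clades in descending count order whenever laminar-compatible."""
    if not ct.counts:
        raise ValueError("empty clade table")
    order = sorted(ct.counts,
                   key=lambda cl: (-ct.counts[cl], len(cl), sorted(cl)))
    accepted: list[frozenset] = []
    for cl in order:
        if compatible(cl, accepted):
            accepted.append(cl)
    tree = tree_from_laminar(accepted, ct.ingroup)
    if ct.outgroup is not None:
        tree = Node(None, [Node(ct.outgroup), tree])
    support = {cl: ct.frequency(cl) for cl in accepted}
    return ConsensusTree(tree, support, ct.outgroup, ct.ingroup)


@dataclass
class ConflictSummary:
    """Per consensus node: concordant / top-alternative / other counts."""

    table: pd.DataFrame
    n_trees: int


def node_conflict(c: ConsensusTree, ts) -> ConflictSummary:
    """PhyParts-style decomposition of support at every consensus clade.

    For each consensus clade X, a tree is concordant if it contains X;
    otherwise the tree's alternative is its smallest clade properly
    overlapping X (ties break on the lexicographically smallest member
    set), and the most frequent alternative is reported separately from
    the remainder.
    """
    trees = [root_on_outgroup(as_node(t), c.outgroup) if c.outgroup else as_node(t)
             for t in ts]
    tree_clusters = []
    for t in trees:
        cls = set()
        for cl in clusters(t, nontrivial=False):
            cls.add(cl - {c.outgroup} if c.outgroup else cl)
        tree_clusters.append(cls)
    n = len(trees)

    rows = []
    for clade in c.clades():
        conc = 0
        alts: dict[frozenset, int] = {}
        for cls in tree_clusters:
            if clade in cls:
                conc += 1
                continue
            conflicting = [x for x in cls
                           if (x & clade) and not (x <= clade or clade <= x)]
            if conflicting:
                alt = min(conflicting, key=lambda x: (len(x), sorted(x)))
            else:
                alt = frozenset()
            alts[alt] = alts.get(alt, 0) + 1
        if alts:
            top_alt, top_count = min(alts.items(),
                                     key=lambda kv: (-kv[1], sorted(kv[0])))
        else:
            top_alt, top_count = frozenset(), 0
        rows.append({
            "clade": ",".join(sorted(clade)),
            "concordant": conc,
            "top_alternative": top_count,
            "top_alternative_clade": ",".join(sorted(top_alt)),
            "other": n - conc - top_count,
        })
    return ConflictSummary(pd.DataFrame(rows), n)


# ---------------------------------------------------------------------------
# exhaustive maximum-quartet-support species tree


def _enumerate_unrooted(labels: list[str]) -> list[Node]:
    """All unrooted binary topologies over labels (labels sorted first)."""
    labels = sorted(labels)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    base = Node(None, [Node(labels[0]), Node(labels[1]), Node(labels[2])])
    trees = [base]
    for lab in labels[3:]:
        new_trees = []
        for t in trees:
            edges = [n for n in t.postorder() if n is not t]
            for k in range(len(edges)):
                t2 = t.copy()
                edges2 = [n for n in t2.postorder() if n is not t2]
                target = edges2[k]
                # replace target by (target, new_leaf)
                parent = next(p for p in t2.postorder() if target in p.children)
                idx = parent.children.index(target)
                parent.children[idx] = Node(None, [target, Node(lab)])
                new_trees.append(t2)
        trees = new_trees
    return trees


def quartet_species_tree(ts, max_taxa: int = 10
                         ) -> tuple[Node, float, list[Node]]:
    """Exhaustive maximum-quartet-support species tree for small taxon sets.

    Scores every unrooted binary topology by the number of induced quartets
    it shares with the trees in the set and returns the argmax together
    with the normalized score (score / (n_trees x n_quartets)) and the list
    of co-optimal topologies (ties).  Statistically consistent under the
    MSC; intended for taxon sets of at most ``max_taxa``.
    """
    nodes = [as_node(t) for t in ts]
    labels = sorted(set().union(*(n.leaves() for n in nodes)))
    if len(labels) > max_taxa:
        raise ValueError(
            f"{len(labels)} taxa exceed exhaustive search limit {max_taxa}")
    quartets = list(itertools.combinations(labels, 4))

    # tally observed quartet resolutions over the tree set
    counts: dict[tuple, dict[frozenset, int]] = {q: {} for q in quartets}
    for n in nodes:
        d = leaf_path_distances(n, topological=True)
        present = n.leaves()
        for q in quartets:
            if not set(q) <= present:
                continue
            res = quartet_resolution_from_distances(d, *q)
            if res is not None:
                counts[q][res] = counts[q].get(res, 0) + 1

    best_score = -1
    best: list[Node] = []
    for cand in _enumerate_unrooted(labels):
        d = leaf_path_distances(cand, topological=True)
        score = 0
        for q in quartets:
            res = quartet_resolution_from_distances(d, *q)
            score += counts[q].get(res, 0)
        if score > best_score:
            best_score = score
            best = [cand]
        elif score == best_score:
            best.append(cand)
    norm = best_score / (len(nodes) * len(quartets)) if nodes and quartets else 0.0
    return best[0], norm, best
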