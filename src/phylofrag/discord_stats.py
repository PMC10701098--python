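"""Discordance statistics over a tree set.

Four complementary views of gene-tree heterogeneity: a census of unique
unrooted topologies, the leaf stability index (LSI) of each taxon, branch
attachment frequencies (BAF) of a focal taxon against the consensus, and
threshold-filtered split frequencies from a random subsample (the analytic
content of a consensus network, without the layout).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._trees import (Node, as_node, bipartitions, canonical_split, clusters,
                     split_weights, topology_key, triplet_resolution)
from .tree_summary import ConsensusTree


@dataclass
class TopologyCensus:
    counts: dict[tuple, int]
    n_trees: int

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def frequencies(self) -> list[float]:
        return sorted((c / self.n_trees for c in self.counts.values()),
                      reverse=True)


def count_topologies(ts) -> TopologyCensus:
    """Census of unique unrooted topologies (branch lengths stripped)."""
    counts: dict[tuple, int] = {}
    n = 0
    for t in ts:
        key = topology_key(as_node(t))
        counts[key] = counts.get(key, 0) + 1
        n += 1
    return TopologyCensus(counts, n)


def leaf_stability_index(ts, taxon: str, variant: str = "max") -> float:
    """Mean over taxon pairs of the modal rooted-triplet resolution frequency.

    For every unordered pair {x, y} of other taxa, the three resolutions of
    the rooted triplet {taxon, x, y} are tallied over the trees containing
    all three leaves; the ``max`` variant (default, range [1/3, 1]) averages
    the maximum resolution frequency, the ``difference`` variant averages
    (max - second).  Trees are used as rooted, so root them on the study
    outgroup beforehand; prune the outgroup leaf as well if the index
    should average over ingroup triplets only (rooted triplets containing
    the outgroup are resolved by the rooting itself and dilute the signal).
    """
    if variant not in ("max", "difference"):
        raise ValueError(f"unknown LSI variant {variant!r}")
    nodes = [as_node(t) for t in ts]
    others = sorted(set().union(*(n.leaves() for n in nodes)) - {taxon})
    if not any(taxon in n.leaves() for n in nodes):
        raise ValueError(f"taxon {taxon!r} absent from every tree")

    per_pair = []
    for x, y in itertools.combinations(others, 2):
        tallies = {frozenset((taxon, x)): 0, frozenset((taxon, y)): 0,
                   frozenset((x, y)): 0}
        denom = 0
        for n in nodes:
            leaves = n.leaves()
            if not {taxon, x, y} <= leaves:
                continue
            denom += 1
            res = triplet_resolution(n, taxon, x, y)
            if res is not None:
                tallies[res] += 1
        if denom == 0:
            continue
        freqs = sorted((c / denom for c in tallies.values()), reverse=True)
        per_pair.append(freqs[0] if variant == "max" else freqs[0] - freqs[1])
    return float(np.mean(per_pair))


@dataclass
class BAFTable:
    """Attachment counts of a focal taxon onto consensus edges."""

    taxon: str
    counts: dict[frozenset, int]  # consensus-minus-taxon edge -> count
    unmapped: int
    n_trees: int  # trees containing the taxon

    def table(self) -> pd.DataFrame:
        rows = [{"edge": ",".join(sorted(e)), "count": c,
                 "frequency": c / self.n_trees}
                for e, c in sorted(self.counts.items(),
                                   key=lambda kv: -kv[1])]
        rows.append({"edge": "(unmapped)", "count": self.unmapped,
                     "frequency": self.unmapped / self.n_trees})
        return pd.DataFrame(rows)


def _attachment_split(node: Node, taxon: str) -> Optional[frozenset]:
    """Bipartition of the remaining leaves defined by the taxon's attachment."""
    parent = None
    target = None
    for n in node.postorder():
        for c in n.children:
            if c.is_leaf and c.label == taxon:
                parent, target = n, c
    if target is None:
        return None
    rest = node.leaves() - {taxon}
    side = frozenset(x.label for x in parent.postorder()
                     if x.is_leaf and x.label != taxon)
    if len(side) == len(rest):  # degenerate: parent is the root
        kids = [c for c in parent.children if c is not target]
        side = frozenset(x.label for k in kids for x in k.postorder() if x.is_leaf)
    return canonical_split(side, rest)


def branch_attachment_frequencies(ts, c: ConsensusTree, taxon: str) -> BAFTable:
    """Count where a taxon attaches, mapped onto consensus edges.

    Per local tree the taxon is removed; its former attachment defines a
    bipartition of the remaining leaves.  Exact matches against edges of
    the consensus-minus-taxon are counted per edge, everything else is
    ``unmapped`` (near-miss assignment would require an arbitrary metric).
    """
    cons = c.tree.copy()
    # remove taxon from the consensus and collect its edge bipartitions
    cons_minus = _prune_taxon(cons, taxon)
    rest = cons_minus.leaves()
    edges = set()
    for cl in clusters(cons_minus, nontrivial=False):
        if 1 <= len(cl) <= len(rest) - 1:
            edges.add(canonical_split(cl, rest))
    for leaf in rest:  # pendant edges
        edges.add(canonical_split(frozenset([leaf]), rest))

    counts: dict[frozenset, int] = {}
    unmapped = 0
    n_with = 0
    for t in ts:
        node = as_node(t)
        if taxon not in node.leaves():
            continue
        n_with += 1
        split = _attachment_split(node, taxon)
        split = frozenset(split & rest) if split is not None else None
        if split is not None and canonical_split(split, rest) in edges:
            key = canonical_split(split, rest)
            counts[key] = counts.get(key, 0) + 1
        else:
            unmapped += 1
    return BAFTable(taxon, counts, unmapped, n_with)


def _prune_taxon(tree: Node, taxon: str) -> Node:
    """Remove one leaf and suppress the resulting unifurcation."""
    def prune(n: Node) -> Optional[Node]:
        if n.is_leaf:
            return None if n.label == taxon else n
        kids = [k for k in (prune(c) for c in n.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1 and n.children != kids:
            only = kids[0]
            if only.length is not None or n.length is not None:
                only.length = (only.length or 0.0) + (n.length or 0.0)
            return only
        n.children = kids
        return n

    out = prune(tree.copy())
    if out is None:
        raise ValueError(f"tree contains only {taxon!r}")
    while not out.is_leaf and len(out.children) == 1:
        out = out.children[0]
    return out


@dataclass
class SplitTable:
    table: pd.DataFrame  # columns: split, frequency, median_weight
    n_sampled: int


def frequent_splits(ts, subsample: float = 0.2, threshold: float = 0.2,
                    seed: int = 0) -> SplitTable:
    """Split frequencies over a random subsample, thresholded for inclusion.

    Tallies unrooted bipartitions over a random ``subsample`` fraction of
    the tree set and keeps those with frequency >= ``threshold``, reporting
    the median branch length (edge weight) of each retained split.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    trees = list(ts)
    rng = np.random.default_rng(seed)
    m = max(1, int(round(subsample * len(trees))))
    idx = rng.choice(len(trees), size=m, replace=False)
    tally: dict[frozenset, int] = {}
    weights: dict[frozenset, list[float]] = {}
    for i in idx:
        node = as_node(trees[i])
        for bp, w in split_weights(node).items():
            tally[bp] = tally.get(bp, 0) + 1
            weights.setdefault(bp, []).append(w)
    rows = []
    for bp, cnt in tally.items():
        freq = cnt / m
        if freq >= threshold:
            rows.append({"split": ",".join(sorted(bp)),
                         "frequency": freq,
                         "median_weight": float(np.median(weights[bp]))})
    rows.sort(key=lambda r: -r["frequency"])
    return SplitTable(pd.DataFrame(rows), m)
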