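"""Distance matrices and neighbor-joining trees, per window and genome-wide.

Distances are uncorrected p-distances with pairwise deletion: a site counts
for a pair only when both residues are in {A,C,G,T}.  The genome-wide matrix
is by default the ratio of summed mismatch and comparable-site counts, which
equals the p-distance of the concatenated alignment; the literal sum of
per-window fractional distances is kept behind a flag.

Neighbor joining follows Saitou & Nei's Q-criterion with a deterministic
tie-break (lexicographically smallest label pair).  Negative estimated
branch lengths are retained (with a warning) so that additivity identities
hold exactly; clamping is offered as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._trees import Node, root_on_outgroup, as_node
from .genome_windows import WindowAlignment


class UndefinedDistanceError(ValueError):
    """A pair of samples shares no comparable sites."""


@dataclass
class DistanceMatrix:
    """Pairwise mismatch and comparable-site counts with derived distances."""

    labels: list[str]
    diffs: np.ndarray  # (n, n) float
    comps: np.ndarray  # (n, n) float
    is_counts: bool = True  # False for wrapped plain distances

    def __post_init__(self):
        n = len(self.labels)
        self.diffs = np.asarray(self.diffs, dtype=float)
        self.comps = np.asarray(self.comps, dtype=float)
        if self.diffs.shape != (n, n) or self.comps.shape != (n, n):
            raise ValueError("matrix shapes must match labels")
        if not np.allclose(self.diffs, self.diffs.T):
            raise ValueError("diffs must be symmetric")
        if self.is_counts and (self.diffs > self.comps + 1e-9).any():
            raise ValueError("comparable counts must be >= differences")

    @property
    def n(self) -> int:
        return len(self.labels)

    def distances(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(self.comps > 0, self.diffs / np.maximum(self.comps, 1e-300),
                         np.nan)
        np.fill_diagonal(d, 0.0)
        return d

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                if self.comps[i, j] == 0:
                    out.append((self.labels[i], self.labels[j]))
        return out

    @classmethod
    def from_distances(cls, labels: Sequence[str], d: np.ndarray
                       ) -> "DistanceMatrix":
        """Wrap a plain distance matrix (unit comparable counts)."""
        d = np.asarray(d, dtype=float)
        return cls(list(labels), d, np.ones_like(d), is_counts=False)


def pairwise_distances(w: WindowAlignment) -> DistanceMatrix:
    """p-distance with pairwise deletion over one window alignment."""
    if len(w.samples) < 3:
        raise ValueError("need at least 3 samples")
    mat = w.matrix
    valid = mat < 4
    n = len(w.samples)
    diffs = np.zeros((n, n))
    comps = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            c = int(both.sum())
            d = int((mat[i, both] != mat[j, both]).sum())
            comps[i, j] = comps[j, i] = c
            diffs[i, j] = diffs[j, i] = d
    dm = DistanceMatrix(list(w.samples), diffs, comps)
    dead = [s for k, s in enumerate(w.samples) if not valid[k].any()]
    if dead:
        raise UndefinedDistanceError(
            f"samples with no callable sites: {dead}")
    return dm


def genome_distance(ms: Sequence[DistanceMatrix],
                    mode: str = "ratio_of_sums") -> DistanceMatrix:
    """Combine per-window matrices into one genome-wide matrix.

    ``ratio_of_sums`` divides summed mismatches by summed comparable sites
    (site-weighted; equals the concatenation p-distance).  The literal
    ``sum_of_distances`` mode adds the per-window fractional distances.
    """
    if not ms:
        raise ValueError("no matrices given")
    labels = ms[0].labels
    for m in ms[1:]:
        if m.labels != labels:
            raise ValueError("taxa mismatch across matrices")
    if mode == "ratio_of_sums":
        diffs = sum(m.diffs for m in ms)
        comps = sum(m.comps for m in ms)
        return DistanceMatrix(list(labels), diffs, comps)
    if mode == "sum_of_distances":
        total = np.sum([m.distances() for m in ms], axis=0)
        return DistanceMatrix.from_distances(labels, total)
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(d: DistanceMatrix, clamp_negative: bool = False) -> Node:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    Ties in the Q-criterion break on the lexicographically smallest label
    pair, making the result deterministic.  Negative branch-length
    estimates are retained with a warning unless ``clamp_negative``.
    """
    if d.n < 3:
        raise ValueError("need at least 3 taxa")
    if d.undefined_pairs():
        raise UndefinedDistanceError(
            f"undefined distances for pairs: {d.undefined_pairs()}")

    dist = d.distances().copy()
    nodes = [Node(lab) for lab in d.labels]
    reps = list(d.labels)  # smallest leaf label under each active node
    active = list(range(d.n))
    negative = False

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(dist[i, j] for j in active if j != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * dist[i, j] - sums[i] - sums[j]
                pair = tuple(sorted((reps[i], reps[j])))
                if q < best_q - 1e-12 or (abs(q - best_q) <= 1e-12 and
                                          (best is None or pair < best[2])):
                    best_q = q
                    best = (i, j, pair)
        i, j, _ = best
        li = 0.5 * dist[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = dist[i, j] - li
        if li < 0 or lj < 0:
            negative = True
        new = Node(None, [nodes[i], nodes[j]])
        nodes[i].length = li
        nodes[j].length = lj
        # new row
        newdist = np.zeros(len(nodes) + 1)
        for k in active:
            if k in (i, j):
                continue
            newdist[k] = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
        dist = np.pad(dist, ((0, 1), (0, 1)))
        dist[-1, :len(newdist)] = newdist
        dist[:len(newdist), -1] = newdist
        nodes.append(new)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    li = 0.5 * (dist[i, j] + dist[i, k] - dist[j, k])
    lj = 0.5 * (dist[i, j] + dist[j, k] - dist[i, k])
    lk = 0.5 * (dist[i, k] + dist[j, k] - dist[i, j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        if length < 0:
            negative = True
        nodes[idx].length = length
    root = Node(None, [nodes[i], nodes[j], nodes[k]])

    if negative:
        if clamp_negative:
            for n in root.postorder():
                if n.length is not None and n.length < 0:
                    n.length = 0.0
        else:
            warnings.warn("negative branch lengths retained in NJ tree",
                          stacklevel=2)
    return root


def root_with_outgroup(t, taxon: str) -> Node:
    """Root an (un)rooted tree on the outgroup's pendant edge."""
    return root_on_outgroup(t, taxon)


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_genome_tree(ms: Sequence[DistanceMatrix], B: int = 100,
                          seed: int = 0, mode: str = "ratio_of_sums"
                          ) -> tuple[Node, dict[frozenset, float]]:
    """Genome NJ tree with bootstrap % support over the window matrices.

    Resamples the matrix list with replacement B times; support of each
    bipartition of the full-data tree is the percentage of replicates whose
    NJ tree contains it.  Returns ``(tree, support)`` where support maps
    canonical bipartitions to percentages; the tree's internal node labels
    carry the same numbers when written to Newick via
    :func:`support_newick`.
    """
    from ._trees import bipartitions

    if len(ms) < 2:
        raise ValueError("need at least 2 matrices to bootstrap")
    rng = np.random.default_rng(seed)
    main = nj_tree(genome_distance(ms, mode=mode))
    target = bipartitions(main)
    hits = {bp: 0 for bp in target}
    for _ in range(B):
        idx = rng.integers(0, len(ms), size=len(ms))
        rep = nj_tree(genome_distance([ms[i] for i in idx], mode=mode))
        found = bipartitions(rep)
        for bp in target:
            if bp in found:
                hits[bp] += 1
    support = {bp: 100.0 * h / B for bp, h in hits.items()}
    return main, support


def support_newick(tree: Node, support: dict[frozenset, float]) -> str:
    """Newick string with bipartition support as internal node labels."""
    from ._trees import canonical_split

    all_leaves = tree.leaves()

    def fmt(n: Node) -> str:
        if n.is_leaf:
            s = n.label
        else:
            s = "(" + ",".join(fmt(c) for c in n.children) + ")"
            cl = frozenset(x.label for x in n.postorder() if x.is_leaf)
            key = canonical_split(cl, all_leaves)
            if key in support and n is not tree:
                s += f"{support[key]:g}"
        if n.length is not None:
            s += f":{n.length:g}"
        return s

    return fmt(tree) + ";"


@dataclass
class TreeSet:
    """An ordered collection of trees over a shared label universe."""

    trees: list
    provenance: Optional[list] = None

    def __post_init__(self):
        if self.provenance is None:
            self.provenance = list(range(len(self.trees)))

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def nodes(self) -> list[Node]:
        return [as_node(t) for t in self.trees]

    def universe(self) -> frozenset:
        out: frozenset = frozenset()
        for t in self.trees:
            out = out | as_node(t).leaves()
        return out
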