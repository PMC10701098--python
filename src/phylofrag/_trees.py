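"""Lightweight rooted/unrooted tree primitives shared across modules.

All discordance and consensus statistics reduce to set operations on leaf
clusters (rooted) or bipartitions (unrooted).  This module provides a minimal
``Node`` structure plus those operations, with converters to and from
dendropy trees so that Newick I/O goes through an established parser.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import dendropy


class Node:
    """A tree node: ``label`` on leaves, ``length`` of the subtending edge."""

    __slots__ = ("label", "children", "length")

    def __init__(self, label: Optional[str] = None, children: Optional[list] = None,
                 length: Optional[float] = None):
        self.label = label
        self.children: list[Node] = children if children is not None else []
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> frozenset:
        return frozenset(n.label for n in self.postorder() if n.is_leaf)

    def newick(self, lengths: bool = True, support: Optional[dict] = None) -> str:
        def fmt(n: Node) -> str:
            if n.is_leaf:
                s = n.label
            else:
                s = "(" + ",".join(fmt(c) for c in n.children) + ")"
                if support is not None:
                    key = frozenset(x.label for x in n.postorder() if x.is_leaf)
                    if key in support:
                        s += f"{support[key]:.4f}"
                elif n.label:
                    s += n.label
            if lengths and n.length is not None:
                s += f":{n.length:g}"
            return s

        return fmt(self) + ";"

    def copy(self) -> "Node":
        n = Node(self.label, [c.copy() for c in self.children], self.length)
        return n

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.newick(lengths=False)})"


# ---------------------------------------------------------------------------
# conversion

def from_dendropy(tree: "dendropy.Tree") -> Node:
    def conv(dnode) -> Node:
        if dnode.is_leaf():
            lab = dnode.taxon.label if dnode.taxon is not None else dnode.label
            return Node(lab, length=dnode.edge.length)
        kids = [conv(c) for c in dnode.child_nodes()]
        return Node(dnode.label, kids, dnode.edge.length)

    return conv(tree.seed_node)


def to_dendropy(node: Node, taxon_namespace: Optional[dendropy.TaxonNamespace] = None
                ) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=node.newick(), schema="newick",
                             taxon_namespace=taxon_namespace,
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    return tree


def parse_newick(newick: str) -> Node:
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True,
                             suppress_internal_node_taxa=True)
    return from_dendropy(tree)


def as_node(tree) -> Node:
    """Coerce a dendropy Tree, Newick string, or Node into a Node."""
    if isinstance(tree, Node):
        return tree
    if isinstance(tree, dendropy.Tree):
        return from_dendropy(tree)
    if isinstance(tree, str):
        return parse_newick(tree)
    if hasattr(tree, "as_node"):
        return tree.as_node()
    raise TypeError(f"cannot interpret {type(tree).__name__} as a tree")


# ---------------------------------------------------------------------------
# clusters / bipartitions

def clusters(node: Node, nontrivial: bool = True) -> list[frozenset]:
    """Rooted leaf clusters, one per internal node (excluding the root set)."""
    all_leaves = node.leaves()
    out = []
    memo: dict[int, frozenset] = {}
    for n in node.postorder():
        if n.is_leaf:
            memo[id(n)] = frozenset([n.label])
        else:
            cl = frozenset().union(*(memo[id(c)] for c in n.children))
            memo[id(n)] = cl
            if not nontrivial or (1 < len(cl) < len(all_leaves)):
                out.append(cl)
    return out


def canonical_split(side: frozenset, all_leaves: frozenset) -> frozenset:
    """Represent a bipartition by the side containing the smallest label."""
    anchor = min(all_leaves)
    return side if anchor in side else all_leaves - side


def bipartitions(tree, nontrivial: bool = True) -> set[frozenset]:
    """Unrooted bipartitions as canonical frozensets."""
    node = as_node(tree)
    all_leaves = node.leaves()
    out = set()
    for cl in clusters(node, nontrivial=False):
        lo, hi = (2, len(all_leaves) - 2) if nontrivial else (1, len(all_leaves) - 1)
        if lo <= len(cl) <= hi or lo <= len(all_leaves - cl) <= hi:
            if min(len(cl), len(all_leaves - cl)) >= (2 if nontrivial else 1):
                out.add(canonical_split(cl, all_leaves))
    return out


def split_weights(tree) -> dict[frozenset, float]:
    """Branch length of each nontrivial bipartition (root-adjacent lengths summed)."""
    node = as_node(tree)
    all_leaves = node.leaves()
    weights: dict[frozenset, float] = {}
    for n in node.postorder():
        if n is node:
            continue
        cl = frozenset(x.label for x in n.postorder() if x.is_leaf)
        if min(len(cl), len(all_leaves - cl)) < 2:
            continue
        key = canonical_split(cl, all_leaves)
        weights[key] = weights.get(key, 0.0) + (n.length or 0.0)
    return weights


def topology_key(tree) -> tuple:
    """Canonical hashable key for an unrooted topology (lengths ignored)."""
    node = as_node(tree)
    all_leaves = node.leaves()
    splits = frozenset(bipartitions(node))
    return (all_leaves, splits)


# ---------------------------------------------------------------------------
# rooting

def root_on_outgroup(tree, outgroup: str) -> Node:
    """Return a tree rooted such that ``outgroup`` is a child of the root.

    The root is placed on the outgroup's pendant edge, with the pendant
    length kept on the outgroup side, so all leaf-to-leaf path lengths are
    preserved.  Former degree-two root nodes are suppressed.
    """
    node = as_node(tree)
    if outgroup not in node.leaves():
        raise ValueError(f"outgroup {outgroup!r} not among leaves")

    # undirected adjacency over the original nodes
    adj: dict[int, list[tuple[Node, Optional[float]]]] = {}
    target = None
    for n in node.postorder():
        adj.setdefault(id(n), [])
        for c in n.children:
            adj[id(n)].append((c, c.length))
            adj.setdefault(id(c), []).append((n, c.length))
        if n.is_leaf and n.label == outgroup:
            target = n
    assert target is not None
    (attach, pendant_len), = [(m, w) for m, w in adj[id(target)]]

    def build(n: Node, par: Node, incoming: Optional[float]) -> Node:
        if n.is_leaf:
            return Node(n.label, [], incoming)
        kids = [build(m, n, w) for m, w in adj[id(n)] if m is not par]
        if len(kids) == 1:  # suppress former degree-2 root
            only = kids[0]
            if incoming is not None or only.length is not None:
                only.length = (only.length or 0.0) + (incoming or 0.0)
            return only
        return Node(None, kids, incoming)

    rest = build(attach, target, 0.0)
    return Node(None, [Node(outgroup, [], pendant_len), rest], None)


def rooted_clusters(tree, outgroup: str) -> list[frozenset]:
    """Nontrivial rooted clusters over the ingroup after outgroup rooting."""
    rooted = root_on_outgroup(tree, outgroup)
    ingroup = rooted.leaves() - {outgroup}
    out = []
    for cl in clusters(rooted, nontrivial=False):
        cl = cl - {outgroup}
        if 2 <= len(cl) <= len(ingroup):
            out.append(cl)
    # the full ingroup appears once per rooting; deduplicate
    seen = set()
    uniq = []
    for cl in out:
        if cl not in seen:
            seen.add(cl)
            uniq.append(cl)
    return uniq


# ---------------------------------------------------------------------------
# triplets / quartets

def triplet_resolution(rooted_tree, a: str, b: str, c: str) -> Optional[frozenset]:
    """Resolution of the rooted triplet {a,b,c}: the cherry pair, or None.

    The input must be rooted; the pair whose MRCA excludes the third taxon
    is returned as a frozenset.  None is returned for unresolved triplets.
    """
    node = as_node(rooted_tree)
    trip = {a, b, c}
    best = None
    best_size = None
    for cl in clusters(node, nontrivial=False):
        inter = cl & trip
        if len(inter) == 2 and (best_size is None or len(cl) < best_size):
            best, best_size = frozenset(inter), len(cl)
    return best


def leaf_path_distances(tree, topological: bool = False) -> dict[tuple[str, str], float]:
    """Pairwise path lengths between leaves (edge counts if topological)."""
    node = as_node(tree)
    dists: dict[tuple[str, str], float] = {}
    memo: dict[int, list[tuple[str, float]]] = {}
    for n in node.postorder():
        if n.is_leaf:
            memo[id(n)] = [(n.label, 0.0)]
            continue
        lists = []
        for c in n.children:
            step = 1.0 if topological else (c.length or 0.0)
            lists.append([(lab, d + step) for lab, d in memo[id(c)]])
        for i in range(len(lists)):
            for j in range(i + 1, len(lists)):
                for la, da in lists[i]:
                    for lb, db in lists[j]:
                        key = (la, lb) if la < lb else (lb, la)
                        dists[key] = da + db
        memo[id(n)] = [x for lst in lists for x in lst]
    return dists


def quartet_resolution_from_distances(d: dict, a: str, b: str, c: str, e: str
                                      ) -> Optional[frozenset]:
    """Quartet topology by the four-point rule on topological distances."""
    def g(x, y):
        return d[(x, y)] if (x, y) in d else d[(y, x)]

    s_ab = g(a, b) + g(c, e)
    s_ac = g(a, c) + g(b, e)
    s_ae = g(a, e) + g(b, c)
    m = min(s_ab, s_ac, s_ae)
    if [s_ab, s_ac, s_ae].count(m) > 1:
        return None
    if m == s_ab:
        return frozenset([frozenset([a, b]), frozenset([c, e])])
    if m == s_ac:
        return frozenset([frozenset([a, c]), frozenset([b, e])])
    return frozenset([frozenset([a, e]), frozenset([b, c])])


def compatible(clade: frozenset, others: Iterable[frozenset]) -> bool:
    """True if ``clade`` nests with or is disjoint from every set in others."""
    for o in others:
        inter = clade & o
        if inter and not (clade <= o or o <= clade):
            return False
    return True


def tree_from_laminar(clades: Iterable[frozenset], leaves: frozenset) -> Node:
    """Build a rooted tree displaying a laminar family of clades over leaves."""
    fam = sorted(set(clades) | {leaves}, key=len, reverse=True)
    nodes = {cl: Node(None) for cl in fam}
    leaf_nodes = {lab: Node(lab) for lab in leaves}

    def smallest_parent(item: frozenset, exclude=None):
        best = None
        for cl in fam:
            if item < cl or (item <= cl and cl is not exclude and len(cl) > len(item)):
                if best is None or len(cl) < len(best):
                    best = cl
        return best

    for cl in fam:
        if cl == leaves:
            continue
        par = None
        for other in fam:
            if cl < other and (par is None or len(other) < len(par)):
                par = other
        nodes[par].children.append(nodes[cl])
    for lab in leaves:
        par = None
        for cl in fam:
            if lab in cl and (par is None or len(cl) < len(par)):
                par = cl
        nodes[par].children.append(leaf_nodes[lab])
    return nodes[leaves]
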