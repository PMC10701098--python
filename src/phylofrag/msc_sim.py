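"""Multispecies-coalescent simulation with pulse introgression.

Gene trees are generated backward in time within the branches of a dated
species tree: ``k`` lineages in a branch with diploid effective size ``Ne``
coalesce at total rate ``k(k-1)/2`` per ``2Ne`` generations.  At an
introgression pulse, every lineage currently in the recipient branch jumps
to the donor branch independently with probability ``gamma`` — the standard
instantaneous-admixture model underlying D-statistic theory.

Time is measured in generations throughout; years enter only through
``gen_time`` at configuration I/O.  Loci are unlinked and free of
intra-locus recombination, mirroring the per-window independence assumption
of window-based phylogenomics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np

from . import _trees
from ._trees import Node

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}


# ---------------------------------------------------------------------------
# species tree model


@dataclass(frozen=True)
class IntrogressionEdge:
    """A pulse: lineages in ``recipient`` jump to ``donor`` with prob gamma."""

    donor: str
    recipient: str
    time: float  # generations before present
    gamma: float

    def __post_init__(self):
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must be in [0,1], got {self.gamma}")
        if self.time < 0:
            raise ValueError("pulse time must be non-negative")


class SpeciesTreeModel:
    """Rooted dated species tree with per-branch Ne and optional pulses.

    Parameters
    ----------
    newick:
        Rooted binary tree; branch lengths in generations; leaves at time 0.
    ne:
        Diploid effective size: a scalar applied to every branch, or a
        mapping from branch id to Ne (missing ids fall back to ``"default"``).
        Branch ids are leaf labels, internal-node labels from the Newick, or
        auto-generated ``"(x,y)"`` ids joining the smallest leaf of each
        child subtree.  The root id also sets the ancestral (above-root) Ne.
    mu:
        Mutation rate per site per generation (default 0.86e-8, a typical
        felid pedigree-scaled rate).
    gen_time:
        Years per generation (default 3.8), used only for unit conversion.
    edges:
        Introgression pulses.
    """

    def __init__(self, newick: str, ne, mu: float = 0.86e-8,
                 gen_time: float = 3.8,
                 edges: Sequence[IntrogressionEdge] = ()):
        if mu <= 0:
            raise ValueError("mu must be positive")
        if gen_time <= 0:
            raise ValueError("gen_time must be positive")
        self.newick = newick
        self.mu = mu
        self.gen_time = gen_time
        self.edges = [e if isinstance(e, IntrogressionEdge)
                      else IntrogressionEdge(**e) for e in edges]

        root = _trees.parse_newick(newick)
        self._root = root
        self.ids: list[str] = []
        self.parent: dict[str, Optional[str]] = {}
        self.children: dict[str, list[str]] = {}
        self.node_time: dict[str, float] = {}

        def walk(n: Node) -> tuple[str, float, str]:
            """Returns (id, node_time, min_leaf)."""
            if n.is_leaf:
                bid = n.label
                t = 0.0
                mleaf = n.label
            else:
                infos = [walk(c) for c in n.children]
                times = []
                for (cid, ct, _), c in zip(infos, n.children):
                    if c.length is None:
                        raise ValueError("species tree needs branch lengths")
                    times.append(ct + c.length)
                if max(times) - min(times) > 1e-6 * max(max(times), 1.0):
                    raise ValueError(
                        f"species tree is not ultrametric at node over "
                        f"{[i[0] for i in infos]}: child depths {times}")
                t = float(np.mean(times))
                mleaf = min(i[2] for i in infos)
                bid = n.label or "(" + ",".join(sorted(i[2] for i in infos)) + ")"
                for (cid, _, _) in infos:
                    self.parent[cid] = bid
                self.children[bid] = [i[0] for i in infos]
            if bid in self.node_time:
                raise ValueError(f"duplicate branch id {bid!r}")
            self.ids.append(bid)
            self.node_time[bid] = t
            self.children.setdefault(bid, [])
            return bid, t, mleaf

        self.root_id, _, _ = walk(root)
        self.parent[self.root_id] = None
        self.taxa = sorted(i for i in self.ids if not self.children[i])

        if isinstance(ne, (int, float)):
            self.ne = {i: float(ne) for i in self.ids}
        else:
            default = ne.get("default")
            self.ne = {}
            for i in self.ids:
                val = ne.get(i, default)
                if val is None:
                    raise ValueError(f"no Ne given for branch {i!r}")
                self.ne[i] = float(val)
        for i, v in self.ne.items():
            if v <= 0:
                raise ValueError(f"Ne must be positive on branch {i!r}")

        for e in self.edges:
            for bid in (e.donor, e.recipient):
                if bid not in self.node_time:
                    raise ValueError(f"unknown branch id {bid!r} in pulse")
                lo = self.node_time[bid]
                hi = self.branch_end(bid)
                if not (lo < e.time < hi):
                    raise ValueError(
                        f"pulse time {e.time} outside branch {bid!r} "
                        f"interval ({lo}, {hi})")

    def branch_end(self, bid: str) -> float:
        par = self.parent[bid]
        return math.inf if par is None else self.node_time[par]

    # -- configuration I/O -------------------------------------------------

    @classmethod
    def from_config(cls, config: dict) -> "SpeciesTreeModel":
        edges = [IntrogressionEdge(**e) for e in config.get("edges", [])]
        return cls(config["newick"], config["ne"], config.get("mu", 0.86e-8),
                   config.get("gen_time", 3.8), edges)

    @classmethod
    def from_json(cls, path) -> "SpeciesTreeModel":
        with open(path) as fh:
            return cls.from_config(json.load(fh))

    def to_config(self) -> dict:
        return {
            "newick": self.newick,
            "ne": dict(self.ne),
            "mu": self.mu,
            "gen_time": self.gen_time,
            "edges": [vars(e) for e in self.edges],
        }

    def years(self, generations: float) -> float:
        return generations * self.gen_time

    def generations(self, years: float) -> float:
        return years / self.gen_time


def example_model() -> SpeciesTreeModel:
    """Packaged example: an 8-taxon Neotropical cat radiation plus outgroup.

    Node ages follow published whole-genome divergence-time estimates for
    the ocelot lineage; per-branch Ne values are illustrative.  Two pulses
    emulate the strong inferred exchanges (about one third of the genome)
    between Geoffroy's cat and the southern tiger cat, and from the
    ancestral small-cat clade into the ocelot.
    """
    ref = resources.files("phylofrag.data") / "example_model.json"
    with resources.as_file(ref) as path:
        return SpeciesTreeModel.from_json(path)


# ---------------------------------------------------------------------------
# gene trees


class CoalNode:
    """Gene-tree node with an absolute time (generations before present)."""

    __slots__ = ("label", "children", "time")

    def __init__(self, label: Optional[str], children: tuple, time: float):
        self.label = label
        self.children = children
        self.time = time

    @property
    def is_leaf(self) -> bool:
        return not self.children


class GeneTree:
    """A rooted ultrametric gene tree for one locus."""

    def __init__(self, root: CoalNode, locus: int):
        self.root = root
        self.locus = locus

    def as_node(self) -> Node:
        def conv(n: CoalNode, parent_time: Optional[float]) -> Node:
            length = None if parent_time is None else parent_time - n.time
            if n.is_leaf:
                return Node(n.label, [], length)
            return Node(None, [conv(c, n.time) for c in n.children], length)

        return conv(self.root, None)

    def newick(self) -> str:
        return self.as_node().newick()

    def leaves(self) -> frozenset:
        out = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.label)
            else:
                stack.extend(n.children)
        return frozenset(out)

    def tmrca(self) -> float:
        return self.root.time

    def topology_class(self, taxon_of: Optional[dict] = None) -> Optional[frozenset]:
        """Rooted topology as a frozenset of nontrivial leaf clusters.

        With ``taxon_of`` mapping lineage label to taxon, leaves are
        collapsed to the species level; None is returned when the induced
        species tree is undefined (some taxon is non-monophyletic).
        """
        node = self.as_node()
        lineage_clusters = _trees.clusters(node, nontrivial=False)
        if not taxon_of:
            return frozenset(c for c in _trees.clusters(node))

        by_taxon: dict[str, set] = {}
        for lab, taxon in taxon_of.items():
            if lab in node.leaves():
                by_taxon.setdefault(taxon, set()).add(lab)
        cluster_set = set(lineage_clusters)
        for taxon, labs in by_taxon.items():
            if len(labs) > 1 and frozenset(labs) not in cluster_set:
                return None
        taxa = frozenset(by_taxon)
        projected = set()
        for cl in lineage_clusters:
            tset = frozenset(taxon_of[x] for x in cl)
            # keep only clusters that are unions of whole taxa
            if all(by_taxon[t] <= cl for t in tset) and 1 < len(tset) < len(taxa):
                projected.add(tset)
        return frozenset(projected)


@dataclass(frozen=True)
class TruthRecord:
    """Per-locus ground truth emitted alongside each simulated gene tree."""

    locus: int
    topology_class: Optional[frozenset]
    introgressed: bool


def _coalesce(lineages: list, ne: float, t0: float, t1: float, rng) -> float:
    """Coalesce in place between absolute times t0 and t1; returns end time."""
    t = t0
    while len(lineages) >= 2:
        k = len(lineages)
        rate = k * (k - 1) / 2.0 / (2.0 * ne)
        t = t + rng.exponential(1.0 / rate)
        if t >= t1:
            return t1
        i, j = rng.choice(k, size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        a = lineages.pop(j)
        b = lineages.pop(i)
        lineages.append(CoalNode(None, (a, b), t))
    return t1


def simulate_gene_trees(model: SpeciesTreeModel, samples: dict[str, int],
                        n_loci: int, seed: int
                        ) -> tuple[list[GeneTree], list[TruthRecord]]:
    """Simulate independent gene trees under the MSC with pulses.

    ``samples`` maps taxon label to the number of haploid lineages sampled
    from it.  Lineage labels are the taxon label itself for single samples,
    else ``taxon_1 .. taxon_k``.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    for taxon in samples:
        if taxon not in model.taxa:
            raise ValueError(f"taxon {taxon!r} absent from model")

    rng = np.random.default_rng(seed)
    single = all(k == 1 for k in samples.values())
    taxon_of = {}
    labels: dict[str, list[str]] = {}
    for taxon, k in samples.items():
        labs = [taxon] if k == 1 else [f"{taxon}_{i + 1}" for i in range(k)]
        labels[taxon] = labs
        for lab in labs:
            taxon_of[lab] = taxon

    # event schedule: speciations (children merge into parent) and pulses
    events: list[tuple[float, int, object]] = []
    for bid in model.ids:
        if model.children[bid]:
            events.append((model.node_time[bid], 1, bid))
    for e in model.edges:
        events.append((e.time, 0, e))
    events.sort(key=lambda x: (x[0], x[1]))

    trees: list[GeneTree] = []
    truths: list[TruthRecord] = []
    for locus in range(n_loci):
        active: dict[str, list] = {
            taxon: [CoalNode(lab, (), 0.0) for lab in labels[taxon]]
            for taxon in samples
        }
        t_prev = 0.0
        introgressed = False
        for t_ev, kind, payload in events:
            for bid, lin in active.items():
                if len(lin) >= 2:
                    _coalesce(lin, model.ne[bid], t_prev, t_ev, rng)
            if kind == 0:  # pulse
                e: IntrogressionEdge = payload
                rec = active.get(e.recipient, [])
                if rec:
                    keep, move = [], []
                    draws = rng.random(len(rec))
                    for lineage, u in zip(rec, draws):
                        (move if u < e.gamma else keep).append(lineage)
                    if move:
                        introgressed = True
                        active[e.recipient] = keep
                        active.setdefault(e.donor, []).extend(move)
            else:  # speciation: children branches merge into parent branch
                bid = payload
                merged = []
                for cid in model.children[bid]:
                    merged.extend(active.pop(cid, []))
                if merged:
                    active.setdefault(bid, []).extend(merged)
            t_prev = t_ev
        root_lin = active.get(model.root_id, [])
        _coalesce(root_lin, model.ne[model.root_id], t_prev, math.inf, rng)
        (root,) = root_lin
        gt = GeneTree(root, locus)
        trees.append(gt)
        topo = gt.topology_class(None if single else taxon_of)
        truths.append(TruthRecord(locus, topo, introgressed))
    return trees, truths


def expected_triplet_frequencies(t_coal: float) -> tuple[float, float, float]:
    """MSC rooted-triplet topology probabilities for internal branch t_coal.

    The concordant resolution has probability 1 - (2/3)exp(-t); each
    discordant resolution has probability (1/3)exp(-t).
    """
    if t_coal < 0:
        raise ValueError("t_coal must be non-negative")
    disc = math.exp(-t_coal) / 3.0
    return (1.0 - 2.0 * disc, disc, disc)


# ---------------------------------------------------------------------------
# sequences


@dataclass
class LocusAlignment:
    """Equal-length sequences simulated on one gene tree."""

    locus: int
    samples: list[str]
    matrix: np.ndarray  # (n_samples, length) uint8 codes into BASES

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequences(self) -> dict[str, str]:
        lut = np.frombuffer("ACGTN".encode(), dtype=np.uint8)
        return {s: lut[self.matrix[i]].tobytes().decode()
                for i, s in enumerate(self.samples)}


def _jc69_probs(expected_subs: float) -> float:
    """JC69 probability that a site differs across a branch."""
    return 0.75 * (1.0 - math.exp(-4.0 * expected_subs / 3.0))


def _hky_matrix(expected_subs: float, kappa: float, freqs: np.ndarray) -> np.ndarray:
    """HKY transition matrix for a branch of given expected substitutions."""
    from scipy.linalg import expm

    q = np.empty((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            q[i, j] = freqs[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(freqs * np.diag(q)).sum()
    return expm(q * expected_subs / scale)


def simulate_sequences(tree: GeneTree, length: int, mu: float,
                       model: str = "JC69", seed: int = 0,
                       kappa: float = 2.0,
                       freqs: Sequence[float] = (0.25, 0.25, 0.25, 0.25)
                       ) -> LocusAlignment:
    """Evolve i.i.d. sites along a gene tree.

    Expected substitutions per site on a branch equal ``mu`` times the
    branch duration in generations.  JC69 is the default; HKY adds a
    transition/transversion ratio ``kappa`` and base frequencies.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    model = model.upper()
    if model not in ("JC69", "HKY"):
        raise ValueError(f"unknown substitution model {model!r}")
    rng = np.random.default_rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    freqs = freqs / freqs.sum()

    root_seq = rng.choice(4, size=length, p=freqs if model == "HKY" else None)
    root_seq = root_seq.astype(np.uint8)

    rows: dict[str, np.ndarray] = {}

    def evolve(n: CoalNode, parent_seq: np.ndarray, parent_time: float):
        dur = parent_time - n.time
        if dur < 0:
            raise ValueError("negative branch duration in gene tree")
        seq = parent_seq.copy()
        esubs = mu * dur
        if esubs > 0:
            if model == "JC69":
                p_diff = _jc69_probs(esubs)
                hit = rng.random(length) < p_diff
                nhit = int(hit.sum())
                if nhit:
                    seq[hit] = (seq[hit] + rng.integers(1, 4, size=nhit)) % 4
            else:
                pmat = _hky_matrix(esubs, kappa, freqs)
                new = np.empty(length, dtype=np.uint8)
                for s in range(4):
                    idx = seq == s
                    k = int(idx.sum())
                    if k:
                        new[idx] = rng.choice(4, size=k, p=pmat[s])
                seq = new
        if n.is_leaf:
            rows[n.label] = seq
        else:
            for c in n.children:
                evolve(c, seq, n.time)

    root = tree.root
    for c in root.children:
        evolve(c, root_seq, root.time)
    if root.is_leaf:  # single-lineage degenerate tree
        rows[root.label] = root_seq

    samples = sorted(rows)
    matrix = np.stack([rows[s] for s in samples])
    return LocusAlignment(tree.locus, samples, matrix)


# ---------------------------------------------------------------------------
# genome assembly


def _draw_runs(length: int, target: int, mean_run: float, rng) -> np.ndarray:
    """Boolean mask built from geometric-length runs until ~target covered."""
    mask = np.zeros(length, dtype=bool)
    covered = 0
    guard = 0
    while covered < target and guard < 100 * length:
        run = int(rng.geometric(1.0 / mean_run))
        start = int(rng.integers(0, length))
        end = min(start + run, length)
        newly = int((~mask[start:end]).sum())
        mask[start:end] = True
        covered += newly
        guard += run
    return mask


def assemble_genomes(loci: Sequence[LocusAlignment], missing_rate: float,
                     mask_fraction: float, seed: int,
                     chrom: str = "chr1", mean_run: float = 500.0):
    """Concatenate loci into per-sample chromosomes with missingness and a mask.

    Returns ``(genomes, mask, truth_windows)`` where genomes is a dict of
    sample id to a :class:`phylofrag.genome_windows.ConsensusGenome`, mask is
    a :class:`phylofrag.genome_windows.MaskTrack` of shared repeat-like
    intervals covering about ``mask_fraction`` of the genome, and
    truth_windows records each locus's coordinates.  Per-sample missing data
    is injected as geometric-length runs of 'N' totalling about
    ``missing_rate`` of the genome, emulating mapping dropouts.
    """
    from .genome_windows import ConsensusGenome, MaskTrack

    samples = loci[0].samples
    for la in loci:
        if la.samples != samples:
            raise ValueError("inconsistent sample sets across loci")
    rng = np.random.default_rng(seed)

    big = np.concatenate([la.matrix for la in loci], axis=1)
    length = big.shape[1]

    truth_windows = []
    pos = 0
    for la in loci:
        truth_windows.append((la.locus, chrom, pos, pos + la.length))
        pos += la.length

    if missing_rate > 0:
        for i in range(len(samples)):
            mask = _draw_runs(length, int(round(missing_rate * length)),
                              mean_run, rng)
            big[i, mask] = 4  # 'N'

    intervals: list[tuple[int, int]] = []
    if mask_fraction > 0:
        m = _draw_runs(length, int(round(mask_fraction * length)), mean_run, rng)
        # boolean mask -> merged intervals
        edges = np.flatnonzero(np.diff(np.concatenate(([0], m.view(np.int8), [0]))))
        intervals = [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])]

    lut = np.frombuffer("ACGTN".encode(), dtype=np.uint8)
    genomes = {
        s: ConsensusGenome(s, {chrom: lut[big[i]].tobytes().decode()})
        for i, s in enumerate(samples)
    }
    mask_track = MaskTrack({chrom: intervals})
    return genomes, mask_track, truth_windows


# ---------------------------------------------------------------------------
# diploid genotypes and pseudohaploidization


@dataclass
class DiploidGenotypes:
    """Per-site genotype calls for one diploid sample.

    ``genotypes`` codes: 0 hom-ref, 1 het, 2 hom-alt, -1 missing.  ``ref``
    and ``alt`` are uint8 base codes into ``BASES``; ``callable_mask`` marks
    sites usable for heterozygosity estimation.
    """

    sample: str
    genotypes: np.ndarray  # int8
    callable_mask: np.ndarray  # bool
    ref: np.ndarray  # uint8 codes
    alt: np.ndarray  # uint8 codes
    chrom: str = "chr1"

    def __post_init__(self):
        n = len(self.genotypes)
        if not (len(self.callable_mask) == len(self.ref) == len(self.alt) == n):
            raise ValueError("genotype and mask arrays must have equal length")

    @property
    def length(self) -> int:
        return len(self.genotypes)


def simulate_diploid_with_roh(length: int, theta_bg: float,
                              roh_intervals: Sequence[tuple[int, int]],
                              theta_roh: float, seed: int,
                              sample: str = "sample1"
                              ) -> tuple[DiploidGenotypes, list[tuple[int, int]]]:
    """Simulate per-site het calls with depressed rates inside ROH tracts.

    Heterozygous sites arise i.i.d. with probability ``theta_bg`` outside
    and ``theta_roh`` inside the given intervals (0-based half-open,
    non-overlapping).  Truth segments are returned verbatim.
    """
    iv = sorted((int(s), int(e)) for s, e in roh_intervals)
    prev_end = -1
    for s, e in iv:
        if s < 0 or e > length or s >= e:
            raise ValueError(f"interval ({s},{e}) outside [0,{length})")
        if s < prev_end:
            raise ValueError("overlapping ROH intervals")
        prev_end = e

    rng = np.random.default_rng(seed)
    theta = np.full(length, theta_bg)
    for s, e in iv:
        theta[s:e] = theta_roh
    het = rng.random(length) < theta
    genotypes = np.where(het, 1, 0).astype(np.int8)
    ref = rng.integers(0, 4, size=length, dtype=np.uint8)
    alt = ((ref + rng.integers(1, 4, size=length)) % 4).astype(np.uint8)
    callable_mask = np.ones(length, dtype=bool)
    g = DiploidGenotypes(sample, genotypes, callable_mask, ref, alt)
    return g, list(iv)


def pseudohaploidize(g: DiploidGenotypes, seed: int) -> str:
    """Collapse a diploid to one random allele per site.

    Homozygous sites emit their allele, heterozygous sites emit either
    allele with probability 1/2, and uncallable or missing sites emit 'N'.
    """
    rng = np.random.default_rng(seed)
    codes = np.where(g.genotypes == 2, g.alt, g.ref).astype(np.uint8)
    het = g.genotypes == 1
    pick_alt = rng.random(int(het.sum())) < 0.5
    het_codes = np.where(pick_alt, g.alt[het], g.ref[het])
    codes[het] = het_codes
    codes[(g.genotypes < 0) | ~g.callable_mask] = 4
    lut = np.frombuffer("ACGTN".encode(), dtype=np.uint8)
    return lut[codes].tobytes().decode()
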