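"""Gene-flow detection: site-pattern statistics and branch-length mixtures.

Two independent routes to introgression:

* ABBA/BABA site-pattern statistics (Patterson's D, the f4 admixture ratio,
  and the f-branch summary) computed from allele frequencies with a
  weighted block jackknife for statistical support;
* a two-component mixture on triplet internal branch lengths, fitted by
  expectation-maximization, separating ILS-only discordance (exponential
  branch lengths from zero) from ILS-plus-introgression (an additional
  exponential shifted away from zero), scored by BIC.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm

from ._trees import Node, as_node, root_on_outgroup, triplet_resolution
from .genome_windows import encode


# ---------------------------------------------------------------------------
# site patterns


@dataclass
class PatternBlocks:
    """Weighted ABBA/BABA/BBAA sums in contiguous jackknife blocks."""

    quartet: tuple[str, str, str, str]
    abba: np.ndarray
    baba: np.ndarray
    bbaa: np.ndarray
    sizes: np.ndarray  # usable sites per block

    @property
    def n_blocks(self) -> int:
        return len(self.abba)

    def totals(self) -> tuple[float, float, float]:
        return float(self.abba.sum()), float(self.baba.sum()), float(self.bbaa.sum())


def _taxon_matrix(seqs) -> np.ndarray:
    if isinstance(seqs, np.ndarray):
        mat = seqs if seqs.ndim == 2 else seqs[None, :]
        return mat.astype(np.uint8)
    rows = [encode(s) if isinstance(s, str) else np.asarray(s, dtype=np.uint8)
            for s in ([seqs] if isinstance(seqs, str) else list(seqs))]
    return np.stack(rows)


def site_pattern_weights(alignment: Mapping[str, object],
                         quartet: Sequence[str]
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-site ABBA/BABA/BBAA weights from derived-allele frequencies.

    ``alignment`` maps taxon to one or more aligned sequences; the fourth
    quartet member is the outgroup whose major allele polarizes each site.
    Only biallelic sites callable in all four taxa contribute.  Returns
    (abba, baba, bbaa, usable) arrays over sites.
    """
    p1, p2, p3, out = quartet
    for t in quartet:
        if t not in alignment:
            raise ValueError(f"quartet taxon {t!r} missing from alignment")
    mats = {t: _taxon_matrix(alignment[t]) for t in quartet}
    length = mats[p1].shape[1]
    base_counts = {}
    callable_ = {}
    for t, m in mats.items():
        if m.shape[1] != length:
            raise ValueError("sequences must share a coordinate axis")
        counts = np.stack([(m == b).sum(axis=0) for b in range(4)])
        base_counts[t] = counts
        callable_[t] = counts.sum(axis=0)

    anc = np.argmax(base_counts[out], axis=0)  # ties: smaller code
    present = np.stack([sum((base_counts[t][b] > 0).astype(np.int8)
                            for t in quartet) > 0 for b in range(4)])
    n_alleles = present.sum(axis=0)
    not_anc = present.copy()
    not_anc[anc, np.arange(length)] = False
    derived = np.argmax(not_anc, axis=0)
    usable = ((n_alleles == 2) & (not_anc.sum(axis=0) == 1))
    for t in quartet:
        usable &= callable_[t] > 0

    idx = np.arange(length)
    freqs = {}
    for t in quartet:
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[t] = np.where(callable_[t] > 0,
                                base_counts[t][derived, idx] /
                                np.maximum(callable_[t], 1), 0.0)
    f1, f2, f3, f4 = (freqs[t] for t in quartet)
    abba = np.where(usable, (1 - f1) * f2 * f3 * (1 - f4), 0.0)
    baba = np.where(usable, f1 * (1 - f2) * f3 * (1 - f4), 0.0)
    bbaa = np.where(usable, f1 * f2 * (1 - f3) * (1 - f4), 0.0)
    return abba, baba, bbaa, usable


def count_site_patterns(alignment: Mapping[str, object],
                        quartet: Sequence[str], n_blocks: int = 20,
                        block_edges: Optional[np.ndarray] = None
                        ) -> PatternBlocks:
    """ABBA/BABA/BBAA sums partitioned into contiguous jackknife blocks.

    Blocks are contiguous in genome order with near-equal usable-site
    counts; precomputed ``block_edges`` (site-index boundaries) may be
    supplied to keep two pattern sets on identical blocks.
    """
    abba, baba, bbaa, usable = site_pattern_weights(alignment, quartet)
    total_usable = int(usable.sum())
    if block_edges is None:
        if total_usable < n_blocks:
            raise ValueError(
                f"only {total_usable} usable sites for {n_blocks} blocks")
        ranks = np.cumsum(usable) - 1  # usable-site rank at each position
        block_of = np.clip(ranks * n_blocks // max(total_usable, 1),
                           0, n_blocks - 1)
    else:
        n_blocks = len(block_edges) - 1
        block_of = np.clip(np.searchsorted(block_edges, np.arange(len(usable)),
                                           side="right") - 1, 0, n_blocks - 1)
    sums = np.zeros((3, n_blocks))
    sizes = np.zeros(n_blocks)
    for arr, row in ((abba, 0), (baba, 1), (bbaa, 2)):
        np.add.at(sums[row], block_of, arr)
    np.add.at(sizes, block_of, usable.astype(float))
    return PatternBlocks(tuple(quartet), sums[0], sums[1], sums[2], sizes)


# ---------------------------------------------------------------------------
# jackknife


def block_jackknife(block_components: np.ndarray,
                    stat: Callable[[np.ndarray], float],
                    sizes: np.ndarray) -> tuple[float, float, float, float, bool]:
    """Weighted delete-one block jackknife (Busing et al. 1999).

    ``block_components`` has shape (n_blocks, c); ``stat`` maps the summed
    component vector to the statistic.  Returns (estimate, SE, Z, two-sided
    p, zero_se flag); with SE = 0 the Z and p are NaN and the flag is set
    rather than reporting infinity.
    """
    comp = np.asarray(block_components, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    g = comp.shape[0]
    if g < 2:
        raise ValueError("need at least 2 blocks")
    totals = comp.sum(axis=0)
    est = stat(totals)
    n = sizes.sum()
    h = n / np.maximum(sizes, 1e-300)
    theta_del = np.array([stat(totals - comp[j]) for j in range(g)])
    theta_j = g * est - float(((1 - sizes / n) * theta_del).sum())
    var = float((1.0 / g) * np.sum(
        (h * est - (h - 1) * theta_del - theta_j) ** 2 / (h - 1)))
    se = math.sqrt(max(var, 0.0))
    if se <= 1e-12 * max(1.0, abs(est)):
        return est, 0.0, float("nan"), float("nan"), True
    z = est / se
    p = 2.0 * norm.sf(abs(z))
    return est, se, z, p, False


@dataclass
class DStat:
    """Patterson's D with block-jackknife support."""

    d: float
    se: float
    z: float
    p: float
    n_blocks: int
    abba: float
    baba: float
    bbaa: float
    zero_se: bool = False


def patterson_d(pb: PatternBlocks) -> DStat:
    """D = (ABBA - BABA) / (ABBA + BABA), with jackknife SE/Z/p."""
    abba, baba, bbaa = pb.totals()
    if abba + baba == 0:
        raise ZeroDivisionError("no ABBA/BABA signal (zero denominator)")

    comp = np.stack([pb.abba, pb.baba], axis=1)

    def stat(tot):
        num, den = tot[0] - tot[1], tot[0] + tot[1]
        return num / den if den else 0.0

    d, se, z, p, flag = block_jackknife(comp, stat, pb.sizes)
    return DStat(d, se, z, p, pb.n_blocks, abba, baba, bbaa, flag)


@dataclass
class F4Ratio:
    """f4 admixture-ratio estimate of the admixture fraction gamma."""

    value: float
    se: float
    z: float
    p: float
    n_blocks: int
    zero_se: bool = False


def f4_ratio(pb_num: PatternBlocks, pb_den: PatternBlocks) -> F4Ratio:
    """Ratio of f4 sums; the denominator replaces the recipient with a
    second sample of the donor lineage, so the ratio estimates gamma under
    a pulse model."""
    if pb_num.n_blocks != pb_den.n_blocks:
        raise ValueError("numerator and denominator need matching blocks")
    den_tot = pb_den.abba.sum() - pb_den.baba.sum()
    if den_tot == 0:
        raise ZeroDivisionError("zero f4 denominator")
    comp = np.stack([pb_num.abba, pb_num.baba, pb_den.abba, pb_den.baba],
                    axis=1)

    def stat(tot):
        den = tot[2] - tot[3]
        return (tot[0] - tot[1]) / den if den else 0.0

    val, se, z, p, flag = block_jackknife(comp, stat,
                                          pb_num.sizes + pb_den.sizes)
    return F4Ratio(val, se, z, p, pb_num.n_blocks, flag)


def f4_ratio_from_alignment(alignment: Mapping[str, object],
                            p1: str, p2: str, p3: str, out: str,
                            n_blocks: int = 20) -> F4Ratio:
    """f4-ratio with the donor taxon's samples split between numerator and
    denominator roles.

    Requires at least two sequences for the donor ``p3``; with a single
    pseudohaploid donor sample the estimator is unavailable.
    """
    donor = _taxon_matrix(alignment[p3])
    if donor.shape[0] < 2:
        raise ValueError(
            f"f4-ratio needs two samples of the donor {p3!r}; only "
            f"{donor.shape[0]} available")
    p3a, p3b = donor[:1], donor[1:2]
    sub = dict(alignment)
    sub["__p3a"], sub["__p3b"] = p3a, p3b
    # shared blocks: partition sites by the numerator's usable-site ranks
    _, _, _, usable = site_pattern_weights(sub, (p1, p2, "__p3a", out))
    total = int(usable.sum())
    if total < n_blocks:
        raise ValueError(f"only {total} usable sites for {n_blocks} blocks")
    ranks = np.cumsum(usable) - 1
    block_of = np.clip(ranks * n_blocks // total, 0, n_blocks - 1)
    edges = np.searchsorted(block_of, np.arange(n_blocks), side="left")
    pb_num = count_site_patterns(sub, (p1, p2, "__p3a", out),
                                 block_edges=np.append(edges, len(usable)))
    pb_den = count_site_patterns(sub, (p1, "__p3b", "__p3a", out),
                                 block_edges=np.append(edges, len(usable)))
    return f4_ratio(pb_num, pb_den)


# ---------------------------------------------------------------------------
# f-branch


@dataclass
class FBranchMatrix:
    """fb values per (species-tree branch, candidate donor taxon)."""

    matrix: pd.DataFrame  # index: branch id, columns: taxa; NaN = undefined
    f_table: pd.DataFrame  # intermediate per-(A,b) medians, for audit


def species_tree_trios(species_tree, outgroup: str
                       ) -> list[tuple[str, str, str]]:
    """All (P1, P2, P3) trios consistent with the rooted species tree.

    For each leaf trio with topology ((x,y),z) both (x,y,z) and (y,x,z)
    orderings are emitted: P3 is the candidate donor, P2 the recipient.
    """
    rooted = root_on_outgroup(as_node(species_tree), outgroup)
    ingroup = sorted(rooted.leaves() - {outgroup})
    trios = []
    for x, y, z in itertools.combinations(ingroup, 3):
        res = triplet_resolution(rooted, x, y, z)
        if res is None:
            continue
        (a, b), (c,) = sorted(res), sorted(set((x, y, z)) - res)
        trios.append((a, b, c))
        trios.append((b, a, c))
    return trios


def f_branch(species_tree, f4_results: pd.DataFrame,
             outgroup: str) -> FBranchMatrix:
    """Assign f4-ratio signals to species-tree branches.

    ``f4_results`` must have columns P1, P2, P3, value where value is the
    f4 admixture ratio for the trio (P1, P2; P3) on the species tree.  For
    branch a and donor taxon b: fb(a, b) = min over leaves A below a of the
    median over P1 configurations of f(A, b); negative values clamp to 0;
    cells where b descends from a (or no estimate exists) are NaN.
    """
    rooted = root_on_outgroup(as_node(species_tree), outgroup)
    ingroup = sorted(rooted.leaves() - {outgroup})

    med = (f4_results.groupby(["P2", "P3"])["value"].median()
           .rename("f").reset_index())
    f_of = {(r.P2, r.P3): r.f for r in med.itertuples()}

    branches: list[frozenset] = []
    for n in rooted.postorder():
        if n is rooted:
            continue
        cl = frozenset(x.label for x in n.postorder() if x.is_leaf) - {outgroup}
        if 1 <= len(cl) < len(ingroup) and cl not in branches:
            branches.append(cl)

    rows = {}
    for cl in branches:
        bid = ",".join(sorted(cl))
        row = {}
        for b in ingroup:
            if b in cl:
                row[b] = float("nan")
                continue
            vals = [f_of[(A, b)] for A in sorted(cl) if (A, b) in f_of]
            if len(vals) < len(cl):
                row[b] = float("nan")
            else:
                row[b] = max(0.0, min(vals))
        rows[bid] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index")[ingroup]
    return FBranchMatrix(matrix, med)


# ---------------------------------------------------------------------------
# triplet branch lengths (QuIBL-style)


@dataclass
class TripletLengths:
    """Internal branch lengths of a rooted triplet, per resolution."""

    triplet: tuple[str, str, str]
    outgroup: str
    lengths: dict[frozenset, list[float]]
    skipped: int = 0

    def counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.lengths.items()}


def _mrca_depth(node: Node, targets: frozenset) -> float:
    """Depth (root-to-node path length) of the MRCA of ``targets``."""
    best = None

    def walk(n: Node, depth: float) -> frozenset:
        nonlocal best
        if n.is_leaf:
            got = frozenset([n.label]) & targets
        else:
            got = frozenset()
            for c in n.children:
                got |= walk(c, depth + (c.length or 0.0))
        if got == targets and (best is None or depth > best):
            best = depth
        return got

    walk(node, 0.0)
    return best if best is not None else 0.0


def extract_triplet_lengths(ts, triplet: Sequence[str], outgroup: str
                            ) -> TripletLengths:
    """Per-tree triplet resolution and internal branch length.

    Each tree containing all four leaves is rooted on the outgroup and
    restricted to the triplet; the internal branch is the path between the
    cherry pair's MRCA and the triplet MRCA.  Unresolved restrictions are
    skipped and counted.
    """
    a, b, c = triplet
    lengths: dict[frozenset, list[float]] = {
        frozenset((a, b)): [], frozenset((a, c)): [], frozenset((b, c)): []}
    skipped = 0
    for t in ts:
        node = as_node(t)
        leaves = node.leaves()
        if not {a, b, c, outgroup} <= leaves:
            continue
        rooted = root_on_outgroup(node, outgroup)
        res = triplet_resolution(rooted, a, b, c)
        if res is None:
            skipped += 1
            continue
        d_all = _mrca_depth(rooted, frozenset((a, b, c)))
        d_pair = _mrca_depth(rooted, res)
        lengths[res].append(max(d_pair - d_all, 0.0))
    return TripletLengths((a, b, c), outgroup, lengths, skipped)


# ---------------------------------------------------------------------------
# mixture EM


@dataclass
class QuiblFit:
    """Two-component branch-length mixture fit.

    Model 1: a single exponential from zero (pure ILS).  Model 2: with
    probability ``pi2`` the internal branch is exponential from an offset
    ``theta`` (discordance locked in by gene flow before the window
    coalesces), sharing the rate ``1/lam`` with the from-zero component.
    """

    pi2: float
    lam: float
    theta: float
    loglik1: float
    loglik2: float
    bic1: float
    bic2: float
    n: int
    trace: list = field(default_factory=list)
    low_power: bool = False

    @property
    def delta_bic(self) -> float:
        return self.bic1 - self.bic2


def _mix_loglik(x: np.ndarray, pi2: float, lam: float, theta: float) -> float:
    f1 = np.exp(-x / lam) / lam
    f2 = np.where(x >= theta, np.exp(-np.maximum(x - theta, 0.0) / lam) / lam, 0.0)
    mix = (1 - pi2) * f1 + pi2 * f2
    if (mix <= 0).any():
        return -np.inf
    return float(np.log(mix).sum())


def quibl_em(lengths: Sequence[float], max_steps: int = 50, seed: int = 0,
             tol: float = 1e-8) -> QuiblFit:
    """Fit the 1- and 2-component branch-length models by EM.

    The EM iterates responsibilities and closed-form (pi2, lam) updates
    with the offset theta profiled by a bounded one-dimensional search per
    step, accepted only when it improves the observed-data log-likelihood,
    so the trace is monotone non-decreasing.  BIC compares both models.
    """
    x = np.asarray(lengths, dtype=float)
    if (x <= 0).any():
        raise ValueError("branch lengths must be positive")
    n = len(x)
    low_power = n < 20
    rng = np.random.default_rng(seed)

    lam1 = float(x.mean())
    loglik1 = float(-n * math.log(lam1) - n)
    bic1 = 1 * math.log(n) - 2 * loglik1

    best = None
    for theta0 in (float(np.median(x)), float(np.percentile(x, 75)),
                   float(rng.uniform(0, x.max()))):
        pi2, lam, theta = 0.5, max(lam1 / 2, 1e-12), min(theta0, x.max() * 0.99)
        trace = [_mix_loglik(x, pi2, lam, theta)]
        for _ in range(max_steps):
            f1 = np.exp(-x / lam) / lam
            f2 = np.where(x >= theta,
                          np.exp(-np.maximum(x - theta, 0.0) / lam) / lam, 0.0)
            mix = (1 - pi2) * f1 + pi2 * f2
            mix = np.maximum(mix, 1e-300)
            r = pi2 * f2 / mix
            pi2_new = float(r.mean())
            lam_new = float(((1 - r) * x + r * np.maximum(x - theta, 0.0)).sum() / n)
            lam_new = max(lam_new, 1e-12)
            pi2, lam = pi2_new, lam_new
            ll = _mix_loglik(x, pi2, lam, theta)
            # profile theta by bounded search; keep only improvements
            res = minimize_scalar(lambda th: -_mix_loglik(x, pi2, lam, th),
                                  bounds=(0.0, float(x.max()) * 0.999),
                                  method="bounded")
            if -res.fun > ll:
                theta = float(res.x)
                ll = -res.fun
            trace.append(ll)
            if abs(trace[-1] - trace[-2]) < tol:
                break
        if best is None or trace[-1] > best[0]:
            best = (trace[-1], pi2, lam, theta, trace)

    loglik2, pi2, lam, theta, trace = best
    bic2 = 3 * math.log(n) - 2 * loglik2
    return QuiblFit(pi2, lam, theta, loglik1, loglik2, bic1, bic2, n,
                    trace, low_power)


def quibl_classify(fit: QuiblFit, delta_bic: float = 10.0) -> dict:
    """ILS-only vs ILS+introgression verdict by BIC difference.

    The two-component model must beat the single exponential by more than
    ``delta_bic`` BIC units to call introgression, in which case ``pi2`` is
    reported as the introgressed fraction for that topology.
    """
    if fit.delta_bic > delta_bic:
        return {"verdict": "ILS+introgression", "pi2": fit.pi2,
                "delta_bic": fit.delta_bic}
    return {"verdict": "ILS-only", "pi2": None, "delta_bic": fit.delta_bic}
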