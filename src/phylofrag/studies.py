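"""Self-contained simulation studies exercising the whole pipeline.

Each function builds its own synthetic inputs with :mod:`phylofrag.msc_sim`,
runs one analysis stage, and returns summary numbers.  They back both the
calibration test suite and the reproduction script, so the study conditions
(sample sizes, rates, pulse strengths) live in exactly one place.

Problem sizes are chosen to finish on a single CPU in minutes while leaving
the statistical targets comfortably resolvable; every study scales with its
arguments if more precision is wanted.
"""

from __future__ import annotations

import itertools
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import diversity_demog, discord_stats, introgression, msc_sim, treebuild
from ._trees import Node, bipartitions, leaf_path_distances, topology_key
from .tree_summary import clade_frequencies, greedy_consensus


# ---------------------------------------------------------------------------
# MSC calibration


def triplet_concordance(t_values: Sequence[float] = (0.0, 0.5, 1.0, 2.0),
                        n_loci: int = 10_000, ne: float = 1000.0,
                        seed: int = 0) -> dict[float, dict[str, float]]:
    """Observed vs analytic concordant-triplet frequencies.

    For each internal branch length (coalescent units) a rooted triplet
    species tree is simulated and the frequency of the concordant topology
    is compared with 1 - (2/3)exp(-t).
    """
    out = {}
    for k, t in enumerate(t_values):
        gens = t * 2 * ne
        nwk = f"((A:1000,B:1000)ab:{gens},C:{1000 + gens})r;"
        model = msc_sim.SpeciesTreeModel(nwk, ne=ne)
        trees, _ = msc_sim.simulate_gene_trees(
            model, {"A": 1, "B": 1, "C": 1}, n_loci, seed=seed + k)
        conc = sum(1 for tr in trees
                   if tr.topology_class() == frozenset([frozenset("AB")]))
        expected = msc_sim.expected_triplet_frequencies(t)[0]
        se = float(np.sqrt(expected * (1 - expected) / n_loci))
        out[t] = {"observed": conc / n_loci, "expected": expected,
                  "binomial_se": se}
    return out


# ---------------------------------------------------------------------------
# NJ on additive matrices


def random_additive_case(n_taxa: int, rng) -> tuple[Node, "treebuild.DistanceMatrix"]:
    """A random binary tree with positive lengths and its path-length matrix."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [Node(lab, length=float(rng.uniform(0.5, 3.0))) for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        b = nodes.pop(int(j))
        a = nodes.pop(int(i))
        nodes.append(Node(None, [a, b], float(rng.uniform(0.5, 3.0))))
    tree = Node(None, nodes)
    d = leaf_path_distances(tree)
    mat = np.zeros((n_taxa, n_taxa))
    for a, b in itertools.combinations(range(n_taxa), 2):
        la, lb = labels[a], labels[b]
        mat[a, b] = mat[b, a] = d[(la, lb)] if (la, lb) in d else d[(lb, la)]
    return tree, treebuild.DistanceMatrix.from_distances(labels, mat)


def nj_additive_recovery(n_cases: int = 100, seed: int = 0) -> float:
    """Fraction of random additive matrices (6-10 taxa) recovered exactly."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cases):
        n_taxa = int(rng.integers(6, 11))
        truth, dm = random_additive_case(n_taxa, rng)
        est = treebuild.nj_tree(dm)
        if bipartitions(est) == bipartitions(truth):
            hits += 1
    return hits / n_cases


# ---------------------------------------------------------------------------
# consensus recovery


def _eight_taxon_model(internal_cu: float = 0.5, ne: float = 5000.0,
                       edges=()) -> msc_sim.SpeciesTreeModel:
    """Caterpillar-ish 8-taxon species tree with equal internal branches."""
    step = internal_cu * 2 * ne
    t1 = 2000.0
    # two balanced quartets joined at the root side; internal branches are
    # `step` or longer everywhere
    nwk = (f"(((((A:{t1},B:{t1})n1:{step},C:{t1 + step})n2:{step},"
           f"(D:{t1},E:{t1})n3:{2 * step})n4:{step},"
           f"((F:{t1},G:{t1})n5:{step},H:{t1 + step})n6:{2 * step})n7:"
           f"{4 * step},OUT:{t1 + 3 * step + 4 * step})root;")
    return msc_sim.SpeciesTreeModel(nwk, ne=ne, edges=edges)


def consensus_recovery(n_reps: int = 100, n_loci: int = 1000,
                       internal_cu: float = 0.5, seed: int = 0) -> float:
    """Fraction of replicates where the greedy consensus over simulated
    gene trees equals the true 8-taxon species-tree topology."""
    model = _eight_taxon_model(internal_cu)
    truth = _species_tree_clusters(model)
    hits = 0
    for r in range(n_reps):
        trees, _ = msc_sim.simulate_gene_trees(
            model, {t: 1 for t in model.taxa}, n_loci, seed=seed + 7919 * r)
        ct = clade_frequencies([t.as_node() for t in trees], "OUT")
        cons = greedy_consensus(ct)
        got = {cl for cl in cons.support if len(cl) > 1}
        if got == truth:
            hits += 1
    return hits / n_reps


def _species_tree_clusters(model: msc_sim.SpeciesTreeModel) -> set[frozenset]:
    from ._trees import clusters, parse_newick, root_on_outgroup

    rooted = root_on_outgroup(parse_newick(model.newick), "OUT")
    ingroup = rooted.leaves() - {"OUT"}
    return {cl - {"OUT"} for cl in clusters(rooted, nontrivial=False)
            if 2 <= len(cl - {"OUT"}) <= len(ingroup)}


# ---------------------------------------------------------------------------
# site-pattern simulation helpers


def _quartet_model(gamma: float, ne: float = 10_000.0, pulse_time: float = 200.0,
                   donor_samples: int = 1) -> msc_sim.SpeciesTreeModel:
    """(((P1,P2),P3),O) with an optional recent pulse P3 -> P2."""
    t12 = 2 * ne * 1.0      # 1 coalescent unit
    t123 = t12 + 2 * ne * 0.5
    tout = 10 * ne
    nwk = (f"(((P1:{t12},P2:{t12})a:{t123 - t12},P3:{t123})b:{tout - t123},"
           f"O:{tout})r;")
    edges = []
    if gamma > 0:
        edges = [{"donor": "P3", "recipient": "P2", "time": pulse_time,
                  "gamma": gamma}]
    return msc_sim.SpeciesTreeModel(nwk, ne=ne, edges=edges)


def simulate_snp_alignment(model: msc_sim.SpeciesTreeModel,
                           samples: dict[str, int], n_loci: int,
                           locus_length: int, mu: float, seed: int
                           ) -> dict[str, np.ndarray]:
    """Concatenated per-taxon sequence matrices from unlinked loci."""
    trees, _ = msc_sim.simulate_gene_trees(model, samples, n_loci, seed)
    chunks: dict[str, list[np.ndarray]] = {t: [] for t in samples}
    for tr in trees:
        la = msc_sim.simulate_sequences(tr, locus_length, mu,
                                        seed=seed + 1_000_003 + tr.locus)
        idx = {s: i for i, s in enumerate(la.samples)}
        for taxon, k in samples.items():
            labs = [taxon] if k == 1 else [f"{taxon}_{i + 1}" for i in range(k)]
            chunks[taxon].append(la.matrix[[idx[lab] for lab in labs]])
    return {t: np.concatenate(v, axis=1) for t, v in chunks.items()}


def dstat_null_calibration(n_reps: int = 100, n_loci: int = 2000,
                           locus_length: int = 100, mu: float = 5e-7,
                           seed: int = 0) -> dict[str, float]:
    """Type-I error of |Z| >= 3 for Patterson's D under gamma = 0."""
    model = _quartet_model(gamma=0.0)
    quartet = ("P1", "P2", "P3", "O")
    false_pos = 0
    for r in range(n_reps):
        aln = simulate_snp_alignment(model, {t: 1 for t in quartet}, n_loci,
                                     locus_length, mu, seed=seed + 104_729 * r)
        d = introgression.patterson_d(
            introgression.count_site_patterns(aln, quartet))
        if not d.zero_se and abs(d.z) >= 3:
            false_pos += 1
    return {"type1_rate": false_pos / n_reps, "n_reps": n_reps,
            "sites_per_rep": n_loci * locus_length}


def dstat_power_and_f4(gamma: float = 0.2, n_reps: int = 100,
                       n_loci: int = 2000, locus_length: int = 100,
                       mu: float = 5e-7, seed: int = 0) -> dict[str, float]:
    """Power of D (|Z| >= 3) and mean f4-ratio under a recent pulse P3->P2."""
    model = _quartet_model(gamma=gamma, donor_samples=2)
    samples = {"P1": 1, "P2": 1, "P3": 2, "O": 1}
    quartet = ("P1", "P2", "P3", "O")
    detected = 0
    f4_values = []
    for r in range(n_reps):
        aln = simulate_snp_alignment(model, samples, n_loci, locus_length,
                                     mu, seed=seed + 15_485_863 * r % (2**31))
        d = introgression.patterson_d(
            introgression.count_site_patterns(aln, quartet))
        if not d.zero_se and d.z >= 3:
            detected += 1
        f4 = introgression.f4_ratio_from_alignment(aln, *quartet)
        f4_values.append(f4.value)
    return {"power": detected / n_reps,
            "f4_ratio_mean": float(np.mean(f4_values)),
            "gamma": gamma, "n_reps": n_reps,
            "sites_per_rep": n_loci * locus_length}


# ---------------------------------------------------------------------------
# f-branch localization


def _five_taxon_model(gamma: float, ne: float = 10_000.0,
                      pulse_time: float = 200.0) -> msc_sim.SpeciesTreeModel:
    """((((P1,P2),P3),P4),O) with pulse P3 -> P2 when gamma > 0."""
    u = 2 * ne
    t12, t123, t1234, tout = u, 1.5 * u, 2.5 * u, 10 * ne
    nwk = (f"((((P1:{t12},P2:{t12})a:{t123 - t12},P3:{t123})b:{t1234 - t123},"
           f"P4:{t1234})c:{tout - t1234},O:{tout})r;")
    edges = []
    if gamma > 0:
        edges = [{"donor": "P3", "recipient": "P2", "time": pulse_time,
                  "gamma": gamma}]
    return msc_sim.SpeciesTreeModel(nwk, ne=ne, edges=edges)


def fbranch_localization(gamma: float = 0.3, n_reps: int = 100,
                         n_loci: int = 1500, locus_length: int = 100,
                         mu: float = 5e-7, seed: int = 0) -> dict[str, float]:
    """How often the f-branch matrix maximum lands on the true cell.

    The true cell is (recipient's terminal branch, donor taxon) for a pulse
    P3 -> P2 on a 4-ingroup-taxon species tree.
    """
    model = _five_taxon_model(gamma=gamma)
    samples = {t: 2 for t in ("P1", "P2", "P3", "P4")}
    samples["O"] = 1
    trios = introgression.species_tree_trios(model.newick, "O")
    hits = 0
    for r in range(n_reps):
        aln = simulate_snp_alignment(model, samples, n_loci, locus_length,
                                     mu, seed=(seed + 32_452_843 * r) % (2**31))
        rows = []
        for p1, p2, p3 in trios:
            try:
                f4 = introgression.f4_ratio_from_alignment(aln, p1, p2, p3, "O")
            except (ValueError, ZeroDivisionError):
                continue
            rows.append({"P1": p1, "P2": p2, "P3": p3, "value": f4.value})
        fb = introgression.f_branch(model.newick, pd.DataFrame(rows), "O")
        mat = fb.matrix
        if mat.isna().all().all():
            continue
        flat = mat.stack()
        (branch, taxon) = flat.idxmax()
        if branch == "P2" and taxon == "P3":
            hits += 1
    return {"localization_rate": hits / n_reps, "gamma": gamma,
            "n_reps": n_reps, "sites_per_rep": n_loci * locus_length}


# ---------------------------------------------------------------------------
# branch-length mixture recovery


def quibl_recovery(pi2_values: Sequence[float] = (0.2, 0.5, 0.8),
                   n: int = 2000, n_reps: int = 20, lam: float = 1.0,
                   theta: float = 2.0, seed: int = 0) -> dict[float, float]:
    """Mean |pi2_hat - pi2| over replicates of mixture draws."""
    rng = np.random.default_rng(seed)
    out = {}
    for pi2 in pi2_values:
        errs = []
        for _ in range(n_reps):
            n2 = int(rng.binomial(n, pi2))
            x = np.concatenate([rng.exponential(lam, n - n2),
                                theta + rng.exponential(lam, n2)])
            fit = introgression.quibl_em(x, seed=int(rng.integers(2**31)))
            errs.append(abs(fit.pi2 - pi2))
        out[pi2] = float(np.mean(errs))
    return out


# ---------------------------------------------------------------------------
# ROH recovery


def roh_recovery(length: int = 3_000_000, window: int = 10_000,
                 theta_bg: float = 0.002, theta_roh: float = 0.0002,
                 seed: int = 0) -> dict[str, float]:
    """Middle-third ROH construction plus a null genome.

    Returns base-level overlap with truth, the absolute error of the
    recovered ROH fraction against 1/3, and the false ROH fraction on a
    genome without any ROH.
    """
    truth_iv = [(length // 3, 2 * length // 3)]
    g, _ = msc_sim.simulate_diploid_with_roh(length, theta_bg, truth_iv,
                                             theta_roh, seed=seed)
    track, _, _ = diversity_demog.window_heterozygosity(g, window=window)
    res = diversity_demog.roh_hmm(track, theta_roh=theta_roh)
    state = np.zeros(track.n_windows, dtype=bool)
    for _, s, e, _ in res.segments:
        state[s // window:e // window] = True
    truth = np.zeros(track.n_windows, dtype=bool)
    truth[truth_iv[0][0] // window:truth_iv[0][1] // window] = True
    overlap = float((state & truth).sum() / truth.sum())

    g0, _ = msc_sim.simulate_diploid_with_roh(length, theta_bg, [],
                                              theta_roh, seed=seed + 1)
    track0, _, _ = diversity_demog.window_heterozygosity(g0, window=window)
    res0 = diversity_demog.roh_hmm(track0, theta_roh=theta_roh)
    return {"base_overlap": overlap,
            "fraction_error": abs(res.roh_fraction - 1 / 3),
            "null_roh_fraction": res0.roh_fraction}
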