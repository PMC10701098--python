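import math

import numpy as np
import pytest

from phylofrag import msc_sim
from phylofrag._trees import leaf_path_distances


def triplet_model(t_coal: float, ne: float = 400.0, gamma: float = 0.0,
                  pulse_time: float = 100.0) -> msc_sim.SpeciesTreeModel:
    gens = t_coal * 2 * ne
    edges = []
    if gamma > 0:
        edges = [{"donor": "C", "recipient": "B", "time": pulse_time,
                  "gamma": gamma}]
    return msc_sim.SpeciesTreeModel(
        f"((A:1000,B:1000)ab:{gens},C:{1000 + gens})r;", ne=ne, edges=edges)


AB = frozenset([frozenset("AB")])
BC = frozenset([frozenset("BC")])


class TestSpeciesTreeModel:
    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="ultrametric"):
            msc_sim.SpeciesTreeModel("((A:1000,B:500)ab:100,C:1100)r;", ne=100)
        with pytest.raises(ValueError, match="Ne must be positive"):
            msc_sim.SpeciesTreeModel("((A:10,B:10)ab:5,C:15)r;", ne=-1)
        with pytest.raises(ValueError, match="mu must be positive"):
            msc_sim.SpeciesTreeModel("((A:10,B:10)ab:5,C:15)r;", ne=10, mu=0)
        with pytest.raises(ValueError, match="outside branch"):
            triplet_model(1.0, gamma=0.5, pulse_time=5000.0)

    def test_config_roundtrip(self):
        m = triplet_model(1.0, gamma=0.2)
        m2 = msc_sim.SpeciesTreeModel.from_config(m.to_config())
        assert m2.newick == m.newick
        assert m2.ne == m.ne
        assert m2.edges == m.edges

    def test_example_model_loads(self):
        m = msc_sim.example_model()
        assert len(m.taxa) == 9
        assert len(m.edges) == 2
        assert m.mu == pytest.approx(0.86e-8)
        assert m.gen_time == pytest.approx(3.8)


class TestSimulateGeneTrees:
    def test_two_taxon_mean_tmrca_matches_closed_form(self):
        T, ne, n = 1000.0, 500.0, 8000
        m = msc_sim.SpeciesTreeModel(f"(A:{T},B:{T})r;", ne=ne)
        trees, _ = msc_sim.simulate_gene_trees(m, {"A": 1, "B": 1}, n, seed=11)
        mean = np.mean([t.tmrca() for t in trees])
        se = 2 * ne / math.sqrt(n)  # TMRCA-T is Exp(mean 2Ne)
        assert abs(mean - (T + 2 * ne)) < 3 * se

    @pytest.mark.parametrize("t_coal", [0.0, 1.0])
    def test_triplet_topology_frequencies(self, t_coal):
        n = 8000
        trees, _ = msc_sim.simulate_gene_trees(
            triplet_model(t_coal), {"A": 1, "B": 1, "C": 1}, n, seed=5)
        conc = sum(1 for t in trees if t.topology_class() == AB)
        p = msc_sim.expected_triplet_frequencies(t_coal)[0]
        assert abs(conc / n - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_full_pulse_makes_donor_recipient_pair_modal(self):
        n = 4000
        trees, truth = msc_sim.simulate_gene_trees(
            triplet_model(1.0, gamma=1.0), {"A": 1, "B": 1, "C": 1}, n, seed=6)
        bc = sum(1 for t in trees if t.topology_class() == BC)
        assert bc / n > 0.5
        assert all(rec.introgressed for rec in truth)

    def test_matches_independent_coalescent_simulator(self):
        """Concordance frequency agrees with msprime on the same model."""
        msprime = pytest.importorskip("msprime")
        ne, t_coal, n = 400.0, 1.0, 4000
        gens = t_coal * 2 * ne
        dem = msprime.Demography()
        # with ploidy=1 msprime coalesces pairs at rate 1/N, so a diploid
        # effective size ne corresponds to initial_size = 2*ne
        for name in ("A", "B", "C", "AB", "ABC"):
            dem.add_population(name=name, initial_size=2 * ne)
        dem.add_population_split(time=1000, derived=["A", "B"], ancestral="AB")
        dem.add_population_split(time=1000 + gens, derived=["AB", "C"],
                                 ancestral="ABC")
        reps = msprime.sim_ancestry(
            samples={"A": 1, "B": 1, "C": 1}, demography=dem, ploidy=1,
            num_replicates=n, random_seed=42)
        conc_ms = 0
        for ts in reps:
            tree = ts.first()
            if tree.mrca(0, 1) != tree.root:
                conc_ms += 1
        trees, _ = msc_sim.simulate_gene_trees(
            triplet_model(t_coal, ne=ne), {"A": 1, "B": 1, "C": 1}, n, seed=7)
        conc = sum(1 for t in trees if t.topology_class() == AB)
        p = msc_sim.expected_triplet_frequencies(t_coal)[0]
        se = math.sqrt(p * (1 - p) / n)
        assert abs(conc / n - conc_ms / n) < 4 * se

    def test_seed_reproducibility(self):
        m = triplet_model(0.5, gamma=0.3)
        a, ta = msc_sim.simulate_gene_trees(m, {"A": 1, "B": 1, "C": 1}, 50,
                                            seed=9)
        b, tb = msc_sim.simulate_gene_trees(m, {"A": 1, "B": 1, "C": 1}, 50,
                                            seed=9)
        assert [t.newick() for t in a] == [t.newick() for t in b]
        assert ta == tb
        c, _ = msc_sim.simulate_gene_trees(m, {"A": 1, "B": 1, "C": 1}, 50,
                                           seed=10)
        assert [t.newick() for t in a] != [t.newick() for t in c]

    def test_unknown_taxon_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            msc_sim.simulate_gene_trees(triplet_model(1.0), {"Z": 1}, 1, seed=0)

    def test_multi_lineage_labels_and_truth(self):
        trees, truth = msc_sim.simulate_gene_trees(
            triplet_model(2.0), {"A": 2, "B": 1, "C": 1}, 20, seed=3)
        assert trees[0].leaves() == {"A_1", "A_2", "B", "C"}
        assert all(not rec.introgressed for rec in truth)


class TestExpectedTripletFrequencies:
    def test_values(self):
        assert msc_sim.expected_triplet_frequencies(0.0) == pytest.approx(
            (1 / 3, 1 / 3, 1 / 3))
        conc, d1, d2 = msc_sim.expected_triplet_frequencies(1.0)
        # 1 - (2/3)e^-1 = 0.754747...
        assert conc == pytest.approx(1 - (2 / 3) * math.exp(-1), abs=1e-12)
        assert round(conc, 4) == 0.7547
        assert round(d1, 4) == round(d2, 4) == 0.1226
        assert msc_sim.expected_triplet_frequencies(50.0)[0] == pytest.approx(1.0)

    def test_sums_to_one_and_rejects_negative(self):
        assert sum(msc_sim.expected_triplet_frequencies(0.7)) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            msc_sim.expected_triplet_frequencies(-0.1)


def two_leaf_tree(depth: float) -> msc_sim.GeneTree:
    a = msc_sim.CoalNode("X", (), 0.0)
    b = msc_sim.CoalNode("Y", (), 0.0)
    return msc_sim.GeneTree(msc_sim.CoalNode(None, (a, b), depth), 0)


class TestSimulateSequences:
    def test_zero_branches_give_identical_sequences(self):
        la = msc_sim.simulate_sequences(two_leaf_tree(0.0), 500, 1e-3, seed=1)
        seqs = la.sequences()
        assert seqs["X"] == seqs["Y"]

    def test_jc69_expected_p_distance(self):
        # leaf-to-leaf path of 0.01 expected substitutions
        L = 100_000
        la = msc_sim.simulate_sequences(two_leaf_tree(500.0), L, 1e-5, seed=2)
        p = 0.75 * (1 - math.exp(-4 * 0.01 / 3))
        obs = np.mean(la.matrix[0] != la.matrix[1])
        assert abs(obs - p) < 3 * math.sqrt(p * (1 - p) / L)

    def test_jc69_saturation(self):
        la = msc_sim.simulate_sequences(two_leaf_tree(1e9), 20_000, 1e-5, seed=3)
        obs = np.mean(la.matrix[0] != la.matrix[1])
        assert abs(obs - 0.75) < 0.02

    def test_hky_runs_and_is_reproducible(self):
        t = two_leaf_tree(500.0)
        a = msc_sim.simulate_sequences(t, 1000, 1e-5, model="HKY", seed=4,
                                       kappa=4.0)
        b = msc_sim.simulate_sequences(t, 1000, 1e-5, model="HKY", seed=4,
                                       kappa=4.0)
        assert (a.matrix == b.matrix).all()

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown substitution model"):
            msc_sim.simulate_sequences(two_leaf_tree(1.0), 10, 1e-5,
                                       model="GTR")


class TestAssembleGenomes:
    def _loci(self, n=4, L=1000, seed=0):
        m = triplet_model(1.0)
        trees, _ = msc_sim.simulate_gene_trees(m, {"A": 1, "B": 1, "C": 1},
                                               n, seed=seed)
        return [msc_sim.simulate_sequences(t, L, 1e-5, seed=seed + t.locus)
                for t in trees]

    def test_lossless_concatenation(self):
        loci = self._loci()
        genomes, mask, truth = msc_sim.assemble_genomes(loci, 0.0, 0.0, seed=1)
        concat = "".join(la.sequences()["A"] for la in loci)
        assert genomes["A"].chromosomes["chr1"] == concat
        assert mask.total_masked() == 0
        assert [(s, e) for _, _, s, e in truth] == [
            (i * 1000, (i + 1) * 1000) for i in range(4)]

    def test_mask_fraction_emulates_repeat_content(self):
        loci = self._loci(n=100, L=1000)  # 100 kb genome
        _, mask, _ = msc_sim.assemble_genomes(loci, 0.0, 0.44, seed=2)
        assert 44_000 <= mask.total_masked() <= 46_000

    def test_missing_rate_injected_per_sample(self):
        loci = self._loci(n=20, L=1000)
        genomes, _, _ = msc_sim.assemble_genomes(loci, 0.25, 0.0, seed=3)
        frac = genomes["B"].chromosomes["chr1"].count("N") / 20_000
        assert 0.25 <= frac <= 0.30

    def test_same_seed_identical_output(self):
        loci = self._loci()
        g1, m1, _ = msc_sim.assemble_genomes(loci, 0.1, 0.2, seed=7)
        g2, m2, _ = msc_sim.assemble_genomes(loci, 0.1, 0.2, seed=7)
        assert g1["C"].chromosomes == g2["C"].chromosomes
        assert m1.intervals == m2.intervals

    def test_inconsistent_samples_rejected(self):
        loci = self._loci(n=2)
        loci[1].samples = ["A", "B", "Z"]
        with pytest.raises(ValueError, match="inconsistent sample sets"):
            msc_sim.assemble_genomes(loci, 0.0, 0.0, seed=0)


class TestDiploidAndPseudohaploid:
    def test_roh_interval_suppresses_heterozygosity(self):
        g, truth = msc_sim.simulate_diploid_with_roh(
            30_000, 0.002, [(10_000, 20_000)], 0.0, seed=1)
        assert truth == [(10_000, 20_000)]
        assert g.genotypes[10_000:20_000].sum() == 0
        assert g.genotypes[:10_000].sum() > 0

    def test_het_count_binomial(self):
        L, theta = 1_000_000, 0.002
        g, _ = msc_sim.simulate_diploid_with_roh(L, theta, [], 0.0002, seed=2)
        n_het = int((g.genotypes == 1).sum())
        sd = math.sqrt(L * theta * (1 - theta))
        assert abs(n_het - L * theta) < 3 * sd

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            msc_sim.simulate_diploid_with_roh(100, 0.01, [(0, 50), (40, 80)],
                                              0.0, seed=0)

    def test_pseudohaploid_hom_sites_deterministic(self):
        g, _ = msc_sim.simulate_diploid_with_roh(1000, 0.0, [], 0.0, seed=3)
        s1 = msc_sim.pseudohaploidize(g, seed=1)
        s2 = msc_sim.pseudohaploidize(g, seed=99)
        assert s1 == s2  # no het sites -> no randomness
        assert set(s1) <= set("ACGT")

    def test_pseudohaploid_het_sites_fair_coin(self):
        L = 10_000
        g, _ = msc_sim.simulate_diploid_with_roh(L, 1.0, [], 1.0, seed=4)
        assert (g.genotypes == 1).all()
        seq = msc_sim.pseudohaploidize(g, seed=5)
        codes = np.frombuffer(seq.encode(), dtype=np.uint8)
        ref_picked = int((codes == np.frombuffer("ACGTN".encode(),
                                                 dtype=np.uint8)[g.ref]).sum())
        assert abs(ref_picked - L / 2) < 3 * math.sqrt(L * 0.25)

    def test_pseudohaploid_uncallable_is_n(self):
        g, _ = msc_sim.simulate_diploid_with_roh(100, 0.0, [], 0.0, seed=6)
        g.callable_mask[10:20] = False
        seq = msc_sim.pseudohaploidize(g, seed=0)
        assert seq[10:20] == "N" * 10
        assert "N" not in seq[:10]
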