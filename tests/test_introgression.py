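import math

import numpy as np
import pandas as pd
import pytest

from phylofrag import introgression as ig
from phylofrag._trees import parse_newick


QUARTET = ("P1", "P2", "P3", "O")


class TestSitePatterns:
    def test_fixed_abba_site(self):
        aln = {"P1": "A", "P2": "C", "P3": "C", "O": "A"}
        abba, baba, bbaa, usable = ig.site_pattern_weights(aln, QUARTET)
        assert usable[0]
        assert (abba[0], baba[0], bbaa[0]) == (1.0, 0.0, 0.0)

    def test_polymorphic_p2_half_weight(self):
        aln = {"P1": ["A"], "P2": ["A", "C"], "P3": ["C"], "O": ["A"]}
        abba, baba, bbaa, _ = ig.site_pattern_weights(aln, QUARTET)
        assert abba[0] == pytest.approx(0.5)
        assert baba[0] == 0.0

    def test_monomorphic_and_triallelic_sites_ignored(self):
        aln = {"P1": "AAG", "P2": "AAC", "P3": "ACT", "O": "AAA"}
        abba, baba, bbaa, usable = ig.site_pattern_weights(aln, QUARTET)
        assert not usable[0]  # monomorphic
        assert not usable[2]  # three alleles
        assert abba[0] == baba[0] == bbaa[0] == 0.0

    def test_bbaa_pattern(self):
        aln = {"P1": "C", "P2": "C", "P3": "A", "O": "A"}
        abba, baba, bbaa, _ = ig.site_pattern_weights(aln, QUARTET)
        assert bbaa[0] == 1.0 and abba[0] == 0.0

    def test_blocks_near_equal_and_errors(self):
        rng = np.random.default_rng(0)
        n = 1000
        p1 = "".join(rng.choice(list("AC"), n))
        aln = {"P1": p1, "P2": p1[::-1], "P3": p1, "O": "A" * n}
        pb = ig.count_site_patterns(aln, QUARTET, n_blocks=10)
        assert pb.n_blocks == 10
        assert pb.sizes.sum() > 0
        assert pb.sizes.max() - pb.sizes.min() <= 1
        with pytest.raises(ValueError, match="usable sites"):
            ig.count_site_patterns({"P1": "AC", "P2": "CA", "P3": "AC",
                                    "O": "AA"}, QUARTET, n_blocks=10)
        with pytest.raises(ValueError, match="missing"):
            ig.count_site_patterns(aln, ("P1", "P2", "PX", "O"))


def blocks_from(abba, baba, sizes=None):
    abba = np.asarray(abba, float)
    baba = np.asarray(baba, float)
    if sizes is None:
        sizes = np.ones_like(abba)
    return ig.PatternBlocks(QUARTET, abba, baba, np.zeros_like(abba),
                            np.asarray(sizes, float))


class TestPattersonD:
    def test_simple_ratio(self):
        d = ig.patterson_d(blocks_from([10, 10, 10], [4, 3, 3]))
        assert d.d == pytest.approx(0.5)
        assert d.abba == 30 and d.baba == 10

    def test_swapping_p1_p2_negates_d(self):
        rng = np.random.default_rng(1)
        n = 400
        seqs = {t: "".join(rng.choice(list("AC"), n)) for t in QUARTET}
        seqs["O"] = "A" * n
        pb = ig.count_site_patterns(seqs, QUARTET, n_blocks=5)
        swapped = ig.count_site_patterns(seqs, ("P2", "P1", "P3", "O"),
                                         n_blocks=5)
        d1 = ig.patterson_d(pb)
        d2 = ig.patterson_d(swapped)
        assert d1.d == pytest.approx(-d2.d)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            ig.patterson_d(blocks_from([0, 0], [0, 0]))


class TestBlockJackknife:
    def test_matches_delete_one_closed_form(self):
        """Equal-size blocks reduce to the standard jackknife of the mean."""
        vals = np.array([1.0, 2.0, 3.0, 4.0])
        g = len(vals)
        # the mean expressed as a ratio statistic: sum / block count
        comp = np.stack([vals, np.ones(g)], axis=1)

        est, se, z, p, flag = ig.block_jackknife(
            comp, lambda tot: tot[0] / tot[1], np.ones(g))
        # delete-one means and classical formula
        theta_del = np.array([(vals.sum() - v) / (g - 1) for v in vals])
        se_expect = math.sqrt((g - 1) / g * ((theta_del - theta_del.mean()) ** 2).sum())
        assert est == pytest.approx(vals.mean())
        assert se == pytest.approx(se_expect)
        assert not flag

    def test_identical_blocks_flagged_zero_se(self):
        d = ig.patterson_d(blocks_from([5, 5, 5], [1, 1, 1]))
        assert d.zero_se and math.isnan(d.z)

    def test_normal_p_value(self):
        comp = np.array([[1.0], [2.0], [1.5], [2.5]])
        est, se, z, p, _ = ig.block_jackknife(comp, lambda t: t[0],
                                              np.ones(4))
        from scipy.stats import norm
        assert p == pytest.approx(2 * norm.sf(abs(z)))
        assert 2 * norm.sf(1.96) == pytest.approx(0.05, abs=1e-3)

    def test_requires_two_blocks(self):
        with pytest.raises(ValueError, match="2 blocks"):
            ig.block_jackknife(np.array([[1.0]]), lambda t: t[0], np.ones(1))


class TestF4Ratio:
    def test_recipient_cloned_from_donor_gives_one(self):
        rng = np.random.default_rng(2)
        n = 2000
        donor_a = "".join(rng.choice(list("AC"), n))
        donor_b = "".join(rng.choice(list("AC"), n))
        aln = {"P1": ["A" * n], "P2": [donor_b], "P3": [donor_a, donor_b],
               "O": ["A" * n]}
        f4 = ig.f4_ratio_from_alignment(aln, *QUARTET)
        assert f4.value == pytest.approx(1.0)

    def test_single_donor_sample_unavailable(self):
        aln = {"P1": "ACAC", "P2": "CACA", "P3": "ACCA", "O": "AAAA"}
        with pytest.raises(ValueError, match="two samples of the donor"):
            ig.f4_ratio_from_alignment(aln, *QUARTET)

    def test_zero_denominator_rejected(self):
        num = blocks_from([5, 5], [1, 1])
        den = blocks_from([2, 2], [2, 2])
        with pytest.raises(ZeroDivisionError):
            ig.f4_ratio(num, den)


class TestFBranch:
    SPECIES = "((((P1:1,P2:1):1,P3:2):1,P4:3):1,O:4);"

    def test_manual_aggregation(self):
        rows = []
        # f(P2, P3) from two P1-configurations: median of 0.1, 0.3 = 0.2
        rows.append({"P1": "P1", "P2": "P2", "P3": "P3", "value": 0.1})
        rows.append({"P1": "P4", "P2": "P2", "P3": "P3", "value": 0.3})
        # f(P1, P3) available too; min over {P1,P2} descendants applies
        rows.append({"P1": "P2", "P2": "P1", "P3": "P3", "value": 0.05})
        rows.append({"P1": "P4", "P2": "P1", "P3": "P3", "value": 0.07})
        fb = ig.f_branch(self.SPECIES, pd.DataFrame(rows), "O")
        mat = fb.matrix
        assert mat.loc["P2", "P3"] == pytest.approx(0.2)
        assert mat.loc["P1", "P3"] == pytest.approx(0.06)
        # internal branch (P1,P2): min(f(P1,P3), f(P2,P3)) = 0.06
        assert mat.loc["P1,P2", "P3"] == pytest.approx(0.06)

    def test_negative_values_clamped_and_self_cells_undefined(self):
        rows = [{"P1": "P2", "P2": "P1", "P3": "P3", "value": -0.1}]
        fb = ig.f_branch(self.SPECIES, pd.DataFrame(rows), "O")
        assert fb.matrix.loc["P1", "P3"] == 0.0
        assert math.isnan(fb.matrix.loc["P1", "P1"])  # donor inside branch
        assert math.isnan(fb.matrix.loc["P1,P2", "P2"])

    def test_species_tree_trios(self):
        trios = ig.species_tree_trios(self.SPECIES, "O")
        assert ("P1", "P2", "P3") in trios and ("P2", "P1", "P3") in trios
        assert ("P3", "P1", "P2") not in trios  # P3 cannot be the cherry
        assert len(trios) == 8  # 4 leaf trios x 2 orderings


class TestTripletLengths:
    def test_internal_length_and_counts(self):
        trees = [parse_newick("(((A:1,B:1):0.5,C:1.5):1,O:2.5);")] * 3 + \
                [parse_newick("(((A:1,C:1):0.2,B:1.2):1,O:2.2);")] * 2 + \
                [parse_newick("((A:1,B:1):1,O:2);")]  # missing C -> skipped
        tl = ig.extract_triplet_lengths(trees, ("A", "B", "C"), "O")
        assert tl.counts()[frozenset("AB")] == 3
        assert tl.counts()[frozenset("AC")] == 2
        assert tl.lengths[frozenset("AB")] == pytest.approx([0.5] * 3)
        assert tl.lengths[frozenset("AC")] == pytest.approx([0.2] * 2)
        total = sum(tl.counts().values()) + tl.skipped
        assert total == 5  # the 4-leaf trees only


class TestQuiblEM:
    def test_null_prefers_single_component(self, rng):
        x = rng.exponential(1.0, 2000)
        fit = ig.quibl_em(x, seed=1)
        assert fit.bic1 < fit.bic2
        verdict = ig.quibl_classify(fit)
        assert verdict["verdict"] == "ILS-only"
        assert verdict["pi2"] is None

    def test_pure_alternative_recovers_offset(self, rng):
        x = 2.0 + rng.exponential(1.0, 2000)
        fit = ig.quibl_em(x, seed=2)
        assert fit.pi2 > 0.9
        assert 1.8 <= fit.theta <= 2.2
        assert ig.quibl_classify(fit)["verdict"] == "ILS+introgression"

    def test_balanced_mixture_recovery(self, rng):
        x = np.concatenate([rng.exponential(1.0, 1000),
                            2.0 + rng.exponential(1.0, 1000)])
        fit = ig.quibl_em(x, seed=3)
        assert 0.4 <= fit.pi2 <= 0.6
        assert fit.delta_bic > 10

    def test_loglik_trace_monotone(self, rng):
        x = np.concatenate([rng.exponential(1.0, 300),
                            1.5 + rng.exponential(1.0, 200)])
        fit = ig.quibl_em(x, seed=4)
        assert all(b >= a - 1e-7 for a, b in zip(fit.trace, fit.trace[1:]))

    def test_classification_rule(self):
        fit = ig.QuiblFit(0.5, 1.0, 2.0, -10.0, -8.0, 20.0, 17.0, 100)
        assert ig.quibl_classify(fit)["verdict"] == "ILS-only"  # dBIC=3
        fit2 = ig.QuiblFit(0.5, 1.0, 2.0, -10.0, -8.0, 40.0, 10.0, 100)
        out = ig.quibl_classify(fit2)  # dBIC=30
        assert out["verdict"] == "ILS+introgression"
        assert out["pi2"] == 0.5

    def test_low_power_flag_and_errors(self, rng):
        fit = ig.quibl_em(rng.exponential(1.0, 10), seed=5)
        assert fit.low_power
        with pytest.raises(ValueError, match="positive"):
            ig.quibl_em([1.0, -0.5])
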