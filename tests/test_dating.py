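"""Distance models, NJ recovery on additive matrices, Fitch parsimony
against exhaustive minimisation, calibration-prior algebra and
strict-clock least-squares dating."""

import itertools
import math

import dendropy
import numpy as np
import pytest
from scipy.integrate import quad

from botodelim.containers import HaplotypeAlignment, InputError
from botodelim.dating import (DistanceMatrix, build_calibration,
                              bootstrap_monophyly, default_calibrations,
                              fitch_score, neighbor_joining,
                              pairwise_distance, rate_time_convert,
                              strict_clock_dating, three_lineage_tree,
                              OptimizationError, SATURATED)
from botodelim.simulate import SyntheticSeqSpec, simulate_sequence_alignment


class TestPairwiseDistance:
    def test_identical_pair_zero_all_models(self):
        aln = HaplotypeAlignment(["a", "b"], ["g", "h"], ["ACGTA", "ACGTA"])
        for model in ("p", "JC69", "K80"):
            assert pairwise_distance(aln, model).get("a", "b") == 0.0

    def test_jc69_closed_form(self):
        # p = 3/80 = 0.0375 -> d = -3/4 ln(1 - 0.05) = 0.038470 (5 s.f.)
        seq_a = "A" * 80
        seq_b = "G" * 3 + "A" * 77
        aln = HaplotypeAlignment(["a", "b"], ["g", "h"], [seq_a, seq_b])
        d = pairwise_distance(aln, "JC69").get("a", "b")
        assert d == pytest.approx(-0.75 * math.log(1 - 4 * 0.0375 / 3), rel=1e-12)
        assert d == pytest.approx(0.038470, abs=5e-6)

    def test_jc_dominates_p(self, three_lineage_alignment):
        p = pairwise_distance(three_lineage_alignment, "p").values
        jc = pairwise_distance(three_lineage_alignment, "JC69").values
        assert np.all(jc >= p - 1e-12)

    def test_saturation_sentinel(self):
        aln = HaplotypeAlignment(["a", "b"], ["g", "h"], ["AAAA", "CCCC"])
        assert pairwise_distance(aln, "JC69").get("a", "b") == SATURATED

    def test_ambiguous_sites_excluded_pairwise(self):
        aln = HaplotypeAlignment(["a", "b"], ["g", "h"], ["ACN-", "ACGT"])
        assert pairwise_distance(aln, "p").get("a", "b") == 0.0

    def test_k80_equals_jc_when_rates_equal(self):
        # transitions and transversions at JC proportions -> K80 close to JC
        seq_a = "A" * 300
        seq_b = "G" * 5 + "C" * 5 + "T" * 5 + "A" * 285
        aln = HaplotypeAlignment(["a", "b"], ["g", "h"], [seq_a, seq_b])
        jc = pairwise_distance(aln, "JC69").get("a", "b")
        k80 = pairwise_distance(aln, "K80").get("a", "b")
        assert k80 == pytest.approx(jc, rel=0.02)


class TestNeighborJoining:
    def _tree_distances(self, tree):
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        return lambda a, b: pdm.distance(taxa[a], taxa[b])

    def test_three_taxon_branch_lengths(self):
        d = DistanceMatrix(["a", "b", "c"],
                           np.array([[0, 0.2, 0.5], [0.2, 0, 0.5], [0.5, 0.5, 0]]))
        tree = neighbor_joining(d)
        dist = self._tree_distances(tree)
        assert dist("a", "b") == pytest.approx(0.2, abs=1e-9)
        assert dist("a", "c") == pytest.approx(0.5, abs=1e-9)

    def test_additive_four_taxon_recovery(self):
        # tree ((a:1,b:2):1,(c:3,d:4)); path distances are additive
        vals = {("a", "b"): 3, ("a", "c"): 5, ("a", "d"): 6,
                ("b", "c"): 6, ("b", "d"): 7, ("c", "d"): 7}
        taxa = ["a", "b", "c", "d"]
        m = np.zeros((4, 4))
        for (x, y), v in vals.items():
            i, j = taxa.index(x), taxa.index(y)
            m[i, j] = m[j, i] = v
        tree = neighbor_joining(DistanceMatrix(taxa, m))
        dist = self._tree_distances(tree)
        for (x, y), v in vals.items():
            assert dist(x, y) == pytest.approx(v, abs=1e-9)

    def test_newick_round_trip(self, three_lineage_alignment):
        tree = neighbor_joining(pairwise_distance(three_lineage_alignment, "p"))
        newick = tree.as_string(schema="newick")
        re_read = dendropy.Tree.get(data=newick, schema="newick",
                                    taxon_namespace=tree.taxon_namespace)
        assert (dendropy.calculate.treecompare.symmetric_difference(
            tree, re_read) == 0)

    def test_nonfinite_rejected(self):
        m = np.array([[0, 1, np.inf], [1, 0, 1], [np.inf, 1, 0]])
        with pytest.raises(InputError):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], m))


def brute_force_parsimony(tree, alignment):
    """Minimise changes over all internal-state assignments exhaustively."""
    internal = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    seq_by_id = dict(zip(alignment.ids, alignment.sequences))
    total = 0
    for s in range(alignment.length):
        best = None
        for assignment in itertools.product("ACGT", repeat=len(internal)):
            state = {id(n): a for n, a in zip(internal, assignment)}
            for leaf in tree.leaf_node_iter():
                state[id(leaf)] = seq_by_id[leaf.taxon.label][s]
            changes = 0
            for node in tree.preorder_node_iter():
                for child in node.child_nodes():
                    changes += state[id(node)] != state[id(child)]
            best = changes if best is None else min(best, changes)
        total += best
    return total


class TestFitchScore:
    def test_invariant_alignment_zero(self):
        aln = HaplotypeAlignment(["a", "b", "c"], list("ghi"),
                                 ["AAA", "AAA", "AAA"])
        tree = dendropy.Tree.get(data="((a,b),c);", schema="newick")
        assert fitch_score(tree, aln) == 0

    def test_single_informative_site(self):
        aln = HaplotypeAlignment(list("abcd"), list("ghij"),
                                 ["A", "A", "C", "C"])
        tree = dendropy.Tree.get(data="((a,b),(c,d));", schema="newick")
        assert fitch_score(tree, aln) == 1

    def test_matches_exhaustive_minimisation(self, rng):
        topo = "((a,b),(c,(d,e)));"
        for _ in range(5):
            seqs = ["".join(rng.choice(list("ACGT"), size=4)) for _ in range(5)]
            aln = HaplotypeAlignment(list("abcde"), list("vwxyz"), seqs)
            tree = dendropy.Tree.get(data=topo, schema="newick")
            assert fitch_score(tree, aln) == brute_force_parsimony(tree, aln)

    def test_tip_mismatch_rejected(self):
        aln = HaplotypeAlignment(["a", "b"], ["g", "h"], ["A", "C"])
        tree = dendropy.Tree.get(data="((a,b),c);", schema="newick")
        with pytest.raises(InputError):
            fitch_score(tree, aln)


class TestBootstrapMonophyly:
    def test_strong_support_at_study_divergence(self, three_lineage_alignment):
        res = bootstrap_monophyly(three_lineage_alignment, reps=50, seed=2)
        assert all(s >= 0.9 for s in res.support.values())

    def test_no_signal_flag(self):
        aln = simulate_sequence_alignment(SyntheticSeqSpec(
            rate=0.0, within_theta=0.0, seed=1,
            samples_per_lineage=(3, 3, 3)))
        res = bootstrap_monophyly(aln, reps=5, seed=0)
        assert res.no_signal

    def test_singleton_group_trivially_supported(self):
        aln = simulate_sequence_alignment(SyntheticSeqSpec(
            seed=3, samples_per_lineage=(1, 4, 4)))
        res = bootstrap_monophyly(aln, reps=10, seed=0)
        assert "A" in res.trivial_groups and res.support["A"] == 1.0

    def test_sequence_order_invariance(self, three_lineage_alignment):
        res1 = bootstrap_monophyly(three_lineage_alignment, reps=20, seed=7)
        order = list(range(three_lineage_alignment.n))[::-1]
        shuffled = HaplotypeAlignment(
            [three_lineage_alignment.ids[i] for i in order],
            [three_lineage_alignment.groups[i] for i in order],
            [three_lineage_alignment.sequences[i] for i in order])
        res2 = bootstrap_monophyly(shuffled, reps=20, seed=7)
        assert set(res1.support) == set(res2.support)
        for g in res1.support:
            assert abs(res1.support[g] - res2.support[g]) <= 0.15


class TestCalibrationPriors:
    def test_mysticeti_odontoceti_worked_example(self):
        cal = build_calibration("mysticeti_odontoceti", 33.5, 40.0, sd=1.068)
        assert cal.mu == pytest.approx(math.log(6.5) - 1.6449 * 1.068, abs=1e-3)
        assert cal.mu == pytest.approx(0.1149, abs=1e-3)
        assert cal.quantile(0.95) == pytest.approx(40.0, abs=1e-9)

    def test_support_lower_bound(self):
        cal = build_calibration("x", 10.0, 11.2, sd=1.061)
        assert cal.quantile(1e-12) == pytest.approx(10.0, abs=1e-3)
        assert cal.cdf(9.99) == 0.0

    def test_all_packaged_calibrations_hit_their_upper_bound(self):
        for cal in default_calibrations():
            assert cal.quantile(0.95) == pytest.approx(cal.old, abs=1e-9)

    def test_density_integrates_to_one(self):
        cal = build_calibration("x", 11.2, 16.6, sd=1.223)
        total, _ = quad(cal.pdf, cal.offset, cal.offset + 5000)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_quantile_cdf_inverse(self):
        cal = build_calibration("x", 23.7, 30.0, sd=1.135)
        for q in (0.05, 0.5, 0.95):
            assert cal.cdf(cal.quantile(q)) == pytest.approx(q, abs=1e-9)

    def test_sigma_solved_when_sd_absent(self):
        cal = build_calibration("x", 33.5, 40.0)
        assert cal.mu == 0.0
        assert cal.quantile(0.95) == pytest.approx(40.0, abs=1e-9)

    def test_bad_ordering_rejected(self):
        with pytest.raises(InputError):
            build_calibration("x", 40.0, 33.5)


class TestStrictClockDating:
    def _clocklike_matrix(self, t1=2.08, t2=2.87, rate=0.0101):
        taxa = ["a", "b", "c"]
        m = np.array([[0, 2 * rate * t1, 2 * rate * t2],
                      [2 * rate * t1, 0, 2 * rate * t2],
                      [2 * rate * t2, 2 * rate * t2, 0]])
        return DistanceMatrix(taxa, m)

    def test_exact_recovery_on_clocklike_input(self):
        d = self._clocklike_matrix()
        fit = strict_clock_dating(d, three_lineage_tree(["a", "b", "c"]), 2.87)
        assert fit.height_of(["a", "b"]) == pytest.approx(2.08, rel=1e-9)
        assert fit.rate == pytest.approx(0.0101, rel=1e-9)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_three_taxon_height_ratio(self):
        d = self._clocklike_matrix(t1=1.0, t2=4.0, rate=0.01)
        fit = strict_clock_dating(d, three_lineage_tree(["a", "b", "c"]), 4.0)
        assert (fit.height_of(["a", "b"]) / 4.0
                == pytest.approx(d.get("a", "b") / d.get("a", "c"), rel=1e-9))

    def test_scale_consistency(self):
        d = self._clocklike_matrix()
        d2 = DistanceMatrix(d.taxa, d.values * 3.0)
        topo = three_lineage_tree(["a", "b", "c"])
        f1 = strict_clock_dating(d, topo, 2.87)
        f2 = strict_clock_dating(d2, three_lineage_tree(["a", "b", "c"]), 2.87)
        assert f2.rate == pytest.approx(3 * f1.rate, rel=1e-9)
        assert f2.height_of(["a", "b"]) == pytest.approx(
            f1.height_of(["a", "b"]), rel=1e-9)

    def test_five_taxon_forward_inverse(self):
        # forward-construct clocklike distances on ((a,b),(c,(d,e))) and invert
        heights = {("a", "b"): 1.0, ("d", "e"): 0.5, ("c", "d", "e"): 2.0,
                   ("a", "b", "c", "d", "e"): 3.0}
        rate = 0.02
        taxa = list("abcde")
        mrca = {}
        for pair in itertools.combinations(taxa, 2):
            for clade, h in sorted(heights.items(), key=lambda kv: kv[1]):
                if set(pair) <= set(clade):
                    mrca[pair] = h
                    break
        m = np.zeros((5, 5))
        for (x, y), h in mrca.items():
            i, j = taxa.index(x), taxa.index(y)
            m[i, j] = m[j, i] = 2 * rate * h
        topo = dendropy.Tree.get(data="((a,b),(c,(d,e)));", schema="newick")
        fit = strict_clock_dating(DistanceMatrix(taxa, m), topo, 3.0)
        for clade, h in heights.items():
            assert fit.height_of(clade) == pytest.approx(h, rel=1e-6)
        assert fit.rate == pytest.approx(rate, rel=1e-6)

    def test_zero_signal_raises(self):
        d = DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        with pytest.raises(OptimizationError):
            strict_clock_dating(d, three_lineage_tree(["a", "b", "c"]), 1.0)


class TestRateTimeConvert:
    def test_published_rate_arithmetic(self):
        # d = 0.0420 over T = 2.08 My -> r ~ 1.01e-8 /site/yr
        r = rate_time_convert(d=0.0420, T=2.08e6)
        assert r == pytest.approx(1.0096e-8, rel=1e-3)

    def test_zero_divergence_zero_rate(self):
        assert rate_time_convert(d=0.0, T=1e6) == 0.0

    def test_round_trip(self):
        r = rate_time_convert(d=0.05, T=2.5e6)
        assert rate_time_convert(r=r, T=2.5e6) == pytest.approx(0.05, abs=1e-12)
        assert rate_time_convert(d=0.05, r=r) == pytest.approx(2.5e6, rel=1e-12)

    def test_bad_inputs(self):
        with pytest.raises(InputError):
            rate_time_convert(d=0.1, T=0.0)
        with pytest.raises(InputError):
            rate_time_convert(d=0.1)
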