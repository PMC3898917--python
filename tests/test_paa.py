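"""Diagnostic-site analysis: profile construction against a brute-force
column scan, the disjointness rule against an exhaustive oracle, and the
aggregation invariants of individual-level PAA."""

import numpy as np
import pytest

from botodelim.containers import CharacterMatrix, HaplotypeAlignment, InputError
from botodelim.paa import (DiagnosticReport, MorphRange, diagnostic_counts,
                           find_diagnostic_sites, range_diagnosis,
                           site_state_profile)
from botodelim.simulate import SyntheticSeqSpec, simulate_sequence_alignment


def brute_force_profile(alignment):
    """Independent oracle: per-column set computation by direct scanning."""
    cells = {}
    for pos in range(1, alignment.length + 1):
        row = {}
        for g in alignment.group_names():
            states = set()
            for gg, s in zip(alignment.groups, alignment.sequences):
                if gg == g and s[pos - 1] in "ACGT":
                    states.add(s[pos - 1])
            row[g] = frozenset(states)
        if all(row.values()):
            cells[pos] = row
    return cells


def brute_force_diagnostics(matrix, mode="attribute"):
    """Oracle: test subset-disjointness exhaustively for every (site, group)."""
    hits = set()
    for locus in matrix.loci:
        for pos in matrix.positions(locus):
            row = matrix.cells[locus][pos]
            for g in row:
                union = set()
                for h in row:
                    if h != g:
                        union |= row[h]
                if not (row[g] & union) and (mode == "attribute" or len(row[g]) == 1):
                    hits.add((locus, pos, g))
    return hits


def random_matrix(rng, n_sites=15, groups=("g1", "g2", "g3")):
    bases = "ACGT"
    cells = {}
    for pos in range(1, n_sites + 1):
        row = {}
        for g in groups:
            k = rng.integers(1, 4)
            row[g] = frozenset(rng.choice(list(bases), size=k, replace=False))
        cells[pos] = row
    return CharacterMatrix({"locus": cells})


class TestSiteStateProfile:
    def test_identical_sequences_give_singletons(self):
        aln = HaplotypeAlignment(["a", "b"], ["g1", "g2"], ["ACGT", "ACGT"])
        m = site_state_profile(aln)
        for pos in m.positions("locus"):
            assert m.cell("locus", pos, "g1") == m.cell("locus", pos, "g2")
            assert len(m.cell("locus", pos, "g1")) == 1

    def test_polymorphic_group_collects_both_states(self):
        aln = HaplotypeAlignment(["a", "b", "c"], ["g1", "g1", "g2"],
                                 ["AAG", "AAA", "CCA"])
        assert site_state_profile(aln).cell("locus", 3, "g1") == {"A", "G"}

    def test_all_ambiguous_site_dropped_globally(self):
        aln = HaplotypeAlignment(["a", "b"], ["g1", "g2"], ["ANG", "ACG"])
        m = site_state_profile(aln)
        assert m.positions("locus") == [1, 3]

    def test_matches_brute_force_on_synthetic_lineages(self):
        aln = simulate_sequence_alignment(SyntheticSeqSpec(seed=7))
        m = site_state_profile(aln)
        oracle = brute_force_profile(aln)
        assert set(m.positions("locus")) == set(oracle)
        for pos, row in oracle.items():
            for g, states in row.items():
                assert m.cell("locus", pos, g) == states


class TestFindDiagnosticSites:
    def test_matches_exhaustive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for mode in ("attribute", "strict-fixed"):
            for _ in range(25):
                m = random_matrix(rng)
                got = {(e.locus, e.position, e.group)
                       for e in find_diagnostic_sites(m, mode).entries}
                assert got == brute_force_diagnostics(m, mode)

    def test_shared_state_site_diagnoses_nobody(self):
        m = CharacterMatrix({"l": {1: {"a": frozenset("A"),
                                       "b": frozenset("A"),
                                       "c": frozenset("A")}}})
        assert find_diagnostic_sites(m).entries == []

    def test_single_group_rejected(self):
        m = CharacterMatrix({"l": {1: {"a": frozenset("A")}}})
        with pytest.raises(InputError):
            find_diagnostic_sites(m)

    def test_label_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        m = random_matrix(rng)
        base = {(e.position, e.group) for e in find_diagnostic_sites(m).entries}
        swap = {"g1": "g2", "g2": "g1", "g3": "g3"}
        swapped = CharacterMatrix({"locus": {
            pos: {swap[g]: s for g, s in row.items()}
            for pos, row in m.cells["locus"].items()}})
        got = {(e.position, e.group) for e in find_diagnostic_sites(swapped).entries}
        assert got == {(p, swap[g]) for p, g in base}

    def test_growing_focal_set_never_creates_diagnostics(self):
        # adding a sequence to a group only grows its state set, so its own
        # diagnostic sites can only be lost, and other groups' only gained
        rng = np.random.default_rng(5)
        for _ in range(20):
            m = random_matrix(rng, n_sites=10)
            pos = int(rng.integers(1, 11))
            grown = {p: dict(r) for p, r in m.cells["locus"].items()}
            extra = frozenset(rng.choice(list("ACGT"), size=1))
            grown[pos]["g1"] = grown[pos]["g1"] | extra
            m2 = CharacterMatrix({"locus": grown})
            before = {(e.position, e.group)
                      for e in find_diagnostic_sites(m).entries}
            after = {(e.position, e.group)
                     for e in find_diagnostic_sites(m2).entries}
            assert not {x for x in after - before if x[1] == "g1"}

    def test_attribute_superset_of_strict_fixed(self, table2):
        attr = {(e.locus, e.position, e.group)
                for e in find_diagnostic_sites(table2, "attribute").entries}
        strict = {(e.locus, e.position, e.group)
                  for e in find_diagnostic_sites(table2, "strict-fixed").entries}
        assert strict <= attr
        # the two rules differ exactly at sites with a polymorphic focal set
        diff = attr - strict
        for locus, pos, g in diff:
            assert len(table2.cell(locus, pos, g)) >= 2
        assert ("cytb", 873, "geoffrensis") in diff


class TestDiagnosticCounts:
    def test_counts_conserve_entries(self, table2):
        rep = find_diagnostic_sites(table2)
        counts = diagnostic_counts(rep)
        assert counts.to_numpy().sum() == len(rep.entries)

    def test_empty_report_all_zero(self):
        rep = DiagnosticReport([], groups=("a", "b"), loci=("l",))
        assert diagnostic_counts(rep).to_numpy().sum() == 0


class TestRangeDiagnosis:
    TEETH = MorphRange("teeth/hemimandible", "araguaiaensis", 24, 28)

    @pytest.mark.parametrize("other, verdict", [
        (MorphRange("teeth/hemimandible", "boliviensis", 31, 35), "disjoint"),
        (MorphRange("teeth/hemimandible", "geoffrensis", 25, 29), "overlapping"),
        (MorphRange("teeth/hemimandible", "x", 24, 28), "overlapping"),
    ])
    def test_tooth_count_ranges(self, other, verdict):
        assert range_diagnosis(self.TEETH, other) == verdict

    def test_braincase_width_ranges_disjoint(self):
        a = MorphRange("parietal braincase width", "araguaiaensis", 9.6, 11.5,
                       n=2, units="cm")
        b = MorphRange("parietal braincase width", "geoffrensis", 11.6, 13.5,
                       n=9, units="cm")
        assert range_diagnosis(a, b) == "disjoint"

    def test_trait_mismatch_rejected(self):
        with pytest.raises(InputError):
            range_diagnosis(self.TEETH, MorphRange("other", "x", 1, 2))
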