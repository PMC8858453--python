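"""Selection strategies: NRM, H greedy, P1 greedy, key ancestors, combined."""

from collections import Counter

import numpy as np
import pytest

import seqpanel as sp
from seqpanel.haplib import Core, CoreLibrary, HaplotypeLibrary

from conftest import make_pedigree, random_pedigree


# ---------------------------------------------------------------------------
# numerator relationship matrix
# ---------------------------------------------------------------------------

class TestBuildNrm:
    def test_parent_offspring_relationship_half(self):
        ped = make_pedigree([
            ("A", "0", "0", "M", 2), ("B", "0", "0", "F", 2),
            ("C", "A", "B", "M", 1),
        ])
        nrm = sp.build_nrm(ped)
        assert nrm.a("A", "C") == pytest.approx(0.5)
        assert nrm.a("A", "B") == 0.0
        assert nrm.a("C", "C") == pytest.approx(1.0)

    def test_full_sibs_and_inbred_offspring(self):
        ped = make_pedigree([
            ("A", "0", "0", "M", 3), ("B", "0", "0", "F", 3),
            ("C", "A", "B", "M", 2), ("D", "A", "B", "F", 2),
            ("E", "C", "D", "M", 1),
        ])
        nrm = sp.build_nrm(ped)
        assert nrm.a("C", "D") == pytest.approx(0.5)
        assert nrm.a("E", "E") == pytest.approx(1.25)
        assert nrm.inbreeding("E") == pytest.approx(0.25)

    def test_subset_matches_full_matrix(self):
        rng = np.random.default_rng(5)
        ped = random_pedigree(12, rng)
        full = sp.build_nrm(ped)
        sub = sp.build_nrm(ped, subset=["A05", "A11", "A03"])
        for i in sub.ids:
            for j in sub.ids:
                assert sub.a(i, j) == pytest.approx(full.a(i, j))

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(6)
        ped = random_pedigree(15, rng)
        nrm = sp.build_nrm(ped)
        assert np.linalg.eigvalsh(nrm.values).min() >= -1e-8


# ---------------------------------------------------------------------------
# H: haplotype greedy
# ---------------------------------------------------------------------------

def library_from_entries(core_entries):
    """core_entries: list of dict hap -> (freq, {animal: copies})."""
    cores = []
    for k, entries in enumerate(core_entries):
        haps = sorted(entries, key=lambda h: (-entries[h][0], h))
        freqs = np.array([entries[h][0] for h in haps])
        carriers = [Counter(entries[h][1]) for h in haps]
        cores.append(
            CoreLibrary(Core(1, 2 * k, 2 * k + 2), np.arange(2 * k, 2 * k + 2),
                        haps, freqs, carriers, n_included_copies=8)
        )
    animals = sorted({a for e in core_entries for v in e.values() for a in v[1]})
    return HaplotypeLibrary(cores, animals)


class TestHaplotypeGreedy:
    def test_hand_enumerated_two_picks(self):
        """a4 carries h1+h3 (score .75); after masking, a1 vs a3 tie at .125
        resolves to the smaller id."""
        lib = library_from_entries([
            {
                "h1": (0.5, {"a1": 1, "a2": 2, "a4": 1}),
                "h2": (0.125, {"a1": 1}),
                "h3": (0.25, {"a3": 1, "a4": 1}),
                "h4": (0.125, {"a3": 1}),
            }
        ])
        s = sp.select_haplotype_greedy(lib, ["a1", "a2", "a3", "a4"], 2)
        assert s.ids == ["a4", "a1"]
        assert s.scores == pytest.approx([0.75, 0.125])

    def test_single_shared_haplotype_first_pick_covers_all(self):
        lib = library_from_entries([{"h1": (1.0, {"a1": 2, "a2": 2, "a3": 2})}])
        s = sp.select_haplotype_greedy(lib, ["a1", "a2", "a3"], 3)
        assert s.ids == ["a1", "a2", "a3"]  # remainder filled in id order
        assert s.scores[0] == pytest.approx(1.0)
        assert s.scores[1:] == [0.0, 0.0]

    def test_threshold_zero_admits_all_frequencies(self):
        lib = library_from_entries([
            {"h1": (0.999, {"a1": 2}), "h2": (0.001, {"a2": 1})}
        ])
        s = sp.select_haplotype_greedy(lib, ["a1", "a2"], 2, freq_threshold=0.0)
        assert s.scores == pytest.approx([0.999, 0.001])

    def test_threshold_excludes_rare_haplotypes(self):
        lib = library_from_entries([
            {"h1": (0.9, {"a1": 2}), "h2": (0.1, {"a2": 1})}
        ])
        s = sp.select_haplotype_greedy(lib, ["a1", "a2"], 2, freq_threshold=0.5)
        assert s.scores[1] == 0.0  # a2's rare haplotype no longer scores

    def test_n_target_above_candidates_rejected(self):
        lib = library_from_entries([{"h1": (1.0, {"a1": 2})}])
        with pytest.raises(ValueError):
            sp.select_haplotype_greedy(lib, ["a1"], 2)

    def test_duplicate_copies_count_once_per_distinct_haplotype(self):
        lib = library_from_entries([{"h1": (0.8, {"a1": 2, "a2": 1}),
                                  "h2": (0.2, {"a2": 1})}])
        s = sp.select_haplotype_greedy(lib, ["a1", "a2"], 1)
        # a2 scores 0.8+0.2 = 1.0 > a1's 0.8 despite a1's two copies of h1
        assert s.ids == ["a2"]


# ---------------------------------------------------------------------------
# P1: relationship maximization
# ---------------------------------------------------------------------------

class TestPedigreeRelationship:
    def test_common_parent_picked_first(self):
        ped = make_pedigree([
            ("S", "0", "0", "M", 2), ("X", "0", "0", "M", 2),
            ("D1", "0", "0", "F", 2), ("D2", "0", "0", "F", 2),
            ("C1", "S", "D1", "M", 1), ("C2", "S", "D2", "F", 1),
            ("C3", "S", "D1", "M", 1),
        ])
        nrm = sp.build_nrm(ped)
        pop = ["C1", "C2", "C3"]
        s = sp.select_pedigree_relationship(nrm, ["S", "X", "D1", "D2"], pop, 1)
        assert s.ids == ["S"]

    def test_selecting_everything_reaches_full_set_objective(self):
        rng = np.random.default_rng(2)
        ped = random_pedigree(8, rng)
        nrm = sp.build_nrm(ped)
        cands = ped.ids[:5]
        s = sp.select_pedigree_relationship(nrm, cands, ped.ids, 5)
        assert sorted(s.ids) == sorted(cands)

    def test_objective_non_decreasing_along_greedy_path(self):
        rng = np.random.default_rng(3)
        ped = random_pedigree(14, rng)
        nrm = sp.build_nrm(ped)
        s = sp.select_pedigree_relationship(nrm, ped.ids[:8], ped.ids, 8)
        assert all(b >= a - 1e-9 for a, b in zip(s.scores, s.scores[1:]))


# ---------------------------------------------------------------------------
# P2: ancestor contributions and key ancestors
# ---------------------------------------------------------------------------

def brute_force_contribution(ped, ancestor, target, blocked):
    """Sum over ancestral paths of (1/2)^length, honouring blocked animals."""
    if target == ancestor:
        return 1.0
    if target in blocked:
        return 0.0
    s, d = ped.parents(target)
    total = 0.0
    for p in (s, d):
        if p != "0":
            total += 0.5 * brute_force_contribution(ped, ancestor, p, blocked)
    return total


class TestAncestorContributions:
    def test_founder_parents_of_full_sibs_explain_half_each(self):
        ped = make_pedigree([
            ("A", "0", "0", "M", 2), ("B", "0", "0", "F", 2),
            ("C", "A", "B", "M", 1), ("D", "A", "B", "F", 1),
        ])
        c = sp.ancestor_contributions(ped, ["C", "D"])
        assert c["A"] == pytest.approx(0.5)
        assert c["B"] == pytest.approx(0.5)

    def test_grandparent_through_one_parent_quarter(self):
        ped = make_pedigree([
            ("G", "0", "0", "M", 3), ("P", "G", "0", "M", 2),
            ("X", "P", "0", "F", 1),
        ])
        c = sp.ancestor_contributions(ped, ["X"])
        assert c["G"] == pytest.approx(0.25)

    def test_blocking_matches_brute_force_path_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            ped = random_pedigree(8, rng)
            ref = ped.ids[-3:]
            blocked = [ped.ids[3]]
            c = sp.ancestor_contributions(ped, ref, blocked=blocked)
            for anc in ped.ids:
                if anc in blocked:
                    continue
                expect = np.mean(
                    [brute_force_contribution(ped, anc, t, set(blocked)) for t in ref]
                )
                assert c[anc] == pytest.approx(expect, abs=1e-12)

    def test_empty_reference_rejected(self):
        ped = make_pedigree([("A", "0", "0", "M", 1)])
        with pytest.raises(ValueError):
            sp.ancestor_contributions(ped, [])


class TestSelectKeyAncestors:
    def test_chain_with_unknown_dams_halves_contribution(self):
        ped = make_pedigree([
            ("A", "0", "0", "M", 4), ("B", "A", "0", "M", 3),
            ("C", "B", "0", "M", 2), ("D", "C", "0", "M", 1),
        ])
        res = sp.select_key_ancestors(ped, reference=["B"], candidates=["A"],
                                      cum_threshold=None)
        assert res.ids == ["A"]
        assert res.marginal[0] == pytest.approx(0.5)
        assert res.cumulative[-1] <= 1 + 1e-9

    def test_all_founders_of_known_pedigree_explain_everything(self, small_population):
        _, ped, _, _ = small_population
        res = sp.select_key_ancestors(
            ped, candidates=ped.founders, n_max=len(ped.founders),
            min_marginal=0.0, cum_threshold=None,
        )
        assert res.cumulative[-1] == pytest.approx(1.0, abs=1e-9)

    def test_marginal_never_exceeds_raw(self, small_population):
        _, ped, _, _ = small_population
        res = sp.select_key_ancestors(ped, n_max=15, cum_threshold=None)
        for r, m in zip(res.raw, res.marginal):
            assert m <= r + 1e-12


# ---------------------------------------------------------------------------
# C: combined approach
# ---------------------------------------------------------------------------

def _combined_fixture(available=("a", "b", "c", "d", "e", "f")):
    ped = make_pedigree([
        ("d", "0", "0", "M", 3, "d" in available),
        ("e", "0", "0", "F", 3, "e" in available),
        ("f", "0", "0", "F", 3, "f" in available),
        ("a", "0", "0", "M", 2, "a" in available),
        ("b", "d", "e", "M", 1, "b" in available),
        ("c", "d", "f", "F", 1, "c" in available),
    ])
    H = sp.SelectionSet("H", ["a", "b", "c"], [3.0, 2.0, 1.0])
    P1 = sp.SelectionSet("P1", ["a", "d"], [1.0, 0.5])
    P2 = sp.ContributionResult(["d", "e"], [0.5, 0.3], [0.5, 0.3], [0.5, 0.8])
    return ped, H, P1, P2


class TestCombineSelection:
    def test_hand_applied_steps(self):
        ped, H, P1, P2 = _combined_fixture()
        s = sp.combine_selection(H, P1, P2, ped, {"LR": 3})
        assert s.ids == ["a", "d", "b"]
        assert s.steps == [1, 2, 3]

    def test_unavailable_animal_skipped_and_step4_used(self):
        ped, H, P1, P2 = _combined_fixture(available=("b", "c", "d", "e", "f"))
        s = sp.combine_selection(H, P1, P2, ped, {"LR": 3})
        assert s.ids == ["d", "b", "c"]
        assert s.steps == [2, 3, 4]

    def test_empty_intersections_return_short_with_warning(self):
        ped = make_pedigree([
            ("x", "0", "0", "M", 1), ("y", "0", "0", "F", 1),
        ])
        H = sp.SelectionSet("H", ["x"], [1.0])
        P1 = sp.SelectionSet("P1", ["y"], [1.0])
        P2 = sp.ContributionResult([], [], [], [])
        with pytest.warns(UserWarning, match="eligible"):
            s = sp.combine_selection(H, P1, P2, ped, {"LR": 2})
        assert len(s) < 2

    def test_budget_met_and_all_available(self, small_population):
        _, ped, H, G = small_population
        part = sp.partition_cores(G.markers, 50)
        lib = sp.build_library(H, part)
        selH = sp.select_haplotype_greedy(lib, G.ids, 30)
        nrm = sp.build_nrm(ped)
        selP1 = sp.select_pedigree_relationship(nrm, G.ids, G.ids, 30)
        resP2 = sp.select_key_ancestors(ped, cum_threshold=None, n_max=40,
                                        min_marginal=1e-4)
        s = sp.combine_selection(selH, selP1, resP2, ped, {"LR": 10})
        assert len(s) == 10
        assert all(ped.is_available(a) for a in s.ids)
        assert len(set(s.ids)) == len(s.ids)


def test_select_random_inclusion_frequency_hypergeometric():
    rng = np.random.default_rng(0)
    counts = Counter()
    for _ in range(10_000):
        s = sp.select_random(["a", "b", "c", "d"], 2, rng)
        counts.update(s.ids)
    for a in "abcd":
        assert abs(counts[a] / 10_000 - 0.5) < 0.02


def test_select_random_deterministic_per_seed():
    a = sp.select_random(list("abcdefgh"), 3, np.random.default_rng(42))
    b = sp.select_random(list("abcdefgh"), 3, np.random.default_rng(42))
    assert a.ids == b.ids
    full = sp.select_random(list("abc"), 3, np.random.default_rng(0))
    assert sorted(full.ids) == ["a", "b", "c"]
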