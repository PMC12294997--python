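"""Deferred-acceptance matching: unit examples, oracles, properties."""

import numpy as np
import pytest

from scrubmatch.matching import (
    InputError,
    MatchResult,
    PreferenceTable,
    SizeError,
    derive_ranks,
    enumerate_stable_matchings,
    gale_shapley,
    rematch_on_update,
    verify_stability,
)
from scrubmatch.profiles import CompatibilityMatrix
from scrubmatch.synthetic_data import GeneratorConfig, generate_cohort

from conftest import random_matrix


def matrix_2x2(s11=0.9, s12=0.4, s21=0.8, s22=0.6):
    return CompatibilityMatrix(("p1", "p2"), ("r1", "r2"), np.array([[s11, s12], [s21, s22]]))


class TestDeriveRanks:
    def test_ties_share_a_rank(self):
        m = CompatibilityMatrix(("p",), ("r1", "r2", "r3"), np.array([[0.9, 0.5, 0.5]]))
        prefs = derive_ranks(m)
        assert [prefs.rank_p[("p", r)] for r in ("r1", "r2", "r3")] == [1, 2, 2]

    def test_all_equal_scores_all_rank_one(self):
        m = CompatibilityMatrix(("p1", "p2"), ("r1", "r2"), np.full((2, 2), 0.5))
        prefs = derive_ranks(m)
        assert set(prefs.rank_p.values()) == {1}
        assert set(prefs.rank_r.values()) == {1}

    def test_matches_brute_force_definition_on_random_matrix(self):
        rng = np.random.default_rng(7)
        m = random_matrix(rng, 5, 5)
        prefs = derive_ranks(m)
        for i, p in enumerate(m.patients):
            for j, r in enumerate(m.providers):
                expected = 1 + sum(
                    1 for jj in range(5) if m.scores[i, jj] > m.scores[i, j]
                )
                assert prefs.rank_p[(p, r)] == expected
        for j, r in enumerate(m.providers):
            for i, p in enumerate(m.patients):
                expected = 1 + sum(
                    1 for ii in range(5) if m.scores[ii, j] > m.scores[i, j]
                )
                assert prefs.rank_r[(r, p)] == expected


class TestGaleShapley:
    def test_2x2_unique_stable_matching(self):
        # exhaustive enumeration shows {(p1,r1),(p2,r2)} is the only stable matching
        m = matrix_2x2()
        prefs = derive_ranks(m)
        res = gale_shapley(prefs, m)
        assert res.pairs == (("p1", "r1"), ("p2", "r2"))
        assert res.stable and not res.unmatched
        assert enumerate_stable_matchings(prefs, m) == [res.pairs]

    def test_single_pair_one_proposal(self):
        m = CompatibilityMatrix(("p1",), ("r1",), np.array([[0.3]]))
        prefs = derive_ranks(m)
        res = gale_shapley(prefs, m)
        assert res.pairs == (("p1", "r1"),) and res.proposals == 1

    def test_two_patients_one_provider_lower_scored_exhausts(self):
        m = CompatibilityMatrix(("p1", "p2"), ("r1",), np.array([[0.9], [0.4]]))
        prefs = derive_ranks(m)
        res = gale_shapley(prefs, m)
        assert res.pairs == (("p1", "r1"),)
        assert res.unmatched == ("p2",)
        assert res.stable
        assert res.proposals <= 2

    def test_capacity_two_provider_takes_both(self):
        m = CompatibilityMatrix(("p1", "p2"), ("r1",), np.array([[0.9], [0.4]]))
        prefs = derive_ranks(m)
        res = gale_shapley(prefs, m, capacities={"r1": 2})
        assert res.pairs == (("p1", "r1"), ("p2", "r1"))
        assert res.stable

    def test_capacity_displaces_worst_assignee(self):
        # three patients chase r1 (cap 2); the weakest is displaced to r2
        scores = np.array([[0.9, 0.1], [0.8, 0.2], [0.7, 0.3]])
        m = CompatibilityMatrix(("p1", "p2", "p3"), ("r1", "r2"), scores)
        prefs = derive_ranks(m)
        res = gale_shapley(prefs, m, capacities={"r1": 2, "r2": 1})
        assert dict(res.pairs) == {"p1": "r1", "p2": "r1", "p3": "r2"}
        assert res.stable

    def test_inconsistent_id_sets_rejected(self):
        m = matrix_2x2()
        prefs = derive_ranks(m)
        other = CompatibilityMatrix(("p1", "pX"), ("r1", "r2"), np.full((2, 2), 0.5))
        with pytest.raises(InputError):
            gale_shapley(prefs, other)

    def test_explicit_equal_ranks_resolved_by_score(self):
        # explicit lists rank both patients first at r1; the score tie-break
        # (live only for external preferences) must pick the higher S(p, r1)
        m = CompatibilityMatrix(("p1", "p2"), ("r1", "r2"), np.array([[0.6, 0.5], [0.9, 0.5]]))
        rank_p = {("p1", "r1"): 1, ("p1", "r2"): 2, ("p2", "r1"): 1, ("p2", "r2"): 2}
        rank_r = {("r1", "p1"): 1, ("r1", "p2"): 1, ("r2", "p1"): 1, ("r2", "p2"): 1}
        prefs = PreferenceTable(("p1", "p2"), ("r1", "r2"), rank_p, rank_r, explicit=True)
        res = gale_shapley(prefs, m)
        assert dict(res.pairs)["p2"] == "r1"  # S(p2,r1)=0.9 beats S(p1,r1)=0.6

    def test_proposal_bound_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n, mm = int(rng.integers(1, 9)), int(rng.integers(1, 9))
            mat = random_matrix(rng, n, mm)
            res = gale_shapley(derive_ranks(mat), mat)
            assert res.proposals <= n * mm


class TestVerifyStability:
    def test_gale_shapley_output_always_stable(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            mat = random_matrix(rng, 8, 8)
            prefs = derive_ranks(mat)
            res = gale_shapley(prefs, mat)
            assert verify_stability(res, prefs, mat) == []

    def test_swapped_pairs_create_blocking_pair(self):
        m = matrix_2x2()
        prefs = derive_ranks(m)
        swapped = MatchResult(
            pairs=(("p1", "r2"), ("p2", "r1")), unmatched=(), proposals=0, stable=False
        )
        blocking = verify_stability(swapped, prefs, m)
        assert blocking == [("p1", "r1")]

    def test_empty_matching_blocks_everywhere_with_spare_capacity(self):
        m = matrix_2x2()
        prefs = derive_ranks(m)
        empty = MatchResult(pairs=(), unmatched=("p1", "p2"), proposals=0, stable=False)
        blocking = set(verify_stability(empty, prefs, m))
        assert blocking == {(p, r) for p in ("p1", "p2") for r in ("r1", "r2")}


class TestEnumerationOracle:
    def test_single_pair(self):
        m = CompatibilityMatrix(("p1",), ("r1",), np.array([[0.3]]))
        prefs = derive_ranks(m)
        assert enumerate_stable_matchings(prefs, m) == [(("p1", "r1"),)]

    def test_size_guard(self):
        rng = np.random.default_rng(0)
        mat = random_matrix(rng, 9, 9)
        with pytest.raises(SizeError):
            enumerate_stable_matchings(derive_ranks(mat), mat)

    def test_patient_optimality_on_random_instances(self):
        # classical deferred-acceptance property: the patient-proposing
        # outcome is weakly preferred by every patient to any stable matching
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(2, 5))
            mat = random_matrix(rng, n, n)
            prefs = derive_ranks(mat)
            res = gale_shapley(prefs, mat)
            stable_set = enumerate_stable_matchings(prefs, mat)
            assert res.pairs in stable_set
            got = dict(res.pairs)
            for other in stable_set:
                for p, r in other:
                    assert prefs.rank_p[(p, got[p])] <= prefs.rank_p[(p, r)]


class TestRematchOnUpdate:
    def test_idempotent_when_profiles_unchanged(self):
        ps, rs, _ = generate_cohort(GeneratorConfig(seed=21, n_patients=6, m_providers=4))
        first = rematch_on_update(None, ps, rs)
        second = rematch_on_update(first, ps, rs)
        assert first == second

    def test_provider_removal_reenters_patient(self):
        ps, rs, planted = generate_cohort(
            GeneratorConfig(seed=22, n_patients=3, m_providers=3, planted_matching=True)
        )
        base = rematch_on_update(None, ps, rs)
        gone = base.pairs[0][1]
        res = rematch_on_update(base, ps, [r for r in rs if r.provider_id != gone])
        affected = base.pairs[0][0]
        # the displaced patient is re-processed: either matched elsewhere or unmatched
        assert affected in dict(res.pairs) or affected in res.unmatched

    def test_score_flip_swaps_the_2x2_matching(self):
        # direct score-matrix route: raise S(p2, r1) above S(p1, r1)
        m = matrix_2x2(s11=0.9, s12=0.4, s21=0.95, s22=0.6)
        prefs = derive_ranks(m)
        res = gale_shapley(prefs, m)
        assert dict(res.pairs) == {"p2": "r1", "p1": "r2"}
        assert enumerate_stable_matchings(prefs, m) == [res.pairs]
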