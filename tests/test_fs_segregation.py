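"""Gamete model, segregation chi-squared and full-sib family solving."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyblock.combinatorics import MISSING, get_table, mrkdos_of_hapcomb
from polyblock.fs import (
    Demoted,
    FSFamily,
    SegregationParams,
    _PairScorer,
    _score_pair_block,
    expected_gmrk_distribution,
    fs_segregation_pvalue,
    gamete_distribution,
    impute_fs_indiv,
    progeny_ghap_distribution,
    resolve_group_conflicts,
    solve_one_fs,
)
from polyblock.simulate import simulate_cross


# -- gamete / progeny models ------------------------------------------------


@pytest.mark.parametrize("alpha", [0.0, 0.1, 0.5])
def test_diploid_gametes_ignore_alpha(alpha):
    assert gamete_distribution((0, 1), 2, alpha) == {(0,): 0.5, (1,): 0.5}


def test_tetraploid_homozygote():
    d = gamete_distribution((2, 2, 2, 2), 4, 0.3)
    assert set(d) == {(2, 2)}
    assert d[(2, 2)] == pytest.approx(1.0)


def test_tetraploid_duplex_no_dr():
    d = gamete_distribution((0, 0, 1, 1), 4, 0.0)
    assert d[(0, 0)] == pytest.approx(1 / 6)
    assert d[(0, 1)] == pytest.approx(2 / 3)
    assert d[(1, 1)] == pytest.approx(1 / 6)


def test_tetraploid_dr_mass():
    """A fully heterozygous parent gives double-reduction gametes at rate alpha."""
    d = gamete_distribution((0, 1, 2, 3), 4, 0.1)
    dr = sum(p for g, p in d.items() if g[0] == g[1])
    assert dr == pytest.approx(0.1)
    assert sum(d.values()) == pytest.approx(1.0, abs=1e-12)


def test_hexaploid_gamete_distribution_normalized():
    d = gamete_distribution((0, 1, 2, 3, 4, 5), 6, 0.05)
    assert sum(d.values()) == pytest.approx(1.0, abs=1e-12)
    dr = sum(p for g, p in d.items() if len(set(g)) < 3)
    assert dr == pytest.approx(0.05)


def test_gamete_distribution_validation():
    with pytest.raises(ValueError):
        gamete_distribution((0, 1, 2), 3)
    with pytest.raises(ValueError):
        gamete_distribution((0, 1), 2, alpha=1.0)


def test_progeny_trivial_and_backcross():
    d = progeny_ghap_distribution((0, 0, 0, 0), (0, 0, 0, 0))
    assert set(d) == {(0, 0, 0, 0)} and d[(0, 0, 0, 0)] == pytest.approx(1.0)
    d = progeny_ghap_distribution((0, 1), (0, 0))
    assert d[(0, 0)] == pytest.approx(0.5) and d[(0, 1)] == pytest.approx(0.5)


def test_progeny_duplex_by_homozygote():
    d = progeny_ghap_distribution((0, 0, 1, 1), (0, 0, 0, 0), alpha=0.0)
    assert d[(0, 0, 0, 0)] == pytest.approx(1 / 6)
    assert d[(0, 0, 0, 1)] == pytest.approx(2 / 3)
    assert d[(0, 0, 1, 1)] == pytest.approx(1 / 6)


@settings(deadline=None, max_examples=40)
@given(
    st.lists(st.integers(0, 7), min_size=4, max_size=4),
    st.lists(st.integers(0, 7), min_size=4, max_size=4),
    st.floats(0.0, 0.3),
)
def test_progeny_distribution_sums_to_one(g1, g2, alpha):
    d = progeny_ghap_distribution(tuple(g1), tuple(g2), alpha=alpha)
    assert sum(d.values()) == pytest.approx(1.0, abs=1e-12)


def test_diploid_reduces_to_mendelian():
    """alpha plays no role in diploids: F2 of 0x1 cross is 1:2:1."""
    d = progeny_ghap_distribution((0, 1), (0, 1), alpha=0.25)
    assert d == {
        (0, 0): pytest.approx(0.25),
        (0, 1): pytest.approx(0.5),
        (1, 1): pytest.approx(0.25),
    }


# -- dosage-error channel ---------------------------------------------------


def test_expected_gmrk_no_error_is_pushforward():
    ghap_dist = {(0, 0, 1, 1): 0.5, (0, 0, 0, 1): 0.5}
    d = expected_gmrk_distribution(ghap_dist, 0.0, 4, 1)
    assert d == {(2,): 0.5, (1,): 0.5}


def test_expected_gmrk_boundary_error():
    d = expected_gmrk_distribution({(0, 0, 0, 0): 1.0}, 0.025, 4, 1)
    assert d[(0,)] == pytest.approx(0.975)
    assert d[(1,)] == pytest.approx(0.025)


def test_expected_gmrk_interior_split():
    d = expected_gmrk_distribution({(0, 0, 1, 1): 1.0}, 0.025, 4, 1)
    assert d[(2,)] == pytest.approx(0.975)
    assert d[(1,)] == pytest.approx(0.0125)
    assert d[(3,)] == pytest.approx(0.0125)


# -- chi-squared ------------------------------------------------------------


def test_pvalue_perfect_fit():
    expected = {(0,): 0.5, (1,): 0.5}
    assert fs_segregation_pvalue({(0,): 50, (1,): 50}, expected, 100) == pytest.approx(1.0)


def test_pvalue_30_70():
    expected = {(0,): 0.5, (1,): 0.5}
    p = fs_segregation_pvalue({(0,): 30, (1,): 70}, expected, 100)
    assert p == pytest.approx(6.33e-5, rel=1e-2)


def test_pvalue_category_order_invariant():
    expected = {(0,): 0.3, (1,): 0.45, (2,): 0.25}
    obs = {(0,): 10, (1,): 25, (2,): 15}
    p1 = fs_segregation_pvalue(obs, expected, 50)
    p2 = fs_segregation_pvalue(
        dict(reversed(list(obs.items()))), dict(reversed(list(expected.items()))), 50
    )
    assert p1 == p2


def test_pvalue_pooled_category_carries_unexpected():
    """An observed but unexpected class lands in the pooled category."""
    expected = {(0,): 0.9, (1,): 0.08, (2,): 0.02}  # n=10: (1,),(2,) pool
    obs = {(0,): 8, (4,): 2}  # (4,) impossible under the candidate
    p = fs_segregation_pvalue(obs, expected, 10)
    exp_pool = 10 * 0.1
    stat = (8 - 9.0) ** 2 / 9.0 + (2 - exp_pool) ** 2 / exp_pool
    from scipy.stats import chi2

    assert p == pytest.approx(float(chi2.sf(stat, 1)))


def test_pvalue_impossible_with_zero_pool_mass():
    p = fs_segregation_pvalue({(0,): 5, (3,): 5}, {(0,): 1.0}, 10)
    assert p == 0.0


def test_pvalue_rejects_empty_family():
    with pytest.raises(ValueError):
        fs_segregation_pvalue({}, {(0,): 1.0}, 0)


# -- fast scorer vs reference -----------------------------------------------


def test_fast_scorer_matches_reference(rng, table34):
    """JIT kernel, numpy scorer and the dict-based P agree on random families."""
    params = SegregationParams()
    for trial in range(8):
        p1 = tuple(sorted(rng.integers(0, 8, size=4)))
        p2 = tuple(sorted(rng.integers(0, 8, size=4)))
        kids = simulate_cross(p1, p2, 40, params.alpha, rng)
        obs = Counter(tuple(mrkdos_of_hapcomb(k, 3)) for k in kids)
        scorer = _PairScorer(obs, 40, 3, 4, params)
        cands1 = [tuple(sorted(rng.integers(0, 8, size=4))) for _ in range(5)] + [p1]
        cands2 = [tuple(sorted(rng.integers(0, 8, size=4))) for _ in range(5)] + [p2]
        stats_jit, dfs_jit = _score_pair_block(scorer, cands1, cands2, False)
        from scipy.stats import chi2

        i = 0
        for a in cands1:
            for b in cands2:
                stat_np, df_np = scorer.stat_df(a, b)
                if math.isinf(stat_np):
                    assert math.isinf(stats_jit[i])
                else:
                    assert stats_jit[i] == pytest.approx(stat_np, rel=1e-9)
                    assert dfs_jit[i] == df_np
                # dict-based public computation as the slow oracle
                ghap_dist = progeny_ghap_distribution(a, b, alpha=params.alpha)
                exp = expected_gmrk_distribution(ghap_dist, params.epsilon, 4, 3)
                p_ref = fs_segregation_pvalue(obs, exp, 40)
                p_fast = float(chi2.sf(stats_jit[i], dfs_jit[i]))
                assert p_fast == pytest.approx(p_ref, rel=1e-6, abs=1e-12)
                i += 1


# -- solving families -------------------------------------------------------


def make_family(p1, p2, n, alpha, rng, nmrk, name="F1", seed_offspring=None):
    fam = FSFamily(name, "P1", "P2", tuple(f"o{i}" for i in range(n)))
    kids = seed_offspring or simulate_cross(p1, p2, n, alpha, rng)
    dosages = {"P1": mrkdos_of_hapcomb(p1, nmrk), "P2": mrkdos_of_hapcomb(p2, nmrk)}
    for o, k in zip(fam.offspring, kids):
        dosages[o] = mrkdos_of_hapcomb(k, nmrk)
    return fam, dosages, kids


def test_solve_forced_homozygous_parents(table24):
    """Nulliplex x quadruplex parents leave a single near-perfect candidate."""
    fam = FSFamily("F1", "P1", "P2", tuple(f"o{i}" for i in range(30)))
    dosages = {"P1": np.array([0, 0]), "P2": np.array([4, 4])}
    for o in fam.offspring:
        dosages[o] = np.array([2, 2])
    res = solve_one_fs(fam, dosages, set(), table24, SegregationParams(epsilon=0.0))
    assert isinstance(res, list) and len(res) == 1
    assert res[0].pair == ((0, 0, 0, 0), (3, 3, 3, 3))
    assert res[0].p_value == pytest.approx(1.0)
    # with the default dosage-error rate the candidate is still unique
    res = solve_one_fs(fam, dosages, set(), table24)
    assert isinstance(res, list) and len(res) == 1
    assert res[0].pair == ((0, 0, 0, 0), (3, 3, 3, 3))


def test_solve_missing_parent_dosage_demotes(table24):
    fam = FSFamily("F1", "P1", "P2", ("o0",))
    dosages = {"P1": np.array([0, MISSING]), "P2": np.array([4, 4]), "o0": np.array([2, 2])}
    res = solve_one_fs(fam, dosages, set(), table24)
    assert res == Demoted("missing_parent_dosage")


def test_solve_pair_cap_demotes(table24):
    fam = FSFamily("F1", "P1", "P2", tuple(f"o{i}" for i in range(10)))
    dosages = {"P1": np.array([2, 2]), "P2": np.array([2, 2])}
    for o in fam.offspring:
        dosages[o] = np.array([2, 2])
    assert SegregationParams().max_parent_combs == 150_000
    # (2,2) x (2,2) parents admit 3x3 = 9 candidate pairs
    res = solve_one_fs(fam, dosages, set(), table24, SegregationParams(max_parent_combs=8))
    assert res == Demoted("too_many_combinations")


def test_solve_no_genotyped_offspring_demotes(table24):
    fam = FSFamily("F1", "P1", "P2", ("o0",))
    dosages = {"P1": np.array([0, 0]), "P2": np.array([0, 0]), "o0": np.array([0, MISSING])}
    assert solve_one_fs(fam, dosages, set(), table24) == Demoted("no_genotyped_offspring")


def test_true_pair_survives_on_matching_simulation(rng, table34):
    """With matching alpha and no dosage errors the true parental pair is
    always among the surviving candidates."""
    params = SegregationParams()
    for trial in range(5):
        p1 = tuple(sorted(rng.integers(0, 8, size=4)))
        p2 = tuple(sorted(rng.integers(0, 8, size=4)))
        fam, dosages, _ = make_family(p1, p2, 60, params.alpha, rng, 3)
        res = solve_one_fs(fam, dosages, set(), table34, params)
        assert isinstance(res, list)
        assert any(c.pair == (p1, p2) for c in res)


def test_solve_selfing(table24):
    """A selfing family constrains both parental slots to the same genotype."""
    fam = FSFamily("F1", "P1", "P1", tuple(f"o{i}" for i in range(40)))
    rng = np.random.default_rng(5)
    p = (0, 0, 3, 3)
    kids = simulate_cross(p, p, 40, 0.0, rng)
    dosages = {"P1": mrkdos_of_hapcomb(p, 2)}
    for o, k in zip(fam.offspring, kids):
        dosages[o] = mrkdos_of_hapcomb(k, 2)
    res = solve_one_fs(fam, dosages, set(), table24, SegregationParams(alpha=0.0))
    assert isinstance(res, list)
    assert all(c.ghap_p1 == c.ghap_p2 for c in res)
    assert any(c.pair == (p, p) for c in res)


# -- group conflict resolution ----------------------------------------------


def _cand(g1, g2, p):
    from polyblock.fs import FSCandidate

    return FSCandidate(g1, g2, p, {})


def test_resolve_single_family_passthrough():
    fam = FSFamily("F1", "A", "B", ("o1", "o2"))
    c = _cand((0, 0, 0, 0), (0, 0, 1, 1), 0.8)
    res = resolve_group_conflicts([fam], {"F1": [c]})
    assert res.family_candidate["F1"] is c
    assert res.parent_ghap == {"A": (0, 0, 0, 0), "B": (0, 0, 1, 1)}
    assert res.demoted == []


def test_resolve_shared_parent_intersection():
    """The shared-parent genotype all families can agree on is selected."""
    f1 = FSFamily("F1", "S", "B", tuple(f"x{i}" for i in range(10)))
    f2 = FSFamily("F2", "S", "C", tuple(f"y{i}" for i in range(10)))
    gS, gS2 = (0, 0, 0, 1), (0, 0, 1, 1)
    gB, gC = (0, 0, 0, 0), (0, 1, 1, 1)
    cands = {
        "F1": [_cand(gS, gB, 0.9), _cand(gS2, gB, 0.8)],
        "F2": [_cand(gS, gC, 0.7)],
    }
    res = resolve_group_conflicts([f1, f2], cands)
    assert res.parent_ghap["S"] == gS
    assert res.family_candidate["F1"].pair == (gS, gB)
    assert res.demoted == []


def test_resolve_removes_worst_and_demotes():
    """A family whose only candidate conflicts with the majority is demoted."""
    f1 = FSFamily("F1", "S", "B", tuple(f"x{i}" for i in range(50)))
    f2 = FSFamily("F2", "S", "C", tuple(f"y{i}" for i in range(10)))
    gS, gSalt = (0, 0, 0, 1), (0, 0, 1, 1)
    cands = {
        "F1": [_cand(gS, (0, 0, 0, 0), 0.9)],
        "F2": [_cand(gSalt, (0, 1, 1, 1), 0.95)],
    }
    res = resolve_group_conflicts([f1, f2], cands)
    assert res.demoted == ["F2"]
    assert res.parent_ghap["S"] == gS


def test_resolve_tie_keeps_shared_assignments_only():
    """Under co-optimal solutions only identical assignments are kept."""
    fam = FSFamily("F1", "A", "B", ("o1",))
    c1 = _cand((0, 0, 0, 0), (0, 0, 1, 1), 0.5)
    c2 = _cand((0, 0, 0, 0), (0, 1, 1, 1), 0.5)
    res = resolve_group_conflicts([fam], {"F1": [c1, c2]})
    assert res.family_candidate["F1"] is None
    assert res.parent_ghap.get("A") == (0, 0, 0, 0)
    assert "B" not in res.parent_ghap
    assert len(res.family_co_optimal["F1"]) == 2


def test_resolve_empty_group_rejected():
    with pytest.raises(ValueError):
        resolve_group_conflicts([], {})


# -- imputation -------------------------------------------------------------


def test_impute_unique_match():
    gmrks = [(0, 2), (2, 2), (2, 0)]
    assert impute_fs_indiv(np.array([0, MISSING]), gmrks) == (0, 2)
    assert impute_fs_indiv(np.array([2, MISSING]), gmrks) is None  # two matches
    assert impute_fs_indiv(np.array([MISSING, MISSING]), gmrks) is None
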