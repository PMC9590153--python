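"""Population simulator: designs, determinism, truth consistency, scoring."""

import numpy as np
import pandas as pd
import pytest

from polyblock.combinatorics import enumerate_hapcombs, mrkdos_of_hapcomb
from polyblock.fs import gamete_distribution
from polyblock.pipeline import AssignmentResult, BlockResult, check_parent_offspring
from polyblock.simulate import (
    dataset2_config,
    dataset3_config,
    score_against_truth,
    simulate_cross,
    simulate_population,
    snp_heterozygosity,
)


def test_dataset2_preset_shape():
    sim = simulate_population(dataset2_config(seed=2))
    assert sim.dosages.shape[1] == 460  # 10 parents + 9 x 50 offspring
    assert len(sim.blocks) == 60
    sizes = sorted({len(m) for m in sim.blocks.values()})
    assert sizes == [3, 4, 5, 6, 7]
    assert len(sim.structure.families) == 9
    assert all(f.parent1 == "P01" for f in sim.structure.families)
    assert not sim.dosages.isna().any().any()  # published design: no missing


def test_dataset3_preset_shape():
    sim = simulate_population(dataset3_config(seed=2))
    assert sim.dosages.shape[1] == 203  # 3 parents + 100 FS + 100 unrelated
    assert len(sim.structure.families) == 2


def test_same_seed_identical():
    cfg = dataset3_config(seed=9, markers_per_block=(3, 4))
    cfg.n_blocks = 3
    a = simulate_population(cfg)
    b = simulate_population(cfg)
    pd.testing.assert_frame_equal(a.dosages, b.dosages)
    assert a.truth.ghap == b.truth.ghap


def test_truth_consistent_with_dosages():
    """Without simulated errors the emitted dosages equal the truth dosages,
    and the true combination is always among the enumerated solutions."""
    cfg = dataset2_config(seed=4, markers_per_block=(3, 4))
    cfg.n_blocks = 2
    sim = simulate_population(cfg)
    for b, markers in sim.blocks.items():
        nmrk = len(markers)
        sub = sim.dosages.loc[markers]
        for indiv, hc in sim.truth.ghap[b].items():
            obs = sub[indiv].to_numpy().astype(int)
            assert np.array_equal(obs, mrkdos_of_hapcomb(hc, nmrk))
            assert hc in enumerate_hapcombs(obs, 4)


def test_truth_gamete_decomposable():
    """Every simulated offspring decomposes into parental gametes at the
    simulation's double-reduction rate."""
    cfg = dataset2_config(seed=6, markers_per_block=(3, 3))
    cfg.n_blocks = 2
    sim = simulate_population(cfg)
    blocks = {
        b: BlockResult(b, [], {}, dict(sim.truth.ghap[b]), {}) for b in sim.blocks
    }
    result = AssignmentResult(4, blocks)
    ped = {o: (f.parent1, f.parent2) for f in sim.structure.families for o in f.offspring}
    report = check_parent_offspring(result, ped, alpha=cfg.alpha)
    for b in report:
        assert all(v == "match" for v in report[b].values())


def test_error_and_missing_rates_applied():
    cfg = dataset3_config(seed=8, markers_per_block=(4, 4))
    cfg.n_blocks = 6
    cfg.epsilon_sim = 0.1
    cfg.missing_rate = 0.1
    sim = simulate_population(cfg)
    frac_missing = sim.dosages.isna().to_numpy().mean()
    assert 0.05 < frac_missing < 0.15
    # errors: compare against truth dosages
    n = err = 0
    for b, markers in sim.blocks.items():
        sub = sim.dosages.loc[markers]
        for indiv, hc in sim.truth.ghap[b].items():
            true = mrkdos_of_hapcomb(hc, len(markers))
            obs = sub[indiv].to_numpy()
            ok = ~np.isnan(obs)
            n += ok.sum()
            err += (obs[ok] != true[ok]).sum()
            assert np.abs(obs[ok] - true[ok]).max(initial=0) <= 1  # off-by-one only
    assert 0.05 < err / n < 0.15


def test_founder_haplotype_band():
    """Blocks large enough to express it hit the configured 14-26 distinct
    founder-haplotype band."""
    cfg = dataset2_config(seed=3, markers_per_block=(6, 7))
    cfg.n_blocks = 6
    sim = simulate_population(cfg)
    for b in sim.blocks:
        assert 14 <= len(sim.truth.founder_pool[b]) <= 26


def test_two_population_design_split():
    cfg = dataset3_config(seed=3, markers_per_block=(5, 5))
    cfg.n_blocks = 4
    sim = simulate_population(cfg)
    u1 = [i for i in sim.dosages.columns if i.startswith("U1_")]
    u2 = [i for i in sim.dosages.columns if i.startswith("U2_")]
    assert len(u1) == len(u2) == 50


def test_heterozygosity_in_published_band():
    sim = simulate_population(dataset2_config(seed=1))
    het = snp_heterozygosity(sim.dosages, 4)
    assert 0.70 < het.mean() < 0.88


def test_simulate_cross_frequencies(rng):
    """Empirical gamete frequencies match the closed-form distribution."""
    p1 = (0, 1, 2, 3)
    n = 20000
    kids = simulate_cross(p1, (4, 4, 4, 4), n, 0.1, rng)
    gd = gamete_distribution(p1, 4, 0.1)
    from collections import Counter

    counts = Counter()
    for kid in kids:  # the p1 gamete is whatever is not the (4,4) gamete
        rest = list(kid)
        rest.remove(4)
        rest.remove(4)
        counts[tuple(sorted(rest))] += 1
    for gam, p in gd.items():
        se = (n * p * (1 - p)) ** 0.5
        assert abs(counts.get(gam, 0) - n * p) < 4 * se + 1


def test_score_against_truth_counts():
    truth_ghap = {"b1": {"a": (0, 0, 1, 1), "b": (0, 0, 0, 0), "c": (1, 1, 1, 1), "d": (0, 1, 1, 1)}}
    from polyblock.simulate import TruthSet

    assignments = {"a": (0, 0, 1, 1), "b": (0, 0, 0, 0), "c": (0, 1, 1, 1), "d": (0, 1, 1, 1)}
    res = AssignmentResult(4, {"b1": BlockResult("b1", [], {}, assignments, {})})
    sc = score_against_truth(res, TruthSet(truth_ghap, {}))
    row = sc["per_block"].iloc[0]
    assert row["n_haplotyped"] == 4
    assert row["n_correct"] == 3
    assert row["pct_correct"] == 75.0
    # all unassigned: correctness undefined
    res2 = AssignmentResult(4, {"b1": BlockResult("b1", [], {}, {k: None for k in assignments}, {})})
    sc2 = score_against_truth(res2, TruthSet(truth_ghap, {}))
    assert sc2["per_block"].iloc[0]["pct_haplotyped"] == 0.0
    assert np.isnan(sc2["per_block"].iloc[0]["pct_correct"])
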