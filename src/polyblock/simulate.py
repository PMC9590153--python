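"""Synthetic autopolyploid populations for validating the haplotyper.

Emulates the two study designs used for validation: a tetraploid population
of 9 full-sib families of 50 that all share one parent (10 parents total,
founders structured into three clusters of related individuals), and a
population of 2 full-sib families of 50 sharing a parent plus two groups of
50 unrelated individuals drawn from two distinct random-mating source
populations.  All markers of a haploblock sit at one map position: gametes
carry whole founder haplotypes and no recombination occurs within blocks.

Founder haplotypes per block are drawn from a skewed frequency pool whose
size is configurable (the published simulations segregate 14-26 founder
alleles per locus); meiosis follows the same polysomic gamete model with
double reduction used by the solver.  The published simulated data sets
contain no dosage errors and no missing data, so the presets default to
``epsilon_sim=0`` and ``missing_rate=0``; both rates are available for
robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .combinatorics import mrkdos_of_hapcomb
from .fs import FSFamily, gamete_distribution
from .pipeline import AssignmentResult, PopulationStructure


@dataclass(frozen=True)
class SimFamily:
    name: str
    parent1: str
    parent2: str
    n_offspring: int


@dataclass
class SimConfig:
    ploidy: int = 4
    n_blocks: int = 60
    markers_per_block: tuple[int, int] = (3, 7)  # inclusive range, cycled evenly
    founder_design: str = "clusters"  # "clusters" | "two_pops"
    n_clusters: int = 3
    founder_haplotypes: tuple[int, int] = (14, 26)  # target distinct codes/block
    parents: tuple[str, ...] = ()
    parent_group: Mapping[str, int] = field(default_factory=dict)  # cluster or pop
    families: tuple[SimFamily, ...] = ()
    n_unrelated: tuple[int, ...] = ()  # per source population (two_pops design)
    alpha: float = 0.025  # double-reduction rate of the simulated meioses
    epsilon_sim: float = 0.0  # applied dosage-error rate
    missing_rate: float = 0.0
    seed: int = 1


@dataclass
class TruthSet:
    ghap: dict  # block -> {individual -> nondecreasing code tuple}
    founder_pool: dict  # block -> sorted list of pool codes


@dataclass
class SimResult:
    dosages: pd.DataFrame
    blocks: dict  # block -> ordered marker ids
    structure: PopulationStructure
    truth: TruthSet
    config: SimConfig


def dataset2_config(seed: int = 1, markers_per_block=(3, 7)) -> SimConfig:
    """9 tetraploid FS families of 50 sharing one parent; 10 parents."""
    parents = tuple(f"P{i:02d}" for i in range(1, 11))
    fams = tuple(
        SimFamily(f"F{i}", "P01", f"P{i + 1:02d}", 50) for i in range(1, 10)
    )
    groups = {p: i % 3 for i, p in enumerate(parents)}
    return SimConfig(
        ploidy=4,
        n_blocks=60,
        markers_per_block=markers_per_block,
        founder_design="clusters",
        n_clusters=3,
        parents=parents,
        parent_group=groups,
        families=fams,
        seed=seed,
    )


def dataset3_config(seed: int = 1, markers_per_block=(3, 7)) -> SimConfig:
    """2 tetraploid FS families of 50 sharing a parent + 2x50 unrelated."""
    parents = ("P01", "P02", "P03")
    fams = (SimFamily("F1", "P01", "P02", 50), SimFamily("F2", "P01", "P03", 50))
    return SimConfig(
        ploidy=4,
        n_blocks=60,
        markers_per_block=markers_per_block,
        founder_design="two_pops",
        parents=parents,
        parent_group={"P01": 0, "P02": 0, "P03": 1},
        families=fams,
        n_unrelated=(50, 50),
        seed=seed,
    )


def _block_sizes(config: SimConfig) -> list[int]:
    lo, hi = config.markers_per_block
    sizes = list(range(lo, hi + 1))
    return [sizes[i % len(sizes)] for i in range(config.n_blocks)]


def simulate_founders(config: SimConfig, nmrk: int, rng: np.random.Generator):
    """Founder haplotype pool(s) and parental genotypes for one block.

    Returns ``(pools, parent_ghaps)`` where ``pools`` is a list per
    group/population of ``(codes, weights)``.  The pool targets a distinct
    haplotype count drawn from ``config.founder_haplotypes``, capped by the
    2^nmrk haplotype space and by the number of founder homologs.
    """
    nhap = 2**nmrk
    lo, hi = config.founder_haplotypes
    target = int(rng.integers(lo, hi + 1))
    n_slots = len(config.parents) * config.ploidy + sum(config.n_unrelated) * config.ploidy
    target = min(target, nhap, n_slots)

    # geometric frequency skew calibrated so per-individual SNP
    # heterozygosity of the presets falls in the 73-85% band
    pool = rng.choice(nhap, size=target, replace=False)
    weights = 0.75 ** np.arange(target)

    n_groups = config.n_clusters if config.founder_design == "clusters" else max(
        2, len(set(config.parent_group.values()))
    )
    pools = []
    if config.founder_design == "clusters":
        # a shared core plus round-robin private haplotypes per cluster
        n_shared = max(1, target // 3)
        for c in range(n_groups):
            idx = list(range(n_shared)) + [
                i for i in range(n_shared, target) if (i - n_shared) % n_groups == c
            ]
            pools.append((pool[idx], weights[idx] / weights[idx].sum()))
    else:
        # two disjoint source populations (no enforced sharing)
        halves = np.array_split(np.arange(target), n_groups)
        for idx in halves:
            pools.append((pool[idx], weights[idx] / weights[idx].sum()))

    parent_ghaps = {}
    for p in config.parents:
        codes, w = pools[config.parent_group.get(p, 0) % len(pools)]
        draw = rng.choice(codes, size=config.ploidy, p=w, replace=True)
        parent_ghaps[p] = tuple(sorted(int(x) for x in draw))

    # soft fix-up: give unused pool codes to random founder homolog slots so
    # the achieved distinct count matches the target
    used = {c for g in parent_ghaps.values() for c in g}
    unused = [int(c) for c in pool if int(c) not in used]
    if unused and config.founder_design == "clusters":
        plist = list(config.parents)
        for c in unused:
            p = plist[int(rng.integers(len(plist)))]
            g = list(parent_ghaps[p])
            g[int(rng.integers(config.ploidy))] = c
            parent_ghaps[p] = tuple(sorted(g))
    return pools, parent_ghaps


def simulate_cross(p1, p2, n: int, alpha: float, rng: np.random.Generator):
    """Sample ``n`` offspring genotypes of a cross (union of two gametes)."""
    out = []
    dists = []
    for parent in (p1, p2):
        d = gamete_distribution(parent, len(parent), alpha)
        gams = list(d)
        dists.append((gams, np.array([d[g] for g in gams])))
    for _ in range(n):
        gam1 = dists[0][0][rng.choice(len(dists[0][0]), p=dists[0][1])]
        gam2 = dists[1][0][rng.choice(len(dists[1][0]), p=dists[1][1])]
        out.append(tuple(sorted(gam1 + gam2)))
    return out


def simulate_population(config: SimConfig) -> SimResult:
    """Simulate dosage data, family structure and the truth set."""
    rng = np.random.default_rng(config.seed)
    sizes = _block_sizes(config)
    block_names = [f"bl{i + 1:03d}" for i in range(config.n_blocks)]

    individuals = list(config.parents)
    families = []
    for fam in config.families:
        offs = tuple(f"{fam.name}_{i + 1:03d}" for i in range(fam.n_offspring))
        families.append(FSFamily(fam.name, fam.parent1, fam.parent2, offs))
        individuals.extend(offs)
    unrelated: list[tuple[str, int]] = []
    for pop, n_u in enumerate(config.n_unrelated):
        for i in range(n_u):
            name = f"U{pop + 1}_{i + 1:03d}"
            unrelated.append((name, pop))
            individuals.append(name)

    blocks = {}
    truth_ghap = {}
    founder_pool = {}
    dosage_rows = {}
    for bname, nmrk in zip(block_names, sizes):
        markers = [f"{bname}_m{j + 1}" for j in range(nmrk)]
        blocks[bname] = markers
        pools, parent_ghaps = simulate_founders(config, nmrk, rng)
        ghaps: dict[str, tuple] = dict(parent_ghaps)
        for fam in families:
            offs_g = simulate_cross(
                ghaps[fam.parent1], ghaps[fam.parent2], len(fam.offspring), config.alpha, rng
            )
            ghaps.update(zip(fam.offspring, offs_g))
        for name, pop in unrelated:
            codes, w = pools[pop % len(pools)]
            draw = rng.choice(codes, size=config.ploidy, p=w, replace=True)
            ghaps[name] = tuple(sorted(int(x) for x in draw))
        truth_ghap[bname] = ghaps
        founder_pool[bname] = sorted({int(c) for g in parent_ghaps.values() for c in g})

        dos = np.array([mrkdos_of_hapcomb(ghaps[i], nmrk) for i in individuals], dtype=float).T
        if config.epsilon_sim > 0:
            err = rng.random(dos.shape) < config.epsilon_sim
            shift = np.where(rng.random(dos.shape) < 0.5, -1, 1)
            shifted = dos + shift
            shifted = np.where(shifted < 0, 1, shifted)
            shifted = np.where(shifted > config.ploidy, config.ploidy - 1, shifted)
            dos = np.where(err, shifted, dos)
        if config.missing_rate > 0:
            dos = np.where(rng.random(dos.shape) < config.missing_rate, np.nan, dos)
        for j, m in enumerate(markers):
            dosage_rows[m] = dos[j]

    dosages = pd.DataFrame.from_dict(dosage_rows, orient="index", columns=individuals)
    return SimResult(
        dosages=dosages,
        blocks=blocks,
        structure=PopulationStructure(families),
        truth=TruthSet(truth_ghap, founder_pool),
        config=config,
    )


def score_against_truth(result: AssignmentResult, truth: TruthSet) -> dict:
    """Compare inferred genotypes with the simulation truth.

    An assignment is correct when it equals the true haplotype combination
    as a multiset.  Returns per-block rows plus overall means (percentages
    averaged over blocks, matching how the validation tables are reported).
    """
    rows = []
    for bname, block in result.blocks.items():
        tr = truth.ghap.get(bname)
        if tr is None or block.error:
            continue
        n = n_hap = n_correct = 0
        for indiv, true_g in tr.items():
            if indiv not in block.assignments:
                continue
            n += 1
            hc = block.assignments[indiv]
            if hc is not None:
                n_hap += 1
                n_correct += hc == tuple(true_g)
        rows.append(
            {
                "block": bname,
                "n": n,
                "n_haplotyped": n_hap,
                "n_correct": n_correct,
                "n_incorrect": n_hap - n_correct,
                "pct_haplotyped": 100.0 * n_hap / n if n else np.nan,
                "pct_correct": 100.0 * n_correct / n_hap if n_hap else np.nan,
                "n_haplotypes_inferred": len(block.haplotypes_used),
                "n_haplotypes_true": len({c for g in tr.values() for c in g}),
            }
        )
    per_block = pd.DataFrame(rows)
    overall = {
        "mean_pct_haplotyped": float(per_block["pct_haplotyped"].mean()),
        "mean_pct_correct": float(per_block["pct_correct"].mean()),
        "total_correct": int(per_block["n_correct"].sum()),
        "total_incorrect": int(per_block["n_incorrect"].sum()),
        "total_not_haplotyped": int((per_block["n"] - per_block["n_haplotyped"]).sum()),
        "mean_n_haplotypes_inferred": float(per_block["n_haplotypes_inferred"].mean()),
        "mean_n_haplotypes_true": float(per_block["n_haplotypes_true"].mean()),
    }
    return {"per_block": per_block, "overall": overall}


def snp_heterozygosity(dosages: pd.DataFrame, ploidy: int) -> pd.Series:
    """Per-individual fraction of heterozygous (non-0, non-ploidy) SNP calls."""
    arr = dosages.to_numpy(dtype=float)
    het = (arr > 0) & (arr < ploidy)
    obs = ~np.isnan(arr)
    return pd.Series(het.sum(axis=0) / obs.sum(axis=0), index=dosages.columns)
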