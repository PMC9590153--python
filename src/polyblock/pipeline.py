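"""Per-haploblock orchestration of the three haplotyping stages.

``infer_haplotypes`` runs, for each haploblock independently (linkage between
blocks is not used):

1. a parsimony inventory of haplotypes likely present (Stage 1) — only as
   input for the family analysis, its assignments are discarded;
2. full-sib family solving by segregation analysis (Stage 2), with groups of
   families linked through shared parents resolved jointly; families that
   cannot be solved are demoted to unrelated material for that block;
3. haplotyping of all remaining material seeded with the haplotypes
   confirmed in the solved families (Stage 3).

With no full-sib families (or ``use_fs=False``) stages 1 and 2 are skipped
and everything is processed as unrelated material.  The whole pipeline is
deterministic: identical inputs and parameters give identical results.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .combinatorics import MISSING, CapacityError, get_table
from .fs import (
    Demoted,
    FSFamily,
    SegregationParams,
    gamete_support,
    impute_family,
    offspring_assignments,
    resolve_group_conflicts,
    solve_one_fs,
)
from .stage1 import Stage1Params, infer_haps_noFS
from .stage3 import haplotype_unrelated

logger = logging.getLogger("polyblock")

PROV_FS = "fs_solved"


@dataclass
class PopulationStructure:
    """Full-sib families; everyone else is treated as unrelated."""

    families: list[FSFamily] = field(default_factory=list)

    def __post_init__(self):
        seen: dict[str, str] = {}
        for f in self.families:
            for o in f.offspring:
                if o in seen:
                    raise ValueError(
                        f"offspring {o} belongs to two families ({seen[o]}, {f.name})"
                    )
                seen[o] = f.name

    @property
    def parents(self) -> set[str]:
        return {p for f in self.families for p in f.parents}

    @property
    def fs_individuals(self) -> set[str]:
        return {o for f in self.families for o in f.offspring}


def group_fs_families(structure: PopulationStructure) -> list[list[FSFamily]]:
    """Connected components of the family graph linked through shared parents."""
    fams = structure.families
    parent_of: dict[str, list[int]] = {}
    for i, f in enumerate(fams):
        for p in f.parents:
            parent_of.setdefault(p, []).append(i)
    comp = [-1] * len(fams)
    ncomp = 0
    for i in range(len(fams)):
        if comp[i] >= 0:
            continue
        stack = [i]
        comp[i] = ncomp
        while stack:
            j = stack.pop()
            for p in fams[j].parents:
                for k in parent_of[p]:
                    if comp[k] < 0:
                        comp[k] = ncomp
                        stack.append(k)
        ncomp += 1
    return [[f for i, f in enumerate(fams) if comp[i] == c] for c in range(ncomp)]


@dataclass
class BlockResult:
    block: str
    markers: list[str]
    inventory: dict  # code -> provenance
    assignments: dict  # individual -> nondecreasing code tuple, or None
    family_status: dict  # family name -> "solved" | "demoted:<reason>"
    error: str | None = None

    @property
    def n_assigned(self) -> int:
        return sum(1 for hc in self.assignments.values() if hc is not None)

    @property
    def haplotypes_used(self) -> set[int]:
        return {c for hc in self.assignments.values() if hc for c in hc}


@dataclass
class AssignmentResult:
    ploidy: int
    blocks: dict  # block name -> BlockResult


def _block_dosages(dosages: pd.DataFrame, markers: list[str]) -> dict[str, np.ndarray]:
    sub = dosages.loc[markers]
    arr = sub.to_numpy(dtype=float)
    arr = np.where(np.isnan(arr), MISSING, arr).astype(np.int64)
    return {indiv: arr[:, j] for j, indiv in enumerate(sub.columns)}


def infer_haplotypes(
    dosages: pd.DataFrame,
    blocks: Mapping[str, list[str]],
    structure: PopulationStructure | None = None,
    ploidy: int = 4,
    seg_params: SegregationParams | None = None,
    stage1_params: Stage1Params | None = None,
    known_haplotypes: Mapping[str, Iterable[int]] | None = None,
    use_fs: bool = True,
    limits: Mapping[int, int] | None = None,
) -> AssignmentResult:
    """Haplotype every individual for every haploblock.

    Parameters
    ----------
    dosages : markers x individuals matrix; NaN marks missing dosages.
    blocks : haploblock name -> ordered marker ids (all present in dosages).
    structure : full-sib families; ``None`` or empty = all unrelated.
    known_haplotypes : optional a-priori haplotype codes per block.
    use_fs : disable to haplotype everything as unrelated material
        (the FS-off comparison).
    """
    if structure is None:
        structure = PopulationStructure([])
    seg_params = seg_params or SegregationParams()
    stage1_params = stage1_params or Stage1Params()
    known_haplotypes = known_haplotypes or {}
    for name, markers in blocks.items():
        missing = [m for m in markers if m not in dosages.index]
        if missing:
            raise ValueError(f"block {name}: markers absent from dosage matrix: {missing}")

    results: dict[str, BlockResult] = {}
    groups = group_fs_families(structure) if use_fs else []
    for name in blocks:
        markers = list(blocks[name])
        prior = set(int(c) for c in known_haplotypes.get(name, ()))
        try:
            table = get_table(len(markers), ploidy, limits=limits)
        except CapacityError as e:
            logger.warning("block %s skipped: %s", name, e)
            results[name] = BlockResult(
                name, markers, {}, {c: None for c in dosages.columns}, {}, error=str(e)
            )
            continue
        bd = _block_dosages(dosages, markers)
        results[name] = _hap_one_block(
            name, markers, bd, groups, structure, prior, table, seg_params, stage1_params
        )
    return AssignmentResult(ploidy=ploidy, blocks=results)


def _hap_one_block(
    name, markers, bd, groups, structure, prior, table, seg_params, s1_params
) -> BlockResult:
    family_status: dict[str, str] = {}
    stage2_assigned: dict[str, tuple] = {}
    solved_members: set[str] = set()

    if groups:
        # Stage 1: inventory only; its individual assignments are ignored
        inv1, _ = infer_haps_noFS(bd, prior=prior, params=s1_params, table=table)
        inv_codes = set(inv1)
        for grp in groups:
            cands = {}
            active = []
            for fam in grp:
                res = solve_one_fs(fam, bd, inv_codes, table, seg_params)
                if isinstance(res, Demoted):
                    family_status[fam.name] = f"demoted:{res.reason}"
                    logger.info("block %s family %s demoted (%s)", name, fam.name, res.reason)
                else:
                    cands[fam.name] = res
                    active.append(fam)
            if not active:
                continue
            resol = resolve_group_conflicts(active, cands)
            for fname in resol.demoted:
                family_status[fname] = "demoted:group_conflict"
                logger.info("block %s family %s demoted (group_conflict)", name, fname)
            for p, g in resol.parent_ghap.items():
                stage2_assigned[p] = tuple(g)
            for fam in active:
                if fam.name in resol.demoted:
                    continue
                family_status[fam.name] = "solved"
                solved_members.update(fam.offspring)
                solved_members.update(fam.parents)
                cand = resol.family_candidate.get(fam.name)
                if cand is not None:
                    offa = offspring_assignments(fam, cand, bd, table.nmrk, seg_params.alpha)
                    for o, hc in offa.items():
                        if hc is not None:
                            stage2_assigned[o] = hc
                    for o, hc in impute_family(fam, cand, bd, table.nmrk, seg_params).items():
                        stage2_assigned[o] = hc
                else:
                    # several co-optimal pairs: assign only offspring whose
                    # Ghap is identical and unique under all of them
                    per_sol = [
                        offspring_assignments(fam, c, bd, table.nmrk, seg_params.alpha)
                        for c in resol.family_co_optimal[fam.name]
                    ]
                    for o in fam.offspring:
                        vals = {a[o] for a in per_sol}
                        if len(vals) == 1 and None not in vals:
                            stage2_assigned[o] = next(iter(vals))

    confirmed = set(prior) | {c for hc in stage2_assigned.values() for c in hc}
    stage3_indivs = [i for i in bd if i not in solved_members]
    inv3, assign3 = haplotype_unrelated(
        {i: bd[i] for i in stage3_indivs}, confirmed, s1_params, table=table
    )

    inventory = {c: PROV_FS for c in sorted(confirmed - set(prior))}
    for c in sorted(prior):
        inventory[c] = "a_priori"
    for c, prov in inv3.items():
        if c not in confirmed:
            inventory[c] = prov
    assignments: dict[str, tuple | None] = {}
    for indiv in bd:
        if indiv in stage2_assigned:
            assignments[indiv] = stage2_assigned[indiv]
        else:
            assignments[indiv] = assign3.get(indiv)
    return BlockResult(name, markers, dict(sorted(inventory.items())), assignments, family_status)


# ---------------------------------------------------------------------------
# replicate merging


def merge_replicates(dosages: pd.DataFrame, replicate_map: Mapping[str, str]) -> pd.DataFrame:
    """Merge replicate samples of the same individual into consensus columns.

    Per marker the consensus is the unique non-missing dosage among the
    replicates; replicates disagreeing on a non-missing value give missing.
    Columns not in ``replicate_map`` are kept as-is.
    """
    groups: dict[str, list[str]] = {}
    order: list[str] = []
    for col in dosages.columns:
        target = replicate_map.get(col, col)
        if target not in groups:
            groups[target] = []
            order.append(target)
        groups[target].append(col)
    out = {}
    for target in order:
        cols = dosages[groups[target]].to_numpy(dtype=float)
        consensus = np.full(len(dosages), np.nan)
        for i in range(cols.shape[0]):
            vals = np.unique(cols[i][~np.isnan(cols[i])])
            if len(vals) == 1:
                consensus[i] = vals[0]
        out[target] = consensus
    return pd.DataFrame(out, index=dosages.index)


# ---------------------------------------------------------------------------
# pedigree checking

MATCH, CONFLICT, NON_CHECKABLE = "match", "conflict", "non_checkable"


def _gamete_partitions(hc: tuple[int, ...]):
    p = len(hc)
    seen = set()
    for pos in itertools.combinations(range(p), p // 2):
        gam1 = tuple(sorted(hc[i] for i in pos))
        gam2 = tuple(sorted(hc[i] for i in range(p) if i not in pos))
        seen.add((gam1, gam2))
    return seen


def check_parent_offspring(
    result: AssignmentResult,
    pedigree: Mapping[str, tuple[str | None, str | None]],
    alpha: float = 0.025,
) -> dict[str, dict[str, str]]:
    """Compatibility of inferred offspring genotypes with their parents.

    An offspring with two assigned parents matches iff its haplotype
    combination splits into two gametes, each producible by the respective
    parent under the gamete model at rate ``alpha``; with one assigned parent
    only one gamete is constrained.  Individuals (or all their parents)
    without assignments are non-checkable.
    """
    report: dict[str, dict[str, str]] = {}
    support_cache: dict[tuple, set] = {}

    def support(g):
        if g not in support_cache:
            support_cache[g] = gamete_support(g, alpha=alpha)
        return support_cache[g]

    for bname, block in result.blocks.items():
        rep: dict[str, str] = {}
        for indiv, (p1, p2) in pedigree.items():
            if indiv not in block.assignments:
                continue
            hc = block.assignments.get(indiv)
            g1 = block.assignments.get(p1) if p1 is not None else None
            g2 = block.assignments.get(p2) if p2 is not None else None
            if hc is None or (g1 is None and g2 is None):
                rep[indiv] = NON_CHECKABLE
                continue
            parts = _gamete_partitions(hc)
            if g1 is not None and g2 is not None:
                ok = any(
                    (a in support(g1) and b in support(g2))
                    or (b in support(g1) and a in support(g2))
                    for a, b in parts
                )
            else:
                gp = g1 if g1 is not None else g2
                ok = any(a in support(gp) or b in support(gp) for a, b in parts)
            rep[indiv] = MATCH if ok else CONFLICT
        report[bname] = rep
    return report


# ---------------------------------------------------------------------------
# summary statistics

CAT_FS, CAT_PARENT, CAT_OTHER, CAT_ALL = "FS individuals", "FS parents", "other", "all"


def summarize(
    result: AssignmentResult,
    structure: PopulationStructure | None,
    dosages: pd.DataFrame,
    report: Mapping[str, Mapping[str, str]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-block and overall haplotyping statistics per individual category.

    Returns ``{"per_block": ..., "overall": ...}``.  The overall table
    carries both averaging orders: ``mean_pct_*`` averages the per-block
    percentages, ``pooled_pct_*`` pools individuals over blocks first.
    """
    structure = structure or PopulationStructure([])
    parents = structure.parents
    fs_ind = structure.fs_individuals
    categories = {
        CAT_FS: sorted(fs_ind),
        CAT_PARENT: sorted(parents),
        CAT_OTHER: sorted(set(dosages.columns) - fs_ind - parents),
        CAT_ALL: list(dosages.columns),
    }
    rows = []
    for bname, block in result.blocks.items():
        if block.error:
            continue
        full = ~dosages.loc[block.markers].isna().any(axis=0)
        for cat, members in categories.items():
            if not members:
                continue
            n = len(members)
            n_full = int(full[members].sum())
            n_hap = sum(1 for i in members if block.assignments.get(i) is not None)
            rep = (report or {}).get(bname, {})
            n_match = sum(1 for i in members if rep.get(i) == MATCH)
            n_confl = sum(1 for i in members if rep.get(i) == CONFLICT)
            n_check = n_match + n_confl
            rows.append(
                {
                    "block": bname,
                    "category": cat,
                    "n": n,
                    "n_fully_genotyped": n_full,
                    "n_haplotyped": n_hap,
                    "n_matching": n_match,
                    "n_conflicting": n_confl,
                    "n_non_checkable": n_hap - n_check,
                    "pct_fully_genotyped": 100.0 * n_full / n,
                    "pct_haplotyped": 100.0 * n_hap / n,
                    "pct_checkable": 100.0 * n_check / n,
                    "pct_matching": (100.0 * n_match / n_check) if n_check else np.nan,
                    "n_haplotypes": len(block.haplotypes_used),
                }
            )
    per_block = pd.DataFrame(rows)
    overall_rows = []
    for cat in categories:
        sub = per_block[per_block["category"] == cat] if len(per_block) else per_block
        if len(sub) == 0:
            continue
        tot = sub[["n", "n_fully_genotyped", "n_haplotyped", "n_matching", "n_conflicting", "n_non_checkable"]].sum()
        n_check = tot["n_matching"] + tot["n_conflicting"]
        overall_rows.append(
            {
                "category": cat,
                "n_blocks": sub["block"].nunique(),
                "mean_n_haplotypes": sub["n_haplotypes"].mean(),
                "mean_pct_fully_genotyped": sub["pct_fully_genotyped"].mean(),
                "mean_pct_haplotyped": sub["pct_haplotyped"].mean(),
                "mean_pct_checkable": sub["pct_checkable"].mean(),
                "mean_pct_matching": sub["pct_matching"].mean(),
                "pooled_pct_fully_genotyped": 100.0 * tot["n_fully_genotyped"] / tot["n"],
                "pooled_pct_haplotyped": 100.0 * tot["n_haplotyped"] / tot["n"],
                "total_matching": int(tot["n_matching"]),
                "total_conflicting": int(tot["n_conflicting"]),
                "total_non_checkable": int(tot["n_non_checkable"]),
                "pooled_pct_matching": (100.0 * tot["n_matching"] / n_check) if n_check else np.nan,
            }
        )
    return {"per_block": per_block, "overall": pd.DataFrame(overall_rows)}
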