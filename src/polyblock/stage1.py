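"""Stage 1: parsimonious inventory of haplotypes present in a population.

Works from dosage data alone (no family information).  Two steps:

a. *Forced* haplotypes: if every combination explaining an individual's
   dosages contains a haplotype, that haplotype is certainly present in that
   individual (e.g. an all-0/ploidy individual is homozygous for one
   haplotype).  Haplotypes forced in at least ``min_frac`` of the usable
   individuals (default 10%) are accepted; the threshold guards against
   dosage-scoring errors.

b. For each individual not fully explained by the known set, take the
   solutions introducing the fewest additional haplotypes and collect the
   haplotypes required by *all* of them; those required in at least
   ``min_frac`` of individuals join the known set.  Step b is iterated to a
   fixpoint; if the iteration cycles through several sets instead, the result
   of the first execution of step b is kept (it is the one anchored in the
   near-certain step-a haplotypes).

An individual is assigned a haplotype combination only when exactly one of
its solutions uses known haplotypes alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .combinatorics import MISSING, HapCombTable, get_table

PROV_APRIORI = "a_priori"
PROV_FORCED = "forced"
PROV_PARSIMONY = "parsimony"


@dataclass
class Stage1Params:
    """Thresholds of the parsimony inventory.

    min_frac: fraction of usable individuals in which a haplotype must be
        forced/required to be accepted (default 0.10).
    relaxed_frac / relaxed_min_count: threshold of the single relaxed cycle
        run on unrelated material (default 1% but at least 2 individuals).
    max_iter: hard stop for the step-b iteration.
    """

    min_frac: float = 0.10
    relaxed_frac: float = 0.01
    relaxed_min_count: int = 2
    max_iter: int = 50

    def __post_init__(self):
        if not 0 < self.relaxed_frac <= self.min_frac <= 1:
            raise ValueError("need 0 < relaxed_frac <= min_frac <= 1")


class _DosageClass:
    """All individuals sharing one dosage vector, with their solution rows."""

    def __init__(self, indivs: list[str], rows: np.ndarray, table: HapCombTable):
        self.indivs = indivs
        self.rows = rows
        nhap = 2**table.nmrk
        combs = table.combs[rows]
        present = np.zeros((len(rows), nhap), dtype=bool)
        present[np.arange(len(rows))[:, None], combs.astype(np.int64)] = True
        self.present = present  # (n_solutions, nhap) code-membership matrix
        self.forced = present.all(axis=0) if len(rows) else np.zeros(nhap, bool)

    def new_counts(self, known_mask: np.ndarray) -> np.ndarray:
        """Distinct not-yet-known haplotypes introduced by each solution."""
        return (self.present & ~known_mask).sum(axis=1)


def _group_classes(
    dosages: Mapping[str, np.ndarray], table: HapCombTable
) -> list[_DosageClass]:
    groups: dict[tuple, list[str]] = {}
    for indiv in dosages:
        g = np.asarray(dosages[indiv])
        if np.all(g == MISSING):
            continue  # all-missing individuals are excluded from Stage 1
        groups.setdefault(tuple(int(x) for x in g), []).append(indiv)
    out = []
    for g in sorted(groups):
        rows = table.lookup(np.array(g))
        out.append(_DosageClass(groups[g], rows, table))
    return out


def forced_haps(g, ploidy: int, table: HapCombTable | None = None) -> set[int]:
    """Haplotypes contained in every combination explaining ``g``."""
    g = np.asarray(g)
    if not np.any(g != MISSING):
        raise ValueError("dosage vector has no observed entries")
    if table is None:
        table = get_table(len(g), ploidy)
    cls = _DosageClass([], table.lookup(g), table)
    if len(cls.rows) == 0:
        raise RuntimeError("in-range dosage vector has no solutions")
    return {int(c) for c in np.flatnonzero(cls.forced)}

def min_new_solutions(
    g, known: Iterable[int], ploidy: int, table: HapCombTable | None = None
) -> list[tuple[int, ...]]:
    """Solutions of ``g`` introducing the fewest haplotypes outside ``known``.

    Preserves lexicographic order of the full solution list.
    """
    g = np.asarray(g)
    if table is None:
        table = get_table(len(g), ploidy)
    cls = _DosageClass([], table.lookup(g), table)
    mask = np.zeros(2**table.nmrk, dtype=bool)
    mask[list(known)] = True
    counts = cls.new_counts(mask)
    best = counts.min()
    return [
        tuple(int(c) for c in table.combs[r])
        for r in cls.rows[np.flatnonzero(counts == best)]
    ]


def _threshold(frac: float, n: int, min_count: int = 1) -> int:
    return max(math.ceil(frac * n), min_count)


def _step_b_required(classes, known_mask: np.ndarray) -> np.ndarray:
    """Per-haplotype individual counts of 'required in all minimal solutions'."""
    nhap = known_mask.size
    counts = np.zeros(nhap, dtype=np.int64)
    for cls in classes:
        nc = cls.new_counts(known_mask)
        if nc.min() == 0:
            continue  # completely explained by the known set
        minimal = cls.present[nc == nc.min()]
        required = minimal.all(axis=0) & ~known_mask
        counts[required] += len(cls.indivs)
    return counts


def _assignments(classes, known_mask: np.ndarray, table: HapCombTable) -> dict:
    out = {}
    for cls in classes:
        nc = cls.new_counts(known_mask)
        idx = np.flatnonzero(nc == 0)
        hc = (
            tuple(int(c) for c in table.combs[cls.rows[idx[0]]])
            if len(idx) == 1
            else None
        )
        for indiv in cls.indivs:
            out[indiv] = hc
    return out


def infer_haps_noFS(
    dosages: Mapping[str, np.ndarray],
    prior: Iterable[int] = (),
    params: Stage1Params | None = None,
    table: HapCombTable | None = None,
    ploidy: int | None = None,
):
    """Parsimony haplotype inventory + per-individual assignments.

    Parameters
    ----------
    dosages : per-individual dosage vectors of one haploblock.
    prior : a-priori known haplotype codes (always kept, no threshold).

    Returns
    -------
    inventory : dict code -> provenance ("a_priori" | "forced" | "parsimony")
    assignments : dict individual -> nondecreasing code tuple, or None
    """
    if params is None:
        params = Stage1Params()
    if not dosages:
        raise ValueError("no individuals supplied")
    first = np.asarray(next(iter(dosages.values())))
    if table is None:
        table = get_table(len(first), ploidy if ploidy is not None else 4)
    classes = _group_classes(dosages, table)
    if not classes:
        raise ValueError("no individual has an observed dosage")
    n_used = sum(len(c.indivs) for c in classes)
    thr = _threshold(params.min_frac, n_used)
    nhap = 2**table.nmrk

    prior = set(int(c) for c in prior)
    # step a: forced haplotypes over the threshold
    forced_counts = np.zeros(nhap, dtype=np.int64)
    for cls in classes:
        forced_counts[cls.forced] += len(cls.indivs)
    step_a = {int(c) for c in np.flatnonzero(forced_counts >= thr)}

    def mask_of(codes):
        m = np.zeros(nhap, dtype=bool)
        m[list(codes)] = True
        return m

    # step b iterated to fixpoint; on a cycle keep the first execution
    known = prior | step_a
    first_b: set[int] | None = None
    seen = [frozenset(known)]
    for _ in range(params.max_iter):
        req = _step_b_required(classes, mask_of(known))
        step_b = {int(c) for c in np.flatnonzero(req >= thr)}
        new_known = prior | step_a | step_b
        if first_b is None:
            first_b = new_known
        if new_known == known:
            break
        if frozenset(new_known) in seen:
            known = first_b
            break
        seen.append(frozenset(new_known))
        known = new_known

    inventory = {}
    for c in sorted(known):
        if c in prior:
            inventory[c] = PROV_APRIORI
        elif c in step_a:
            inventory[c] = PROV_FORCED
        else:
            inventory[c] = PROV_PARSIMONY
    assignments = _assignments(classes, mask_of(known), table)
    for indiv in dosages:
        assignments.setdefault(indiv, None)  # all-missing individuals
    return inventory, assignments
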