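"""Stage 3: haplotyping of unrelated material.

All individuals that are not members of a solved full-sib family — unrelated
samples, plus families demoted during Stage 2 — are analyzed with the same
parsimony procedure as Stage 1, but seeded with the haplotypes confirmed in
the solved families.  If the strict 10% presence threshold leaves individuals
unexplained, a single relaxed cycle of step b is run with a lower threshold
(1% of individuals, but at least 2); its result is accepted only when it
strictly increases the number of uniquely solved individuals without costing
any previously unique individual its unique solution.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np

from .combinatorics import HapCombTable
from .stage1 import (
    PROV_PARSIMONY,
    Stage1Params,
    _assignments,
    _group_classes,
    _step_b_required,
    _threshold,
    infer_haps_noFS,
)


def haplotype_unrelated(
    dosages: Mapping[str, np.ndarray],
    confirmed: Iterable[int] = (),
    params: Stage1Params | None = None,
    table: HapCombTable | None = None,
    ploidy: int | None = None,
):
    """Inventory + assignments for the unrelated material of one haploblock.

    ``confirmed`` are haplotype codes established upstream (a-priori known
    plus those present in solved full-sib families); they seed the inventory
    and bypass the presence thresholds.
    """
    if params is None:
        params = Stage1Params()
    if not dosages:
        return {}, {}
    inventory, assignments = infer_haps_noFS(
        dosages, prior=confirmed, params=params, table=table, ploidy=ploidy
    )
    if table is None:
        from .combinatorics import get_table

        nmrk = len(np.asarray(next(iter(dosages.values()))))
        table = get_table(nmrk, ploidy if ploidy is not None else 4)

    if all(hc is not None for hc in assignments.values()):
        return inventory, assignments

    # one relaxed cycle of step b
    classes = _group_classes(dosages, table)
    n_used = sum(len(c.indivs) for c in classes)
    thr = _threshold(params.relaxed_frac, n_used, params.relaxed_min_count)
    nhap = 2**table.nmrk
    known_mask = np.zeros(nhap, dtype=bool)
    known_mask[list(inventory)] = True
    req = _step_b_required(classes, known_mask)
    extra = {int(c) for c in np.flatnonzero(req >= thr)}
    if not extra:
        return inventory, assignments

    relaxed_mask = known_mask.copy()
    relaxed_mask[sorted(extra)] = True
    relaxed_assignments = _assignments(classes, relaxed_mask, table)
    for indiv in dosages:
        relaxed_assignments.setdefault(indiv, None)

    n_before = sum(1 for hc in assignments.values() if hc is not None)
    n_after = sum(1 for hc in relaxed_assignments.values() if hc is not None)
    lost = any(
        assignments[i] is not None and relaxed_assignments[i] is None
        for i in assignments
    )
    if n_after > n_before and not lost:
        inventory = dict(inventory)
        for c in sorted(extra):
            inventory[c] = PROV_PARSIMONY
        return inventory, relaxed_assignments
    return inventory, assignments
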