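"""Haplotype encoding and exhaustive enumeration of haplotype combinations.

A haploblock of ``nmrk`` tightly linked bi-allelic markers has ``2**nmrk``
possible haplotypes.  Each haplotype is encoded as an integer code in
``[0, 2**nmrk)`` whose bit ``j`` (bit 0 = first marker in block order) is the
allele carried at marker ``j``.  An individual of even ploidy ``p`` carries a
multiset of ``p`` haplotypes (a *haplotype combination*, stored as a
nondecreasing tuple of codes); the observable data are the per-marker allele
dosages, i.e. the column sums of the bit patterns.

The central object is :class:`HapCombTable`: the exhaustive, pre-computed map
from every fully observed marker-dosage vector to the list of haplotype
combinations that produce it.  Everything downstream (parsimony inventory,
full-sib segregation scoring, imputation) is a walk over these lists.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np

MISSING = -1

#: Largest block size per ploidy for which exhaustive tables are built by
#: default.  C(2^nmrk + ploidy - 1, ploidy) grows steeply; these caps keep the
#: tables in memory.
DEFAULT_NMRK_LIMITS = {2: 8, 4: 8, 6: 6}

_TABLE_FORMAT_VERSION = 1


def haplotype_space_size(nmrk: int) -> int:
    """Number of distinct haplotypes a block of ``nmrk`` markers can carry."""
    if nmrk < 1:
        raise ValueError("nmrk must be >= 1")
    return 2**nmrk


def haplotype_alleles(code: int, nmrk: int) -> np.ndarray:
    """Binary allele vector of a haplotype code (entry j = bit j of code)."""
    if not 0 <= code < 2**nmrk:
        raise ValueError(f"haplotype code {code} out of range for {nmrk} markers")
    return (code >> np.arange(nmrk)) & 1


def mrkdos_of_hapcomb(hc, nmrk: int) -> np.ndarray:
    """Marker-dosage vector produced by a haplotype combination.

    Dosage at marker j is the number of haplotypes in ``hc`` carrying the
    alternative allele at j; dosages are additive over haplotypes.
    """
    dos = np.zeros(nmrk, dtype=np.int64)
    for code in hc:
        dos += haplotype_alleles(int(code), nmrk)
    return dos


def count_all_hapcombs(nmrk: int, ploidy: int) -> int:
    """Total number of haplotype multisets of size ploidy: C(2^nmrk+p-1, p)."""
    from math import comb

    return comb(2**nmrk + ploidy - 1, ploidy)


def gmrk_index(g, ploidy: int) -> int:
    """Mixed-radix key of a fully observed dosage vector: sum d_j*(p+1)^j."""
    idx = 0
    for j, d in enumerate(g):
        d = int(d)
        if d == MISSING:
            raise ValueError("gmrk_index requires a fully observed dosage vector")
        if not 0 <= d <= ploidy:
            raise ValueError(f"dosage {d} out of range 0..{ploidy}")
        idx += d * (ploidy + 1) ** j
    return idx


def _validate_dosages(g, ploidy: int) -> np.ndarray:
    g = np.asarray(g, dtype=np.int64)
    bad = (g != MISSING) & ((g < 0) | (g > ploidy))
    if bad.any():
        raise ValueError(f"dosage out of range 0..{ploidy}: {g[bad]}")
    return g


class HapCombTable:
    """Exhaustive table of haplotype combinations, keyed by dosage vector.

    Combinations are generated in lexicographic order over nondecreasing
    code tuples; all lookups preserve that order, so every downstream
    tie-break is reproducible.

    Attributes
    ----------
    combs : (N, ploidy) int16 array of codes, lexicographically ordered.
    dosages : (N, nmrk) int16 array, row i = marker dosages of combs[i].
    """

    def __init__(self, nmrk: int, ploidy: int, combs: np.ndarray, dosages: np.ndarray):
        self.nmrk = int(nmrk)
        self.ploidy = int(ploidy)
        self.combs = combs
        self.dosages = dosages
        keys = dosages.astype(np.int64) @ (ploidy + 1) ** np.arange(nmrk, dtype=np.int64)
        order = np.argsort(keys, kind="stable")
        self._sorted_rows = order
        self._sorted_keys = keys[order]

    @classmethod
    def build(cls, nmrk: int, ploidy: int, limits=None) -> "HapCombTable":
        """Enumerate all C(2^nmrk+p-1, p) combinations and index them.

        Refuses sizes above the configured per-ploidy caps with a capacity
        error; pass ``limits`` to override.
        """
        if nmrk < 1:
            raise ValueError("nmrk must be >= 1")
        if ploidy < 2 or ploidy % 2:
            raise ValueError("ploidy must be an even integer >= 2")
        limits = DEFAULT_NMRK_LIMITS if limits is None else limits
        cap = limits.get(ploidy)
        if cap is not None and nmrk > cap:
            raise CapacityError(
                f"blocks of {nmrk} markers exceed the {cap}-marker capacity "
                f"for ploidy {ploidy}"
            )
        nhap = 2**nmrk
        combs = np.array(
            list(itertools.combinations_with_replacement(range(nhap), ploidy)),
            dtype=np.int16,
        ).reshape(-1, ploidy)
        bits = ((np.arange(nhap)[:, None] >> np.arange(nmrk)) & 1).astype(np.int16)
        dosages = bits[combs].sum(axis=1, dtype=np.int16)
        return cls(nmrk, ploidy, combs, dosages)

    def __len__(self) -> int:
        return len(self.combs)

    def rows_for_key(self, key: int) -> np.ndarray:
        """Row indices (ascending = lexicographic) of combs with this key."""
        lo = np.searchsorted(self._sorted_keys, key, side="left")
        hi = np.searchsorted(self._sorted_keys, key, side="right")
        return np.sort(self._sorted_rows[lo:hi])

    def lookup(self, g) -> np.ndarray:
        """All combinations consistent with ``g`` at every non-missing marker.

        Missing entries (``MISSING``) are handled by a union over their
        possible values, so masking an entry can only enlarge the result.
        Returns row indices into :attr:`combs`, in lexicographic order.
        """
        g = _validate_dosages(g, self.ploidy)
        if len(g) != self.nmrk:
            raise ValueError(f"expected {self.nmrk} dosages, got {len(g)}")
        miss = np.flatnonzero(g == MISSING)
        if miss.size == 0:
            return self.rows_for_key(gmrk_index(g, self.ploidy))
        parts = []
        for vals in itertools.product(range(self.ploidy + 1), repeat=miss.size):
            gg = g.copy()
            gg[miss] = vals
            parts.append(self.rows_for_key(gmrk_index(gg, self.ploidy)))
        return np.sort(np.concatenate(parts))

    # -- persistence ---------------------------------------------------

    def save(self, path) -> None:
        """Persist to an .npz container with a versioned header."""
        np.savez(
            path,
            format_version=np.int64(_TABLE_FORMAT_VERSION),
            nmrk=np.int64(self.nmrk),
            ploidy=np.int64(self.ploidy),
            count=np.int64(len(self.combs)),
            combs=self.combs,
            dosages=self.dosages,
        )

    @classmethod
    def load(cls, path) -> "HapCombTable":
        with np.load(Path(path)) as z:
            if int(z["format_version"]) != _TABLE_FORMAT_VERSION:
                raise ValueError("unsupported table format version")
            nmrk, ploidy = int(z["nmrk"]), int(z["ploidy"])
            combs, dosages = z["combs"], z["dosages"]
            if len(combs) != int(z["count"]):
                raise ValueError("corrupt table: count mismatch")
        return cls(nmrk, ploidy, combs, dosages)


class CapacityError(ValueError):
    """Requested block size exceeds the configured exhaustive-table capacity."""


_table_cache: dict[tuple[int, int], HapCombTable] = {}


def get_table(nmrk: int, ploidy: int, limits=None) -> HapCombTable:
    """Process-wide cache of built tables (they are expensive and reusable)."""
    key = (nmrk, ploidy)
    if key not in _table_cache:
        _table_cache[key] = HapCombTable.build(nmrk, ploidy, limits=limits)
    return _table_cache[key]


def build_hapcomb_table(nmrk: int, ploidy: int, limits=None) -> HapCombTable:
    return HapCombTable.build(nmrk, ploidy, limits=limits)


def enumerate_hapcombs(g, ploidy: int, nmrk: int | None = None, table: HapCombTable | None = None) -> list[tuple[int, ...]]:
    """All haplotype combinations whose dosages match ``g`` where observed.

    Returned as nondecreasing code tuples in lexicographic order.
    """
    g = np.asarray(g)
    if table is None:
        table = get_table(nmrk if nmrk is not None else len(g), ploidy)
    rows = table.lookup(g)
    return [tuple(int(c) for c in table.combs[r]) for r in rows]
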