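"""Stage 2: haplotyping full-sib families from observed dosage segregation.

For each candidate pair of parental haplotype combinations we predict the
segregation of offspring genotypes under polysomic inheritance with a
double-reduction (DR) rate ``alpha``, fold in a per-marker dosage-error rate
``epsilon``, and score the prediction against the observed offspring
dosage-genotype counts with a Pearson chi-squared goodness-of-fit test.
Candidate pairs close enough to the best one are retained; conflicts between
families sharing a parent are resolved by discarding the parental combination
that leaves the most offspring unexplained.

Gamete model (one ``alpha`` parameter, fully polysomic):
with probability 1 - alpha the gamete is a uniform draw of ploidy/2 distinct
homologs; with probability alpha one uniformly chosen homolog is transmitted
twice and the remaining gamete slots are filled by a uniform draw from the
other homologs (for tetraploids the DR gamete is the duplicated homolog
alone).  Diploids have single-homolog gametes, so alpha is ignored.

Dosage-error model: independently per marker, a true dosage d is observed as
d with probability 1 - epsilon and as an adjacent dosage with probability
epsilon (split equally between d-1 and d+1; folded entirely onto the single
neighbour at the 0/ploidy boundaries).  Array dosage errors are
overwhelmingly off-by-one, which this captures with a single parameter.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2

from .combinatorics import MISSING, HapCombTable

__all__ = [
    "SegregationParams",
    "Demoted",
    "FSFamily",
    "FSCandidate",
    "gamete_distribution",
    "gamete_support",
    "progeny_ghap_distribution",
    "expected_gmrk_distribution",
    "fs_segregation_pvalue",
    "solve_one_fs",
    "resolve_group_conflicts",
    "impute_fs_indiv",
    "impute_family",
    "offspring_assignments",
]


@dataclass
class SegregationParams:
    """Thresholds and model rates of the family-segregation stage."""

    alpha: float = 0.025  # double-reduction frequency
    epsilon: float = 0.025  # per-marker dosage-error probability
    p_ratio: float = 0.001  # keep candidates with P >= p_ratio * P_best
    p_min: float = 1e-8  # absolute P floor
    max_parent_combs: int = 150_000  # pair-count cap before demotion
    impute_p_ratio: float = 0.1  # P_with >= ratio * P_without
    impute_max_frac: float = 0.5  # reject if >= this fraction imputed


@dataclass(frozen=True)
class FSFamily:
    name: str
    parent1: str
    parent2: str
    offspring: tuple[str, ...]

    def __post_init__(self):
        if {self.parent1, self.parent2} & set(self.offspring):
            raise ValueError(f"family {self.name}: parent listed as offspring")

    @property
    def parents(self) -> tuple[str, str]:
        return (self.parent1, self.parent2)


@dataclass(frozen=True)
class Demoted:
    """A family reclassified as unrelated material for one haploblock."""

    reason: str  # missing_parent_dosage | no_genotyped_offspring |
    #              too_many_combinations | no_acceptable_solution | group_conflict


@dataclass
class FSCandidate:
    """One candidate pair of parental haplotype combinations."""

    ghap_p1: tuple[int, ...]
    ghap_p2: tuple[int, ...]
    p_value: float
    expected_gmrk: dict = field(repr=False)  # error-free progeny Gmrk distribution

    @property
    def pair(self):
        return (self.ghap_p1, self.ghap_p2)


# ---------------------------------------------------------------------------
# gamete / progeny models


def gamete_distribution(ghap: Sequence[int], ploidy: int | None = None, alpha: float = 0.0) -> dict[tuple[int, ...], float]:
    """Distribution of gametes (sorted code multisets) of one parent."""
    ghap = tuple(ghap)
    if ploidy is None:
        ploidy = len(ghap)
    if ploidy != len(ghap) or ploidy % 2 or ploidy < 2:
        raise ValueError("ghap length must equal the (even) ploidy")
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    half = ploidy // 2
    dist: dict[tuple[int, ...], float] = {}
    a = 0.0 if half < 2 else alpha  # no DR possible with 1-homolog gametes
    w = (1.0 - a) / math.comb(ploidy, half)
    for pos in itertools.combinations(range(ploidy), half):
        gam = tuple(sorted(ghap[i] for i in pos))
        dist[gam] = dist.get(gam, 0.0) + w
    if a > 0:
        w_dr = a / (ploidy * math.comb(ploidy - 1, half - 2))
        for i in range(ploidy):
            others = [j for j in range(ploidy) if j != i]
            for rest in itertools.combinations(others, half - 2):
                gam = tuple(sorted((ghap[i], ghap[i]) + tuple(ghap[j] for j in rest)))
                dist[gam] = dist.get(gam, 0.0) + w_dr
    return dist


def gamete_support(ghap: Sequence[int], ploidy: int | None = None, alpha: float = 0.0) -> set[tuple[int, ...]]:
    """Gametes with nonzero probability (used by the pedigree check)."""
    return set(gamete_distribution(ghap, ploidy, alpha))


def progeny_ghap_distribution(g1, g2, ploidy: int | None = None, alpha: float = 0.0) -> dict[tuple[int, ...], float]:
    """Offspring haplotype-combination distribution of a parental pair."""
    d1 = gamete_distribution(g1, ploidy, alpha)
    d2 = gamete_distribution(g2, ploidy, alpha)
    out: dict[tuple[int, ...], float] = {}
    for gam1, p1 in d1.items():
        for gam2, p2 in d2.items():
            child = tuple(sorted(gam1 + gam2))
            out[child] = out.get(child, 0.0) + p1 * p2
    return out


def _error_channel(ploidy: int, epsilon: float) -> np.ndarray:
    """(ploidy+1)x(ploidy+1) matrix T[d, d'] = P(observe d' | true d)."""
    T = np.eye(ploidy + 1) * (1.0 - epsilon)
    for d in range(ploidy + 1):
        nbrs = [x for x in (d - 1, d + 1) if 0 <= x <= ploidy]
        for x in nbrs:
            T[d, x] += epsilon / len(nbrs)
    return T


def expected_gmrk_distribution(ghap_dist: Mapping[tuple, float], epsilon: float, ploidy: int, nmrk: int) -> dict[tuple[int, ...], float]:
    """Push a Ghap distribution to observed-Gmrk space through the error model."""
    bits = (np.arange(2**nmrk)[:, None] >> np.arange(nmrk)) & 1
    base: dict[tuple, float] = {}
    for ghap, p in ghap_dist.items():
        g = tuple(int(x) for x in bits[list(ghap)].sum(axis=0))
        base[g] = base.get(g, 0.0) + p
    if epsilon == 0:
        return base
    T = _error_channel(ploidy, epsilon)
    out: dict[tuple, float] = {}
    for g, p in base.items():
        per_marker = [[(x, T[d, x]) for x in range(ploidy + 1) if T[d, x] > 0] for d in g]
        for combo in itertools.product(*per_marker):
            obs = tuple(x for x, _ in combo)
            w = p
            for _, t in combo:
                w *= t
            out[obs] = out.get(obs, 0.0) + w
    return out


# ---------------------------------------------------------------------------
# chi-squared test


def fs_segregation_pvalue(observed: Mapping[tuple, int], expected: Mapping[tuple, float], n: int) -> float:
    """Pearson goodness-of-fit P of observed offspring genotype counts.

    Expected classes with fewer than 1 expected individual are pooled with
    the observed-but-unexpected classes into a single category, limiting the
    small-count bias of the test.  df = categories - 1 (floor 1).
    """
    if n < 1:
        raise ValueError("family must contain at least one genotyped offspring")
    retained = {c: p * n for c, p in expected.items() if p * n >= 1.0}
    exp_pool = n - sum(retained.values())
    obs_pool = sum(cnt for c, cnt in observed.items() if c not in retained)
    stat = sum((observed.get(c, 0) - e) ** 2 / e for c, e in retained.items())
    ncat = len(retained)
    if exp_pool > 1e-9:
        stat += (obs_pool - exp_pool) ** 2 / exp_pool
        ncat += 1
    elif obs_pool > 0:
        return 0.0  # observed offspring impossible under this candidate
    df = max(ncat - 1, 1)
    return float(chi2.sf(stat, df))


def _truncated_expected(gmrk_probs: dict, epsilon: float, ploidy: int, n: int) -> dict:
    """Exact expected probabilities of every class that could be retained.

    Classes needing k dosage errors have probability <= (epsilon/2)^k, so only
    classes within K errors of the error-free support can reach n*p >= 1;
    their probabilities are computed exactly (including channel leakage).
    The pooled category is handled downstream as n minus the retained mass,
    so truncation does not change the test.
    """
    if epsilon == 0 or not gmrk_probs:
        return gmrk_probs
    K = 0
    while n * (epsilon / 2) ** (K + 1) >= 1.0 and K < 8:
        K += 1
    support = list(gmrk_probs)
    cand = set(support)
    frontier = set(support)
    for _ in range(K):
        nxt = set()
        for g in frontier:
            for j in range(len(g)):
                for d in (g[j] - 1, g[j] + 1):
                    if 0 <= d <= ploidy:
                        nxt.add(g[:j] + (d,) + g[j + 1 :])
        frontier = nxt - cand
        cand |= frontier
    T = _error_channel(ploidy, epsilon)
    S = np.array(support)
    C = np.array(sorted(cand))
    p = np.array([gmrk_probs[g] for g in support])
    M = np.ones((len(S), len(C)))
    for j in range(S.shape[1]):
        M *= T[S[:, j][:, None], C[None, :, j]]
    probs = p @ M
    return {tuple(int(x) for x in c): float(pr) for c, pr in zip(C, probs)}


# ---------------------------------------------------------------------------
# solving one family
#
# The inner loop works in mixed-radix index space: a dosage vector g maps to
# sum_j g_j * (ploidy+1)^j.  Gamete dosages are at most ploidy/2 per marker,
# so the index of an offspring genotype is simply the sum of its two gamete
# indices (no carries), which turns the progeny-genotype distribution of a
# parental pair into an outer sum of two small sparse vectors.


class _PairScorer:
    """Vectorized chi-squared scoring of parental pairs for one family."""

    def __init__(self, observed: Counter, n: int, nmrk: int, ploidy: int, params: SegregationParams):
        self.n = n
        self.nmrk = nmrk
        self.ploidy = ploidy
        self.params = params
        radix = (ploidy + 1) ** np.arange(nmrk, dtype=np.int64)
        self.radix = radix
        space = (ploidy + 1) ** nmrk
        idx = np.arange(space)
        decode = np.empty((space, nmrk), dtype=np.int64)
        for j in range(nmrk):
            decode[:, j] = (idx // radix[j]) % (ploidy + 1)
        self.decode = decode
        self.T = _error_channel(ploidy, params.epsilon)
        obs_items = sorted((int(np.dot(np.array(g), radix)), c) for g, c in observed.items())
        self.obs_idx = np.array([i for i, _ in obs_items], dtype=np.int64)
        self.obs_cnt = np.array([c for _, c in obs_items], dtype=np.float64)
        # classes needing k dosage errors receive at most epsilon^k leakage;
        # K is the largest error count whose classes could still be retained
        eps = params.epsilon
        K = 0
        while eps > 0 and n * eps ** (K + 1) >= 0.25 and K < 8:
            K += 1
        self.K = K
        nhap = 2**nmrk
        bits = ((np.arange(nhap)[:, None] >> np.arange(nmrk)) & 1).astype(np.int64)
        self.code_idx = bits @ radix  # dosage index of each single haplotype
        self._gam_cache: dict = {}
        self._dense = np.zeros(space)  # scratch buffer for leakage bounds

    def gamete_dist(self, ghap: tuple):
        """Sparse (indices, probabilities) gamete dosage distribution."""
        hit = self._gam_cache.get(ghap)
        if hit is not None:
            return hit
        gd = gamete_distribution(ghap, self.ploidy, self.params.alpha)
        idx = np.array(
            [int(sum(self.code_idx[c] for c in gam)) for gam in gd], dtype=np.int64
        )
        p = np.array(list(gd.values()))
        order = np.argsort(idx)
        out = (idx[order], p[order])
        self._gam_cache[ghap] = out
        return out

    def progeny_classes(self, g1: tuple, g2: tuple):
        """Aggregated error-free progeny genotype distribution of a pair."""
        i1, p1 = self.gamete_dist(g1)
        i2, p2 = self.gamete_dist(g2)
        idx = (i1[:, None] + i2[None, :]).ravel()
        w = (p1[:, None] * p2[None, :]).ravel()
        order = np.argsort(idx, kind="stable")
        idx, w = idx[order], w[order]
        cut = np.flatnonzero(np.r_[True, idx[1:] != idx[:-1]])
        return idx[cut], np.add.reduceat(w, cut)

    def _neighbors(self, idx: np.ndarray) -> np.ndarray:
        """Indices one dosage step away from each index in ``idx``."""
        S = self.decode[idx]
        out = []
        for j in range(self.nmrk):
            step = int(self.radix[j])
            out.append(idx[S[:, j] > 0] - step)
            out.append(idx[S[:, j] < self.ploidy] + step)
        return np.concatenate(out) if out else idx[:0]

    def _expected(self, classes: np.ndarray, probs: np.ndarray):
        """Expected probabilities of every class that can reach 1 expected.

        With a dosage-error rate only classes whose direct mass plus the
        one-step channel leakage from their neighbours could reach one
        expected individual are candidates (expected-count resolution 0.25);
        their probabilities are then computed exactly, including leakage.
        Everything else is pooled downstream via n minus the retained mass.
        """
        eps = self.params.epsilon
        if eps == 0:
            return classes, probs
        n = self.n
        S = self.decode[classes]
        dense = self._dense
        dense[classes] = probs
        # one-step leakage mass arriving at each support class
        leak = np.zeros(len(classes))
        for j in range(self.nmrk):
            step = int(self.radix[j])
            lo = S[:, j] > 0
            hi = S[:, j] < self.ploidy
            leak[lo] += dense[classes[lo] - step]
            leak[hi] += dense[classes[hi] + step]
        dense[classes] = 0.0
        ub = n * (probs + eps * leak + (eps**2 if self.K > 1 else 0.0))
        C = classes[ub >= 1.0]
        # unobserved classes reachable from one massive neighbour
        heavy = classes[probs * n * eps >= 0.25]
        if len(heavy):
            C = np.unique(np.concatenate([C, self._neighbors(heavy)]))
        if not len(C):
            return C, np.zeros(0)
        D = self.decode[C]
        M = self.T[S[:, 0][:, None], D[None, :, 0]]
        for j in range(1, self.nmrk):
            M = M * self.T[S[:, j][:, None], D[None, :, j]]
        return C, probs @ M

    def stat_df(self, g1: tuple, g2: tuple):
        """Pearson statistic and df of one parental pair (inf => P = 0)."""
        classes, probs = self.progeny_classes(g1, g2)
        C, E = self._expected(classes, probs)
        n = self.n
        exp = n * E
        keep = exp >= 1.0
        Ck, expk = C[keep], exp[keep]
        obs_on = np.zeros(len(Ck))
        if len(Ck):
            pos = np.clip(np.searchsorted(Ck, self.obs_idx), 0, len(Ck) - 1)
            hit = Ck[pos] == self.obs_idx
            np.add.at(obs_on, pos[hit], self.obs_cnt[hit])
        stat = float(((obs_on - expk) ** 2 / expk).sum()) if len(Ck) else 0.0
        ncat = len(Ck)
        exp_pool = n - expk.sum()
        obs_pool = n - obs_on.sum()
        if exp_pool > 1e-9:
            stat += (obs_pool - exp_pool) ** 2 / exp_pool
            ncat += 1
        elif obs_pool > 0.5:
            return np.inf, 1
        return stat, max(ncat - 1, 1)


try:  # numba accelerates the pair scan ~30x; the numpy path is equivalent
    from ._fastscore import score_pairs as _score_pairs_jit
except ImportError:  # pragma: no cover
    _score_pairs_jit = None


def _pad_gamete_dists(scorer: _PairScorer, ghaps):
    dists = [scorer.gamete_dist(g) for g in ghaps]
    kmax = max(len(i) for i, _ in dists)
    I = np.zeros((len(dists), kmax), dtype=np.int64)
    P = np.zeros((len(dists), kmax))
    k = np.empty(len(dists), dtype=np.int64)
    for s, (i, p) in enumerate(dists):
        I[s, : len(i)] = i
        P[s, : len(i)] = p
        k[s] = len(i)
    return I, P, k


def _score_pair_block(scorer: _PairScorer, t1, t2, selfing: bool):
    """Pearson statistic + df for every parental pair (t1 x t2 or diagonal)."""
    if _score_pairs_jit is not None:
        I1, P1, k1 = _pad_gamete_dists(scorer, t1)
        I2, P2, k2 = (I1, P1, k1) if selfing else _pad_gamete_dists(scorer, t2)
        return _score_pairs_jit(
            I1, P1, k1, I2, P2, k2,
            scorer.obs_idx, scorer.obs_cnt, scorer.decode, scorer.radix, scorer.T,
            scorer.n, scorer.params.epsilon, scorer.ploidy, scorer.K > 1, selfing,
        )
    pairs = [(g, g) for g in t1] if selfing else [(a, b) for a in t1 for b in t2]
    stats = np.empty(len(pairs))
    dfs = np.empty(len(pairs), dtype=np.int64)
    for i, (g1, g2) in enumerate(pairs):
        stats[i], dfs[i] = scorer.stat_df(g1, g2)
    return stats, dfs


def _pair_gmrk_dist(g1, g2, alpha, nmrk):
    """Error-free progeny Gmrk distribution of a parental pair (dict form)."""
    bits = (np.arange(2 ** nmrk)[:, None] >> np.arange(nmrk)) & 1
    dist: dict[tuple, float] = {}
    for ghap, p in progeny_ghap_distribution(g1, g2, alpha=alpha).items():
        g = tuple(int(x) for x in bits[list(ghap)].sum(axis=0))
        dist[g] = dist.get(g, 0.0) + p
    return dist


def solve_one_fs(
    fam: FSFamily,
    dosages: Mapping[str, np.ndarray],
    inventory: set[int],
    table: HapCombTable,
    params: SegregationParams | None = None,
):
    """Candidate parental pairs for one full-sib family, or :class:`Demoted`.

    Parents are required to have complete dosage vectors.  Pairs built from
    inventory-only haplotypes are scored first; only if none survives the
    P-value filters are all dosage-consistent parental combinations scored.
    """
    if params is None:
        params = SegregationParams()
    try:
        gp1 = np.asarray(dosages[fam.parent1])
        gp2 = np.asarray(dosages[fam.parent2])
    except KeyError as e:
        raise KeyError(f"unknown parent id in family {fam.name}: {e}")
    if np.any(gp1 == MISSING) or np.any(gp2 == MISSING):
        return Demoted("missing_parent_dosage")
    full = [
        o
        for o in fam.offspring
        if o in dosages and not np.any(np.asarray(dosages[o]) == MISSING)
    ]
    n = len(full)
    if n == 0:
        return Demoted("no_genotyped_offspring")
    observed = Counter(tuple(int(x) for x in np.asarray(dosages[o])) for o in full)

    rows1 = table.lookup(gp1)
    rows2 = table.lookup(gp2)
    inv_mask = np.zeros(2**table.nmrk, dtype=bool)
    if inventory:
        inv_mask[sorted(inventory)] = True
    keep1 = inv_mask[table.combs[rows1].astype(np.int64)].all(axis=1)
    keep2 = inv_mask[table.combs[rows2].astype(np.int64)].all(axis=1)

    scorer = _PairScorer(observed, n, table.nmrk, table.ploidy, params)

    def as_tuples(rows):
        return [tuple(int(c) for c in table.combs[r]) for r in rows]

    selfing = fam.parent1 == fam.parent2
    for r1, r2 in ((rows1[keep1], rows2[keep2]), (rows1, rows2)):
        npairs = len(r1) if selfing else len(r1) * len(r2)
        if npairs == 0:
            continue
        if npairs > params.max_parent_combs:
            return Demoted("too_many_combinations")
        t1 = as_tuples(r1)
        t2 = t1 if selfing else as_tuples(r2)
        pairs = [(g1, g1) for g1 in t1] if selfing else [
            (g1, g2) for g1 in t1 for g2 in t2
        ]
        stats, dfs = _score_pair_block(scorer, t1, t2, selfing)
        pvals = chi2.sf(stats, dfs)
        best = pvals.max()
        ok = np.flatnonzero((pvals >= params.p_ratio * best) & (pvals > params.p_min))
        if len(ok):
            return [
                FSCandidate(
                    pairs[i][0],
                    pairs[i][1],
                    float(pvals[i]),
                    _pair_gmrk_dist(pairs[i][0], pairs[i][1], params.alpha, table.nmrk),
                )
                for i in ok
            ]
    return Demoted("no_acceptable_solution")


# ---------------------------------------------------------------------------
# resolving groups of families linked by shared parents


@dataclass
class GroupResolution:
    parent_ghap: dict  # parent id -> ghap (only parents unique across optima)
    family_candidate: dict  # family name -> FSCandidate (unique) or None
    family_co_optimal: dict  # family name -> list of co-optimal FSCandidates
    demoted: list  # family names demoted during conflict resolution


def resolve_group_conflicts(
    group: Sequence[FSFamily], candidates: Mapping[str, list[FSCandidate]]
) -> GroupResolution:
    """Select the best joint parental solution for linked families.

    Repeatedly removes the parental combination with the most incompatible
    offspring until all remaining families are mutually compatible, demoting
    families that lose their last candidate; then maximizes the product of
    family P values, and under ties keeps only assignments identical across
    all co-optimal solutions.
    """
    if not group:
        raise ValueError("empty family group")
    cands = {f.name: list(candidates[f.name]) for f in group}
    active = [f for f in group if cands[f.name]]
    demoted = [f.name for f in group if not cands[f.name]]

    def slot_ghaps(fam, parent):
        out = []
        for c in cands[fam.name]:
            for slot, pid in ((c.ghap_p1, fam.parent1), (c.ghap_p2, fam.parent2)):
                if pid == parent and slot not in out:
                    out.append(slot)
        return out

    while True:
        worst = None  # (count, parent, ghap)
        parents = sorted({p for f in active for p in f.parents})
        for parent in parents:
            fams = [f for f in active if parent in f.parents]
            ghaps = []
            for f in fams:
                for g in slot_ghaps(f, parent):
                    if g not in ghaps:
                        ghaps.append(g)
            for g in ghaps:
                cnt = sum(len(f.offspring) for f in fams if g not in slot_ghaps(f, parent))
                if cnt > 0 and (worst is None or cnt > worst[0]):
                    worst = (cnt, parent, g)
        if worst is None:
            break
        _, parent, g = worst
        for f in [f for f in active if parent in f.parents]:
            kept = []
            for c in cands[f.name]:
                uses = (f.parent1 == parent and c.ghap_p1 == g) or (
                    f.parent2 == parent and c.ghap_p2 == g
                )
                if not uses:
                    kept.append(c)
            cands[f.name] = kept
            if not kept:
                demoted.append(f.name)
        active = [f for f in active if cands[f.name]]

    if not active:
        return GroupResolution({}, {}, {}, demoted)

    # Families only couple through shared parents, so the joint optimum is
    # found by enumerating assignments of the shared parents and maximizing
    # each family's candidate P given its shared-parent slots; parents of a
    # single family are maximized out within that family.
    n_fams_of: Counter = Counter(p for f in active for p in f.parents)
    shared = sorted(p for p, k in n_fams_of.items() if k > 1)
    domains = {}
    for p in shared:
        dom = []
        for f in active:
            if p in f.parents:
                for g in slot_ghaps(f, p):
                    if g not in dom:
                        dom.append(g)
        domains[p] = dom

    def fam_best(f, assign):
        """(max logP, argmax candidates) of a family given shared slots."""
        best_lp, best_c = -np.inf, []
        for c in cands[f.name]:
            if f.parent1 in assign and c.ghap_p1 != assign[f.parent1]:
                continue
            if f.parent2 in assign and c.ghap_p2 != assign[f.parent2]:
                continue
            lp = math.log(c.p_value)
            if lp > best_lp + 1e-12:
                best_lp, best_c = lp, [c]
            elif lp >= best_lp - 1e-12:
                best_c.append(c)
        return best_lp, best_c

    solutions = []  # (logP, shared assignment dict)

    def dfs(i, assign, logp):
        if i == len(shared):
            solutions.append((logp, dict(assign)))
            return
        p = shared[i]
        done = {q: True for q in shared[: i + 1]}
        for g in domains[p]:
            assign[p] = g
            add = 0.0
            ok = True
            for f in active:
                if p in f.parents and all(
                    (q not in shared) or (q in done) for q in f.parents
                ):
                    lp, _ = fam_best(f, assign)
                    if not np.isfinite(lp):
                        ok = False
                        break
                    add += lp
            if ok:
                dfs(i + 1, assign, logp + add)
            del assign[p]

    dfs(0, {}, 0.0)
    if not solutions:
        # families mutually compatible per-parent but not jointly; demote all
        return GroupResolution({}, {}, {}, demoted + [f.name for f in active])
    best = max(lp for lp, _ in solutions)
    co = [a for lp, a in solutions if lp >= best - 1e-9]

    # pool each family's argmax candidates over all co-optimal solutions
    fam_co: dict[str, list[FSCandidate]] = {f.name: [] for f in active}
    for a in co:
        for f in active:
            for c in fam_best(f, a)[1]:
                if c not in fam_co[f.name]:
                    fam_co[f.name].append(c)

    parent_ghap = {}
    for p in sorted({q for f in active for q in f.parents}):
        vals = set()
        for f in active:
            if p in f.parents:
                for c in fam_co[f.name]:
                    if f.parent1 == p:
                        vals.add(c.ghap_p1)
                    if f.parent2 == p:
                        vals.add(c.ghap_p2)
        if len(vals) == 1:
            parent_ghap[p] = next(iter(vals))
    family_candidate = {
        f.name: (fam_co[f.name][0] if len(fam_co[f.name]) == 1 else None)
        for f in active
    }
    return GroupResolution(parent_ghap, family_candidate, fam_co, demoted)


# ---------------------------------------------------------------------------
# offspring assignment and imputation


def _gmrk_to_ghaps(ghap_dist, nmrk):
    bits = (np.arange(2**nmrk)[:, None] >> np.arange(nmrk)) & 1
    out: dict[tuple, list] = {}
    for ghap in ghap_dist:
        g = tuple(int(x) for x in bits[list(ghap)].sum(axis=0))
        out.setdefault(g, []).append(ghap)
    return out


def offspring_assignments(
    fam: FSFamily,
    cand: FSCandidate,
    dosages: Mapping[str, np.ndarray],
    nmrk: int,
    alpha: float,
) -> dict[str, tuple[int, ...] | None]:
    """Assign fully genotyped offspring whose Gmrk maps to a unique Ghap."""
    ghap_dist = progeny_ghap_distribution(cand.ghap_p1, cand.ghap_p2, alpha=alpha)
    by_gmrk = _gmrk_to_ghaps(ghap_dist, nmrk)
    out: dict[str, tuple[int, ...] | None] = {}
    for o in fam.offspring:
        g = np.asarray(dosages[o])
        if np.any(g == MISSING):
            out[o] = None
            continue
        ghaps = by_gmrk.get(tuple(int(x) for x in g), [])
        out[o] = ghaps[0] if len(ghaps) == 1 else None
    return out


def impute_fs_indiv(
    g: np.ndarray, family_gmrks: Sequence[tuple[int, ...]]
) -> tuple[int, ...] | None:
    """Unique family-possible Gmrk compatible with the non-missing dosages."""
    g = np.asarray(g)
    obs = g != MISSING
    if not obs.any():
        return None
    matches = [G for G in family_gmrks if all(G[j] == g[j] for j in np.flatnonzero(obs))]
    return matches[0] if len(matches) == 1 else None


def impute_family(
    fam: FSFamily,
    cand: FSCandidate,
    dosages: Mapping[str, np.ndarray],
    nmrk: int,
    params: SegregationParams,
) -> dict[str, tuple[int, ...]]:
    """Impute offspring with missing dosages; accept or reject family-wise.

    Returns accepted ``{offspring: ghap}`` assignments (possibly empty).
    Acceptance requires the imputed fraction to stay below
    ``impute_max_frac`` of the family and the chi-squared P including the
    imputed offspring to stay above ``impute_p_ratio`` times the P without.
    """
    ghap_dist = progeny_ghap_distribution(cand.ghap_p1, cand.ghap_p2, alpha=params.alpha)
    by_gmrk = _gmrk_to_ghaps(ghap_dist, nmrk)
    family_gmrks = sorted(by_gmrk)
    full, missing = [], []
    for o in fam.offspring:
        if o not in dosages:
            continue
        g = np.asarray(dosages[o])
        (full if not np.any(g == MISSING) else missing).append(o)
    imputed: dict[str, tuple[int, ...]] = {}  # offspring -> imputed Gmrk
    for o in missing:
        gm = impute_fs_indiv(np.asarray(dosages[o]), family_gmrks)
        if gm is not None:
            imputed[o] = gm
    if not imputed:
        return {}
    if len(imputed) >= params.impute_max_frac * len(fam.offspring):
        return {}
    n0 = len(full)
    if n0 == 0:
        return {}
    obs0 = Counter(tuple(int(x) for x in np.asarray(dosages[o])) for o in full)
    obs1 = obs0.copy()
    obs1.update(imputed.values())
    n1 = n0 + len(imputed)
    exp0 = _truncated_expected(cand.expected_gmrk, params.epsilon, len(cand.ghap_p1), n0)
    exp1 = _truncated_expected(cand.expected_gmrk, params.epsilon, len(cand.ghap_p1), n1)
    p0 = fs_segregation_pvalue(obs0, exp0, n0)
    p1 = fs_segregation_pvalue(obs1, exp1, n1)
    if p1 <= params.impute_p_ratio * p0:
        return {}
    out = {}
    for o, gm in imputed.items():
        ghaps = by_gmrk[gm]
        if len(ghaps) == 1:
            out[o] = ghaps[0]
    return out
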