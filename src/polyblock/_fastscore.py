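"""JIT-compiled inner loop of the family-segregation scorer.

Scores every candidate parental pair of one full-sib family: builds the
progeny genotype-class distribution from the two gamete distributions
(mixed-radix dosage indices add without carries), applies the dosage-error
channel to every class that could reach one expected individual, and returns
the Pearson statistic and degrees of freedom per pair.  Semantics mirror
``fs._PairScorer.stat_df`` exactly; that pure-numpy implementation is the
reference the unit tests compare against.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def score_pairs(
    i1, p1, k1, i2, p2, k2, obs_idx, obs_cnt, decode, radix, T, n, eps, ploidy, use_eps2, selfing
):  # pragma: no cover - exercised via solve_one_fs
    s1 = i1.shape[0]
    s2 = i2.shape[0]
    nmrk = decode.shape[1]
    kmax1 = i1.shape[1]
    kmax2 = i2.shape[1]
    maxm = kmax1 * kmax2
    space = decode.shape[0]
    npairs = s1 if selfing else s1 * s2

    stats = np.empty(npairs)
    dfs = np.ones(npairs, dtype=np.int64)
    idxbuf = np.empty(maxm, dtype=np.int64)
    wbuf = np.empty(maxm)
    classes = np.empty(maxm, dtype=np.int64)
    probs = np.empty(maxm)
    leak = np.empty(maxm)
    cand = np.empty(maxm * (2 * nmrk + 1), dtype=np.int64)
    expv = np.empty(maxm * (2 * nmrk + 1))
    dense = np.zeros(space)
    eps2 = eps * eps if use_eps2 else 0.0

    for a in range(s1):
        brange = 1 if selfing else s2
        for bb in range(brange):
            b = a if selfing else bb
            pid = a if selfing else a * s2 + bb
            # progeny class distribution = outer sum of the gamete dists
            cnt = 0
            for x in range(k1[a]):
                for y in range(k2[b]):
                    idxbuf[cnt] = i1[a, x] + i2[b, y]
                    wbuf[cnt] = p1[a, x] * p2[b, y]
                    cnt += 1
            order = np.argsort(idxbuf[:cnt])
            m = 0
            prev = np.int64(-1)
            for t in range(cnt):
                o = order[t]
                ci = idxbuf[o]
                if ci != prev:
                    classes[m] = ci
                    probs[m] = wbuf[o]
                    m += 1
                    prev = ci
                else:
                    probs[m - 1] += wbuf[o]

            # candidate retained classes and their exact expected probs
            if eps == 0.0:
                mc = m
                for t in range(m):
                    cand[t] = classes[t]
                    expv[t] = n * probs[t]
            else:
                for t in range(m):
                    dense[classes[t]] = probs[t]
                for t in range(m):
                    acc = 0.0
                    ci = classes[t]
                    for j in range(nmrk):
                        d = decode[ci, j]
                        if d > 0:
                            acc += dense[ci - radix[j]]
                        if d < ploidy:
                            acc += dense[ci + radix[j]]
                    leak[t] = acc
                for t in range(m):
                    dense[classes[t]] = 0.0
                mc = 0
                for t in range(m):
                    ub = n * (probs[t] + eps * leak[t] + eps2)
                    if ub >= 1.0:
                        cand[mc] = classes[t]
                        mc += 1
                # unobserved neighbours of classes massive enough to push
                # one error step over 1 expected individual
                for t in range(m):
                    if probs[t] * n * eps >= 0.25:
                        ci = classes[t]
                        for j in range(nmrk):
                            d = decode[ci, j]
                            if d > 0:
                                cand[mc] = ci - radix[j]
                                mc += 1
                            if d < ploidy:
                                cand[mc] = ci + radix[j]
                                mc += 1
                if mc > 1:
                    sub = np.sort(cand[:mc])
                    mu = 0
                    prev = np.int64(-1)
                    for t in range(mc):
                        if sub[t] != prev:
                            sub[mu] = sub[t]
                            mu += 1
                            prev = sub[t]
                    for t in range(mu):
                        cand[t] = sub[t]
                    mc = mu
                # exact expected probability of each candidate
                for u in range(mc):
                    e = 0.0
                    cu = cand[u]
                    for t in range(m):
                        ct = classes[t]
                        w = probs[t]
                        for j in range(nmrk):
                            w *= T[decode[ct, j], decode[cu, j]]
                        e += w
                    expv[u] = n * e

            # Pearson statistic over retained classes + pooled category
            stat = 0.0
            ncat = 0
            exp_sum = 0.0
            obs_sum = 0.0
            op = 0
            nobs = obs_idx.shape[0]
            for u in range(mc):
                if expv[u] < 1.0:
                    continue
                while op < nobs and obs_idx[op] < cand[u]:
                    op += 1
                oc = 0.0
                if op < nobs and obs_idx[op] == cand[u]:
                    oc = obs_cnt[op]
                d = oc - expv[u]
                stat += d * d / expv[u]
                ncat += 1
                exp_sum += expv[u]
                obs_sum += oc
            exp_pool = n - exp_sum
            obs_pool = n - obs_sum
            if exp_pool > 1e-9:
                d = obs_pool - exp_pool
                stat += d * d / exp_pool
                ncat += 1
            elif obs_pool > 0.5:
                stats[pid] = np.inf
                dfs[pid] = 1
                continue
            stats[pid] = stat
            dfs[pid] = max(ncat - 1, 1)
    return stats, dfs
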