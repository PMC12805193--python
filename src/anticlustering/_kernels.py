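"""Numba inner loops for the pairwise-interchange searches.

The kernels maintain, incrementally, the per-group diversity sums and a
nearest-within-group-neighbor structure (value, argmin and runner-up per
object) so that evaluating one candidate swap costs O(N) and a full
best-improvement pass costs O(N^2 * N / K). Everything is deterministic;
all randomness (initial partitions, perturbation coin flips, weight draws)
is supplied by the caller.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# record buffer overflow signal
OVERFLOW = -2


@njit(cache=True)
def _refresh_nw(Ddisp, assign, v, nw1, nw2, nwa):
    N = assign.shape[0]
    a = assign[v]
    m1 = np.inf
    m2 = np.inf
    arg = -1
    for u in range(N):
        if u != v and assign[u] == a:
            d = Ddisp[v, u]
            if d < m1:
                m2 = m1
                m1 = d
                arg = u
            elif d < m2:
                m2 = d
    nw1[v] = m1
    nw2[v] = m2
    nwa[v] = arg


@njit(cache=True)
def _cluster_min(nw1, assign, k):
    m = np.inf
    for v in range(assign.shape[0]):
        if assign[v] == k and nw1[v] < m:
            m = nw1[v]
    return m


@njit(cache=True)
def bpi_kernel(Ddiv, Ddisp, assign, K, w, use_avg, rec_i, rec_j, rec_div, rec_disp):
    """Best-improvement pairwise-interchange search on the weighted criterion.

    Mutates ``assign`` to the local optimum. Records every realized
    exchange (focal i, partner j) together with the criterion values after
    the exchange. Returns the number of records, or OVERFLOW if the buffers
    are too small.
    """
    N = assign.shape[0]
    max_rec = rec_i.shape[0]
    sizes = np.zeros(K, dtype=np.int64)
    for v in range(N):
        sizes[assign[v]] += 1
    s = np.zeros(K)
    for i in range(N):
        for j in range(i + 1, N):
            if assign[i] == assign[j]:
                s[assign[i]] += Ddiv[i, j]
    nw1 = np.empty(N)
    nw2 = np.empty(N)
    nwa = np.empty(N, dtype=np.int64)
    for v in range(N):
        _refresh_nw(Ddisp, assign, v, nw1, nw2, nwa)
    cmin = np.empty(K)
    for k in range(K):
        cmin[k] = _cluster_min(nw1, assign, k)
    # member lists per cluster for O(n_a + n_b) candidate evaluation
    members = np.empty((K, N), dtype=np.int64)
    count = np.zeros(K, dtype=np.int64)
    for v in range(N):
        k = assign[v]
        members[k, count[k]] = v
        count[k] += 1

    nrec = 0
    for _pass in range(100000):
        any_improve = False
        for i in range(N):
            a = assign[i]
            cur_div = 0.0
            for k in range(K):
                if use_avg:
                    cur_div += s[k] / sizes[k]
                else:
                    cur_div += s[k]
            cur_disp = np.inf
            for k in range(K):
                if cmin[k] < cur_disp:
                    cur_disp = cmin[k]
            cur_obj = w * cur_div
            if w < 1.0 and np.isfinite(cur_disp):
                cur_obj += (1.0 - w) * cur_disp
            tol = 1e-9 * (1.0 + abs(cur_obj))
            # diversity sums of i against every cluster
            dsum_i = np.zeros(K)
            for v in range(N):
                dsum_i[assign[v]] += Ddiv[i, v]
            best_gain = tol
            best_j = -1
            best_da = 0.0
            best_db = 0.0
            best_div = 0.0
            best_disp = 0.0
            for j in range(N):
                b = assign[j]
                if b == a:
                    continue
                sum_j_a = 0.0  # sum of Ddiv[j, v] over v in a, v != i
                sum_j_b = 0.0  # sum of Ddiv[j, v] over v in b, v != j
                m = np.inf
                for t in range(count[a]):
                    v = members[a, t]
                    if v == i:
                        continue
                    sum_j_a += Ddiv[j, v]
                    base = nw1[v]
                    if nwa[v] == i:
                        base = nw2[v]
                    if base < m:
                        m = base
                    d2 = Ddisp[v, j]
                    if d2 < m:
                        m = d2
                for t in range(count[b]):
                    v = members[b, t]
                    if v == j:
                        continue
                    sum_j_b += Ddiv[j, v]
                    base = nw1[v]
                    if nwa[v] == j:
                        base = nw2[v]
                    if base < m:
                        m = base
                    d2 = Ddisp[v, i]
                    if d2 < m:
                        m = d2
                for k in range(K):
                    if k != a and k != b and cmin[k] < m:
                        m = cmin[k]
                ddiv_a = sum_j_a - dsum_i[a]
                ddiv_b = (dsum_i[b] - Ddiv[i, j]) - sum_j_b
                if use_avg:
                    new_div = cur_div + ddiv_a / sizes[a] + ddiv_b / sizes[b]
                else:
                    new_div = cur_div + ddiv_a + ddiv_b
                new_obj = w * new_div
                if w < 1.0 and np.isfinite(m):
                    new_obj += (1.0 - w) * m
                gain = new_obj - cur_obj
                if gain > best_gain:
                    best_gain = gain
                    best_j = j
                    best_da = ddiv_a
                    best_db = ddiv_b
                    best_div = new_div
                    best_disp = m
            if best_j >= 0:
                j = best_j
                b = assign[j]
                s[a] += best_da
                s[b] += best_db
                assign[i] = b
                assign[j] = a
                for t in range(count[a]):
                    if members[a, t] == i:
                        members[a, t] = j
                        break
                for t in range(count[b]):
                    if members[b, t] == j:
                        members[b, t] = i
                        break
                for t in range(count[a]):
                    _refresh_nw(Ddisp, assign, members[a, t], nw1, nw2, nwa)
                for t in range(count[b]):
                    _refresh_nw(Ddisp, assign, members[b, t], nw1, nw2, nwa)
                cmin[a] = _cluster_min(nw1, assign, a)
                cmin[b] = _cluster_min(nw1, assign, b)
                if nrec >= max_rec:
                    return OVERFLOW
                rec_i[nrec] = i
                rec_j[nrec] = j
                rec_div[nrec] = best_div
                rec_disp[nrec] = best_disp
                nrec += 1
                any_improve = True
        if not any_improve:
            break
    return nrec


@njit(cache=True)
def perturb_kernel(assign, uniforms, p):
    """Swap each unordered pair (in lexicographic order) with probability p.

    Only pairs currently in different groups are eligible; one pre-drawn
    uniform is consumed per pair regardless of eligibility so the stream
    alignment does not depend on the evolving partition.
    """
    N = assign.shape[0]
    t = 0
    for i in range(N):
        for j in range(i + 1, N):
            u = uniforms[t]
            t += 1
            if assign[i] != assign[j] and u < p:
                tmp = assign[i]
                assign[i] = assign[j]
                assign[j] = tmp
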