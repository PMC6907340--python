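"""Numba kernels for relationship computations on genetic recursion graphs.

A graph node ``i`` obeys ``a_i = sum_p b_ip a_p + e_i`` with independent
residuals, ``Var(e_i) = v_i`` (in units of the base additive covariance), and
parents strictly preceding children in id order.  The relationship matrix is
``A = (I - B)^-1 D (I - B)^-T``; entries for a small set of nodes are obtained
by back-substitution over their ancestor set (the generalized Meuwissen-Luo
scheme), which costs O(#ancestors) per query instead of O(n^2).
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _gather(indptr, parents, roots, mark, stamp, stack, anc):
    """Collect the ancestor closure of ``roots`` (roots included). Returns count."""
    m = 0
    sp = 0
    for ri in range(roots.size):
        r = roots[ri]
        if mark[r] != stamp:
            mark[r] = stamp
            stack[sp] = r
            sp += 1
            anc[m] = r
            m += 1
    while sp > 0:
        sp -= 1
        j = stack[sp]
        for k in range(indptr[j], indptr[j + 1]):
            p = parents[k]
            if mark[p] != stamp:
                mark[p] = stamp
                stack[sp] = p
                sp += 1
                anc[m] = p
                m += 1
    return m


@njit(cache=True)
def a_self_many(indptr, parents, coefs, v, nodes, mark, stamp0, stack, anc, x):
    """Diagonal relationship entries A_ii for each node in ``nodes``."""
    out = np.empty(nodes.size)
    stamp = stamp0
    root = np.empty(1, dtype=np.int64)
    for idx in range(nodes.size):
        stamp += 1
        root[0] = nodes[idx]
        m = _gather(indptr, parents, root, mark, stamp, stack, anc)
        sub = np.sort(anc[:m])[::-1]
        x[root[0]] = 1.0
        acc = 0.0
        for t in range(m):
            j = sub[t]
            xj = x[j]
            if xj != 0.0:
                for k in range(indptr[j], indptr[j + 1]):
                    x[parents[k]] += coefs[k] * xj
                acc += v[j] * xj * xj
        for t in range(m):
            x[sub[t]] = 0.0
        out[idx] = acc
    return out, stamp


@njit(cache=True)
def a_cross(indptr, parents, coefs, v, roots, mark, stamp, stack, anc, pos):
    """Dense relationship block A[roots, roots] (roots must be distinct)."""
    k = roots.size
    m = _gather(indptr, parents, roots, mark, stamp, stack, anc)
    sub = np.sort(anc[:m])[::-1]
    for t in range(m):
        pos[sub[t]] = t
    x = np.zeros((m, k))
    for c in range(k):
        x[pos[roots[c]], c] = 1.0
    g = np.zeros((k, k))
    for t in range(m):
        j = sub[t]
        any_nz = False
        for c in range(k):
            if x[t, c] != 0.0:
                any_nz = True
                break
        if not any_nz:
            continue
        for kk in range(indptr[j], indptr[j + 1]):
            tp = pos[parents[kk]]
            w = coefs[kk]
            for c in range(k):
                x[tp, c] += w * x[t, c]
        vj = v[j]
        for a in range(k):
            xa = x[t, a]
            if xa == 0.0:
                continue
            for b in range(a, k):
                g[a, b] += vj * xa * x[t, b]
    for a in range(k):
        for b in range(a):
            g[a, b] = g[b, a]
    return g


@njit(cache=True)
def gene_drop_full(kinds, dam, sire, n_reps, seed):
    """Gene-drop IBD sampling on a full haplodiploid pedigree.

    kinds: 0 = base queen, 1 = queen (dam + father drone), 2 = drone of dam,
    3 = base drone.  Returns allele label arrays a1, a2 of shape (n, n_reps);
    drones carry their single allele in both slots.
    """
    n = kinds.size
    a1 = np.empty((n, n_reps), dtype=np.int64)
    a2 = np.empty((n, n_reps), dtype=np.int64)
    np.random.seed(seed)
    for i in range(n):
        k = kinds[i]
        if k == 0:  # base queen: two founder alleles
            for r in range(n_reps):
                a1[i, r] = 2 * i
                a2[i, r] = 2 * i + 1
        elif k == 3:  # base drone: one founder allele
            for r in range(n_reps):
                a1[i, r] = 2 * i
                a2[i, r] = 2 * i
        elif k == 2:  # drone: one random maternal gamete
            d = dam[i]
            for r in range(n_reps):
                g = a1[d, r] if np.random.random() < 0.5 else a2[d, r]
                a1[i, r] = g
                a2[i, r] = g
        else:  # queen: maternal gamete + the father drone's allele
            d = dam[i]
            s = sire[i]
            for r in range(n_reps):
                a1[i, r] = a1[d, r] if np.random.random() < 0.5 else a2[d, r]
                a2[i, r] = a1[s, r]
    return a1, a2
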