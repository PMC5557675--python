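"""Affine-gap dynamic-programming kernels (Gotoh recurrences), numba-compiled.

Both kernels take a precomputed position-by-position score matrix ``M`` so
the same code serves profile-vs-sequence (search) and profile-vs-profile
(progressive alignment).  A gap of length k costs ``go + (k-1)*ge``.
"""

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=True)
def local_affine(M, go, ge):
    """Best local alignment over score matrix M (Lp x Lt).

    Returns (score, i0, i1, j0, j1): 0-based inclusive spans on the
    profile (i) and target (j) axes.  Empty alignment scores 0 and
    returns spans (-1, -1, -1, -1).
    """
    n, m = M.shape
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    best = 0.0
    bi = -1
    bj = -1
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - go
            if E[i, j - 1] - ge > e:
                e = E[i, j - 1] - ge
            E[i, j] = e
            f = H[i - 1, j] - go
            if F[i - 1, j] - ge > f:
                f = F[i - 1, j] - ge
            F[i, j] = f
            h = H[i - 1, j - 1] + M[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if bi < 0:
        return 0.0, -1, -1, -1, -1
    # traceback to the zero-scoring cell where the local path starts
    i = bi
    j = bj
    state = 0  # 0=H, 1=E (gap in profile), 2=F (gap in target)
    while True:
        if state == 0:
            if H[i, j] <= 0.0:
                break
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + M[i - 1, j - 1]:
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            if H[i, j - 1] - go >= E[i, j - 1] - ge:
                state = 0
            j -= 1
        else:
            if H[i - 1, j] - go >= F[i - 1, j] - ge:
                state = 0
            i -= 1
    return best, i, bi - 1, j, bj - 1


@njit(cache=True)
def global_affine(M, go, ge):
    """Global alignment over score matrix M (La x Lb) with affine end gaps.

    Returns (score, ops) where ops is an int8 array over the alignment
    columns read left to right: 0 = match column, 1 = gap inserted in A
    (consumes a B position), 2 = gap inserted in B (consumes an A
    position).  Ties prefer match > gap-in-A > gap-in-B.
    """
    n, m = M.shape
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = -(go + (j - 1) * ge)
        H[0, j] = E[0, j]
    for i in range(1, n + 1):
        F[i, 0] = -(go + (i - 1) * ge)
        H[i, 0] = F[i, 0]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - go
            if E[i, j - 1] - ge > e:
                e = E[i, j - 1] - ge
            E[i, j] = e
            f = H[i - 1, j] - go
            if F[i - 1, j] - ge > f:
                f = F[i - 1, j] - ge
            F[i, j] = f
            h = H[i - 1, j - 1] + M[i - 1, j - 1]
            if e > h:
                h = e
            if f > h:
                h = f
            H[i, j] = h
    ops = np.empty(n + m, dtype=np.int8)
    k = n + m
    i = n
    j = m
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + M[i - 1, j - 1]:
                k -= 1
                ops[k] = 0
                i -= 1
                j -= 1
            elif j > 0 and H[i, j] == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            k -= 1
            ops[k] = 1
            if H[i, j - 1] - go >= E[i, j - 1] - ge:
                state = 0
            j -= 1
        else:
            k -= 1
            ops[k] = 2
            if H[i - 1, j] - go >= F[i - 1, j] - ge:
                state = 0
            i -= 1
    return H[n, m], ops[k:]
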