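"""Numba-compiled inner loops of the multilinear sieve.

The hot path evaluates the restless-walk dynamic program once per label
subset (lane) in Gray-code order, XOR-accumulating each lane's top-level
table into the sieve value.  Field arithmetic is schoolbook shift-XOR with
interleaved modular reduction, entirely in uint64; all randomness enters
through precomputed tables, so the kernel is bit-deterministic.
"""

from __future__ import annotations

import numpy as np
from numba import njit, uint64

__all__ = ["sieve_zeta_kernel"]


@njit(cache=True, inline="always")
def _gf_mul(a, c, mod_low, mask, high_bit):
    r = uint64(0)
    one = uint64(1)
    while c:
        if c & one:
            r ^= a
        c >>= one
        carry = a & high_bit
        a = (a << one) & mask
        if carry:
            a ^= mod_low
    return r


@njit(cache=True)
def sieve_zeta_kernel(n, tau, ell, esrc, edst, etime, delta, z, ytab, mod_low, mask, high_bit):
    """XOR over all non-empty label subsets of the level-``ell`` walk table.

    Parameters: edge arrays (int64, 1-based vertices), per-vertex resting
    times ``delta`` (int64, index 0 unused), lane substitution base ``z``
    of shape (n+1, ell) and y-table of shape (ell-1 or 1, m, Delta+1) where
    ``ytab[level-2, e, j]`` is the y-value for edge ``e`` at level-1 index
    ``level-1`` and arrival time ``etime[e] - j``.  Returns the sieve value
    per (time, vertex) cell, shape (tau+1, n+1); row/column 0 unused.
    """
    m = esrc.shape[0]
    zeta = np.zeros((tau + 1, n + 1), dtype=np.uint64)
    zL = np.zeros(n + 1, dtype=np.uint64)
    prev = np.zeros((tau + 1, n + 1), dtype=np.uint64)
    cur = np.zeros((tau + 1, n + 1), dtype=np.uint64)
    total = 1 << ell
    for g in range(1, total):
        # Gray-code step: flip the label indexed by the trailing zeros of g.
        gg = g
        j = 0
        while gg & 1 == 0:
            gg >>= 1
            j += 1
        for u in range(1, n + 1):
            zL[u] ^= z[u, j]
        # level 1: every cell holds the lane substitution of its vertex
        for i in range(1, tau + 1):
            for u in range(1, n + 1):
                prev[i, u] = zL[u]
        for level in range(2, ell + 1):
            for i in range(tau + 1):
                for u in range(n + 1):
                    cur[i, u] = uint64(0)
            for e in range(m):
                t = etime[e]
                if t > tau:
                    continue
                v = esrc[e]
                u = edst[e]
                acc = uint64(0)
                for jj in range(delta[v] + 1):
                    tp = t - jj
                    if tp < 1:
                        break
                    acc ^= _gf_mul(ytab[level - 2, e, jj], prev[tp, v], mod_low, mask, high_bit)
                cur[t, u] ^= _gf_mul(zL[u], acc, mod_low, mask, high_bit)
            tmp = prev
            prev = cur
            cur = tmp
        for i in range(1, tau + 1):
            for u in range(1, n + 1):
                zeta[i, u] ^= prev[i, u]
    return zeta
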