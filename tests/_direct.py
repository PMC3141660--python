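"""Direct-summation references for the per-edge-pair counting formulas.

Two independent implementations of the literal quadruple sums, with no
algebraic rewriting:

* pure-Python nested loops (slow, transparent) — the bedrock oracle;
* an einsum over explicit index-exclusion masks (fast enough for thousands
  of matrices), itself validated against the loops in the test suite.
"""

from __future__ import annotations

import numpy as np


def inner_sum_loops(I, i, k, j, l) -> int:
    d, dp = I.shape
    return int(
        sum(
            I[m, n]
            for m in range(d)
            if m not in (i, k)
            for n in range(dp)
            if n not in (j, l)
        )
    )


def shared_direct_loops(I, i, j) -> int:
    I = np.asarray(I, dtype=np.int64)
    d, dp = I.shape
    S = 0
    for k in range(d):
        if k == i:
            continue
        for l in range(dp):
            if l == j:
                continue
            S += int(I[k, l]) * inner_sum_loops(I, i, k, j, l)
    assert S % 2 == 0
    e = int(I[i, j])
    return (e * (e - 1) // 2) * (S // 2)


def diff_direct_loops(I, i, j) -> int:
    I = np.asarray(I, dtype=np.int64)
    d, dp = I.shape
    tot = 0
    for k in range(d):
        if k == i:
            continue
        for l in range(dp):
            if l == j:
                continue
            tot += int(I[i, l]) * int(I[k, j]) * inner_sum_loops(I, i, k, j, l)
    return int(I[i, j]) * tot


def edge_pair_counts_direct(I):
    """(shared, diff) direct-sum matrices over every behind-index pair (i, j)."""
    I = np.asarray(I, dtype=np.int64)
    d, dp = I.shape
    K = ~np.eye(d, dtype=bool)   # K[i, k] = (k != i)
    L = ~np.eye(dp, dtype=bool)
    A = (K[:, None, :] & K[None, :, :]).astype(np.int64)  # A[i,k,m] = m∉{i,k}
    B = (L[:, None, :] & L[None, :, :]).astype(np.int64)
    T4 = np.einsum("ikm,jln,mn->ijkl", A, B, I)           # inner sums
    Ki = K.astype(np.int64)
    Li = L.astype(np.int64)
    S = np.einsum("ijkl,kl,ik,jl->ij", T4, I, Ki, Li)
    assert not (S & 1).any()
    shared = (I * (I - 1) // 2) * (S >> 1)
    dsum = np.einsum("ijkl,il,kj,ik,jl->ij", T4, I, I, Ki, Li)
    return shared, I * dsum
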