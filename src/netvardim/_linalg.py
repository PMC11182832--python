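"""Exact rank computations: rationals (Fractions) and prime fields (numpy).

Floating point is never used for rank decisions.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

DEFAULT_PRIME = 2_147_483_647  # 2^31 - 1


def rank_exact_rationals(rows) -> int:
    """Rank of a matrix with int/Fraction entries by Gaussian elimination."""
    mat = [[Fraction(x) for x in row] for row in rows]
    if not mat or not mat[0]:
        return 0
    n_rows, n_cols = len(mat), len(mat[0])
    rank = 0
    for col in range(n_cols):
        pivot = None
        for r in range(rank, n_rows):
            if mat[r][col] != 0:
                pivot = r
                break
        if pivot is None:
            continue
        mat[rank], mat[pivot] = mat[pivot], mat[rank]
        pv = mat[rank][col]
        prow = mat[rank]
        for r in range(rank + 1, n_rows):
            factor = mat[r][col]
            if factor == 0:
                continue
            ratio = factor / pv
            row = mat[r]
            for c in range(col, n_cols):
                row[c] -= ratio * prow[c]
        rank += 1
        if rank == n_rows:
            break
    return rank


def rank_mod_p(matrix, p: int = DEFAULT_PRIME) -> int:
    """Rank over F_p; entries reduced mod p.  Products of two reduced
    entries fit in int64 for p < 2^31."""
    a = np.asarray(matrix, dtype=np.int64) % p
    if a.size == 0:
        return 0
    n_rows, n_cols = a.shape
    rank = 0
    for col in range(n_cols):
        nz = np.nonzero(a[rank:, col])[0]
        if nz.size == 0:
            continue
        piv = rank + int(nz[0])
        if piv != rank:
            a[[rank, piv]] = a[[piv, rank]]
        inv = pow(int(a[rank, col]), p - 2, p)
        a[rank] = (a[rank] * inv) % p
        below = a[rank + 1 :, col]
        mask = below != 0
        if mask.any():
            a[rank + 1 :][mask] = (
                a[rank + 1 :][mask] - below[mask, None] * a[rank][None, :]
            ) % p
        rank += 1
        if rank == n_rows:
            break
    return rank
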