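"""Packed storage for symmetric rank-2 and rank-3 tensors.

The expansion state stores covariance-like blocks in a packed vector using
lexicographic index order (i <= j for rank 2, i <= k <= l for rank 3).
This packing is part of the public contract: it is what makes a reduced
9-species model assemble exactly 273 simultaneous equations.
"""

from __future__ import annotations

import numpy as np


def sym2_size(n: int) -> int:
    return n * (n + 1) // 2


def sym3_size(n: int) -> int:
    return n * (n + 1) * (n + 2) // 6


def sym2_indices(n: int) -> list[tuple[int, int]]:
    """Lexicographic (i, j) with i <= j."""
    return [(i, j) for i in range(n) for j in range(i, n)]


def sym3_indices(n: int) -> list[tuple[int, int, int]]:
    """Lexicographic (i, k, l) with i <= k <= l."""
    return [(i, k, l) for i in range(n) for k in range(i, n) for l in range(k, n)]


def pack_sym2(M: np.ndarray) -> np.ndarray:
    n = M.shape[0]
    return np.array([M[i, j] for i, j in sym2_indices(n)])


def unpack_sym2(v: np.ndarray, n: int) -> np.ndarray:
    M = np.zeros((n, n))
    for val, (i, j) in zip(v, sym2_indices(n)):
        M[i, j] = val
        M[j, i] = val
    return M


def pack_sym3(T: np.ndarray) -> np.ndarray:
    n = T.shape[0]
    return np.array([T[i, k, l] for i, k, l in sym3_indices(n)])


def unpack_sym3(v: np.ndarray, n: int) -> np.ndarray:
    T = np.zeros((n, n, n))
    for val, (i, k, l) in zip(v, sym3_indices(n)):
        for a, b, c in {(i, k, l), (i, l, k), (k, i, l), (k, l, i), (l, i, k), (l, k, i)}:
            T[a, b, c] = val
    return T
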