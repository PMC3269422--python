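"""Dynamic-time-warping core (numba-compiled dynamic program)."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def dtw_path(cost):  # pragma: no cover - exercised through dtw_align
    """Minimum-cost monotone alignment path through a cost matrix.

    Symmetric step pattern (diagonal, horizontal, vertical), no band
    constraint. Ties during backtracking prefer the diagonal step. Returns
    the path as two index arrays from (0, 0) to (m-1, n-1).
    """
    m, n = cost.shape
    D = np.empty((m + 1, n + 1))
    D[:] = np.inf
    D[0, 0] = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = cost[i - 1, j - 1] + best

    max_len = m + n
    pi = np.empty(max_len, dtype=np.int64)
    pj = np.empty(max_len, dtype=np.int64)
    i, j = m, n
    k = max_len
    while i > 0 and j > 0:
        k -= 1
        pi[k] = i - 1
        pj[k] = j - 1
        diag = D[i - 1, j - 1]
        up = D[i - 1, j]
        left = D[i, j - 1]
        if diag <= up and diag <= left:
            i -= 1
            j -= 1
        elif up <= left:
            i -= 1
        else:
            j -= 1
    return pi[k:], pj[k:], D[m, n]


def dtw_align(cost: np.ndarray):
    """Python entry point; ensures a float64 contiguous cost matrix."""
    cost = np.ascontiguousarray(cost, dtype=np.float64)
    pi, pj, total = dtw_path(cost)
    return pi, pj, float(total)
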