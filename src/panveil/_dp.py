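"""Affine-gap Needleman–Wunsch dynamic programming kernel.

Operates on a precomputed column-pair score matrix so the same kernel
serves letter–letter alignment (guide-tree distances) and profile–profile
alignment (progressive merging).  Gotoh three-state recursion with full
traceback; gap states do not chain into each other directly.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30


@njit(cache=True)
def nw_affine(S, gap_open, gap_extend):  # pragma: no cover - exercised via wrappers
    """Global alignment over score matrix S (L1 x L2).

    Returns (score, ai, aj): aligned index vectors into the two inputs,
    -1 marking a gap in the corresponding input.
    """
    L1, L2 = S.shape
    M = np.full((L1 + 1, L2 + 1), NEG)
    Ix = np.full((L1 + 1, L2 + 1), NEG)  # gap in input 2 (consumes i)
    Iy = np.full((L1 + 1, L2 + 1), NEG)  # gap in input 1 (consumes j)
    tM = np.zeros((L1 + 1, L2 + 1), dtype=np.int8)
    tX = np.zeros((L1 + 1, L2 + 1), dtype=np.int8)
    tY = np.zeros((L1 + 1, L2 + 1), dtype=np.int8)

    M[0, 0] = 0.0
    for i in range(1, L1 + 1):
        Ix[i, 0] = -gap_open - (i - 1) * gap_extend
        tX[i, 0] = 1 if i > 1 else 0
    for j in range(1, L2 + 1):
        Iy[0, j] = -gap_open - (j - 1) * gap_extend
        tY[0, j] = 1 if j > 1 else 0

    for i in range(1, L1 + 1):
        for j in range(1, L2 + 1):
            # gap states: open from M or extend
            o = M[i - 1, j] - gap_open
            e = Ix[i - 1, j] - gap_extend
            if o >= e:
                Ix[i, j] = o
                tX[i, j] = 0
            else:
                Ix[i, j] = e
                tX[i, j] = 1
            o = M[i, j - 1] - gap_open
            e = Iy[i, j - 1] - gap_extend
            if o >= e:
                Iy[i, j] = o
                tY[i, j] = 0
            else:
                Iy[i, j] = e
                tY[i, j] = 1
            # match state
            best = M[i - 1, j - 1]
            src = 0
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                src = 1
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                src = 2
            M[i, j] = best + S[i - 1, j - 1]
            tM[i, j] = src

    # terminal state
    state = 0
    score = M[L1, L2]
    if Ix[L1, L2] > score:
        score = Ix[L1, L2]
        state = 1
    if Iy[L1, L2] > score:
        score = Iy[L1, L2]
        state = 2

    ai = np.empty(L1 + L2, dtype=np.int64)
    aj = np.empty(L1 + L2, dtype=np.int64)
    t = 0
    i, j = L1, L2
    while i > 0 or j > 0:
        if state == 0:
            src = tM[i, j]
            ai[t] = i - 1
            aj[t] = j - 1
            i -= 1
            j -= 1
            state = src
        elif state == 1:
            src = tX[i, j]
            ai[t] = i - 1
            aj[t] = -1
            i -= 1
            state = 0 if src == 0 else 1
        else:
            src = tY[i, j]
            ai[t] = -1
            aj[t] = j - 1
            j -= 1
            state = 0 if src == 0 else 2
        t += 1
    return score, ai[:t][::-1].copy(), aj[:t][::-1].copy()
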