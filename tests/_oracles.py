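"""Independent brute-force oracles for the alignment tests.

These enumerate every monotone alignment path explicitly and keep the best
score.  They share no code with the dynamic-programming aligners and are
exponential in matrix size, so they are only usable on tiny instances.
"""

from __future__ import annotations

import numpy as np


def brute_force_local(R: np.ndarray, indel: float) -> float:
    """Best local alignment score by enumerating every path from every start cell.

    A path starts at any lattice cell, takes diagonal (match, reward), down
    (gap, -indel) or right (gap, -indel) steps, and may stop anywhere; the
    empty alignment scores 0.
    """
    m, n = R.shape
    best = 0.0

    def extend(i: int, j: int, score: float) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < m and j < n:
            extend(i + 1, j + 1, score + R[i, j])
        if i < m:
            extend(i + 1, j, score - indel)
        if j < n:
            extend(i, j + 1, score - indel)

    for i0 in range(m + 1):
        for j0 in range(n + 1):
            extend(i0, j0, 0.0)
    return best


def brute_force_fitting(R: np.ndarray, indel: float) -> float:
    """Best fitting score: paths start at row 0 (any column), consume all rows.

    The motif (rows) must be aligned end to end; the candidate (columns) is
    free before the start column and after the end column.
    """
    m, n = R.shape
    best = -np.inf

    def extend(i: int, j: int, score: float) -> None:
        nonlocal best
        if i == m and score > best:
            best = score
        if i < m and j < n:
            extend(i + 1, j + 1, score + R[i, j])
        if i < m:
            extend(i + 1, j, score - indel)
        if j < n:
            extend(i, j + 1, score - indel)

    for j0 in range(n + 1):
        extend(0, j0, 0.0)
    return best
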