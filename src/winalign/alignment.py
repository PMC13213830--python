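"""Smith-Waterman-style local alignment and fitting alignment on reward matrices.

Both aligners run dynamic programming over a precomputed window-pair reward
matrix rather than a residue substitution table.  The local variant floors
scores at zero so the aligned region can start and end anywhere in either
protein; the fitting variant is global in the motif (rows) and local in the
candidate (columns), forcing the motif to be mapped end-to-end onto some
subsegment of the candidate.  Gap costs are linear: one fixed indel penalty
per gap step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .similarity import RewardMatrix

__all__ = [
    "AlignmentParams",
    "Step",
    "AlignmentResult",
    "smith_waterman_local",
    "fitting_align",
    "windows_to_residues",
    "score_from_path",
]

# Step operations over window indices:
#   "M"  match      - consumes window i of A and window j of B
#   "GB" gap in B   - consumes window i of A only
#   "GA" gap in A   - consumes window j of B only
Step = tuple[str, int | None, int | None]

_DIAG, _UP, _LEFT, _STOP = 1, 2, 3, 0


@dataclass(frozen=True)
class AlignmentParams:
    """Aligner configuration: per-gap indel penalty and alignment regime."""

    indel_penalty: float = 10.0
    mode: Literal["local", "fitting"] = "local"

    def __post_init__(self) -> None:
        if self.indel_penalty < 0:
            raise ValueError("indel penalty must be nonnegative")
        if self.mode not in ("local", "fitting"):
            raise ValueError(f"unknown alignment mode {self.mode!r}")


@dataclass
class AlignmentResult:
    """One best alignment: DP score, step path, window and residue intervals.

    Window intervals are 0-based inclusive over window start indices; residue
    intervals are 0-based inclusive and derive from the window intervals as
    ``[first_window, last_window + w - 1]``.  ``to_dict`` reports residue
    intervals 1-based for human-facing output.
    """

    score: float
    path: list[Step]
    mode: str
    w: int = 1
    ids: tuple[str, str] = ("A", "B")
    window_range_a: tuple[int, int] | None = None
    window_range_b: tuple[int, int] | None = None

    @property
    def residue_range_a(self) -> tuple[int, int] | None:
        if self.window_range_a is None:
            return None
        return windows_to_residues(self.window_range_a, self.w)

    @property
    def residue_range_b(self) -> tuple[int, int] | None:
        if self.window_range_b is None:
            return None
        return windows_to_residues(self.window_range_b, self.w)

    def cigar(self) -> str:
        """Run-length encoded step string (M = match, D = gap in B, I = gap in A)."""
        sym = {"M": "M", "GB": "D", "GA": "I"}
        out = []
        for op, _, _ in self.path:
            s = sym[op]
            if out and out[-1][1] == s:
                out[-1][0] += 1
            else:
                out.append([1, s])
        return "".join(f"{c}{s}" for c, s in out)

    def to_dict(self) -> dict:
        def one_based(iv):
            return None if iv is None else [iv[0] + 1, iv[1] + 1]

        return {
            "mode": self.mode,
            "score": round(float(self.score), 6),
            "window": self.w,
            "id_a": self.ids[0],
            "id_b": self.ids[1],
            "window_range_a": list(self.window_range_a) if self.window_range_a else None,
            "window_range_b": list(self.window_range_b) if self.window_range_b else None,
            "residue_range_a": one_based(self.residue_range_a),
            "residue_range_b": one_based(self.residue_range_b),
            "cigar": self.cigar(),
        }


def windows_to_residues(window_interval: tuple[int, int], w: int) -> tuple[int, int]:
    """Map an inclusive window-index interval to the residue interval it covers.

    A window starting at position ``p`` spans residues ``p .. p + w - 1``, so
    ``[first, last]`` covers residues ``[first, last + w - 1]``.
    """
    if w < 1:
        raise ValueError("window size must be >= 1")
    first, last = window_interval
    return (first, last + w - 1)


def score_from_path(path: list[Step], Rw: RewardMatrix, indel_penalty: float) -> float:
    """Recompute an alignment score from its step list (consistency check)."""
    total = 0.0
    for op, i, j in path:
        if op == "M":
            total += Rw.values[i, j]
        else:
            total -= indel_penalty
    return total


def _ranges_from_path(path: list[Step]) -> tuple[tuple[int, int] | None, tuple[int, int] | None]:
    rows = [i for op, i, _ in path if op in ("M", "GB")]
    cols = [j for op, _, j in path if op in ("M", "GA")]
    ra = (min(rows), max(rows)) if rows else None
    rb = (min(cols), max(cols)) if cols else None
    return ra, rb


def _traceback(ptr: np.ndarray, i: int, j: int, stop) -> list[Step]:
    steps: list[Step] = []
    while not stop(i, j):
        move = ptr[i, j]
        if move == _DIAG:
            steps.append(("M", i - 1, j - 1))
            i, j = i - 1, j - 1
        elif move == _UP:
            steps.append(("GB", i - 1, None))
            i -= 1
        elif move == _LEFT:
            steps.append(("GA", None, j - 1))
            j -= 1
        else:
            break
    steps.reverse()
    return steps


def smith_waterman_local(Rw: RewardMatrix, params: AlignmentParams = AlignmentParams()) -> AlignmentResult:
    """Best local alignment over the reward matrix.

    Recurrence, with reward cell ``(i-1, j-1)`` feeding frame cell ``(i, j)``::

        H[i, j] = max(0,
                      H[i-1, j-1] + R[i-1, j-1],
                      H[i-1, j]   - indel,
                      H[i, j-1]   - indel)

    boundary row and column are zero.  Score is the maximum over ``H``
    (argmax ties broken toward the smallest ``(i, j)``); traceback follows
    diagonal-then-up-then-left preference and stops at the first zero cell.
    A nonpositive-everywhere reward matrix yields score 0 and an empty path.
    """
    if params.mode != "local":
        raise ValueError("smith_waterman_local requires mode='local'")
    R = Rw.values
    m, n = R.shape
    g = params.indel_penalty
    H = np.zeros((m + 1, n + 1))
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)
    for i in range(1, m + 1):
        Hi, Hp, Ri = H[i], H[i - 1], R[i - 1]
        for j in range(1, n + 1):
            diag = Hp[j - 1] + Ri[j - 1]
            up = Hp[j] - g
            left = Hi[j - 1] - g
            best = diag
            move = _DIAG
            if up > best:
                best, move = up, _UP
            if left > best:
                best, move = left, _LEFT
            if best <= 0.0:
                best, move = 0.0, _STOP
            Hi[j] = best
            ptr[i, j] = move
    flat = int(np.argmax(H))  # C order = smallest (i, j) lexicographically
    bi, bj = divmod(flat, n + 1)
    score = float(H[bi, bj])
    if score <= 0.0:
        return AlignmentResult(score=0.0, path=[], mode="local", w=Rw.w, ids=Rw.ids)
    path = _traceback(ptr, bi, bj, stop=lambda i, j: H[i, j] <= 0.0)
    ra, rb = _ranges_from_path(path)
    return AlignmentResult(
        score=score, path=path, mode="local", w=Rw.w, ids=Rw.ids,
        window_range_a=ra, window_range_b=rb,
    )


def fitting_align(Rw: RewardMatrix, params: AlignmentParams = AlignmentParams(mode="fitting")) -> AlignmentResult:
    """Fit the motif (rows) end-to-end against a subsegment of the candidate (columns).

    Initialization ``H[0, j] = 0`` lets the alignment start anywhere in the
    candidate for free, while ``H[i, 0] = -i * indel`` charges the motif for
    skipping its own start; the recurrence is the local one without the zero
    floor.  The score is the maximum over the last motif row (ties toward the
    smallest column); traceback runs until motif row 0, so every motif window
    appears in the path as a match or a gap step.
    """
    if params.mode != "fitting":
        raise ValueError("fitting_align requires mode='fitting'")
    R = Rw.values
    m, n = R.shape
    g = params.indel_penalty
    if m > n:
        warnings.warn(
            f"motif has more windows ({m}) than candidate ({n}); "
            "the fit will necessarily contain gap steps",
            stacklevel=2,
        )
    H = np.zeros((m + 1, n + 1))
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)
    H[:, 0] = -g * np.arange(m + 1)
    ptr[1:, 0] = _UP
    for i in range(1, m + 1):
        Hi, Hp, Ri = H[i], H[i - 1], R[i - 1]
        for j in range(1, n + 1):
            diag = Hp[j - 1] + Ri[j - 1]
            up = Hp[j] - g
            left = Hi[j - 1] - g
            best = diag
            move = _DIAG
            if up > best:
                best, move = up, _UP
            if left > best:
                best, move = left, _LEFT
            Hi[j] = best
            ptr[i, j] = move
    bj = int(np.argmax(H[m]))  # first occurrence = smallest-column tie-break
    score = float(H[m, bj])
    path = _traceback(ptr, m, bj, stop=lambda i, j: i == 0)
    ra, rb = _ranges_from_path(path)
    return AlignmentResult(
        score=score, path=path, mode="fitting", w=Rw.w, ids=Rw.ids,
        window_range_a=ra, window_range_b=rb,
    )
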