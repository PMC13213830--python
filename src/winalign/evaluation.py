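"""Evaluation against ground-truth aligned regions and the hyperparameter grid.

Ground truth is a set of residue-index correspondences (i_A, i_B) — the
structurally aligned positions of a pair.  A predicted alignment path is
expanded to residue pairs through its windows, and precision / recall / F1
are computed at the residue-pair level, optionally with a Chebyshev slack.
The grid search enumerates sigmoid-transform settings (midpoint x sharpness
x scale) and re-aligns every pair under each, reusing the cosine matrix,
which is the only stage the transform does not touch.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import AlignmentParams, AlignmentResult, fitting_align, smith_waterman_local
from .embedding import EmbeddingMatrix, window_pool
from .similarity import SigmoidParams, build_reward_matrix, cosine_matrix

__all__ = [
    "GroundTruthAlignment",
    "GridSpec",
    "alignment_prf",
    "enumerate_grid",
    "grid_search",
    "read_ground_truth_tsv",
    "interval_jaccard",
]


@dataclass
class GroundTruthAlignment:
    """Known residue correspondences for one protein pair (0-based indices)."""

    pair_id: str
    pairs: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError(f"ground truth for {self.pair_id!r} is empty")

    @classmethod
    def from_intervals(
        cls,
        pair_id: str,
        interval_a: tuple[int, int],
        interval_b: tuple[int, int],
    ) -> "GroundTruthAlignment":
        """Expand co-linear, gapless interval pairs into residue correspondences."""
        la = interval_a[1] - interval_a[0]
        lb = interval_b[1] - interval_b[0]
        if la != lb:
            raise ValueError("interval-form truth requires equal-length intervals")
        pairs = [(interval_a[0] + t, interval_b[0] + t) for t in range(la + 1)]
        return cls(pair_id=pair_id, pairs=pairs)

    @property
    def interval_a(self) -> tuple[int, int]:
        xs = [a for a, _ in self.pairs]
        return (min(xs), max(xs))

    @property
    def interval_b(self) -> tuple[int, int]:
        ys = [b for _, b in self.pairs]
        return (min(ys), max(ys))


@dataclass(frozen=True)
class GridSpec:
    """Axes of the sigmoid-parameter grid search."""

    midpoints: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))
    sharpnesses: tuple[float, ...] = tuple(float(s) for s in range(1, 11))
    scales: tuple[float, ...] = tuple(float(s) for s in range(1, 11))

    def __post_init__(self) -> None:
        if not (self.midpoints and self.sharpnesses and self.scales):
            raise ValueError("every grid axis must be nonempty")

    def __len__(self) -> int:
        return len(self.midpoints) * len(self.sharpnesses) * len(self.scales)


def enumerate_grid(spec: GridSpec = GridSpec()) -> list[SigmoidParams]:
    """Cartesian product of the grid axes in row-major order (midpoint outermost)."""
    return [
        SigmoidParams(midpoint=m, sharpness=sh, scale=sc)
        for m, sh, sc in itertools.product(spec.midpoints, spec.sharpnesses, spec.scales)
    ]


def _predicted_residue_pairs(predicted: AlignmentResult) -> set[tuple[int, int]]:
    """Expand matched window pairs (i, j) to the residue pairs (i+t, j+t), t < w."""
    pairs = set()
    for op, i, j in predicted.path:
        if op == "M":
            for t in range(predicted.w):
                pairs.add((i + t, j + t))
    return pairs


def alignment_prf(
    predicted: AlignmentResult,
    truth: GroundTruthAlignment,
    slack: int = 0,
) -> tuple[float, float, float]:
    """Residue-pair precision, recall and F1 of a predicted alignment.

    A predicted pair counts as a true positive when it lies within Chebyshev
    distance ``slack`` of some not-yet-matched truth pair (each truth pair is
    matchable once).  ``slack=0`` reduces to exact set intersection.  An empty
    prediction scores (0, 0, 0).
    """
    if slack < 0:
        raise ValueError("slack must be nonnegative")
    pred = sorted(_predicted_residue_pairs(predicted))
    if not pred:
        return 0.0, 0.0, 0.0
    truth_pairs = truth.pairs
    if slack == 0:
        tp = len(set(pred) & set(truth_pairs))
    else:
        unused = list(truth_pairs)
        tp = 0
        for pa, pb in pred:
            for idx, (ta, tb) in enumerate(unused):
                if max(abs(pa - ta), abs(pb - tb)) <= slack:
                    tp += 1
                    unused.pop(idx)
                    break
    precision = tp / len(pred)
    recall = tp / len(truth_pairs)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def interval_jaccard(a: tuple[int, int] | None, b: tuple[int, int]) -> float:
    """Jaccard overlap of two inclusive residue intervals (0 if ``a`` is missing)."""
    if a is None:
        return 0.0
    lo = max(a[0], b[0])
    hi = min(a[1], b[1])
    inter = max(0, hi - lo + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union


def grid_search(
    pairs: Sequence[tuple[EmbeddingMatrix, EmbeddingMatrix, GroundTruthAlignment]],
    spec: GridSpec = GridSpec(),
    w: int = 3,
    indel_penalty: float = 10.0,
    mode: str = "local",
    slack: int = 0,
    rescale: bool = True,
) -> pd.DataFrame:
    """Align every pair under every sigmoid setting; one table row per (pair, setting).

    The cosine similarity matrix of each pair is computed once and reused
    across all parameter combinations.  Columns report the alignment score,
    detected region lengths on both sequences, and precision/recall/F1
    against the ground truth; which column defines "best" is the caller's
    objective, not hard-coded here.
    """
    combos = enumerate_grid(spec)
    align_params = AlignmentParams(indel_penalty=indel_penalty, mode=mode)  # type: ignore[arg-type]
    aligner = fitting_align if mode == "fitting" else smith_waterman_local
    rows = []
    for EA, EB, truth in pairs:
        S = cosine_matrix(window_pool(EA, w), window_pool(EB, w))
        for p in combos:
            Rw = build_reward_matrix(S, p, rescale=rescale)
            res = aligner(Rw, align_params)
            precision, recall, f1 = alignment_prf(res, truth, slack=slack)
            ra, rb = res.residue_range_a, res.residue_range_b
            rows.append(
                {
                    "pair_id": truth.pair_id,
                    "midpoint": p.midpoint,
                    "sharpness": p.sharpness,
                    "scale": p.scale,
                    "score": res.score,
                    "len_a": 0 if ra is None else ra[1] - ra[0] + 1,
                    "len_b": 0 if rb is None else rb[1] - rb[0] + 1,
                    "start_a": None if ra is None else ra[0],
                    "end_a": None if ra is None else ra[1],
                    "start_b": None if rb is None else rb[0],
                    "end_b": None if rb is None else rb[1],
                    "precision": precision,
                    "recall": recall,
                    "f1": f1,
                }
            )
    return pd.DataFrame(rows)


def read_ground_truth_tsv(path: str | Path) -> list[GroundTruthAlignment]:
    """Read interval-form truth: pair_id, a_start, a_end, b_start, b_end (1-based).

    Gapped correspondences must be supplied programmatically in pair form;
    the TSV form assumes co-linear gapless intervals.
    """
    truths = []
    df = pd.read_csv(path, sep="\t")
    required = {"pair_id", "a_start", "a_end", "b_start", "b_end"}
    if not required.issubset(df.columns):
        raise ValueError(f"ground-truth TSV must have columns {sorted(required)}")
    for row in df.itertuples(index=False):
        truths.append(
            GroundTruthAlignment.from_intervals(
                str(row.pair_id),
                (int(row.a_start) - 1, int(row.a_end) - 1),
                (int(row.b_start) - 1, int(row.b_end) - 1),
            )
        )
    return truths
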