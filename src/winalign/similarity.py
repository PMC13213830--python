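"""Window-pair cosine similarity and the scaled-sigmoid reward transform.

The pairwise cosine matrix between the window embeddings of two proteins is
the raw alignment signal; a min-max rescale to [-1, 1] followed by a scaled
sigmoid sharpens the contrast between matched and mismatched window pairs,
yielding the reward matrix consumed by the dynamic-programming aligners:

    R(x) = scale * (1 / (1 + exp(-sharpness * (x - midpoint))) - 0.5) * 2
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .embedding import WindowEmbeddings

__all__ = [
    "SimilarityMatrix",
    "SigmoidParams",
    "RewardMatrix",
    "cosine_matrix",
    "rescale_to_unit_interval",
    "sigmoid_reward",
    "build_reward_matrix",
    "matrix_to_tsv",
    "plot_heatmap",
]

_COS_EPS = 1e-9


@dataclass
class SimilarityMatrix:
    """Pairwise window cosine values for one sequence pair, entries in [-1, 1]."""

    values: np.ndarray
    w: int
    ids: tuple[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("similarity matrix must be a nonempty 2-D matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class SigmoidParams:
    """Parameters of the scaled-sigmoid reward transform.

    Defaults (midpoint 0.2, sharpness 9, scale 3) are the configuration used
    for the benchmark experiments; they trade signal sensitivity against
    robustness to background similarity.
    """

    midpoint: float = 0.2
    sharpness: float = 9.0
    scale: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.midpoint <= 1.0:
            raise ValueError("midpoint must lie in [0, 1]")
        if self.sharpness <= 0:
            raise ValueError("sharpness must be > 0")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")


@dataclass
class RewardMatrix:
    """Sigmoid-transformed similarity matrix; entries strictly within (-scale, scale)."""

    values: np.ndarray
    params: SigmoidParams
    ids: tuple[str, str] = ("A", "B")
    w: int = 1
    rescaled_from: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("reward matrix must be a nonempty 2-D matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def cosine_matrix(WA: WindowEmbeddings, WB: WindowEmbeddings) -> SimilarityMatrix:
    """Cosine similarity between every window of A and every window of B.

    Entry (i, j) = dot(a_i, b_j) / (|a_i| |b_j|).  Zero-norm rows get
    similarity 0 by convention; output is clamped to [-1, 1] against
    floating-point overshoot.
    """
    if WA.d != WB.d:
        raise ValueError(f"embedding dimension mismatch: {WA.d} vs {WB.d}")
    if WA.w != WB.w:
        raise ValueError(f"window size mismatch: {WA.w} vs {WB.w}")
    na = np.linalg.norm(WA.values, axis=1)
    nb = np.linalg.norm(WB.values, axis=1)
    dots = WA.values @ WB.values.T
    denom = np.outer(na, nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        sims = np.where(denom > 0, dots / np.where(denom > 0, denom, 1.0), 0.0)
    if np.any(np.abs(sims) > 1.0 + _COS_EPS):
        raise FloatingPointError("cosine values out of tolerance band")
    sims = np.clip(sims, -1.0, 1.0)
    return SimilarityMatrix(values=sims, w=WA.w, ids=(WA.sequence_id, WB.sequence_id))


def rescale_to_unit_interval(S: SimilarityMatrix) -> SimilarityMatrix:
    """Affine map of the matrix onto [-1, 1]: min -> -1, max -> +1.

    Applied per comparison matrix.  A constant matrix maps to all zeros
    (degenerate-range convention) rather than erroring.
    """
    lo = float(S.values.min())
    hi = float(S.values.max())
    if hi == lo:
        values = np.zeros_like(S.values)
    else:
        values = (S.values - lo) / (hi - lo) * 2.0 - 1.0
    return SimilarityMatrix(values=values, w=S.w, ids=S.ids)


def sigmoid_reward(x, p: SigmoidParams = SigmoidParams()):
    """Scaled sigmoid reward; scalar in, scalar out (vectorizes over arrays).

    Zero at ``x == midpoint``, strictly increasing, bounded by ±scale.
    """
    x = np.asarray(x, dtype=np.float64)
    out = p.scale * (1.0 / (1.0 + np.exp(-p.sharpness * (x - p.midpoint))) - 0.5) * 2.0
    if out.ndim == 0:
        return float(out)
    return out


def build_reward_matrix(
    S: SimilarityMatrix,
    p: SigmoidParams = SigmoidParams(),
    rescale: bool = True,
) -> RewardMatrix:
    """Rescale the similarity matrix to [-1, 1] and apply the scaled sigmoid.

    ``rescale=False`` skips the min-max step (ablation flag); cosine values
    already lie in [-1, 1] so the transform stays well defined.
    """
    lo = float(S.values.min())
    hi = float(S.values.max())
    source = rescale_to_unit_interval(S) if rescale else S
    values = sigmoid_reward(source.values, p)
    return RewardMatrix(
        values=values,
        params=p,
        ids=S.ids,
        w=S.w,
        rescaled_from=(lo, hi) if rescale else None,
    )


def matrix_to_tsv(M, path: str | Path) -> None:
    """Export a similarity/reward matrix as TSV with window start coordinates."""
    values = M.values
    cols = "\t".join(str(j) for j in range(values.shape[1]))
    with open(path, "w") as fh:
        fh.write(f"window\t{cols}\n")
        for i, row in enumerate(values):
            body = "\t".join(f"{v:.6f}" for v in row)
            fh.write(f"{i}\t{body}\n")


def plot_heatmap(M, path: str | Path, title: str | None = None) -> None:
    """Render the matrix as a dot-plot-style heatmap (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(M.values, aspect="auto", origin="upper", cmap="viridis")
    ida, idb = getattr(M, "ids", ("A", "B"))
    ax.set_xlabel(f"{idb} window start")
    ax.set_ylabel(f"{ida} window start")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
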