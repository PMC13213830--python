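"""End-to-end convenience layer: embeddings in, alignment out.

Ties the stages together exactly as the detection workflow runs them:
window pooling -> pairwise cosine -> rescale + sigmoid reward -> DP
alignment.  The CLI and the evaluation/screening modules all route through
:func:`align_embeddings` so every entry point shares one code path.
"""

from __future__ import annotations

from dataclasses import dataclass

from .alignment import (
    AlignmentParams,
    AlignmentResult,
    fitting_align,
    smith_waterman_local,
)
from .embedding import EmbeddingMatrix, ProteinSequence, embed, window_pool
from .similarity import (
    RewardMatrix,
    SigmoidParams,
    SimilarityMatrix,
    build_reward_matrix,
    cosine_matrix,
)

__all__ = ["PipelineParams", "PairOutput", "align_embeddings", "align_sequences"]


@dataclass(frozen=True)
class PipelineParams:
    """All knobs of the detection workflow in one place."""

    w: int = 3
    sigmoid: SigmoidParams = SigmoidParams()
    alignment: AlignmentParams = AlignmentParams()
    rescale: bool = True


@dataclass
class PairOutput:
    """Alignment of one pair plus the intermediate matrices for inspection."""

    result: AlignmentResult
    similarity: SimilarityMatrix
    reward: RewardMatrix


def align_embeddings(
    EA: EmbeddingMatrix,
    EB: EmbeddingMatrix,
    params: PipelineParams = PipelineParams(),
) -> PairOutput:
    """Run pooling, similarity, reward transform and alignment on two matrices."""
    WA = window_pool(EA, params.w)
    WB = window_pool(EB, params.w)
    S = cosine_matrix(WA, WB)
    Rw = build_reward_matrix(S, params.sigmoid, rescale=params.rescale)
    if params.alignment.mode == "fitting":
        result = fitting_align(Rw, params.alignment)
    else:
        result = smith_waterman_local(Rw, params.alignment)
    return PairOutput(result=result, similarity=S, reward=Rw)


def align_sequences(
    seq_a: ProteinSequence,
    seq_b: ProteinSequence,
    provider="synthetic",
    params: PipelineParams = PipelineParams(),
    **provider_kwargs,
) -> PairOutput:
    """Embed two sequences with ``provider`` and align them."""
    EA = embed(seq_a, provider, **provider_kwargs)
    EB = embed(seq_b, provider, **provider_kwargs)
    return align_embeddings(EA, EB, params)
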