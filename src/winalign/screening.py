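"""Motif screening: fitting-align a motif against a library and rank the hits.

Every library member receives one fitting alignment of the motif against its
window embeddings; members are ranked by the raw alignment score (descending,
ties broken by id).  Precision@k / recall@k against a user-supplied positive
set evaluate how well the ranking concentrates true motif carriers at the top.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .alignment import AlignmentParams, fitting_align
from .embedding import EmbeddingMatrix, ProteinSequence, embed, window_pool
from .pipeline import PipelineParams
from .similarity import build_reward_matrix, cosine_matrix

__all__ = [
    "ScreeningHit",
    "PositiveSet",
    "screen_embeddings",
    "screen_library",
    "precision_recall_at_k",
    "read_positive_set",
    "hits_to_tsv",
]


@dataclass
class ScreeningHit:
    """One ranked library member with its fitting score and mapped interval."""

    library_id: str
    score: float
    residue_interval: tuple[int, int] | None  # 1-based inclusive, on the member
    rank: int = 0
    normalized_score: float = float("nan")  # score / motif window count, for inspection


@dataclass(frozen=True)
class PositiveSet:
    """Ground-truth ids of motif-containing library members."""

    ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", frozenset(self.ids))

    def __contains__(self, item: str) -> bool:
        return item in self.ids

    def __len__(self) -> int:
        return len(self.ids)


def screen_embeddings(
    motif: EmbeddingMatrix,
    library: Iterable[EmbeddingMatrix],
    params: PipelineParams = PipelineParams(alignment=AlignmentParams(mode="fitting")),
) -> list[ScreeningHit]:
    """Fitting-align ``motif`` against each member matrix and rank by raw score.

    ``library`` may be any iterable (e.g. an :class:`~winalign.embedding.EmbeddingCache`),
    so arbitrarily large libraries stream through one member at a time.
    Members shorter than the window size are scored ``-inf`` and sink to the
    bottom with a warning.
    """
    if params.alignment.mode != "fitting":
        raise ValueError("screening uses fitting alignment; set mode='fitting'")
    Wm = window_pool(motif, params.w)
    n_motif_windows = Wm.n_windows
    hits: list[ScreeningHit] = []
    for member in library:
        if member.n < params.w:
            warnings.warn(
                f"library member {member.sequence_id!r} is shorter than the "
                f"window size ({member.n} < {params.w}); ranked last",
                stacklevel=2,
            )
            hits.append(ScreeningHit(member.sequence_id, -math.inf, None))
            continue
        Wc = window_pool(member, params.w)
        S = cosine_matrix(Wm, Wc)
        Rw = build_reward_matrix(S, params.sigmoid, rescale=params.rescale)
        res = fitting_align(Rw, params.alignment)
        interval = res.residue_range_b
        hits.append(
            ScreeningHit(
                library_id=member.sequence_id,
                score=res.score,
                residue_interval=None if interval is None else (interval[0] + 1, interval[1] + 1),
                normalized_score=res.score / n_motif_windows,
            )
        )
    hits.sort(key=lambda h: (-h.score, h.library_id))
    for rank, h in enumerate(hits, start=1):
        h.rank = rank
    return hits


def screen_library(
    motif: ProteinSequence,
    library: Iterable[ProteinSequence],
    provider="synthetic",
    params: PipelineParams = PipelineParams(alignment=AlignmentParams(mode="fitting")),
    **provider_kwargs,
) -> list[ScreeningHit]:
    """Embed motif and library with one provider, then rank by fitting score."""
    motif_E = embed(motif, provider, **provider_kwargs)

    def members() -> Iterator[EmbeddingMatrix]:
        for seq in library:
            yield embed(seq, provider, **provider_kwargs)

    return screen_embeddings(motif_E, members(), params)


def precision_recall_at_k(
    ranking: list[str], positives: PositiveSet, k: int
) -> tuple[float, float]:
    """Precision and recall over the top ``k`` ranked ids.

    precision@k = |top-k ∩ positives| / k;
    recall@k    = |top-k ∩ positives| / |positives|.
    """
    if len(positives) == 0:
        raise ValueError("positive set is empty; precision/recall undefined")
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k={k} out of range for a ranking of {len(ranking)}")
    tp = sum(1 for lid in ranking[:k] if lid in positives)
    return tp / k, tp / len(positives)


def read_positive_set(path: str | Path) -> PositiveSet:
    """Read positive ids from a one-id-per-line list or a two-column (id, label) TSV.

    In two-column form, rows whose label parses as a false-y value
    (0/false/no/negative) are excluded.
    """
    falsey = {"0", "false", "no", "negative", "neg"}
    ids = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) >= 2 and parts[1].strip().lower() in falsey:
            continue
        ids.add(parts[0].strip())
    if not ids:
        raise ValueError(f"no positive ids found in {path}")
    return PositiveSet(ids=frozenset(ids))


def hits_to_tsv(hits: list[ScreeningHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tid\tscore\tnormalized_score\tstart\tend\n")
        for h in hits:
            start, end = h.residue_interval if h.residue_interval else ("NA", "NA")
            fh.write(
                f"{h.rank}\t{h.library_id}\t{h.score:.6f}\t{h.normalized_score:.6f}"
                f"\t{start}\t{end}\n"
            )
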