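"""Per-residue embeddings and sliding-window mean pooling.

A protein language model (pLM) maps a sequence of length ``n`` to an
``n x d`` matrix of per-residue hidden states.  This module defines the
provider contract for obtaining such matrices (real pLMs behind optional
adapters, plus an always-available deterministic synthetic embedder), the
mean-pooling step that turns them into overlapping window-level embeddings,
and an HDF5-backed cache so a large model never has to run twice.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

import numpy as np
from Bio import SeqIO

__all__ = [
    "ProteinSequence",
    "EmbeddingMatrix",
    "WindowEmbeddings",
    "canonicalize_sequence",
    "read_fasta",
    "write_fasta",
    "embed",
    "synthetic_embed",
    "window_pool",
    "register_provider",
    "get_provider",
    "list_providers",
    "EmbeddingCache",
]

# 20 standard residues plus 'X' for anything nonstandard.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET = STANDARD_AA + "X"
_NONSTANDARD = set("BZUOJ*")


def canonicalize_sequence(residues: str) -> str:
    """Uppercase and map nonstandard residue codes (B, Z, U, O, J, *) to 'X'.

    pLM tokenizers disagree on rare codes; the pipeline works over a single
    21-letter alphabet.  Unknown characters also become 'X'.
    """
    out = []
    for ch in residues.upper():
        if ch in _NONSTANDARD or ch not in ALPHABET:
            ch = "X"
        out.append(ch)
    return "".join(out)


@dataclass(frozen=True)
class ProteinSequence:
    """A named amino-acid sequence over the canonical 21-letter alphabet."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", canonicalize_sequence(self.residues))
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class EmbeddingMatrix:
    """Per-residue embedding rows for one sequence (shape ``n x d``).

    Row count equals the sequence length exactly: provider adapters are
    responsible for stripping any special-token positions.
    """

    sequence_id: str
    values: np.ndarray
    provider_name: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("embedding matrix must be 2-D (n x d)")
        if self.values.shape[0] < 1 or self.values.shape[1] < 1:
            raise ValueError("embedding matrix must be nonempty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite entries in embeddings for {self.sequence_id!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


@dataclass
class WindowEmbeddings:
    """Mean-pooled window vectors: ``n - w + 1`` rows of dimension ``d``."""

    sequence_id: str
    values: np.ndarray
    w: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.w < 1:
            raise ValueError("window size must be >= 1")
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("window embeddings must be a nonempty 2-D matrix")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# Provider registry
# ---------------------------------------------------------------------------

Provider = Callable[[ProteinSequence], np.ndarray]
_PROVIDERS: dict[str, Callable[..., Provider]] = {}


def register_provider(name: str, factory: Callable[..., Provider]) -> None:
    """Register an embedding-provider factory under ``name``."""
    _PROVIDERS[name] = factory


def get_provider(name: str, **kwargs) -> Provider:
    """Instantiate a registered provider; raises ``KeyError`` for unknown names."""
    try:
        factory = _PROVIDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown embedding provider {name!r}; available: {sorted(_PROVIDERS)}"
        ) from None
    return factory(**kwargs)


def list_providers() -> list[str]:
    return sorted(_PROVIDERS)


def embed(seq: ProteinSequence, provider: Provider | str, **kwargs) -> EmbeddingMatrix:
    """Run ``provider`` on ``seq`` and validate the ``n x d`` contract.

    ``provider`` may be a registered name or a callable mapping a
    :class:`ProteinSequence` to an ``(n, d)`` array.
    """
    name = provider if isinstance(provider, str) else getattr(provider, "name", "custom")
    if isinstance(provider, str):
        provider = get_provider(provider, **kwargs)
    values = np.asarray(provider(seq), dtype=np.float64)
    if values.ndim != 2 or values.shape[0] != len(seq):
        raise ValueError(
            f"provider {name!r} returned shape {values.shape} for a length-{len(seq)} "
            "sequence; expected exactly one row per residue (special tokens must be "
            "stripped by the adapter)"
        )
    return EmbeddingMatrix(sequence_id=seq.id, values=values, provider_name=name)


# ---------------------------------------------------------------------------
# Synthetic embedder
# ---------------------------------------------------------------------------

def _context_vector(context: str, d: int, seed_material: str) -> np.ndarray:
    digest = hashlib.blake2b(
        f"{seed_material}|{context}".encode(), digest_size=16
    ).digest()
    rng = np.random.Generator(np.random.PCG64(int.from_bytes(digest, "little")))
    return rng.standard_normal(d)


def synthetic_embed(
    seq: ProteinSequence,
    context_radius: int = 2,
    d: int = 64,
    seed_material: str = "winalign-synthetic-v1",
) -> EmbeddingMatrix:
    """Deterministic local-context embedder standing in for a pLM.

    Row ``i`` is a pure function of the residue window
    ``seq[i - context_radius .. i + context_radius]`` (clipped at the sequence
    ends), of ``d`` and of ``seed_material``: identical local contexts yield
    identical rows, which gives the embedder the locality the alignment method
    assumes, without any model weights.
    """
    if d < 2:
        raise ValueError("embedding dimension must be >= 2")
    if context_radius < 0:
        raise ValueError("context_radius must be >= 0")
    n = len(seq)
    rows = np.empty((n, d))
    cache: dict[str, np.ndarray] = {}
    for i in range(n):
        ctx = seq.residues[max(0, i - context_radius): i + context_radius + 1]
        vec = cache.get(ctx)
        if vec is None:
            vec = _context_vector(ctx, d, seed_material)
            cache[ctx] = vec
        rows[i] = vec
    return EmbeddingMatrix(sequence_id=seq.id, values=rows, provider_name="synthetic")


class SyntheticProvider:
    """Registered wrapper around :func:`synthetic_embed`."""

    name = "synthetic"

    def __init__(self, context_radius: int = 2, d: int = 64,
                 seed_material: str = "winalign-synthetic-v1") -> None:
        self.context_radius = context_radius
        self.d = d
        self.seed_material = seed_material

    def __call__(self, seq: ProteinSequence) -> np.ndarray:
        return synthetic_embed(seq, self.context_radius, self.d, self.seed_material).values


def _transformer_provider(model: str):
    """Factory for the ProtT5/ProstT5 adapters (optional heavyweight deps)."""

    def factory(device: str = "cpu", half: bool = False):
        try:
            import torch  # noqa: F401
            from transformers import T5EncoderModel, T5Tokenizer  # noqa: F401
        except ImportError as exc:  # pragma: no cover - requires optional deps
            raise ImportError(
                f"provider for {model!r} needs the 'torch' and 'transformers' "
                "packages and downloaded model weights; use the 'synthetic' "
                "provider for an offline run"
            ) from exc
        return _TransformerProvider(model, device=device, half=half)

    return factory


class _TransformerProvider:  # pragma: no cover - requires model weights
    """Encoder-side ProtT5/ProstT5 adapter.

    For ProstT5 the amino-acid direction prefix token ``<AA2fold>`` is
    prepended (the encoder was trained with it); the prefix and the trailing
    special token are stripped so exactly ``n`` rows are returned.
    """

    def __init__(self, model: str, device: str = "cpu", half: bool = False) -> None:
        from transformers import T5EncoderModel, T5Tokenizer

        self.name = "prostt5" if "prostt5" in model.lower() else "prott5"
        checkpoint = {
            "prostt5": "Rostlab/ProstT5",
            "prott5": "Rostlab/prot_t5_xl_uniref50",
        }[self.name]
        self.tokenizer = T5Tokenizer.from_pretrained(checkpoint, do_lower_case=False)
        self.model = T5EncoderModel.from_pretrained(checkpoint).to(device).eval()
        if half:
            self.model = self.model.half()
        self.device = device

    def __call__(self, seq: ProteinSequence) -> np.ndarray:
        import torch

        spaced = " ".join(seq.residues)
        if self.name == "prostt5":
            spaced = "<AA2fold> " + spaced
        ids = self.tokenizer(spaced, return_tensors="pt").to(self.device)
        with torch.no_grad():
            out = self.model(**ids).last_hidden_state[0].float().cpu().numpy()
        n = len(seq)
        # drop the prefix token (ProstT5) and the trailing </s>
        start = out.shape[0] - n - 1
        return out[start: start + n]


register_provider("synthetic", SyntheticProvider)
register_provider("prostt5", _transformer_provider("prostt5"))
register_provider("prott5", _transformer_provider("prott5"))


# ---------------------------------------------------------------------------
# Window pooling
# ---------------------------------------------------------------------------

def window_pool(E: EmbeddingMatrix, w: int) -> WindowEmbeddings:
    """Mean-pool per-residue rows over a sliding window of size ``w``.

    Output row ``i`` is the arithmetic mean of rows ``i .. i+w-1`` of ``E``;
    there are ``n - w + 1`` such overlapping windows.
    """
    if w < 1:
        raise ValueError("window size must be >= 1")
    if E.n < w:
        raise ValueError(
            f"sequence {E.sequence_id!r} has {E.n} residues, shorter than window {w}"
        )
    if w == 1:
        pooled = E.values.copy()
    else:
        # (n-w+1, d, w) view, mean over the window axis
        view = np.lib.stride_tricks.sliding_window_view(E.values, w, axis=0)
        pooled = view.mean(axis=-1)
    return WindowEmbeddings(sequence_id=E.sequence_id, values=pooled, w=w)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a multi-record FASTA; id = first whitespace-delimited header token."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(ProteinSequence(id=rec.id, residues=str(rec.seq)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


# ---------------------------------------------------------------------------
# Embedding cache
# ---------------------------------------------------------------------------

class EmbeddingCache:
    """One embedding matrix per sequence id in a self-describing HDF5 file.

    Each dataset is keyed by sequence id and carries ``(n, d, provider_name)``
    attributes, so caches written by a heavyweight model run can be consumed
    later without the model.
    """

    def __init__(self, path: str | Path, mode: str = "a") -> None:
        import h5py

        self.path = Path(path)
        self._h5 = h5py.File(self.path, mode)

    def put(self, E: EmbeddingMatrix) -> None:
        if E.sequence_id in self._h5:
            del self._h5[E.sequence_id]
        ds = self._h5.create_dataset(E.sequence_id, data=E.values)
        ds.attrs["n"] = E.n
        ds.attrs["d"] = E.d
        ds.attrs["provider_name"] = E.provider_name

    def get(self, sequence_id: str) -> EmbeddingMatrix:
        if sequence_id not in self._h5:
            raise KeyError(f"no cached embeddings for {sequence_id!r} in {self.path}")
        ds = self._h5[sequence_id]
        return EmbeddingMatrix(
            sequence_id=sequence_id,
            values=ds[()],
            provider_name=ds.attrs.get("provider_name", "unknown"),
        )

    def __contains__(self, sequence_id: str) -> bool:
        return sequence_id in self._h5

    def ids(self) -> list[str]:
        return sorted(self._h5.keys())

    def __iter__(self) -> Iterator[EmbeddingMatrix]:
        for sid in self.ids():
            yield self.get(sid)

    def close(self) -> None:
        self._h5.close()

    def __enter__(self) -> "EmbeddingCache":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
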