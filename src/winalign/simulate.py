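"""Synthetic embedding fixtures with planted analogous regions.

Real benchmarks of structural analogy (pairs of proteins whose local folds
match despite unrelated sequences) need a large language model to embed;
these generators emulate the *geometry* the detection method relies on
instead: background rows are i.i.d. spherical Gaussians, and a shared latent
block — perturbed by independent Gaussian noise in each copy — is planted
where the two sequences are "structurally analogous".  Everything is a pure
function of its seed, so pipeline tests are bit-reproducible without model
weights or downloads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import STANDARD_AA, EmbeddingMatrix, ProteinSequence
from .evaluation import GroundTruthAlignment
from .screening import PositiveSet

__all__ = [
    "PlantedPairSpec",
    "make_planted_pair",
    "make_planted_library",
    "make_synthetic_fasta",
]


@dataclass(frozen=True)
class PlantedPairSpec:
    """Study conditions for one planted-analog pair.

    Defaults match the package's reference recovery study: two 120-residue
    sequences sharing a 30-residue latent block (at offset 30 in A and 50 in
    B, so the signal is off-diagonal), embedding dimension 64, perturbation
    noise 0.2.
    """

    n_a: int = 120
    n_b: int = 120
    interval_a: tuple[int, int] = (30, 59)
    interval_b: tuple[int, int] = (50, 79)
    d: int = 64
    noise_sigma: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        la = self.interval_a[1] - self.interval_a[0] + 1
        lb = self.interval_b[1] - self.interval_b[0] + 1
        if la != lb:
            raise ValueError("planted intervals must have equal length")
        if la < 1:
            raise ValueError("planted interval must be nonempty")
        if not (0 <= self.interval_a[0] and self.interval_a[1] < self.n_a):
            raise ValueError("planted interval A out of range")
        if not (0 <= self.interval_b[0] and self.interval_b[1] < self.n_b):
            raise ValueError("planted interval B out of range")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")

    @property
    def block_length(self) -> int:
        return self.interval_a[1] - self.interval_a[0] + 1


def make_planted_pair(
    spec: PlantedPairSpec = PlantedPairSpec(),
) -> tuple[EmbeddingMatrix, EmbeddingMatrix, GroundTruthAlignment]:
    """Two embedding matrices sharing a noisy copy of one latent block.

    Background rows are independent standard normals per sequence; the same
    latent block (also standard normal) is copied into both planted
    intervals, each copy perturbed by independent N(0, noise_sigma²) noise.
    Ground truth is the co-linear residue correspondence over the intervals.
    """
    rng = np.random.default_rng(spec.seed)
    A = rng.standard_normal((spec.n_a, spec.d))
    B = rng.standard_normal((spec.n_b, spec.d))
    block = rng.standard_normal((spec.block_length, spec.d))
    a0, a1 = spec.interval_a
    b0, b1 = spec.interval_b
    A[a0: a1 + 1] = block + spec.noise_sigma * rng.standard_normal(block.shape)
    B[b0: b1 + 1] = block + spec.noise_sigma * rng.standard_normal(block.shape)
    truth = GroundTruthAlignment.from_intervals(
        f"planted-seed{spec.seed}", spec.interval_a, spec.interval_b
    )
    EA = EmbeddingMatrix(sequence_id="A", values=A, provider_name="simulated")
    EB = EmbeddingMatrix(sequence_id="B", values=B, provider_name="simulated")
    return EA, EB, truth


def make_planted_library(
    n_members: int = 50,
    n_positives: int = 5,
    motif_length: int = 30,
    member_length: int = 120,
    noise_sigma: float = 0.3,
    d: int = 64,
    seed: int = 0,
) -> tuple[EmbeddingMatrix, list[EmbeddingMatrix], PositiveSet]:
    """A motif matrix plus a library in which some members carry the motif.

    Positives receive a noisy copy of the motif's latent block at a random
    position; decoys are pure background.  Member ids are ``lib_000`` ...;
    which ids are positive is itself randomized by the seed.
    """
    if n_positives > n_members:
        raise ValueError("cannot plant more positives than members")
    if motif_length > member_length:
        raise ValueError("motif longer than library members")
    rng = np.random.default_rng(seed)
    block = rng.standard_normal((motif_length, d))
    motif = EmbeddingMatrix(sequence_id="motif", values=block.copy(), provider_name="simulated")
    positive_idx = set(rng.choice(n_members, size=n_positives, replace=False).tolist())
    library = []
    positive_ids = set()
    for m in range(n_members):
        member_id = f"lib_{m:03d}"
        values = rng.standard_normal((member_length, d))
        if m in positive_idx:
            start = int(rng.integers(0, member_length - motif_length + 1))
            values[start: start + motif_length] = (
                block + noise_sigma * rng.standard_normal(block.shape)
            )
            positive_ids.add(member_id)
        library.append(
            EmbeddingMatrix(sequence_id=member_id, values=values, provider_name="simulated")
        )
    return motif, library, PositiveSet(ids=frozenset(positive_ids))


def make_synthetic_fasta(
    n_sequences: int,
    length_range: tuple[int, int] = (50, 60),
    seed: int = 0,
) -> list[ProteinSequence]:
    """Uniform-random sequences over the 20 standard residues, deterministic in seed."""
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid length range")
    rng = np.random.default_rng(seed)
    letters = np.array(list(STANDARD_AA))
    seqs = []
    for i in range(n_sequences):
        n = int(rng.integers(lo, hi + 1))
        residues = "".join(letters[rng.integers(0, len(letters), size=n)])
        seqs.append(ProteinSequence(id=f"syn_{i:03d}", residues=residues))
    return seqs
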