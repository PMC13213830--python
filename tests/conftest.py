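import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from winalign import EmbeddingMatrix, ProteinSequence, RewardMatrix, SigmoidParams


@pytest.fixture
def simple_sequence() -> ProteinSequence:
    return ProteinSequence(id="seq1", residues="ACDEFGHIKLMNPQRSTVWY")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_reward(values: np.ndarray) -> RewardMatrix:
    """Wrap a raw array as a RewardMatrix for direct aligner tests."""
    return RewardMatrix(values=np.asarray(values, dtype=float), params=SigmoidParams())


def random_embedding(rng: np.random.Generator, n: int, d: int = 8,
                     sequence_id: str = "E") -> EmbeddingMatrix:
    return EmbeddingMatrix(
        sequence_id=sequence_id, values=rng.standard_normal((n, d)),
        provider_name="test",
    )
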