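"""Cosine matrix construction and the scaled-sigmoid reward transform."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cosine as scipy_cosine_distance

from winalign import (
    SigmoidParams,
    WindowEmbeddings,
    build_reward_matrix,
    cosine_matrix,
    rescale_to_unit_interval,
    sigmoid_reward,
)
from winalign.similarity import SimilarityMatrix


def windows(values, w=3, sid="s"):
    return WindowEmbeddings(sequence_id=sid, values=np.asarray(values, float), w=w)


def scalar_sigmoid(x, midpoint, sharpness, scale):
    """Independent scalar evaluation of the reward formula (math.exp route)."""
    return scale * (1.0 / (1.0 + math.exp(-sharpness * (x - midpoint))) - 0.5) * 2.0


class TestCosineMatrix:
    def test_self_similarity_diagonal(self, rng):
        W = windows(rng.standard_normal((5, 8)))
        S = cosine_matrix(W, W)
        np.testing.assert_allclose(np.diag(S.values), 1.0, atol=1e-12)
        np.testing.assert_allclose(S.values, S.values.T, atol=1e-12)

    def test_orthogonal_vectors(self):
        S = cosine_matrix(windows([[1.0, 0.0]]), windows([[0.0, 2.0]]))
        assert S.values[0, 0] == pytest.approx(0.0, abs=1e-15)

    def test_matches_per_pair_scipy_cosine(self, rng):
        """2x3 hand case: each entry equals an independent per-pair cosine."""
        A = rng.standard_normal((2, 2))
        B = rng.standard_normal((3, 2))
        S = cosine_matrix(windows(A), windows(B))
        assert S.values.shape == (2, 3)
        for i in range(2):
            for j in range(3):
                expected = 1.0 - scipy_cosine_distance(A[i], B[j])
                assert S.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_norm_rows_get_zero(self):
        S = cosine_matrix(windows([[0.0, 0.0], [1.0, 1.0]]), windows([[1.0, 2.0]]))
        assert S.values[0, 0] == 0.0
        assert S.values[1, 0] != 0.0

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="dimension mismatch"):
            cosine_matrix(
                windows(rng.standard_normal((3, 4))),
                windows(rng.standard_normal((3, 5))),
            )

    def test_entries_bounded(self, rng):
        S = cosine_matrix(
            windows(rng.standard_normal((20, 3))), windows(rng.standard_normal((15, 3)))
        )
        assert np.all(S.values >= -1.0) and np.all(S.values <= 1.0)


class TestRescale:
    def test_endpoints_forced(self):
        S = SimilarityMatrix(values=np.array([[0.1, 0.6], [0.35, 0.35]]), w=1, ids=("a", "b"))
        out = rescale_to_unit_interval(S).values
        np.testing.assert_allclose(out, [[-1.0, 1.0], [0.0, 0.0]], atol=1e-12)

    def test_full_range_unchanged(self):
        vals = np.array([[-1.0, 0.25], [0.5, 1.0]])
        S = SimilarityMatrix(values=vals, w=1, ids=("a", "b"))
        np.testing.assert_allclose(rescale_to_unit_interval(S).values, vals, atol=1e-12)

    def test_constant_matrix_maps_to_zero(self):
        S = SimilarityMatrix(values=np.full((3, 3), 0.7), w=1, ids=("a", "b"))
        assert np.all(rescale_to_unit_interval(S).values == 0.0)

    def test_order_preserving(self, rng):
        vals = rng.uniform(-1, 1, size=(6, 6))
        S = SimilarityMatrix(values=vals, w=1, ids=("a", "b"))
        out = rescale_to_unit_interval(S).values
        assert np.all(np.sign(np.diff(np.sort(vals.ravel()))) ==
                      np.sign(np.diff(out.ravel()[np.argsort(vals.ravel())])))


class TestSigmoidReward:
    def test_zero_at_midpoint(self):
        for mid in (0.0, 0.2, 0.5, 1.0):
            p = SigmoidParams(midpoint=mid, sharpness=5, scale=2)
            assert sigmoid_reward(mid, p) == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize(
        "x,expected",
        [(1.0, 2.9955238), (-1.0, -2.9998776)],  # frozen from the scalar formula
    )
    def test_default_parameter_endpoints(self, x, expected):
        p = SigmoidParams()  # midpoint 0.2, sharpness 9, scale 3
        got = sigmoid_reward(x, p)
        assert got == pytest.approx(expected, abs=1e-6)
        assert got == pytest.approx(scalar_sigmoid(x, 0.2, 9, 3), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        x=st.floats(-1, 1), delta=st.floats(0.001, 0.5),
        midpoint=st.floats(0, 1), sharpness=st.floats(0.5, 20), scale=st.floats(0.1, 10),
    )
    def test_monotone_bounded_antisymmetric(self, x, delta, midpoint, sharpness, scale):
        p = SigmoidParams(midpoint=midpoint, sharpness=sharpness, scale=scale)
        assert sigmoid_reward(x + delta, p) > sigmoid_reward(x, p)
        assert abs(sigmoid_reward(x, p)) < scale
        assert sigmoid_reward(midpoint + delta, p) == pytest.approx(
            -sigmoid_reward(midpoint - delta, p), abs=1e-12
        )

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            SigmoidParams(midpoint=1.5)
        with pytest.raises(ValueError):
            SigmoidParams(sharpness=0)
        with pytest.raises(ValueError):
            SigmoidParams(scale=-1)


class TestBuildRewardMatrix:
    def test_constant_input(self):
        S = SimilarityMatrix(values=np.full((2, 2), 0.4), w=1, ids=("a", "b"))
        p = SigmoidParams()
        Rw = build_reward_matrix(S, p)
        np.testing.assert_allclose(Rw.values, sigmoid_reward(0.0, p), atol=1e-15)
        assert Rw.rescaled_from == (0.4, 0.4)

    def test_sign_splits_at_midpoint(self, rng):
        vals = rng.uniform(-1, 1, size=(8, 8))
        S = SimilarityMatrix(values=vals, w=1, ids=("a", "b"))
        p = SigmoidParams(midpoint=0.2, sharpness=9, scale=3)
        rescaled = rescale_to_unit_interval(S).values
        Rw = build_reward_matrix(S, p)
        assert np.all(Rw.values[rescaled > p.midpoint] > 0)
        assert np.all(Rw.values[rescaled < p.midpoint] < 0)

    def test_matches_entrywise_scalar_oracle(self, rng):
        vals = rng.uniform(-0.5, 0.9, size=(3, 3))
        S = SimilarityMatrix(values=vals, w=1, ids=("a", "b"))
        p = SigmoidParams()
        Rw = build_reward_matrix(S, p)
        lo, hi = vals.min(), vals.max()
        for i in range(3):
            for j in range(3):
                x = (vals[i, j] - lo) / (hi - lo) * 2.0 - 1.0
                assert Rw.values[i, j] == pytest.approx(
                    scalar_sigmoid(x, p.midpoint, p.sharpness, p.scale), abs=1e-12
                )

    def test_preserves_entry_ordering(self, rng):
        vals = rng.uniform(-1, 1, size=(5, 7))
        S = SimilarityMatrix(values=vals, w=1, ids=("a", "b"))
        Rw = build_reward_matrix(S, SigmoidParams())
        order_in = np.argsort(vals.ravel())
        assert np.all(np.diff(Rw.values.ravel()[order_in]) > 0)

    def test_rescale_flag_disables_minmax(self):
        vals = np.array([[0.2, 0.5]])
        S = SimilarityMatrix(values=vals, w=1, ids=("a", "b"))
        p = SigmoidParams()
        Rw = build_reward_matrix(S, p, rescale=False)
        assert Rw.rescaled_from is None
        assert Rw.values[0, 0] == pytest.approx(0.0, abs=1e-15)  # 0.2 == midpoint
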