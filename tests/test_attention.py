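"""Channel/spatial attention gates and the parallel-additive refinement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from abfp.attention import (
    ChannelAttentionParams,
    SpatialAttentionParams,
    abfp_refine,
    channel_attention,
    load_params,
    save_params,
    spatial_attention,
)
from abfp.autodiff import Tensor
from abfp.pyramid import BalancedSemanticMap

from .conftest import zero_channel_params, zero_spatial_params
from .oracles import (
    finite_difference_grad,
    oracle_abfp_refine,
    oracle_channel_gate,
    oracle_spatial_gate,
)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


class TestChannelAttention:
    def test_zero_parameters_give_half_gates(self, rng):
        f = rng.standard_normal((4, 5, 5)).astype(np.float32)
        gate = channel_attention(f, zero_channel_params(4)).data
        np.testing.assert_allclose(gate, 0.5, atol=1e-7)

    def test_identity_mlp_hand_example(self):
        # avg pools to [1, 1], max pools to [1, 4]; identity MLP sums branches
        f = np.stack([
            np.ones((2, 2), dtype=np.float32),
            np.array([[0.0, 0.0], [0.0, 4.0]], dtype=np.float32),
        ])
        params = ChannelAttentionParams(
            w0=np.eye(2, dtype=np.float32), b0=None,
            w1=np.eye(2, dtype=np.float32), b1=None, reduction_ratio=1,
        )
        gate = channel_attention(f, params).data
        np.testing.assert_allclose(gate, _sigmoid([2.0, 5.0]), atol=1e-6)

    def test_constant_channels_collapse_avg_and_max(self, rng):
        means = rng.standard_normal(6).astype(np.float32)
        f = np.broadcast_to(means[:, None, None], (6, 4, 4)).astype(np.float32).copy()
        params = ChannelAttentionParams.init(6, reduction_ratio=2, seed=5)
        gate = channel_attention(f, params).data
        # avg == max, so the gate is sigmoid(2 * MLP(channel means))
        hidden = np.maximum(0.0, params.w0 @ means + params.b0)
        np.testing.assert_allclose(
            gate, _sigmoid(2.0 * (params.w1 @ hidden + params.b1)), atol=1e-5
        )

    def test_matches_scalar_oracle(self, rng):
        f = rng.standard_normal((4, 6, 6)).astype(np.float32)
        params = ChannelAttentionParams.init(4, reduction_ratio=2, seed=9)
        got = channel_attention(f, params).data
        want = oracle_channel_gate(f, params.w0, params.b0, params.w1, params.b1)
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_permutation_equivariance(self, rng):
        f = rng.standard_normal((5, 4, 4)).astype(np.float32)
        params = ChannelAttentionParams.init(5, reduction_ratio=1, seed=3)
        perm = rng.permutation(5)
        permuted = ChannelAttentionParams(
            w0=params.w0[np.ix_(perm, perm)], b0=params.b0[perm],
            w1=params.w1[np.ix_(perm, perm)], b1=params.b1[perm], reduction_ratio=1,
        )
        np.testing.assert_allclose(
            channel_attention(f[perm], permuted).data,
            channel_attention(f, params).data[perm],
            atol=1e-6,
        )

    def test_invalid_reduction_ratio_rejected(self):
        with pytest.raises(ValueError):
            ChannelAttentionParams(
                w0=np.zeros((2, 5), np.float32), b0=None,
                w1=np.zeros((5, 2), np.float32), b1=None, reduction_ratio=3,
            )

    def test_gate_strictly_inside_unit_interval(self, rng):
        f = 10.0 * rng.standard_normal((8, 4, 4)).astype(np.float32)
        params = ChannelAttentionParams.init(8, reduction_ratio=4, seed=2)
        gate = channel_attention(f, params).data
        assert (gate > 0.0).all() and (gate < 1.0).all()


class TestSpatialAttention:
    def test_zero_parameters_give_half_gates(self, rng):
        f = rng.standard_normal((3, 6, 6)).astype(np.float32)
        gate = spatial_attention(f, zero_spatial_params()).data
        np.testing.assert_allclose(gate, 0.5, atol=1e-7)

    def test_center_tap_on_avg_plane_is_channel_mean(self, rng):
        kernel = np.zeros((1, 2, 7, 7), dtype=np.float32)
        kernel[0, 0, 3, 3] = 1.0  # identity on the channel-average plane
        params = SpatialAttentionParams(kernel=kernel, bias=np.zeros(1, np.float32))
        f = rng.standard_normal((4, 5, 5)).astype(np.float32)
        np.testing.assert_allclose(
            spatial_attention(f, params).data, _sigmoid(f.mean(axis=0)), atol=1e-6
        )

    def test_spatially_constant_input_constant_away_from_border(self, rng):
        f = np.broadcast_to(
            rng.standard_normal(3)[:, None, None].astype(np.float32), (3, 12, 12)
        ).copy()
        params = SpatialAttentionParams.init(seed=8)
        gate = spatial_attention(f, params).data
        interior = gate[3:-3, 3:-3]  # zero padding perturbs a 3-pixel border
        np.testing.assert_allclose(interior, interior[0, 0], atol=1e-6)

    def test_matches_scalar_oracle(self, rng):
        f = rng.standard_normal((3, 8, 8)).astype(np.float32)
        params = SpatialAttentionParams.init(seed=6)
        np.testing.assert_allclose(
            spatial_attention(f, params).data,
            oracle_spatial_gate(f, params.kernel, params.bias),
            atol=1e-6,
        )

    def test_kernel_size_enforced(self):
        with pytest.raises(ValueError):
            SpatialAttentionParams(kernel=np.zeros((1, 2, 5, 5), np.float32), bias=None)


class TestABFPRefine:
    def test_half_gates_are_identity(self, rng):
        f = rng.standard_normal((4, 6, 6)).astype(np.float32)
        bsm = BalancedSemanticMap(f, 1)
        out = abfp_refine(
            bsm, None, None,
            channel_gate=np.full(4, 0.5, np.float32),
            spatial_gate=np.full((6, 6), 0.5, np.float32),
        )
        np.testing.assert_array_equal(out.map, f)

    def test_zero_input_stays_zero(self):
        bsm = BalancedSemanticMap(np.zeros((4, 5, 5), np.float32), 0)
        cap = ChannelAttentionParams.init(4, 2, seed=1)
        sap = SpatialAttentionParams.init(seed=2)
        np.testing.assert_array_equal(abfp_refine(bsm, cap, sap).data, 0.0)

    def test_matches_elementwise_oracle(self, rng):
        f = rng.standard_normal((4, 8, 8)).astype(np.float32)
        cap = ChannelAttentionParams.init(4, 2, seed=21)
        sap = SpatialAttentionParams.init(seed=22)
        got = abfp_refine(BalancedSemanticMap(f, 0), cap, sap).data
        want = oracle_abfp_refine(f, cap, sap)
        assert np.abs(got - want).max() < 1e-6

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), bound=st.floats(0.1, 50.0))
    def test_bounded_by_twice_the_input(self, seed, bound):
        r = np.random.default_rng(seed)
        f = (bound * (2 * r.random((3, 4, 4)) - 1)).astype(np.float32)
        cap = ChannelAttentionParams.init(3, 1, seed=seed)
        sap = SpatialAttentionParams.init(seed=seed + 1)
        out = abfp_refine(BalancedSemanticMap(f, 0), cap, sap).data
        assert np.abs(out).max() <= 2.0 * bound + 1e-4

    def test_gradients_match_finite_differences(self, rng):
        f0 = rng.standard_normal((2, 4, 4)).astype(np.float32)
        cap = ChannelAttentionParams.init(2, 1, seed=31)
        sap = SpatialAttentionParams.init(seed=32)
        g = rng.standard_normal((2, 4, 4)).astype(np.float32)

        ft = Tensor(f0, requires_grad=True)
        out = abfp_refine(BalancedSemanticMap(ft, 0), cap, sap)
        (out.map * Tensor(g)).sum().backward()

        def loss64(f):
            return float((oracle_abfp_refine(f.astype(np.float64), cap, sap) * g).sum())

        fd = finite_difference_grad(loss64, f0)
        rel = np.abs(ft.grad - fd).max() / max(1.0, np.abs(fd).max())
        assert rel < 1e-4

    def test_checkpoint_round_trip(self, tmp_path):
        cap = ChannelAttentionParams.init(8, 4, seed=41)
        sap = SpatialAttentionParams.init(seed=42)
        path = tmp_path / "attn.npz"
        save_params(path, cap, sap)
        cap2, sap2 = load_params(path)
        np.testing.assert_array_equal(cap2.w0, cap.w0)
        np.testing.assert_array_equal(cap2.w1, cap.w1)
        np.testing.assert_array_equal(sap2.kernel, sap.kernel)
        assert cap2.reduction_ratio == cap.reduction_ratio
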