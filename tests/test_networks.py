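"""Network contracts: dilated convolution, shapes, residual identity, gradients."""

import numpy as np
import pytest

from splitreg._engine import Tensor, tsum, mul
from splitreg.networks import (
    DenoiserNet,
    DenoiserNetSpec,
    SimilarityNet,
    SimilarityNetSpec,
    dilated_conv_1d,
)

TINY_SIM = SimilarityNetSpec(
    encoder_channels=(2, 2, 2, 2),
    decoder_channels=(2, 2, 2, 1),
    head_channels=(1, 1),
)
TINY_DEN = DenoiserNetSpec(
    stem_channels=2, dilation_rates=(1, 2), branch_channels=2, fusion_channels=2
)


def loop_dilated_conv(x, w, r):
    out_len = len(x) - r * (len(w) - 1)
    y = []
    for i in range(out_len):
        acc = 0.0
        for k in range(len(w)):
            acc += x[i + r * k] * w[k]
        y.append(acc)
    return np.array(y)


class TestDilatedConv1D:
    def test_rate_one_adjacent_pairs(self):
        np.testing.assert_allclose(dilated_conv_1d([1, 2, 3, 4], [1, 1], 1), [3, 5, 7])

    def test_rate_two_hand_case(self):
        np.testing.assert_allclose(
            dilated_conv_1d([1, 2, 3, 4, 5], [1, 1], 2), [4, 6, 8]
        )

    def test_200_random_cases_match_double_loop(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = int(rng.integers(4, 65))
            r = int(rng.integers(1, 5))
            max_m = (n - 1) // r + 1
            m = int(rng.integers(1, min(max_m, 7) + 1))
            x = rng.normal(size=n)
            w = rng.normal(size=m)
            np.testing.assert_array_equal(
                dilated_conv_1d(x, w, r), loop_dilated_conv(x, w, r)
            )

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            dilated_conv_1d([1, 2, 3], [1, 1, 1], 2)


class TestSimilarityNet:
    @pytest.mark.parametrize("shape", [(64, 64), (32, 48, 64)])
    def test_output_shape_contract(self, shape):
        d = len(shape)
        net = SimilarityNet(TINY_SIM, d)
        rng = np.random.default_rng(0)
        params = net.init_params(rng, np.float32)
        fixed = rng.uniform(size=(1,) + shape).astype(np.float32)
        moving = rng.uniform(size=(1,) + shape).astype(np.float32)
        out = net.forward(params, fixed, moving)
        assert out.shape == (1, d) + shape

    def test_zero_head_gives_zero_field(self):
        net = SimilarityNet(TINY_SIM, 2)
        rng = np.random.default_rng(1)
        params = net.init_params(rng)
        params["head1.w"][:] = 0
        params["head1.b"][:] = 0
        fixed = rng.uniform(size=(2, 32, 32)).astype(np.float32)
        out = net.forward(params, fixed, fixed)
        assert (out.data == 0).all()

    def test_indivisible_axis_rejected_naming_axis(self):
        net = SimilarityNet(TINY_SIM, 2)
        params = net.init_params(np.random.default_rng(0))
        x = np.zeros((1, 32, 40), dtype=np.float32)
        with pytest.raises(ValueError, match="axis 1"):
            net.forward(params, x, x)

    def test_parameter_count_matches_hand_enumeration(self):
        # default 2-D spec: kernel 3, encoder (16,32,32,32) from 2 input
        # channels, decoder (32,32,16,16) with concatenated skips
        # (32,32,16,2), head 16->16->2.
        net = SimilarityNet(SimilarityNetSpec(), 2)
        k2 = 9
        hand = (
            (2 * 16 * k2 + 16)
            + (16 * 32 * k2 + 32)
            + (32 * 32 * k2 + 32)
            + (32 * 32 * k2 + 32)
            + ((32 + 32) * 32 * k2 + 32)
            + ((32 + 32) * 32 * k2 + 32)
            + ((32 + 16) * 16 * k2 + 16)
            + ((16 + 2) * 16 * k2 + 16)
            + (16 * 16 * k2 + 16)
            + (16 * 2 * k2 + 2)
        )
        assert net.param_count() == hand
        params = net.init_params(np.random.default_rng(0))
        assert sum(v.size for v in params.values()) == hand

    def test_deterministic_forward(self):
        net = SimilarityNet(TINY_SIM, 2)
        rng = np.random.default_rng(5)
        params = net.init_params(rng)
        x = np.random.default_rng(6).uniform(size=(1, 32, 32)).astype(np.float32)
        a = net.forward(params, x, x).data
        b = net.forward(params, x, x).data
        np.testing.assert_array_equal(a, b)


class TestDenoiserNet:
    def test_zero_residual_branch_is_identity(self):
        net = DenoiserNet(TINY_DEN, 2)
        rng = np.random.default_rng(2)
        params = net.init_params(rng)
        params["fuse1.w"][:] = 0
        params["fuse1.b"][:] = 0
        u = rng.normal(size=(1, 2, 16, 16))
        out = net.forward(params, u)
        np.testing.assert_array_equal(out.data, u)

    @pytest.mark.parametrize("rates", [(1, 2), (1, 3, 5), (2, 4)])
    def test_output_shape_preserved_for_any_rates(self, rates):
        spec = DenoiserNetSpec(2, rates, 2, 2)
        net = DenoiserNet(spec, 2)
        params = net.init_params(np.random.default_rng(0))
        u = np.random.default_rng(1).normal(size=(1, 2, 32, 32))
        assert net.forward(params, u).shape == u.shape

    def test_single_branch_matches_1d_dilated_oracle(self):
        """A dilated 2-D branch applied to a row-constant input reduces to the
        1-D dilated convolution with equivalent zero padding, row by row."""
        r = 2
        k = 3
        rng = np.random.default_rng(3)
        row = rng.normal(size=24)
        x = np.tile(row, (16, 1))[None, None]  # (1,1,16,24), constant per column
        w1d = rng.normal(size=k)
        w = np.zeros((1, 1, k, k))
        w[0, 0, k // 2, :] = w1d  # only the along-row taps are active
        from splitreg._engine import conv_nd

        out = conv_nd(x, w, None, dilation=r, padding=r * (k - 1) // 2).data[0, 0, 8]
        padded = np.concatenate([np.zeros(r), row, np.zeros(r)])
        expect = dilated_conv_1d(padded, w1d, r)
        np.testing.assert_allclose(out, expect, atol=1e-12)

    def test_receptive_field_grows_with_dilation_rate(self):
        base = np.zeros((1, 2, 33, 33))
        widths = {}
        for rates in [(1, 2), (1, 6)]:
            spec = DenoiserNetSpec(2, rates, 2, 2)
            net = DenoiserNet(spec, 2)
            params = net.init_params(np.random.default_rng(7))
            bumped = base.copy()
            bumped[0, 0, 16, 16] = 1.0
            diff = np.abs(
                net.forward(params, bumped).data - net.forward(params, base).data
            ).sum(axis=(0, 1))
            affected = np.argwhere(diff > 1e-12)
            widths[rates] = np.abs(affected - 16).max()
        assert widths[(1, 6)] > widths[(1, 2)]


class TestGradients:
    @staticmethod
    def _flat_grad_check(forward, params, rtol=1e-2):
        names = sorted(params)
        wrapped = {k: Tensor(params[k].copy(), needs_grad=True) for k in names}
        forward(wrapped).backward()
        rng = np.random.default_rng(0)
        worst = 0.0
        eps = 1e-5
        for k in names:
            flat_idx = rng.choice(params[k].size, size=min(6, params[k].size), replace=False)
            for fi in flat_idx:
                i = np.unravel_index(fi, params[k].shape)
                pp = {n: params[n].copy() for n in names}
                pp[k][i] += eps
                up = forward({n: Tensor(pp[n]) for n in names}).data
                pm = {n: params[n].copy() for n in names}
                pm[k][i] -= eps
                down = forward({n: Tensor(pm[n]) for n in names}).data
                num = (up - down) / (2 * eps)
                ana = wrapped[k].grad[i]
                worst = max(worst, abs(ana - num) / (abs(num) + 1e-8))
        assert worst <= rtol

    def test_similarity_net_gradcheck(self):
        net = SimilarityNet(TINY_SIM, 2)
        assert net.param_count() <= 500
        rng = np.random.default_rng(9)
        params = net.init_params(rng, np.float64)
        params["head1.w"] = rng.normal(0, 0.05, size=params["head1.w"].shape)
        fixed = rng.uniform(size=(1, 16, 16))
        moving = rng.uniform(size=(1, 16, 16))
        target = rng.normal(size=(1, 2, 16, 16))
        self._flat_grad_check(
            lambda p: tsum(mul(net.forward(p, fixed, moving), target)), params
        )

    def test_denoiser_net_gradcheck(self):
        net = DenoiserNet(TINY_DEN, 2)
        assert net.param_count() <= 500
        rng = np.random.default_rng(10)
        params = net.init_params(rng, np.float64)
        params["fuse1.w"] = rng.normal(0, 0.05, size=params["fuse1.w"].shape)
        u = rng.normal(size=(1, 2, 16, 16))
        target = rng.normal(size=(1, 2, 16, 16))
        self._flat_grad_check(
            lambda p: tsum(mul(net.forward(p, u), target)), params
        )


class TestSpecValidation:
    def test_encoder_stage_count(self):
        with pytest.raises(ValueError):
            SimilarityNetSpec(encoder_channels=(8, 8, 8))

    def test_denoiser_needs_two_distinct_rates(self):
        with pytest.raises(ValueError):
            DenoiserNetSpec(dilation_rates=(2,))
        with pytest.raises(ValueError):
            DenoiserNetSpec(dilation_rates=(2, 2))
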