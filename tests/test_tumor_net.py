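"""Structure and behaviour of the Kidney Tumor 3D UNet."""

import numpy as np
import pytest

from renalseg.nn import dice_ce_loss
from renalseg.tumor_net import (
    AttentionGate,
    ResidualBlock,
    TumorNet,
    TumorNetConfig,
    build_tumor_net,
    tiny_tumor_config,
)


@pytest.fixture(scope="module")
def shrunken_net():
    cfg = TumorNetConfig(n_stages=3, channels=(4, 8, 16), residual_blocks=(1, 2, 2),
                         patch_size=(16, 16, 16), batch_size=1, seed=7)
    return build_tumor_net(cfg)


class TestArchitecture:
    def test_default_config_matches_reference_architecture(self):
        cfg = TumorNetConfig()
        net = build_tumor_net(cfg)
        rows = net.describe()
        assert len(rows) == 6
        assert [r["channels"] for r in rows] == [32, 64, 128, 256, 320, 320]
        assert [r["residual_blocks"] for r in rows] == [1, 3, 4, 6, 6, 6]
        assert rows[-1]["output_extent"] == (6, 4, 4)  # 192/32, 128/32, 128/32
        # encoder truly holds that many residual units per stage
        assert [len(blocks) for blocks in net.encoder] == [1, 3, 4, 6, 6, 6]

    def test_shape_contract_and_probability_range(self, shrunken_net, rng):
        x = rng.standard_normal((1, 16, 16, 16)).astype(np.float32)
        y = shrunken_net(x)
        assert y.shape == (1, 16, 16, 16)
        assert 0.0 < y.min() and y.max() < 1.0

    def test_indivisible_patch_rejected_at_config(self):
        with pytest.raises(ValueError, match="divisible"):
            TumorNetConfig(patch_size=(100, 128, 128))

    def test_indivisible_input_rejected_at_forward(self, shrunken_net, rng):
        with pytest.raises(ValueError, match="divisible"):
            shrunken_net(rng.standard_normal((1, 18, 16, 16)).astype(np.float32))

    def test_attention_gates_add_parameters(self):
        base = dict(n_stages=3, channels=(4, 8, 16), residual_blocks=(1, 1, 1),
                    patch_size=(16, 16, 16), batch_size=1)
        with_gates = build_tumor_net(TumorNetConfig(attention_gates=True, **base))
        without = build_tumor_net(TumorNetConfig(attention_gates=False, **base))
        assert with_gates.n_parameters() > without.n_parameters()

    def test_parameter_count_is_pure_function_of_config(self):
        cfg = tiny_tumor_config(seed=3)
        a = build_tumor_net(cfg)
        b = build_tumor_net(cfg)
        assert a.n_parameters() == b.n_parameters()
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert pa.data.shape == pb.data.shape
            np.testing.assert_array_equal(pa.data, pb.data)  # same seed

    def test_eval_forward_is_deterministic(self, shrunken_net, rng):
        x = rng.standard_normal((1, 16, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(shrunken_net(x), shrunken_net(x))


class TestResidualBlock:
    def test_zeroed_weights_reduce_to_activation_of_skip(self, rng):
        blk = ResidualBlock(3, 3, slope=0.01, rng=rng, dtype=np.float64)
        for p in blk.parameters():
            if p.name.endswith(".w") or p.name.endswith(".b"):
                p.data[...] = 0.0
        x = rng.standard_normal((3, 4, 4, 4))
        y = blk(x)
        expected = np.where(x >= 0, x, 0.01 * x)
        np.testing.assert_allclose(y, expected, atol=1e-12)

    def test_stacking_preserves_spatial_extent(self, rng):
        x = rng.standard_normal((4, 6, 6, 6)).astype(np.float32)
        h = x
        blocks = [ResidualBlock(4, 4, rng=rng) for _ in range(4)]
        for b in blocks:
            h = b(h)
        assert h.shape == x.shape

    def test_gradient_reaches_input_through_deep_stack(self, rng):
        blocks = [ResidualBlock(2, 2, rng=rng, dtype=np.float64) for _ in range(6)]
        x = rng.standard_normal((2, 4, 4, 4))
        h = x
        for b in blocks:
            h = b(h, train=True)
        g = np.ones_like(h)
        for b in reversed(blocks):
            g = b.backward(g)
        assert np.linalg.norm(g) > 0


class TestAttentionGate:
    def test_zero_preactivation_halves_skip(self, rng):
        gate = AttentionGate(2, 3, inter_ch=2, rng=rng, dtype=np.float64)
        for p in gate.parameters():
            p.data[...] = 0.0  # psi output 0 -> sigmoid(0) = 0.5
        skip = rng.standard_normal((2, 4, 4, 4))
        gating = rng.standard_normal((3, 2, 2, 2))
        out = gate.forward_pair(skip, gating)
        np.testing.assert_allclose(out, skip * 0.5, atol=1e-12)

    def test_large_positive_preactivation_passes_skip_through(self, rng):
        gate = AttentionGate(2, 3, inter_ch=2, rng=rng, dtype=np.float64)
        for p in gate.parameters():
            p.data[...] = 0.0
        gate.psi.bias.data[...] = 50.0  # saturate the sigmoid
        skip = rng.standard_normal((2, 4, 4, 4))
        gating = rng.standard_normal((3, 2, 2, 2))
        np.testing.assert_allclose(gate.forward_pair(skip, gating), skip, rtol=1e-6)

    def test_alpha_matches_elementwise_oracle_on_toy_field(self, rng):
        gate = AttentionGate(1, 1, inter_ch=1, rng=rng, dtype=np.float64)
        skip = rng.standard_normal((1, 2, 2, 2))
        gating = rng.standard_normal((1, 1, 1, 1))
        alpha = gate.coefficients(skip, gating)
        # hand-rolled: alpha = sigmoid(psi(lrelu(wx*skip + wg*up(gate))))
        wx = gate.w_skip.weight.data[0, 0, 0, 0, 0]
        bx = gate.w_skip.bias.data[0]
        wg = gate.w_gate.weight.data[0, 0, 0, 0, 0]
        bg = gate.w_gate.bias.data[0]
        wp = gate.psi.weight.data[0, 0, 0, 0, 0]
        bp = gate.psi.bias.data[0]
        up = np.repeat(np.repeat(np.repeat(gating, 2, 1), 2, 2), 2, 3)
        pre = wx * skip + bx + wg * up + bg
        pre = np.where(pre >= 0, pre, 0.01 * pre)
        expected = 1 / (1 + np.exp(-(wp * pre + bp)))
        np.testing.assert_allclose(alpha, expected, rtol=1e-10)
        assert np.all((alpha > 0) & (alpha < 1))


class TestWholeNetGradients:
    def test_finite_difference_gradcheck(self):
        cfg = TumorNetConfig(n_stages=2, channels=(3, 5), residual_blocks=(1, 2),
                             patch_size=(4, 4, 4), batch_size=1,
                             dtype="float64", seed=3)
        net = build_tumor_net(cfg)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((1, 4, 4, 4))
        t = (rng.random((4, 4, 4)) > 0.5).astype(float)

        net.zero_grad()
        p = net(x, train=True)
        _, g = dice_ce_loss(p[0], t, return_grad=True)
        gx = net.backward(g[None])

        eps = 1e-6
        for idx in [(0, 0, 0, 0), (0, 1, 2, 3), (0, 3, 3, 1)]:
            xp = x.copy(); xp[idx] += eps
            xm = x.copy(); xm[idx] -= eps
            num = (dice_ce_loss(net(xp)[0], t) - dice_ce_loss(net(xm)[0], t)) / (2 * eps)
            assert gx[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)

        chooser = np.random.default_rng(1)
        params = net.parameters()
        for pi in chooser.choice(len(params), size=8, replace=False):
            par = params[pi]
            flat = par.data.ravel()
            j = int(chooser.integers(0, flat.size))
            orig = flat[j]
            flat[j] = orig + eps
            lp = dice_ce_loss(net(x)[0], t)
            flat[j] = orig - eps
            lm = dice_ce_loss(net(x)[0], t)
            flat[j] = orig
            num = (lp - lm) / (2 * eps)
            ana = par.grad.ravel()[j]
            assert ana == pytest.approx(num, rel=5e-3, abs=1e-6)
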