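"""Edge guidance / aggregation against per-pixel hand evaluations."""

import numpy as np
import pytest

from edgeflow.config import ConfigurationError
from edgeflow.edge import (
    EdgeAggregation,
    EdgeAttentionPair,
    EdgeGuidance,
    SimpleAggregation,
)
from edgeflow.nn import SqueezeExcite, Tensor


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestGuidanceAttention:
    def test_symmetric_weights_give_uniform_attention(self, rng):
        """Order-invariant conv weights force E1 = E2, hence both weights 0.5."""
        egm = EdgeGuidance(1, 1, rng=rng)
        w = rng.normal()
        for conv in (egm.att1, egm.att2):
            conv.weight.data = np.full((1, 2, 1, 1), w)
            conv.bias.data = np.zeros(1)
        att = egm.attention(Tensor(rng.normal(size=(1, 1, 4, 4))),
                            Tensor(rng.normal(size=(1, 1, 2, 2))))
        assert np.allclose(att.E1.data, att.E2.data)
        assert np.allclose(att.E1_prime.data, 0.5)
        assert np.allclose(att.E2_prime.data, 0.5)

    def test_attention_weights_sum_to_one_any_weights(self, rng):
        for _ in range(5):
            egm = EdgeGuidance(2, 3, rng=rng)
            att = egm.attention(Tensor(rng.normal(size=(2, 2, 8, 8))),
                                Tensor(rng.normal(size=(2, 3, 4, 4))))
            total = att.E1_prime.data + att.E2_prime.data
            assert np.allclose(total, 1.0, atol=1e-6)
            assert (att.E_att.data >= 0).all() and (att.E_att.data <= 1).all()

    def test_attention_matches_per_pixel_hand_evaluation(self, rng):
        """2x2 single-channel toy with hand-set conv weights."""
        egm = EdgeGuidance(1, 1, rng=rng)
        egm.proj.weight.data = np.array([[[[1.5]]]])
        egm.proj.bias.data = np.array([0.25])
        egm.att1.weight.data = np.array([[[[0.7]], [[-0.3]]]])
        egm.att1.bias.data = np.array([0.1])
        egm.att2.weight.data = np.array([[[[0.2]], [[0.9]]]])
        egm.att2.bias.data = np.array([-0.4])
        F1 = rng.normal(size=(1, 1, 4, 4))
        F2 = rng.normal(size=(1, 1, 2, 2))
        att = egm.attention(Tensor(F1), Tensor(F2))
        for i in range(2):
            for j in range(2):
                f1p = 1.5 * F1[0, 0, 2 * i : 2 * i + 2, 2 * j : 2 * j + 2].mean() + 0.25
                e1 = 0.7 * f1p - 0.3 * F2[0, 0, i, j] + 0.1
                e2 = 0.2 * F2[0, 0, i, j] + 0.9 * f1p - 0.4
                z = np.exp([e1, e2] - np.max([e1, e2]))
                assert att.E1_prime.data[0, 0, i, j] == pytest.approx(z[0] / z.sum(), abs=1e-10)

    def test_mismatched_batch_rejected(self, rng):
        egm = EdgeGuidance(1, 1, rng=rng)
        with pytest.raises(ValueError):
            egm.attention(Tensor(np.zeros((1, 1, 4, 4))), Tensor(np.zeros((2, 1, 2, 2))))


class TestGuidanceFusion:
    def _pair(self, e1, f1d):
        e1 = Tensor(e1)
        return EdgeAttentionPair(
            F1_down=Tensor(f1d), E1=e1, E2=e1, E_att=e1,
            E1_prime=e1, E2_prime=Tensor(1.0 - e1.data),
        )

    def test_degenerate_attention_returns_f1(self, rng):
        f1d = rng.normal(size=(1, 3, 2, 2))
        att = self._pair(np.ones((1, 1, 2, 2)), f1d)
        out = EdgeGuidance.fuse(att, Tensor(rng.normal(size=(1, 3, 2, 2))))
        assert np.allclose(out.data, f1d)

    def test_equal_attention_returns_mean(self, rng):
        f1d = rng.normal(size=(1, 3, 2, 2))
        f2 = rng.normal(size=(1, 3, 2, 2))
        att = self._pair(np.full((1, 1, 2, 2), 0.5), f1d)
        out = EdgeGuidance.fuse(att, Tensor(f2))
        assert np.allclose(out.data, 0.5 * (f1d + f2))

    def test_fusion_matches_elementwise_loop(self, rng):
        """Random 3x3 toy: convex blend broadcast over channels."""
        f1d = rng.normal(size=(1, 2, 3, 3))
        f2 = rng.normal(size=(1, 2, 3, 3))
        w = rng.uniform(size=(1, 1, 3, 3))
        out = EdgeGuidance.fuse(self._pair(w, f1d), Tensor(f2)).data
        for c in range(2):
            for i in range(3):
                for j in range(3):
                    expect = w[0, 0, i, j] * f1d[0, c, i, j] + (1 - w[0, 0, i, j]) * f2[0, c, i, j]
                    assert out[0, c, i, j] == pytest.approx(expect, abs=1e-12)


class TestChannelAttention:
    def test_identical_channels_stay_identical_with_symmetric_weights(self, rng):
        se = SqueezeExcite(4, 2, rng=rng)
        se.fc1.weight.data = np.ones_like(se.fc1.weight.data) * 0.3
        se.fc1.bias.data[:] = 0.1
        se.fc2.weight.data = np.ones_like(se.fc2.weight.data) * -0.2
        se.fc2.bias.data[:] = 0.05
        x = np.tile(rng.normal(size=(1, 1, 3, 3)), (1, 4, 1, 1))
        out = se(Tensor(x)).data
        for c in range(1, 4):
            assert np.allclose(out[:, c], out[:, 0])

    def test_gate_range_and_spatially_constant_ratio(self, rng):
        se = SqueezeExcite(4, 4, rng=rng)
        x = rng.normal(size=(2, 4, 5, 5)) + 3.0  # keep inputs nonzero
        gate = se.gate(Tensor(x)).data
        assert (gate > 0).all() and (gate < 1).all()
        ratio = se(Tensor(x)).data / x
        assert np.allclose(ratio, ratio[:, :, :1, :1], atol=1e-9)

    def test_two_channel_toy_matches_closed_form(self, rng):
        se = SqueezeExcite(2, 2, rng=rng)
        w1 = np.array([0.4, -0.7])
        b1, b2 = 0.2, -0.1
        w2 = np.array([1.1, 0.6])
        se.fc1.weight.data = w1.reshape(1, 2, 1, 1)
        se.fc1.bias.data = np.array([b1])
        se.fc2.weight.data = w2.reshape(2, 1, 1, 1)
        se.fc2.bias.data = np.array([b2, b2])
        x = np.array([[[[2.0]], [[-1.0]]]])
        h = max(0.0, w1 @ np.array([2.0, -1.0]) + b1)
        gate = _sigmoid(w2 * h + b2)
        out = se(Tensor(x)).data
        assert out[0, 0, 0, 0] == pytest.approx(2.0 * gate[0], abs=1e-12)
        assert out[0, 1, 0, 0] == pytest.approx(-1.0 * gate[1], abs=1e-12)

    def test_reduction_must_divide_channels(self, rng):
        with pytest.raises(ValueError):
            SqueezeExcite(6, 4, rng=rng)


class TestAggregation:
    def test_zero_conv_gives_exact_residual_identity(self, rng):
        eam = EdgeAggregation(4, 8, reduction=2, rng=rng, zero_init=True)
        f4 = rng.normal(size=(2, 8, 2, 2))
        out = eam(Tensor(rng.normal(size=(2, 4, 8, 8))), Tensor(f4))
        assert np.array_equal(out.data, f4)

    def test_output_shape_equals_f4(self, rng):
        eam = EdgeAggregation(4, 8, reduction=2, rng=rng)
        out = eam(Tensor(rng.normal(size=(1, 4, 8, 8))), Tensor(rng.normal(size=(1, 8, 2, 2))))
        assert out.shape == (1, 8, 2, 2)

    def test_toy_matches_hand_arithmetic(self, rng):
        """Center-tap conv makes GAP(F_cat)*F_cat + F4 computable by hand."""
        eam = EdgeAggregation(1, 1, reduction=1, rng=rng)
        # identity gate: fc weights zero -> gate = sigmoid(0) = 0.5
        eam.cab.fc1.weight.data[:] = 0.0
        eam.cab.fc1.bias.data[:] = 0.0
        eam.cab.fc2.weight.data[:] = 0.0
        eam.cab.fc2.bias.data[:] = 0.0
        eam.mix.weight.data[:] = 0.0
        eam.mix.weight.data[0, 0, 1, 1] = 0.8  # edge-feature tap
        eam.mix.weight.data[0, 1, 1, 1] = -0.5  # F4 tap
        eam.mix.bias.data[:] = 0.0
        edge = rng.normal(size=(1, 1, 2, 2))
        f4 = rng.normal(size=(1, 1, 2, 2))
        f_att = 0.5 * edge
        f_cat = 0.8 * f_att - 0.5 * f4
        expect = f_cat.mean() * f_cat + f4
        out = eam(Tensor(edge), Tensor(f4)).data
        assert np.allclose(out, expect, atol=1e-12)

    def test_simple_aggregators_identity_at_init(self, rng):
        f4 = rng.normal(size=(1, 6, 2, 2))
        edge = rng.normal(size=(1, 3, 8, 8))
        for mode in ("add", "mul"):
            agg = SimpleAggregation(3, 6, mode, rng=rng)
            assert np.array_equal(agg(Tensor(edge), Tensor(f4)).data, f4)

    def test_unknown_aggregation_mode_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            SimpleAggregation(3, 6, "concat", rng=rng)
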