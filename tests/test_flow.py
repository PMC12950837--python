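"""Flow correctness: invertibility, exact log-determinants, likelihood loss."""

import numpy as np
import pytest

from edgeflow.config import ConfigurationError, FlowConfig
from edgeflow.flow import (
    CouplingBlock,
    FlowDecoder,
    FlowOutput,
    LOG_2PI,
    flow_nll_loss,
    per_position_logprob,
    positional_encoding,
)
from edgeflow.nn import Adam, Tensor


def perturb(module, rng, scale=0.5):
    """Knock the zero-init subnets away from identity."""
    for p in module.parameters():
        p.data = p.data + rng.normal(0.0, scale, p.data.shape)


def numeric_logdet(fn, z, eps=1e-4):
    """Central finite-difference Jacobian log|det| of a vector map."""
    d = z.size
    J = np.zeros((d, d))
    for i in range(d):
        zp, zm = z.copy(), z.copy()
        zp[i] += eps
        zm[i] -= eps
        J[:, i] = (fn(zp) - fn(zm)) / (2 * eps)
    return np.linalg.slogdet(J)[1]


class TestPositionalEncoding:
    def test_deterministic_single_position(self):
        a = positional_encoding(1, 1, 8)
        b = positional_encoding(1, 1, 8)
        assert a.shape == (8, 1, 1)
        assert np.array_equal(a, b)
        assert np.abs(a).max() <= 1.0

    def test_distinct_positions_distinct_vectors(self):
        enc = positional_encoding(4, 4, 128).reshape(128, -1).T
        for i in range(16):
            for j in range(i + 1, 16):
                assert not np.allclose(enc[i], enc[j])

    def test_concatenation_of_1d_encodings(self):
        """2-D encoding at (r, c) is [enc1d(r), enc1d(c)]."""
        dim = 16
        half = dim // 2

        def enc1d(pos):
            i = np.arange(half // 2)
            freq = 1.0 / (10000.0 ** (2.0 * i / half))
            out = np.empty(half)
            out[0::2] = np.sin(pos * freq)
            out[1::2] = np.cos(pos * freq)
            return out

        enc = positional_encoding(3, 5, dim)
        for r in range(3):
            for c in range(5):
                assert np.allclose(enc[:, r, c], np.concatenate([enc1d(r), enc1d(c)]))

    def test_dim_must_divide_four(self):
        with pytest.raises(ConfigurationError):
            positional_encoding(2, 2, 6)


class TestCouplingBlock:
    def test_identity_init_is_pure_permutation(self, rng):
        block = CouplingBlock(4, 8, rng=rng)
        z = rng.normal(size=(2, 4, 3, 3))
        cond = np.zeros((2, 8, 3, 3))
        out = block.forward(Tensor(z), Tensor(cond))
        assert np.allclose(out.u.data, z[:, block.perm])
        assert np.allclose(out.logdet.data, 0.0)

    @pytest.mark.parametrize("width", [2, 3, 4, 6, 8])
    def test_round_trip_inversion(self, width, rng):
        block = CouplingBlock(width, 8, rng=rng)
        perturb(block, rng)
        z = rng.normal(size=(2, width, 4, 4))
        cond = rng.normal(size=(2, 8, 4, 4))
        u = block.forward(Tensor(z), Tensor(cond)).u.data
        back = block.inverse(u, cond)
        assert np.abs(back - z).max() < 1e-5

    @pytest.mark.parametrize("width", [2, 4, 6, 8])
    def test_logdet_matches_finite_difference_jacobian(self, width, rng):
        block = CouplingBlock(width, 4, rng=rng)
        perturb(block, rng)
        z0 = rng.normal(size=width)
        cond = rng.normal(size=(1, 4, 1, 1))

        def fn(z):
            out = block.forward(Tensor(z.reshape(1, width, 1, 1)), Tensor(cond))
            return out.u.data.ravel()

        analytic = block.forward(Tensor(z0.reshape(1, width, 1, 1)), Tensor(cond)).logdet.data.item()
        assert abs(analytic - numeric_logdet(fn, z0)) < 1e-4

    def test_width_one_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            CouplingBlock(1, 4, rng=rng)


class TestDecoder:
    def test_identity_init_zero_logdet(self, rng):
        dec = FlowDecoder(4, FlowConfig(depth=8, condition_dim=8), rng=rng)
        out = dec(Tensor(rng.normal(size=(1, 4, 2, 2))))
        assert np.allclose(out.logdet.data, 0.0)

    def test_depth_is_eight_by_default(self, rng):
        dec = FlowDecoder(4, FlowConfig(condition_dim=8), rng=rng)
        assert dec.depth == 8

    def test_composed_round_trip(self, rng):
        dec = FlowDecoder(6, FlowConfig(depth=8, condition_dim=8), rng=rng)
        perturb(dec, rng, scale=0.3)
        z = rng.normal(size=(2, 6, 3, 3))
        u = dec(Tensor(z)).u.data
        assert np.abs(dec.inverse(u) - z).max() < 1e-5

    def test_composed_logdet_matches_finite_difference(self, rng):
        dec = FlowDecoder(4, FlowConfig(depth=8, condition_dim=4), rng=rng)
        perturb(dec, rng, scale=0.3)
        z0 = rng.normal(size=4)
        cond = dec.condition(1, 1, 1).data

        def fn(z):
            return dec(Tensor(z.reshape(1, 4, 1, 1)), Tensor(cond)).u.data.ravel()

        analytic = dec(Tensor(z0.reshape(1, 4, 1, 1)), Tensor(cond)).logdet.data.item()
        assert abs(analytic - numeric_logdet(fn, z0)) < 1e-3

    def test_wrong_width_rejected(self, rng):
        dec = FlowDecoder(4, FlowConfig(condition_dim=8), rng=rng)
        with pytest.raises(ConfigurationError):
            dec(Tensor(np.zeros((1, 6, 2, 2))))


class TestLoss:
    def test_origin_loss_is_zero(self):
        out = FlowOutput(u=Tensor(np.zeros((1, 2, 2, 2))), logdet=Tensor(np.zeros((1, 2, 2))))
        assert flow_nll_loss(out).data.item() == 0.0

    def test_unit_vector_loss(self):
        out = FlowOutput(u=Tensor(np.array([1.0, 1.0]).reshape(1, 2, 1, 1)),
                         logdet=Tensor(np.zeros((1, 1, 1))))
        assert flow_nll_loss(out).data.item() == pytest.approx(1.0)

    def test_empty_field_rejected(self):
        out = FlowOutput(u=Tensor(np.zeros((1, 2, 0, 0))), logdet=Tensor(np.zeros((1, 0, 0))))
        with pytest.raises(ValueError):
            flow_nll_loss(out)

    def test_affine_map_matches_change_of_variables_oracle(self, rng):
        """u = A z: loss+const equals the exact negative mean Gaussian log-density."""
        A = rng.normal(size=(2, 2))
        z = rng.normal(size=(5, 2))
        u = z @ A.T
        logdet = np.log(abs(np.linalg.det(A)))
        out = FlowOutput(u=Tensor(u.T[None, :, :, None].reshape(1, 2, 5, 1)),
                         logdet=Tensor(np.full((1, 5, 1), logdet)))
        loss = flow_nll_loss(out).data.item()
        # independent oracle: mean -log p(z) with p from the change of variables
        log_p = -0.5 * (u**2).sum(axis=1) - LOG_2PI + logdet
        assert loss == pytest.approx(-log_p.mean() - LOG_2PI, abs=1e-10)

    def test_loss_decreases_over_training(self, rng):
        dec = FlowDecoder(4, FlowConfig(depth=4, condition_dim=4), rng=rng)
        z = Tensor(rng.normal(size=(8, 4, 2, 2)) * 2.0 + 1.0)
        opt = Adam(list(dec.parameters()), lr=5e-3)
        losses = []
        for _ in range(50):
            opt.zero_grad()
            L = flow_nll_loss(dec(z))
            L.backward()
            opt.step()
            losses.append(L.data.item())
        assert losses[-1] < losses[0]
        # monotone trend: mean of last 10 clearly below mean of first 10
        assert np.mean(losses[-10:]) < np.mean(losses[:10])

    def test_density_integrates_to_one_by_quadrature(self, rng):
        """exp(log p) over a 2-D grid sums to ~1 for a perturbed trained flow."""
        dec = FlowDecoder(2, FlowConfig(depth=4, condition_dim=4), rng=rng)
        perturb(dec, rng, scale=0.3)
        data = Tensor(rng.normal(size=(64, 2, 1, 1)) * 0.8)
        opt = Adam(list(dec.parameters()), lr=5e-3)
        for _ in range(30):
            opt.zero_grad()
            L = flow_nll_loss(dec(data))
            L.backward()
            opt.step()
        lim, n = 8.0, 120
        grid = np.linspace(-lim, lim, n)
        xx, yy = np.meshgrid(grid, grid)
        pts = np.stack([xx.ravel(), yy.ravel()], axis=1).reshape(-1, 2, 1, 1)
        cond = np.broadcast_to(dec.condition(1, 1, 1).data, (len(pts), 4, 1, 1)).copy()
        out = dec(Tensor(pts), Tensor(cond))
        dens = np.exp(per_position_logprob(out)).ravel()
        integral = dens.sum() * (2 * lim / (n - 1)) ** 2
        assert integral == pytest.approx(1.0, abs=0.02)
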