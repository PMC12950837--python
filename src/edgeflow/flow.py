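"""Conditional normalizing-flow decoders over per-position feature vectors.

Each pyramid scale k gets an independent decoder g^k: a stack of affine
coupling blocks mapping the feature field z^k to a latent field u^k that is
trained toward a standard normal, conditioned at every spatial position on a
fixed 2-D sinusoidal positional encoding c^k.  Exact log-determinants make the
per-position log-likelihood

    log p(z) = -||u||^2 / 2 + log|det J| - (d/2) log 2pi

available in closed form, which is what both the training loss and the anomaly
score consume.

Coupling internals follow the common conditional-flow conventions: channels
are split in halves after a fixed random permutation, the transformed half
receives scale/shift predicted from the other half concatenated with the
condition, the raw log-scale is soft-clamped through
``clamp * (2/pi) * atan(raw / clamp)`` (bound 1.9), and the subnet is two 3x3
convolutions whose last layer starts at zero so every block begins as the
identity (u = permuted z, log-det 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .config import ConfigurationError, FlowConfig
from .nn import Conv2d, Module, Tensor, concat
from .nn import functional as F

Array = np.ndarray

LOG_2PI = float(np.log(2.0 * np.pi))


def positional_encoding(height: int, width: int, dim: int) -> Array:
    """Fixed 2-D sinusoidal condition field, shape (dim, height, width).

    The first half of the channels encodes the row index, the second half the
    column index, each with the standard interleaved sin/cos at geometric
    frequencies; values lie in [-1, 1] and distinct positions map to distinct
    vectors.
    """
    if dim % 4:
        raise ConfigurationError("condition dim must be divisible by 4")
    half = dim // 2

    def encode_1d(n: int) -> Array:  # (half, n)
        pos = np.arange(n)[None, :]
        i = np.arange(half // 2)[:, None]
        freq = 1.0 / (10000.0 ** (2.0 * i / half))
        ang = pos * freq
        enc = np.empty((half, n))
        enc[0::2] = np.sin(ang)
        enc[1::2] = np.cos(ang)
        return enc

    rows = encode_1d(height)  # (half, H)
    cols = encode_1d(width)  # (half, W)
    out = np.empty((dim, height, width))
    out[:half] = rows[:, :, None]
    out[half:] = cols[:, None, :]
    return out


@dataclass
class FlowOutput:
    """Latent field plus its accumulated per-position log |det J|."""

    u: Tensor  # (B, C, H, W)
    logdet: Tensor  # (B, H, W)


def _soft_clamp(raw: Tensor, clamp: float) -> Tensor:
    return (raw * (1.0 / clamp)).atan() * (clamp * 2.0 / np.pi)


class CouplingBlock(Module):
    """One conditional affine coupling layer with fixed channel permutation."""

    def __init__(self, channels: int, cond_dim: int, clamp: float = 1.9,
                 hidden_ratio: float = 1.0, rng: Optional[np.random.Generator] = None):
        if channels < 2:
            raise ConfigurationError("coupling needs at least 2 channels")
        rng = rng if rng is not None else np.random.default_rng()
        self.channels = channels
        self.clamp = float(clamp)
        self.perm = rng.permutation(channels)
        self.inv_perm = np.argsort(self.perm)
        self.c1 = channels // 2  # transformed half
        c2 = channels - self.c1  # conditioning half
        hidden = max(2, int(round(hidden_ratio * (c2 + cond_dim))))
        self.net1 = Conv2d(c2 + cond_dim, hidden, 3, padding=1, rng=rng)
        # zero-init last conv => identity transform at start
        self.net2 = Conv2d(hidden, 2 * self.c1, 3, padding=1, zero_init=True)

    def _scale_shift(self, x2: Tensor, cond: Tensor):
        h = self.net1(concat([x2, cond], axis=1)).relu()
        st = self.net2(h)
        s = _soft_clamp(st.narrow(1, 0, self.c1), self.clamp)
        t = st.narrow(1, self.c1, self.c1)
        return s, t

    def forward(self, z: Tensor, cond: Tensor) -> FlowOutput:
        zp = z.take(self.perm, axis=1)
        x1 = zp.narrow(1, 0, self.c1)
        x2 = zp.narrow(1, self.c1, self.channels - self.c1)
        s, t = self._scale_shift(x2, cond)
        u1 = x1 * s.exp() + t
        u = concat([u1, x2], axis=1)
        return FlowOutput(u=u, logdet=s.sum(axis=1))

    def inverse(self, u: Array, cond: Array) -> Array:
        """Exact inverse on plain arrays (no tape)."""
        u = np.asarray(u)
        u1 = Tensor(u[:, : self.c1])
        x2 = Tensor(u[:, self.c1 :])
        s, t = self._scale_shift(x2, Tensor(cond))
        x1 = (u1 - t) * (-s).exp()
        zp = np.concatenate([x1.data, x2.data], axis=1)
        return zp[:, self.inv_perm]


class FlowDecoder(Module):
    """Composition of coupling blocks for one scale; log-dets add up."""

    def __init__(self, channels: int, config: FlowConfig,
                 rng: Optional[np.random.Generator] = None):
        rng = rng if rng is not None else np.random.default_rng()
        self.channels = channels
        self.cond_dim = config.condition_dim
        self.blocks = [
            CouplingBlock(channels, config.condition_dim, clamp=config.clamp,
                          hidden_ratio=config.hidden_ratio, rng=rng)
            for _ in range(config.depth)
        ]

    @property
    def depth(self) -> int:
        return len(self.blocks)

    def condition(self, height: int, width: int, batch: int) -> Tensor:
        enc = positional_encoding(height, width, self.cond_dim)
        return Tensor(np.broadcast_to(enc[None], (batch, *enc.shape)).copy())

    def forward(self, z: Tensor, cond: Optional[Tensor] = None) -> FlowOutput:
        if z.shape[1] != self.channels:
            raise ConfigurationError(
                f"decoder built for width {self.channels}, got {z.shape[1]}"
            )
        if cond is None:
            cond = self.condition(z.shape[2], z.shape[3], z.shape[0])
        logdet = Tensor(np.zeros((z.shape[0], z.shape[2], z.shape[3])))
        x = z
        for block in self.blocks:
            out = block.forward(x, cond)
            x = out.u
            logdet = logdet + out.logdet
        return FlowOutput(u=x, logdet=logdet)

    def inverse(self, u: Array, cond: Optional[Array] = None) -> Array:
        u = np.asarray(u)
        if cond is None:
            cond = self.condition(u.shape[2], u.shape[3], u.shape[0]).data
        x = u
        for block in reversed(self.blocks):
            x = block.inverse(x, cond)
        return x

    def __call__(self, z: Tensor, cond: Optional[Tensor] = None) -> FlowOutput:
        return self.forward(z, cond)


def flow_nll_loss(out: FlowOutput) -> Tensor:
    """Mean over positions of ||u||^2/2 - logdet (additive constant dropped)."""
    if out.u.data.size == 0:
        raise ValueError("empty latent field")
    sq = (out.u * out.u).sum(axis=1) * 0.5  # (B, H, W)
    return (sq - out.logdet).mean()


def per_position_logprob(out: FlowOutput) -> Array:
    """Normalized per-position log-density, shape (B, H, W)."""
    d = out.u.shape[1]
    sq = 0.5 * (out.u.data**2).sum(axis=1)
    return -sq + out.logdet.data - 0.5 * d * LOG_2PI
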