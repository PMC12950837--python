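"""Layer containers with named-parameter registry for checkpointing."""

from __future__ import annotations

from typing import Dict, Iterator, Optional, Tuple

import numpy as np

from . import functional as F
from .tensor import Tensor


class Module:
    """Base class: child modules and parameters are discovered by attribute walk."""

    def parameters(self) -> Iterator[Tensor]:
        for _, p in self.named_parameters():
            yield p

    def named_parameters(self, prefix: str = "") -> Iterator[Tuple[str, Tensor]]:
        for name, val in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield full, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=full + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{full}.{i}.")

    def state_dict(self) -> Dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch; missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Conv2d(Module):
    """Learnable 2-D convolution; He-normal init, optional zero init."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: Optional[np.random.Generator] = None,
        zero_init: bool = False,
    ):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        if zero_init:
            w = np.zeros((out_channels, in_channels, kernel_size, kernel_size))
        else:
            rng = rng if rng is not None else np.random.default_rng()
            fan_in = in_channels * kernel_size * kernel_size
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel_size, kernel_size))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class SqueezeExcite(Module):
    """Channel-attention block: global squeeze, bottleneck, sigmoid gate.

    The gate re-weights channels; with `reduction` r the bottleneck maps
    C -> C/r -> C. C must be divisible by r.
    """

    def __init__(self, channels: int, reduction: int, rng: Optional[np.random.Generator] = None):
        if channels < reduction or channels % reduction:
            raise ValueError(f"channels={channels} not divisible by reduction={reduction}")
        hidden = channels // reduction
        self.fc1 = Conv2d(channels, hidden, 1, rng=rng)
        self.fc2 = Conv2d(hidden, channels, 1, rng=rng)

    def gate(self, x: Tensor) -> Tensor:
        s = F.global_avg_pool(x)
        return self.fc2(self.fc1(s).relu()).sigmoid()

    def __call__(self, x: Tensor) -> Tensor:
        return x * self.gate(x)
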