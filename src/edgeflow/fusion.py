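"""Multi-scale flow fusion (MFF) and the convolution-complexity accounting.

The three shallower decoder outputs are average-pooled onto the deepest grid,
concatenated with the deepest output, squeezed through a two-conv bottleneck
(960 -> 240 -> 960 channels at the default widths), split back per scale and
redistributed: the shallow scales are upsampled and added residually onto the
original maps.  The second bottleneck conv starts at zero, so fusion begins as
an exact identity; with that residual-identity structure each scale keeps its
own coupling log-determinant and the fusion convs contribute none.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import ConfigurationError, FusionConfig
from .flow import FlowOutput
from .nn import Conv2d, Module, Tensor, concat
from .nn import functional as F


def pool_to_grid(x: Tensor, out_side: int) -> Tensor:
    """Average-pool a square map to `out_side`, kernel-3 scheme where feasible.

    Kernel 3 with stride in/out and the smallest padding in {0, 1} that lands
    exactly on the target side (the printed configuration: 32->4 and 16->4 use
    padding 0, 8->4 needs padding 1); when no such padding exists the exact
    block average (kernel = stride = in/out) is used instead.
    """
    in_side = x.shape[2]
    if in_side == out_side:
        return x
    if in_side % out_side:
        raise ConfigurationError(f"cannot pool side {in_side} to {out_side}")
    stride = in_side // out_side
    if in_side >= 3:  # zero padding would bias the mean on sub-kernel grids
        for pad in (0, 1):
            if (in_side + 2 * pad - 3) // stride + 1 == out_side:
                return F.avg_pool2d(x, 3, stride=stride, padding=pad)
    return F.avg_pool2d(x, stride, stride=stride)


@dataclass
class FusedOutputs:
    """Per-scale fused fields plus the pooled intermediates."""

    fused: List[FlowOutput]  # y_f^k with original logdets
    pooled: List[Tensor]  # y_AP^1..3 on the deepest grid


class MultiScaleFusion(Module):
    """Pool / concat / bottleneck / redistribute across the four scales."""

    def __init__(self, widths: Sequence[int], config: FusionConfig,
                 rng: Optional[np.random.Generator] = None):
        self.widths = tuple(widths)
        total = sum(widths)
        hidden = max(1, total // config.bottleneck_ratio)
        k = config.kernel_size
        self.upsample_mode = config.upsample
        self.conv1 = Conv2d(total, hidden, k, padding=k // 2, rng=rng)
        self.conv2 = Conv2d(hidden, total, k, padding=k // 2, zero_init=True)

    def fuse(self, outputs: Sequence[FlowOutput]) -> FusedOutputs:
        if len(outputs) != len(self.widths):
            raise ValueError(f"expected {len(self.widths)} scales")
        for out, w in zip(outputs, self.widths):
            if out.u.shape[1] != w:
                raise ValueError(
                    f"scale width {out.u.shape[1]} does not match configured {w}"
                )
        deep_side = outputs[-1].u.shape[2]
        pooled = [pool_to_grid(out.u, deep_side) for out in outputs[:-1]]
        cat = concat(pooled + [outputs[-1].u], axis=1)
        mixed = self.conv2(self.conv1(cat).relu())
        fused: List[FlowOutput] = []
        start = 0
        for k, (out, w) in enumerate(zip(outputs, self.widths)):
            part = mixed.narrow(1, start, w)
            start += w
            if k < len(self.widths) - 1:
                factor = out.u.shape[2] // deep_side
                part = F.upsample_nearest(part, factor)
            fused.append(FlowOutput(u=out.u + part, logdet=out.logdet))
        return FusedOutputs(fused=fused, pooled=pooled)

    def __call__(self, outputs: Sequence[FlowOutput]) -> FusedOutputs:
        return self.fuse(outputs)


def complexity_coefficient(egm_convs: int = 2, eam_convs: int = 1,
                           flow_blocks: int = 8, mff_convs: int = 2) -> int:
    """Summed multiplier of the C_in*C_out*H*W convolution term.

    Per-module contributions: each edge-guidance conv is pointwise (factor 1);
    each aggregation conv is 3x3 (factor 9); each coupling block carries two
    sets of double 3x3 convolutions (factor 2*(2*9) = 36 per block); each
    fusion conv is counted as 3x3 (factor 9).  The default configuration
    (2, 1, 8, 2) sums to 317.
    """
    counts = (egm_convs, eam_convs, flow_blocks, mff_convs)
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    return egm_convs * 1 + eam_convs * 9 + flow_blocks * 2 * (2 * 9) + mff_convs * 9
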