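"""Edge guidance and edge aggregation.

The edge guidance module (EGM) fuses the two shallowest pyramid levels: F1 is
average-pool downsampled to F2's grid and projected to F2's width (F1'); the
two concatenation orders (F1', F2) and (F2, F1') each pass through a learned
1x1 convolution producing single-channel attention fields E1 and E2; a two-way
softmax across the stacked pair yields convex weights E1', E2' (summing to one
at every position) and the fused edge feature is

    F_edge_fusion = E1' * F1' + E2' * F2

with the single-channel weights broadcast over feature channels.

The edge aggregation module (EAM) then injects that edge feature into the
deepest level: a squeeze-excitation channel-attention block re-weights
F_edge_fusion, the result is average-pooled to F4's grid, concatenated with F4
and mixed by a 3x3 convolution (F_cat); the aggregate is

    F_agg = GAP(F_cat) * F_cat + F4

whose residual form guarantees that zero-initialized convolutions leave F4
untouched — the ablated model is recovered exactly.

Two simpler aggregation baselines (elementwise add / mul after a zero-init 1x1
projection) are provided for the module-ablation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import ConfigurationError, EdgeConfig
from .nn import Conv2d, Module, SqueezeExcite, Tensor, concat
from .nn import functional as F


@dataclass
class EdgeAttentionPair:
    """Intermediate attention fields of the guidance module."""

    F1_down: Tensor  # F1 pooled+projected to F2's grid/width
    E1: Tensor  # pre-softmax, fine-detail order
    E2: Tensor  # pre-softmax, coarse-contour order
    E_att: Tensor  # stacked normalized weights, (B, 2, H, W)
    E1_prime: Tensor
    E2_prime: Tensor


class EdgeGuidance(Module):
    """EGM: interactive attention fusion of F1 and F2."""

    def __init__(self, c1: int, c2: int, rng: Optional[np.random.Generator] = None,
                 zero_init: bool = False):
        self.proj = Conv2d(c1, c2, 1, rng=rng, zero_init=zero_init)
        self.att1 = Conv2d(2 * c2, 1, 1, rng=rng, zero_init=zero_init)
        self.att2 = Conv2d(2 * c2, 1, 1, rng=rng, zero_init=zero_init)

    def attention(self, F1: Tensor, F2: Tensor) -> EdgeAttentionPair:
        if F1.shape[0] != F2.shape[0]:
            raise ValueError("F1/F2 batch dimensions differ")
        factor = F1.shape[2] // F2.shape[2]
        f1d = F.avg_pool2d(F1, factor) if factor > 1 else F1
        f1d = self.proj(f1d)
        e1 = self.att1(concat([f1d, F2], axis=1))
        e2 = self.att2(concat([F2, f1d], axis=1))
        e_att = F.softmax(concat([e1, e2], axis=1), axis=1)
        return EdgeAttentionPair(
            F1_down=f1d,
            E1=e1,
            E2=e2,
            E_att=e_att,
            E1_prime=e_att.narrow(1, 0, 1),
            E2_prime=e_att.narrow(1, 1, 1),
        )

    @staticmethod
    def fuse(att: EdgeAttentionPair, F2: Tensor) -> Tensor:
        """Convex per-position blend; weights broadcast over channels."""
        return att.E1_prime * att.F1_down + att.E2_prime * F2

    def __call__(self, F1: Tensor, F2: Tensor) -> Tensor:
        return self.fuse(self.attention(F1, F2), F2)


@dataclass
class AggregatedFeature:
    F_att: Tensor  # channel-attended edge feature
    F_cat: Tensor  # concat+conv mixture on F4's grid
    F_agg: Tensor  # final aggregate, same shape as F4


class EdgeAggregation(Module):
    """EAM: channel attention, spatial alignment, conv mixing, GAP-gated residual."""

    def __init__(self, c_edge: int, c4: int, reduction: int = 16,
                 rng: Optional[np.random.Generator] = None, zero_init: bool = False):
        if c_edge % reduction:
            raise ConfigurationError(
                f"edge-feature channels {c_edge} not divisible by cab reduction {reduction}"
            )
        self.cab = SqueezeExcite(c_edge, reduction, rng=rng)
        self.mix = Conv2d(c_edge + c4, c4, 3, padding=1, rng=rng, zero_init=zero_init)

    def aggregate(self, edge_feature: Tensor, F4: Tensor) -> AggregatedFeature:
        f_att = self.cab(edge_feature)
        factor = f_att.shape[2] // F4.shape[2]
        pooled = F.avg_pool2d(f_att, factor) if factor > 1 else f_att
        f_cat = self.mix(concat([pooled, F4], axis=1))
        f_agg = F.global_avg_pool(f_cat) * f_cat + F4
        return AggregatedFeature(F_att=f_att, F_cat=f_cat, F_agg=f_agg)

    def __call__(self, edge_feature: Tensor, F4: Tensor) -> Tensor:
        return self.aggregate(edge_feature, F4).F_agg


class SimpleAggregation(Module):
    """ADD / MUL aggregation baselines behind a zero-init 1x1 projection.

    add:  F4 + proj(pool(edge));  mul:  F4 * (1 + proj(pool(edge))).
    Both are the identity on F4 at init.
    """

    def __init__(self, c_edge: int, c4: int, mode: str,
                 rng: Optional[np.random.Generator] = None):
        if mode not in ("add", "mul"):
            raise ConfigurationError(f"unknown aggregation mode {mode!r}")
        self.mode = mode
        self.proj = Conv2d(c_edge, c4, 1, rng=rng, zero_init=True)

    def __call__(self, edge_feature: Tensor, F4: Tensor) -> Tensor:
        factor = edge_feature.shape[2] // F4.shape[2]
        pooled = F.avg_pool2d(edge_feature, factor) if factor > 1 else edge_feature
        p = self.proj(pooled)
        if self.mode == "add":
            return F4 + p
        return F4 * (p + 1.0)


def build_edge_path(widths, config: EdgeConfig, rng: Optional[np.random.Generator] = None):
    """Construct (EdgeGuidance | None, aggregation module | None) from config."""
    if not config.egm_enabled:
        return None, None
    egm = EdgeGuidance(widths[0], widths[1], rng=rng)
    if config.eam_enabled and config.aggregation == "eam":
        agg = EdgeAggregation(widths[1], widths[3], reduction=config.cab_reduction, rng=rng)
    else:
        mode = config.aggregation if config.aggregation in ("add", "mul") else "add"
        agg = SimpleAggregation(widths[1], widths[3], mode, rng=rng)
    return egm, agg
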