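"""Frozen convolutional feature extractor producing the four-level pyramid.

Two backbones are provided:

``table2-resnet18``
    A ResNet18-style extractor whose stem applies one extra spatial halving,
    so the four stage outputs sit at H/8, H/16, H/32 and H/64 with channel
    widths 64/128/256/512 (at 256x256 input: 32x32 ... 4x4).  With
    ``extra_stem_downsample=False`` the standard ResNet strides are used
    instead (stage 1 at H/4).

``tiny-test-backbone``
    A four-stage strided-conv extractor with configurable small widths, used
    for desk-scale experiments and tests; it follows the same H/8 ... H/64
    spatial scheme.

The extractor is deterministic given its weights.  By default the weights are
randomly initialized from the run seed (random frozen features are a
well-studied operating mode for flow-on-features detectors); a user-supplied
``.npz`` of named arrays can be loaded via ``backbone.weights_path``.
Batch-norm layers start as the identity (unit scale, zero shift, unit running
variance), which is exact for random-feature mode and is overwritten when
pretrained weights are loaded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .config import BackboneConfig, ConfigurationError
from .nn import Tensor
from .nn import functional as F

Array = np.ndarray


@dataclass
class FeaturePyramid:
    """Four feature maps at decreasing resolution and increasing width."""

    F1: Array
    F2: Array
    F3: Array
    F4: Array

    @property
    def levels(self) -> Tuple[Array, Array, Array, Array]:
        return (self.F1, self.F2, self.F3, self.F4)

    def __iter__(self):
        return iter(self.levels)


def _conv(x: Array, w: Array, stride: int, padding: int) -> Array:
    return F.conv2d(Tensor(x), Tensor(w), stride=stride, padding=padding).data


class _BN:
    """Inference-mode batch norm; identity at init."""

    def __init__(self, channels: int):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.mean = np.zeros(channels)
        self.var = np.ones(channels)

    def __call__(self, x: Array) -> Array:
        scale = self.gamma / np.sqrt(self.var + 1e-5)
        shift = self.beta - self.mean * scale
        return x * scale[None, :, None, None] + shift[None, :, None, None]

    def arrays(self) -> Dict[str, Array]:
        return {"gamma": self.gamma, "beta": self.beta, "mean": self.mean, "var": self.var}


def _he(rng: np.random.Generator, shape: Tuple[int, ...]) -> Array:
    fan_in = int(np.prod(shape[1:]))
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), shape)


class _BasicBlock:
    """Two 3x3 convs with identity/projection shortcut."""

    def __init__(self, rng, in_ch: int, out_ch: int, stride: int):
        self.stride = stride
        self.w1 = _he(rng, (out_ch, in_ch, 3, 3))
        self.bn1 = _BN(out_ch)
        self.w2 = _he(rng, (out_ch, out_ch, 3, 3))
        self.bn2 = _BN(out_ch)
        self.proj = None
        if stride != 1 or in_ch != out_ch:
            self.proj = _he(rng, (out_ch, in_ch, 1, 1))
            self.bn_proj = _BN(out_ch)

    def __call__(self, x: Array) -> Array:
        out = np.maximum(self.bn1(_conv(x, self.w1, self.stride, 1)), 0.0)
        out = self.bn2(_conv(out, self.w2, 1, 1))
        short = x if self.proj is None else self.bn_proj(_conv(x, self.proj, self.stride, 0))
        return np.maximum(out + short, 0.0)

    def arrays(self, prefix: str) -> Dict[str, Array]:
        d = {f"{prefix}.w1": self.w1, f"{prefix}.w2": self.w2}
        for k, v in self.bn1.arrays().items():
            d[f"{prefix}.bn1.{k}"] = v
        for k, v in self.bn2.arrays().items():
            d[f"{prefix}.bn2.{k}"] = v
        if self.proj is not None:
            d[f"{prefix}.proj"] = self.proj
            for k, v in self.bn_proj.arrays().items():
                d[f"{prefix}.bn_proj.{k}"] = v
        return d


class Backbone:
    """Feature-pyramid extractor. Weights are frozen plain arrays."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        self.config = config
        if config.name == "table2-resnet18":
            self._build_resnet18(seed)
        elif config.name == "tiny-test-backbone":
            self._build_tiny(seed)
        else:
            raise ConfigurationError(f"unknown backbone {config.name!r}")
        if config.weights_path:
            self.load_weights(config.weights_path)

    # ---- construction ---------------------------------------------------
    def _build_resnet18(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        widths = self.config.channel_widths
        self.stem_w = _he(rng, (widths[0], 3, 7, 7))
        self.stem_bn = _BN(widths[0])
        self.stem_stride = 4 if self.config.extra_stem_downsample else 2
        self.blocks: List[List[_BasicBlock]] = []
        in_ch = widths[0]
        for li, out_ch in enumerate(widths):
            stride = 1 if li == 0 else 2
            layer = [
                _BasicBlock(rng, in_ch, out_ch, stride),
                _BasicBlock(rng, out_ch, out_ch, 1),
            ]
            self.blocks.append(layer)
            in_ch = out_ch

    def _build_tiny(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        widths = self.config.channel_widths
        self.stem_w = _he(rng, (widths[0], 3, 3, 3))
        self.level_ws: List[Array] = []
        in_ch = widths[0]
        for out_ch in widths:
            self.level_ws.append(_he(rng, (out_ch, in_ch, 3, 3)))
            in_ch = out_ch

    # ---- weight I/O -----------------------------------------------------
    def weight_arrays(self) -> Dict[str, Array]:
        if self.config.name == "tiny-test-backbone":
            d = {"stem_w": self.stem_w}
            for i, w in enumerate(self.level_ws):
                d[f"level{i + 1}.w"] = w
            return d
        d = {"stem_w": self.stem_w}
        for k, v in self.stem_bn.arrays().items():
            d[f"stem_bn.{k}"] = v
        for li, layer in enumerate(self.blocks):
            for bi, block in enumerate(layer):
                d.update(block.arrays(f"layer{li + 1}.{bi}"))
        return d

    def load_weights(self, path: str) -> None:
        with np.load(path) as npz:
            state = {k: npz[k] for k in npz.files}
        own = self.weight_arrays()
        for name, arr in own.items():
            if name not in state:
                raise KeyError(f"missing backbone weight {name!r} in {path}")
            if state[name].shape != arr.shape:
                raise ValueError(f"shape mismatch for {name}")
            arr[...] = state[name]

    def n_parameters(self) -> int:
        return int(sum(a.size for a in self.weight_arrays().values()))

    # ---- forward --------------------------------------------------------
    def __call__(self, images: Array) -> FeaturePyramid:
        return self.extract(images)

    def extract(self, images: Array) -> FeaturePyramid:
        """images: (B, 3, H, W) normalized float array, H = W divisible by 64."""
        images = np.asarray(images, dtype=np.float64)
        if images.ndim != 4 or images.shape[1] != 3:
            raise ValueError(f"expected (B, 3, H, W) batch, got {images.shape}")
        if images.shape[2] != images.shape[3]:
            raise ValueError("images must be square")
        if images.shape[2] % 64:
            raise ConfigurationError("image side must be divisible by 64")
        if not np.all(np.isfinite(images)):
            raise ValueError("non-finite pixel values")
        if self.config.name == "tiny-test-backbone":
            return self._extract_tiny(images)
        return self._extract_resnet(images)

    def _extract_resnet(self, x: Array) -> FeaturePyramid:
        x = np.maximum(self.stem_bn(_conv(x, self.stem_w, self.stem_stride, 3)), 0.0)
        x = F.max_pool2d_array(x, 3, 2, 1)
        feats = []
        for layer in self.blocks:
            for block in layer:
                x = block(x)
            feats.append(x)
        return FeaturePyramid(*feats)

    def _extract_tiny(self, x: Array) -> FeaturePyramid:
        # Linear random projections: without pretrained weights, rectification
        # would discard half of every intensity shift, so the tiny extractor
        # keeps its strided convolutions linear (a random-feature map).
        x = _conv(x, self.stem_w, 2, 1)
        x = F.avg_pool2d(Tensor(x), 2).data
        feats = []
        for w in self.level_ws:
            x = _conv(x, w, 2, 1)
            feats.append(x)
        return FeaturePyramid(*feats)


def extract_pyramid(images: Array, backbone: Backbone) -> FeaturePyramid:
    """Functional alias used by the pipeline."""
    return backbone.extract(images)


def pyramid_shapes(resolution: int, widths) -> List[Tuple[int, int, int]]:
    """Expected (C, H, W) per level for the H/8 ... H/64 scheme."""
    return [(w, resolution >> (k + 3), resolution >> (k + 3)) for k, w in enumerate(widths)]
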