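"""Turning per-scale latents into anomaly maps and image scores.

Pixel localization uses the additive rule: each scale's negative log-density
map is bilinearly upsampled to the input resolution and the maps are summed.
Image-level detection uses the multiplicative rule: per-scale densities are
multiplied, i.e. log-densities are summed on a common grid (the finest
per-scale grid), the sum is negated into a score map, and the image score is
the mean of its top-N values.  Higher always means more anomalous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from skimage.transform import resize

from .flow import FlowOutput, per_position_logprob

Array = np.ndarray


@dataclass
class AnomalyMaps:
    per_scale: List[Array]  # per-scale log-density maps (B, Hk, Wk)
    pixel_map: Array  # (B, R, R) anomaly heat map, higher = more anomalous
    image_scores: Array  # (B,)
    top_n: int


def per_scale_logprob(out: FlowOutput) -> Array:
    """Normalized log-density per position, shape (B, H, W)."""
    return per_position_logprob(out)


def _resize_batch(maps: Array, side: int) -> Array:
    if maps.shape[1] == side:
        return maps
    out = np.empty((maps.shape[0], side, side))
    for i, m in enumerate(maps):
        out[i] = resize(m, (side, side), order=1, mode="edge",
                        anti_aliasing=False, preserve_range=True)
    return out


def aggregate_pixel(per_scale: Sequence[Array], resolution: int) -> Array:
    """Additive aggregation of upsampled negative log-densities."""
    if not per_scale:
        raise ValueError("need at least one scale")
    total = np.zeros((per_scale[0].shape[0], resolution, resolution))
    for logp in per_scale:
        total += _resize_batch(-np.asarray(logp), resolution)
    return total


def aggregate_image(per_scale: Sequence[Array], top_n: int) -> Array:
    """Multiplicative aggregation on the finest grid, then top-N mean."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    fine = max(m.shape[1] for m in per_scale)
    log_joint = np.zeros((per_scale[0].shape[0], fine, fine))
    for logp in per_scale:
        log_joint += _resize_batch(np.asarray(logp), fine)
    score_map = -log_joint
    flat = score_map.reshape(score_map.shape[0], -1)
    n = top_n
    if n > flat.shape[1]:
        warnings.warn(
            f"top_n={top_n} exceeds score-map size {flat.shape[1]}; clipping",
            stacklevel=2,
        )
        n = flat.shape[1]
    top = np.sort(flat, axis=1)[:, -n:]
    return top.mean(axis=1)


def build_anomaly_maps(outputs: Sequence[FlowOutput], resolution: int,
                       top_n: int) -> AnomalyMaps:
    per_scale = [per_scale_logprob(o) for o in outputs]
    return AnomalyMaps(
        per_scale=per_scale,
        pixel_map=aggregate_pixel(per_scale, resolution),
        image_scores=aggregate_image(per_scale, top_n),
        top_n=min(top_n, max(m.shape[1] for m in per_scale) ** 2),
    )


def normalize_heatmap(pixel_map: Array) -> Array:
    """Min-max normalize to [0, 1] for export only (never for metrics)."""
    lo, hi = pixel_map.min(), pixel_map.max()
    if hi - lo < 1e-12:
        return np.zeros_like(pixel_map)
    return (pixel_map - lo) / (hi - lo)
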