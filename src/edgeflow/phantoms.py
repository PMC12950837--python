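"""Synthetic lesion phantoms with pixel-exact masks.

The generator emulates the statistical structure the detector assumes of
clinical anomaly-detection corpora: training images show only smooth
tissue-like texture (spatially correlated Gaussian noise plus pixel noise),
while each abnormal test image carries exactly one elliptical lesion whose
mean intensity is shifted by a sampled contrast and whose boundary is blurred
by a Gaussian kernel — the blurred-edge, variable-scale regime that motivates
edge-guided detection.  Output is the MVTec-style folder layout
(train/good, test/good, test/anomaly, ground_truth/anomaly) of grayscale PNGs
plus binary mask PNGs, byte-reproducible from the seed.

Default counts (40 train / 10 test-normal / 20 test-anomaly at 64x64) mirror
the proportions of a small clinical ultrasound corpus at a scale where the
full pipeline trains in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

Array = np.ndarray


@dataclass
class PhantomSpec:
    """Parameters of the synthetic dataset."""

    n_train_normal: int = 40
    n_test_normal: int = 10
    n_test_anomaly: int = 20
    resolution: int = 64
    lesion_scale_range: Tuple[float, float] = (0.15, 0.4)
    contrast_range: Tuple[float, float] = (0.3, 0.6)
    edge_blur_sigma: float = 1.5
    texture_smoothness: float = 4.0
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if min(self.n_train_normal, self.n_test_normal, self.n_test_anomaly) < 1:
            raise ValueError("all counts must be >= 1")
        lo, hi = self.lesion_scale_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("lesion_scale_range must satisfy 0 < low <= high < 1")
        if self.edge_blur_sigma < 0 or self.noise_sigma < 0 or self.texture_smoothness < 0:
            raise ValueError("sigmas must be >= 0")


def _background(res: int, smoothness: float, noise_sigma: float,
                rng: np.random.Generator) -> Array:
    """Correlated tissue texture in [0, 1]: smoothed white noise + pixel noise."""
    base = rng.normal(size=(res, res))
    if smoothness > 0:
        base = gaussian_filter(base, smoothness, mode="reflect")
        base /= max(base.std(), 1e-9)
    img = 0.5 + 0.1 * base + rng.normal(0.0, noise_sigma, size=(res, res))
    return np.clip(img, 0.0, 1.0)


def _ellipse_mask(res: int, cy: float, cx: float, a: float, b: float,
                  theta: float) -> Array:
    yy, xx = np.mgrid[0:res, 0:res]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.uint8)


def inject_anomaly(
    image: Array,
    scale_fraction: float,
    edge_blur_sigma: float,
    rng: np.random.Generator,
    contrast: Optional[float] = None,
    max_retries: int = 50,
) -> Tuple[Array, Array]:
    """Place one blurred-edge elliptical lesion; return (image, pre-blur mask).

    `scale_fraction` sets the mean axis as a fraction of the image side; the
    two semi-axes are jittered within [0.7, 1.3] of it.  The lesion's mean
    intensity inside the mask is shifted by `contrast` (sampled sign-symmetric
    around 0 is NOT done here: callers pass a signed value; if None, a signed
    contrast of magnitude 0.45 is used).  Placement is resampled when the
    ellipse would leave the image bounds.
    """
    if not 0.0 < scale_fraction < 1.0:
        raise ValueError("scale_fraction must be in (0, 1)")
    res = image.shape[0]
    if contrast is None:
        contrast = 0.45 * (1 if rng.random() < 0.5 else -1)
    radius = 0.5 * scale_fraction * res
    for _ in range(max_retries):
        a = radius * rng.uniform(0.7, 1.3)
        b = radius * rng.uniform(0.7, 1.3)
        theta = rng.uniform(0.0, np.pi)
        margin = max(a, b)
        lo, hi = margin, res - margin
        if lo >= hi:
            continue
        cy = rng.uniform(lo, hi)
        cx = rng.uniform(lo, hi)
        mask = _ellipse_mask(res, cy, cx, a, b, theta)
        if mask.any():
            break
    else:
        raise ValueError("could not place lesion inside image bounds")
    profile = mask.astype(float)
    if edge_blur_sigma > 0:
        profile = gaussian_filter(profile, edge_blur_sigma, mode="constant")
    out = np.clip(image + contrast * profile, 0.0, 1.0)
    return out, mask


def _save_gray(path: Path, img: Array) -> None:
    Image.fromarray((np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8), "L").save(path)


def generate_dataset(spec: PhantomSpec, out_dir) -> Path:
    """Write the MVTec-style phantom dataset; returns the dataset root."""
    root = Path(out_dir)
    dirs = {
        "train": root / "train" / "good",
        "test_good": root / "test" / "good",
        "test_anom": root / "test" / "anomaly",
        "gt": root / "ground_truth" / "anomaly",
    }
    for d in dirs.values():
        d.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    res = spec.resolution

    for i in range(spec.n_train_normal):
        img = _background(res, spec.texture_smoothness, spec.noise_sigma, rng)
        _save_gray(dirs["train"] / f"{i:03d}.png", img)
    for i in range(spec.n_test_normal):
        img = _background(res, spec.texture_smoothness, spec.noise_sigma, rng)
        _save_gray(dirs["test_good"] / f"{i:03d}.png", img)
    for i in range(spec.n_test_anomaly):
        img = _background(res, spec.texture_smoothness, spec.noise_sigma, rng)
        scale = rng.uniform(*spec.lesion_scale_range)
        contrast = rng.uniform(*spec.contrast_range) * (1 if rng.random() < 0.5 else -1)
        img, mask = inject_anomaly(img, scale, spec.edge_blur_sigma, rng,
                                   contrast=contrast)
        _save_gray(dirs["test_anom"] / f"{i:03d}.png", img)
        Image.fromarray(mask * 255, "L").save(dirs["gt"] / f"{i:03d}_mask.png")
    return root
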