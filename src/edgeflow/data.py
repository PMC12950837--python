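"""Dataset folder loading (MVTec-style layout).

Expected layout::

    root/
      train/good/*.png            # normal images only
      test/good/*.png             # normal test images
      test/<defect>/*.png         # abnormal test images
      ground_truth/<defect>/*_mask.png

Images are resized (bilinear) to the configured resolution, grayscale is
replicated to three channels, and pixels are normalized per config
(default (x - 0.5) / 0.5).  Masks are resized with nearest neighbour.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
from PIL import Image

Array = np.ndarray

IMAGE_EXTS = (".png", ".jpg", ".jpeg")


def load_image(path, resolution: int, mean: float = 0.5, std: float = 0.5) -> Array:
    """Read one image to a normalized (3, R, R) float array."""
    try:
        img = Image.open(path).convert("RGB")
    except Exception as exc:  # noqa: BLE001 - surface as I/O error
        raise IOError(f"cannot read image {path}: {exc}") from exc
    img = img.resize((resolution, resolution), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float64) / 255.0
    arr = (arr - mean) / std
    return arr.transpose(2, 0, 1)


def load_mask(path, resolution: int) -> Array:
    m = Image.open(path).convert("L").resize((resolution, resolution), Image.NEAREST)
    return (np.asarray(m) > 127).astype(np.uint8)


def _list_images(folder: Path) -> List[Path]:
    return sorted(p for p in folder.iterdir() if p.suffix.lower() in IMAGE_EXTS)


@dataclass
class TestSample:
    path: Path
    label: int  # 0 normal, 1 anomalous
    mask_path: Optional[Path]


class FolderDataset:
    """Discovers the split structure and loads batches on demand."""

    def __init__(self, root, resolution: int, mean: float = 0.5, std: float = 0.5):
        self.root = Path(root)
        self.resolution = resolution
        self.mean = mean
        self.std = std
        if not self.root.is_dir():
            raise IOError(f"dataset root {self.root} does not exist")

    # ---- train split ----------------------------------------------------
    def train_paths(self) -> List[Path]:
        train = self.root / "train"
        if not train.is_dir():
            raise IOError(f"missing train/ under {self.root}")
        extra = [d.name for d in train.iterdir() if d.is_dir() and d.name != "good"]
        if extra:
            raise ValueError(
                f"train split must contain only normal images (found {extra}); "
                "anomalous training data is not allowed for unsupervised fitting"
            )
        paths = _list_images(train / "good")
        if not paths:
            raise ValueError(f"no training images under {train / 'good'}")
        return paths

    def train_images(self) -> Array:
        return np.stack(
            [load_image(p, self.resolution, self.mean, self.std) for p in self.train_paths()]
        )

    # ---- test split -----------------------------------------------------
    def test_samples(self) -> List[TestSample]:
        test = self.root / "test"
        if not test.is_dir():
            raise IOError(f"missing test/ under {self.root}")
        samples: List[TestSample] = []
        for sub in sorted(d for d in test.iterdir() if d.is_dir()):
            label = 0 if sub.name == "good" else 1
            for p in _list_images(sub):
                mask = None
                if label:
                    cand = self.root / "ground_truth" / sub.name / f"{p.stem}_mask.png"
                    mask = cand if cand.exists() else None
                samples.append(TestSample(path=p, label=label, mask_path=mask))
        if not samples:
            raise ValueError(f"no test images under {test}")
        return samples

    def load_test(self) -> Tuple[Array, Array, Optional[Array], List[TestSample]]:
        """Returns (images, labels, masks-or-None, samples).

        Masks are returned only when every anomalous sample has one; normal
        samples get all-zero masks.
        """
        samples = self.test_samples()
        images = np.stack(
            [load_image(s.path, self.resolution, self.mean, self.std) for s in samples]
        )
        labels = np.array([s.label for s in samples])
        have_all = all(s.mask_path is not None for s in samples if s.label)
        masks = None
        if have_all and labels.any():
            masks = np.stack(
                [
                    load_mask(s.mask_path, self.resolution)
                    if s.mask_path is not None
                    else np.zeros((self.resolution, self.resolution), dtype=np.uint8)
                    for s in samples
                ]
            )
        return images, labels, masks, samples
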