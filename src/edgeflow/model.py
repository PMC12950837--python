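"""Model / Results surface for the edge-guided multi-scale flow detector.

``AnomalyFlowModel`` owns the frozen feature extractor, the edge path, the
four per-scale conditional flow decoders and the fusion stage; it is built
from a configuration and normal training images (directly or via
``from_folder``).  ``fit()`` runs maximum-likelihood training of the decoders
and fusion/edge convolutions on normal images only and returns an
``AnomalyFlowResults`` holding the loss history and the fitted parameters,
from which scoring, evaluation, prediction and the summary table hang.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .backbone import Backbone, FeaturePyramid
from .config import RunConfig
from .data import FolderDataset, load_image
from .edge import build_edge_path
from .flow import FlowDecoder, FlowOutput, flow_nll_loss
from .fusion import MultiScaleFusion, complexity_coefficient
from .metrics import EvalReport, evaluate_maps
from .nn import Adam, Module, Tensor
from .scoring import AnomalyMaps, build_anomaly_maps, normalize_heatmap

Array = np.ndarray


class _TrainableParts(Module):
    """Container so named_parameters/state_dict cover the whole model."""

    def __init__(self, egm, agg, decoders, mff):
        if egm is not None:
            self.egm = egm
        if agg is not None:
            self.agg = agg
        self.decoders = list(decoders)
        if mff is not None:
            self.mff = mff


class AnomalyFlowModel:
    """Unsupervised density model of normal-image features."""

    def __init__(self, train_images: Optional[Array], config: Optional[RunConfig] = None):
        self.config = config if config is not None else RunConfig()
        self.config.validate()
        self.train_images = None if train_images is None else np.asarray(train_images)
        seed = self.config.seed
        self.backbone = Backbone(self.config.backbone, seed=seed)
        rng = np.random.default_rng(seed + 1)
        widths = self.config.backbone.channel_widths
        self.egm, self.agg = build_edge_path(widths, self.config.edge, rng=rng)
        self.decoders = [
            FlowDecoder(w, self.config.flow, rng=rng) for w in widths
        ]
        self.mff = (
            MultiScaleFusion(widths, self.config.fusion, rng=rng)
            if self.config.fusion.enabled
            else None
        )
        self.parts = _TrainableParts(self.egm, self.agg, self.decoders, self.mff)

    # ---- constructors ---------------------------------------------------
    @classmethod
    def from_folder(cls, root, config: Optional[RunConfig] = None) -> "AnomalyFlowModel":
        config = config if config is not None else RunConfig()
        ds = FolderDataset(root, config.resolution, config.normalize_mean, config.normalize_std)
        model = cls(ds.train_images(), config)
        model.dataset = ds
        return model

    # ---- forward --------------------------------------------------------
    def latent_fields(self, images: Array, record: Optional[list] = None) -> List[Tensor]:
        """Per-scale flow inputs z^k; level 4 is the edge aggregate when enabled."""
        pyr = self.backbone.extract(images)
        if record is not None:
            record.append(("input", images.shape, images.shape))
            for k, f in enumerate(pyr):
                record.append((f"backbone.level{k + 1}", None, f.shape))
        f1, f2, f3, f4 = (Tensor(f) for f in pyr)
        z4 = f4
        if self.egm is not None:
            edge = self.egm(f1, f2)
            if record is not None:
                record.append(("egm.edge_fusion", None, edge.shape))
            z4 = self.agg(edge, f4)
            if record is not None:
                record.append(("eam.aggregate", None, z4.shape))
        return [f1, f2, f3, z4]

    def decode(self, images: Array, record: Optional[list] = None
               ) -> Tuple[List[FlowOutput], List[FlowOutput]]:
        """Returns (raw decoder outputs, outputs after fusion)."""
        zs = self.latent_fields(images, record=record)
        outs = [dec(z) for dec, z in zip(self.decoders, zs)]
        if record is not None:
            for k, (z, o) in enumerate(zip(zs, outs)):
                record.append((f"decoder.layer{k + 1}", z.shape, o.u.shape))
        if self.mff is None:
            return outs, outs
        fused = self.mff.fuse(outs)
        if record is not None:
            for k, p in enumerate(fused.pooled):
                record.append((f"mff.pool.layer{k + 1}", outs[k].u.shape, p.shape))
            total = sum(self.config.backbone.channel_widths)
            side = outs[-1].u.shape[2]
            b = outs[-1].u.shape[0]
            record.append(("mff.concat", None, (b, total, side, side)))
            hidden = total // self.config.fusion.bottleneck_ratio
            record.append(("mff.bottleneck", (b, total, side, side), (b, hidden, side, side)))
            record.append(("mff.expand", (b, hidden, side, side), (b, total, side, side)))
            for k, f in enumerate(fused.fused):
                record.append((f"mff.out.layer{k + 1}", None, f.u.shape))
        return outs, fused.fused

    def loss(self, images: Array) -> Tensor:
        """Summed per-scale negative log-likelihood (constant dropped)."""
        outs, fused = self.decode(images)
        use = fused if self.config.fusion.loss_on == "post_fusion" else outs
        total = flow_nll_loss(use[0])
        for out in use[1:]:
            total = total + flow_nll_loss(out)
        return total

    # ---- fitting --------------------------------------------------------
    def fit(
        self,
        epochs: Optional[int] = None,
        lr: Optional[float] = None,
        batch_size: Optional[int] = None,
        verbose: bool = False,
    ) -> "AnomalyFlowResults":
        if self.train_images is None:
            raise ValueError("model was built without training images")
        opt_cfg = self.config.optimizer
        epochs = epochs if epochs is not None else opt_cfg.epochs
        lr = lr if lr is not None else opt_cfg.lr
        batch_size = batch_size if batch_size is not None else opt_cfg.batch_size
        params = list(self.parts.parameters())
        opt = Adam(params, lr=lr)
        order_rng = np.random.default_rng(self.config.seed + 2)
        n = len(self.train_images)
        history: List[float] = []
        for epoch in range(epochs):
            order = order_rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                batch = self.train_images[order[start : start + batch_size]]
                opt.zero_grad()
                L = self.loss(batch)
                L.backward()
                opt.step()
                losses.append(float(L.data))
            history.append(float(np.mean(losses)))
            if verbose:
                print(f"epoch {epoch + 1}/{epochs}  loss {history[-1]:.4f}")
        return AnomalyFlowResults(self, loss_history=history)

    # ---- scoring --------------------------------------------------------
    def score(self, images: Array, batch_size: int = 16) -> AnomalyMaps:
        images = np.asarray(images)
        if images.ndim == 3:
            images = images[None]
        maps: List[AnomalyMaps] = []
        for start in range(0, len(images), batch_size):
            _, fused = self.decode(images[start : start + batch_size])
            maps.append(
                build_anomaly_maps(fused, self.config.resolution, self.config.scoring.top_n)
            )
        return AnomalyMaps(
            per_scale=[np.concatenate([m.per_scale[k] for m in maps]) for k in range(4)],
            pixel_map=np.concatenate([m.pixel_map for m in maps]),
            image_scores=np.concatenate([m.image_scores for m in maps]),
            top_n=maps[0].top_n,
        )

    # ---- summary --------------------------------------------------------
    def summary_rows(self, batch: int = 1) -> List[Tuple[str, object, object]]:
        res = self.config.resolution
        dummy = np.zeros((batch, 3, res, res))
        record: list = []
        self.decode(dummy, record=record)
        return record

    def n_parameters(self) -> int:
        return self.parts.n_parameters()

    def summary(self, batch: int = 1) -> str:
        rows = self.summary_rows(batch=batch)
        lines = [
            "Edge-guided multi-scale flow anomaly detector",
            f"  resolution       : {self.config.resolution}",
            f"  backbone         : {self.config.backbone.name} "
            f"(frozen, {self.backbone.n_parameters():,} weights)",
            f"  trainable params : {self.n_parameters():,}",
            f"  conv complexity coefficient : {self.complexity_coefficient()}",
            "",
            f"  {'stage':<22}{'input':<22}{'output':<22}",
        ]
        for name, in_shape, out_shape in rows:
            ins = "-" if in_shape is None else str(tuple(in_shape))
            outs = "-" if out_shape is None else str(tuple(out_shape))
            lines.append(f"  {name:<22}{ins:<22}{outs:<22}")
        return "\n".join(lines)

    def complexity_coefficient(self) -> int:
        egm_convs = 2 if self.egm is not None else 0
        eam_convs = 1 if self.agg is not None else 0
        blocks = self.config.flow.depth if self.decoders else 0
        mff_convs = 2 if self.mff is not None else 0
        return complexity_coefficient(egm_convs, eam_convs, blocks, mff_convs)

    # ---- persistence ----------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        state = self.parts.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
        )
        np.savez(path, **state)

    @classmethod
    def load(cls, path, train_images: Optional[Array] = None) -> "AnomalyFlowModel":
        with np.load(path) as npz:
            state = {k: npz[k] for k in npz.files}
        cfg = RunConfig.from_dict(json.loads(state.pop("__config__").tobytes().decode()))
        model = cls(train_images, cfg)
        model.parts.load_state_dict(state)
        return model


@dataclass
class AnomalyFlowResults:
    """Fit outcome: fitted model, loss history, evaluation and summaries."""

    model: AnomalyFlowModel
    loss_history: List[float] = field(default_factory=list)

    @property
    def config(self) -> RunConfig:
        return self.model.config

    def score(self, images: Array, batch_size: int = 16) -> AnomalyMaps:
        return self.model.score(images, batch_size=batch_size)

    def evaluate(
        self,
        images: Array,
        labels: Sequence[int],
        masks: Optional[Array] = None,
        fpr_cap: float = 0.3,
    ) -> EvalReport:
        maps = self.score(images)
        return evaluate_maps(
            maps.image_scores,
            labels,
            pixel_maps=maps.pixel_map if masks is not None else None,
            masks=masks,
            fpr_cap=fpr_cap,
            seed=self.config.seed,
            config_hash=self.config.config_hash(),
        )

    def evaluate_folder(self, root, fpr_cap: float = 0.3):
        """Evaluate on a dataset folder; returns (report, per-image scores)."""
        cfg = self.config
        ds = FolderDataset(root, cfg.resolution, cfg.normalize_mean, cfg.normalize_std)
        images, labels, masks, samples = ds.load_test()
        if masks is None and labels.any():
            warnings.warn(
                "ground-truth masks missing: pixel-level metrics skipped",
                stacklevel=2,
            )
        report = self.evaluate(images, labels, masks, fpr_cap=fpr_cap)
        maps = self.score(images)
        per_image = [
            (str(s.path), float(v)) for s, v in zip(samples, maps.image_scores)
        ]
        return report, per_image

    def predict(self, image_path) -> Tuple[float, Array]:
        """Score one image; returns (image score, [0,1] heat map at input res)."""
        cfg = self.config
        img = load_image(image_path, cfg.resolution, cfg.normalize_mean, cfg.normalize_std)
        maps = self.score(img[None])
        return float(maps.image_scores[0]), normalize_heatmap(maps.pixel_map[0])

    def summary(self) -> str:
        lines = [self.model.summary()]
        if self.loss_history:
            lines.append("")
            lines.append(
                f"  fit: {len(self.loss_history)} epochs, "
                f"loss {self.loss_history[0]:.4f} -> {self.loss_history[-1]:.4f}"
            )
        return "\n".join(lines)

    def save(self, path) -> None:
        self.model.save(path)
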