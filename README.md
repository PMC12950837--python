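# edgeflow

Unsupervised anomaly detection for 2-D medical images (ultrasound, MRI, CT
slices) with edge-guided, multi-scale conditional normalizing flows.

Clinical anomaly detection rarely has labels: lesions are scarce, diverse, and
expensive to annotate, while normal scans are plentiful. `edgeflow` therefore
fits a density model to **normal images only** and flags anything the model
finds unlikely — at the image level (is this scan abnormal?) and at the pixel
level (where is the lesion?). Two properties of medical lesions drive the
architecture: their edges are blurred (speckle, partial-volume effects) and
their sizes vary over an order of magnitude.

## Model

A frozen convolutional backbone extracts a four-level feature pyramid
F₁…F₄ (spatial sides H/8…H/64, widths 64/128/256/512 by default). Three
stages enrich and decode it:

- **Edge guidance (EGM).** F₁ is pooled and projected onto F₂'s grid (F₁′);
  the two concatenation orders (F₁′,F₂) and (F₂,F₁′) pass through learned 1×1
  convolutions giving attention fields E₁, E₂; a two-way softmax yields convex
  weights E₁′+E₂′=1 and the edge feature
  F_edge = E₁′⊗F₁′ ⊕ E₂′⊗F₂.
- **Edge aggregation (EAM).** A squeeze-excitation channel attention
  re-weights F_edge; pooled to F₄'s grid, concatenated with F₄ and mixed by a
  3×3 convolution into F_cat; the aggregate
  F_agg = GAP(F_cat)⊗F_cat ⊕ F₄ replaces F₄ as the deepest flow input.
- **Conditional flows + multi-scale fusion (MFF).** Each scale k has an
  independent decoder g^k of eight affine coupling blocks, conditioned on a
  fixed 2-D sinusoidal positional encoding c^k, mapping the feature field z^k
  to a latent u^k with exact log-determinant. Training minimizes, per scale,

      L^k = (1/N) Σᵢ [ ‖uᵢ^k‖²/2 − log|det Jᵢ^k| ]

  on normal images (maximum likelihood under a standard-normal base). The MFF
  stage pools the three shallow decoder outputs onto the deepest 4×4 grid,
  concatenates (960 channels), squeezes through a 960→240→960 bottleneck and
  redistributes residually, so the four scales exchange information; the
  second conv starts at zero, making fusion an exact identity at
  initialization.

Scoring: per-position log-density log p = −‖u‖²/2 + log|det J| − (d/2)·log 2π.
Pixel maps sum upsampled negative log-densities over scales (additive rule);
image scores multiply per-scale densities — sum log-densities on the finest
grid — negate, and take the top-N mean (higher = more anomalous).

Because clinical corpora cannot ship with the package, a **phantom generator**
emulates their structure: correlated-noise tissue backgrounds, one elliptical
blurred-edge lesion per abnormal image at a sampled scale and contrast, and
pixel-exact masks, in the standard train/good, test/good, test/anomaly,
ground_truth layout.

## Worked example

```python
from edgeflow import AnomalyFlowModel, PhantomSpec, RunConfig, generate_dataset

root = generate_dataset(PhantomSpec(seed=0), "phantoms")
config = RunConfig.tiny_test(seed=1)          # 64x64, small frozen backbone
model = AnomalyFlowModel.from_folder(root, config)
results = model.fit(verbose=True)
report, _ = results.evaluate_folder(root)
print({k: round(v, 2) for k, v in report.as_percent().items()
       if isinstance(v, float)})
```

prints

```
epoch 1/5  loss -3.2996
epoch 2/5  loss -18.2179
epoch 3/5  loss -28.8902
epoch 4/5  loss -36.4031
epoch 5/5  loss -44.3607
{'det_auroc': 98.0, 'seg_auroc': 88.69, 'seg_aupro': 42.51, 'recall': 42.36,
 'precision': 28.91, 'threshold': 68.99, 'fpr_cap': 0.3}
```

The falling loss is the per-scale negative log-likelihood (additive constant
dropped, hence negative values). `det_auroc` is image-level detection AUROC
(%), `seg_auroc` pixel-level localization AUROC, `seg_aupro` the
per-region-overlap area up to FPR 0.3 (small lesions weighted equally with
large ones), and recall/precision are pixel rates at the F1-maximizing
threshold.

The same workflow is available from the shell:

```
edgeflow phantom generate --out phantoms --seed 0
edgeflow train --data phantoms --out run
edgeflow evaluate --data phantoms --checkpoint run/checkpoint.npz --out run
edgeflow predict --checkpoint run/checkpoint.npz --image phantoms/test/anomaly/000.png
edgeflow summary
```

`edgeflow summary` prints the layer-by-layer shape table of the default
256×256 network, the trainable parameter count, and the convolution
complexity coefficient.

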