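# slicefuse

Learnable weighted pooling (LWP) for classifying 3D brain volumes with 2D
convolutional networks.

## The problem

Training 3D CNNs directly on volumetric brain images (for example amyloid
PET in Alzheimer's disease studies, where volumes are 96 × 160 × 160) is
computationally expensive and prone to overfitting on the small cohorts
typical of medical imaging, and there are no ImageNet-scale pretrained 3D
feature extractors to fall back on. A practical alternative is to *fuse*
the volume along one anatomical axis into a single 2D image and classify
that image with an ordinary, optionally pretrained, 2D backbone. The
question is how to weight the slices: fixed schemes (pixel-wise max,
average, or approximate rank pooling) cannot adapt to where the
disease-relevant signal actually lives.

`slicefuse` implements the learnable alternative. Given a volume
V = [I₁, …, I_T] ∈ ℝ^{T×H×W} viewed along a chosen axis (axial, coronal or
sagittal), a small shared-weight CNN ψ — four convolutional layers and a
global average pool — scores every slice, Q_x = ψ(I_x), the scores are
softmax-normalized,

    α_x = exp(Q_x) / Σ_{x'} exp(Q_{x'}),

and the fused image is the convex combination F = Σ_x α_x · I_x. Because ψ
is trained jointly with the classifier, the model learns *which slices
matter*, and the learned α profile is directly interpretable (central brain
slices typically dominate). The fixed baselines are included for
comparison; approximate rank pooling (ARP) uses α_t = 2t − T − 1, which
sums to zero and annihilates constant stacks.

Downstream of fusion, the single-channel image is replicated to three
channels, passed through a 2D backbone, refined by a dual-attention block
(a non-local self-attention branch and a 1D-convolution channel-attention
branch, merged by element-wise sum), and classified by three fully
connected layers (512 → 64 → 2, batch normalization and dropout 0.5 after
the first two). Training minimizes class-weighted binary cross-entropy

    loss = −[ w_p · l · log p + w_n · (1 − l) · log(1 − p) ],

with w_n = 1 and w_p = (#negatives)/(#positives) computed from the data
(214 vs 167 gives w_p = 1.28), under stratified 5-fold cross-validation
with Adam (β₁ = 0.9, β₂ = 0.999).

The whole network stack — a compact reverse-mode autodiff engine, conv/
attention/normalization layers, and Adam — is implemented in numpy inside
the package (`slicefuse._nn`), so everything runs on a plain CPU with no
deep-learning framework. Available backbones: `tiny` (a 4-stage CNN for
desk-scale runs), `resnet34` and `vgg11` (full architectures, randomly
initialized).

## Worked example

Phantom volumes (24 × 32 × 32) contain an ellipsoidal "brain"; positive
volumes additionally carry a focal intensity reduction confined to the
middle third of the fusion axis (slices 8–15), mimicking localized
hypometabolism. Train the LWP model with cross-validation and inspect the
learned slice weights:

```python
import numpy as np
import slicefuse as sf
from slicefuse.training import TrainConfig, cross_validate

spec = sf.SyntheticSpec(n_per_class=20, shape=(24, 32, 32), seed=0)
ds = sf.generate_dataset(spec)

cfg = sf.ModelConfig(backbone_id="tiny", pooling="lwp", attention_mode="dual")
res = cross_validate(cfg, TrainConfig(epochs=15, lr=1e-3, folds=5, seed=1),
                     ds.samples)
print(f"pooled accuracy {res.pooled.acc:.3f}, AUC {res.pooled.auc:.3f}")

model = res.models[0]
alpha = np.mean([sf.slice_weights(model, s).weights for s in ds.samples], axis=0)
lo, hi = spec.resolved_band
print(f"mean alpha in band {alpha[lo:hi].mean():.4f} "
      f"vs outside {np.concatenate([alpha[:lo], alpha[hi:]]).mean():.4f}")
```

Output:

```
pooled accuracy 1.000, AUC 1.000
mean alpha in band 0.0470 vs outside 0.0390
```

The separable phantom task is solved exactly, and the softmax slice
weights are larger inside the informative band (uniform weighting would be
1/24 ≈ 0.0417 everywhere): the model has learned where the signal lives.
`sf.visualize_slices(model, ds.samples[0], "viz/")` renders the per-slice
logit curve, the weight curve, and the fused image.

There is also a CLI (`slicefuse synth|fuse|train|eval|viz|mads`), e.g.

```bash
slicefuse synth --out data --seed 3
slicefuse train --manifest data/manifest.csv --out run --seed 1
slicefuse mads --backbone tiny --pooling lwp --input-shape 24,32,32
```

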