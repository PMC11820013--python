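# camil

Weakly supervised classification of whole-slide pathology images (WSIs)
with a cascaded spatial/channel attention multiple-instance-learning
model, plus the full slide-to-prediction pipeline: tiling, tissue
filtering, patch feature encoding, bag-level training, evaluation and
attention/Grad-CAM heatmaps. A synthetic-data module makes every stage
testable on a laptop with no downloads.

## The problem

A WSI carries one label (e.g. *tumor* / *normal*) but decomposes into
thousands of 256×256 patches, almost all of which are uninformative —
tumor tissue often covers under 10% of a positive slide. Multiple
instance learning (MIL) treats the slide as a *bag* X = {x₁,…,x_N} of
patch feature vectors with the standard assumption

    Y = 1  iff  at least one instance is positive.

Attention-pooling MIL aggregates instances into a bag embedding with
learned weights w (Σⱼ wⱼ = 1). This package's model refines the
instance matrix X ∈ ℝ^{N×C} before pooling with two cascaded
self-attention modules:

- **Spatial (instance) attention** — project A = XW_A + b_A,
  B = XW_B + b_B, form the column-stochastic similarity matrix
  s_ji = softmax_i(A_i·B_j), and add back the reweighted projection
  D = XW_D + b_D through a residual gate:
  E_j = α Σ_i s_ji D_i + X_j.
- **Channel attention** — the same construction on the channel Gram
  matrix EᵀE (C×C): G_:j = β Σ_i c_ji E_:i + E_:j.

The gates α and β are learnable scalars initialized to **zero**, so at
initialization the whole block is the identity and the model coincides
exactly with plain attention-pooling MIL; training opens the gates only
as far as the cross-bag context helps. Five fusion modes are available
(`spatial_then_channel` — the default and best in ablation,
`channel_then_spatial`, `spatial_only`, `channel_only`,
`parallel_concat`), wrapped between a linear-ReLU encoder and decoder,
attention pooling and a sigmoid classifier head.

The model core runs in float64 NumPy on a small in-package reverse-mode
autodiff tape — no deep-learning framework required. Training follows
the bag-per-step recipe: Adam (lr 1e-4, weight decay 1e-5), cosine
annealing over 50 epochs, early stopping on validation AUC, and
10-fold stratified cross-validation reporting ACC@0.5, AUC,
specificity, recall and F1 as mean ± sd.

## Worked example

Train on synthetic bags (200-dim study scaled to 64 channels; positive
bags hide a 10% witness fraction with a +2σ mean shift on 8 channels):

```python
from camil import (SynthConfig, make_bags, CamilConfig, CamilModel,
                   TrainConfig, train_model, binary_metrics)

bags = make_bags(SynthConfig(n_bags=120, feature_dim=64, seed=0))
train, val, test = bags[:72], bags[72:96], bags[96:]
model = CamilModel(CamilConfig(in_dim=64, model_dim=128, pool_hidden=128, seed=0))
best, history = train_model(model, train, TrainConfig(seed=0), val)
probs = model.predict_proba(test)
labels = [b.y for b in test]
print(f"stopped after {len(history)} epochs; "
      f"best val AUC {max(h['val_auc'] for h in history):.3f}")
m = binary_metrics(labels, probs)
print("held-out:", {k: round(v, 3) for k, v in m.items()})

pos = next(b for b in test if b.y == 1)
pred = model.predict(pos.X)
w, wit = pred.instance_weights, pos.instance_labels == 1
print(f"one positive bag: p(tumor)={pred.prob:.3f}, "
      f"mean attention witnesses={w[wit].mean():.4f} vs others={w[~wit].mean():.4f}")
```

Output:

```
stopped after 11 epochs; best val AUC 1.000
held-out: {'accuracy': 1.0, 'auc': 1.0, 'specificity': 1.0, 'recall': 1.0, 'f1': 1.0}
one positive bag: p(tumor)=0.983, mean attention witnesses=0.1628 vs others=0.0004
```

The last line is the weak-supervision payoff: trained only on bag
labels, the pooling attention concentrates (0.16 vs 0.0004 mean weight)
on exactly the instances that carry signal, which is what the heatmap
stage projects back onto slide coordinates.

## Command line

```sh
camil simulate  --config run.yaml          # synthetic bags -> HDF5 feature store
camil preprocess --config run.yaml --image slide.png --slide-id s1
camil featurize --config run.yaml --image slide.png --manifest run/s1_patches.csv --label 1
camil train     --config run.yaml          # checkpoint + per-epoch history
camil evaluate  --config run.yaml [--cv]   # metrics JSON (fixed split or k-fold CV)
camil heatmap   --config run.yaml --slide-id s1
```

Each stage writes a JSON manifest (inputs, config hash, stage seed) so
any run can be reproduced byte-for-byte from its YAML config and one
global seed.

## Scope notes

Real-WSI benchmarks (Camelyon16, TCGA) require hundred-gigabyte
downloads and GPU-scale training and are out of scope here; the
pretrained ResNet18 patch encoder is available as the optional `cnn`
extra, while tests and examples use the deterministic histogram encoder
or synthetic features. See `docs/methods.md` for the model's
assumptions, parameter choices and limitations.
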