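# sgbnet

Saliency-guided boundary-refinement network for retinal vessel
segmentation.

Segmenting retinal blood vessels in fundus photographs underpins
computer-aided diagnosis of diabetic retinopathy, hypertension and other
vascular conditions.  The task is hard where it matters most: vessels
occupy ~10% of the field of view, thin branches fade into a low-contrast
background, and lesions mimic vessel intensity.  `sgbnet` implements a
three-branch encoder–decoder aimed at exactly those failure modes, for
researchers who want a fully inspectable, CPU-runnable reference
implementation with a built-in synthetic data generator.

## The model

A shared residual backbone (stem max-pool and classifier removed)
produces side outputs β₁, β₂, β₃ and deepest features α₄ at strides
{2, 4, 8, 16}.  Three branches cooperate:

* **Scale-adaptive (SA) module** on α₄: fine (1×1), medium (3×3) and
  coarse (5×5) convolution branches are aligned and summed to η, which
  reweights a projection μ of α₄; their concatenation κ is fused with a
  global-average context descriptor ρ to give α_SA.
* **Attention-enhancement (AE) decoder**: each block gates a 3×3
  reduction of a low-level side output with a sigmoid of summed pooled
  channel descriptors — global-average of the low level ⊕ global-max of
  the high level — and fuses with the up-sampled previous output:
  ηAEᵢ = up(γoutᵢ ⊕ up(ηAEᵢ₋₁)).
* **Boundary network**: residual boundary-refinement blocks
  R(β) = Conv3×3(σ(BN(Conv3×3(A(β))))) + A(β) cascade bottom-up over
  adjacent stages to a dedicated boundary head.

Three heads — fused T₀, boundary T₁, feature-guided T₂ — train against

    ℓ = ℓ_seg(T₀) + η·ℓ_focal(T₁) + ψ·ℓ_seg(T₂),   η = 0.7, ψ = 0.3,

where ℓ_focal = −α_t(1−p_t)^γ log p_t (λt = 0.25, γ = 2) and ℓ_seg is
soft Dice.  Training samples random 64×64 patches inside the camera FOV
(Adam, lr 1e−4, batch 8); whole images are predicted by tiling 96×96
windows at stride 32 and averaging overlaps.  Everything runs on a
compact numpy autodiff engine included in the package — no GPU
framework required — and every backward pass is verified against finite
differences in the test suite.

## Worked example

```python
from sgbnet.synthetic import SynthParams, generate_split
from sgbnet.pipeline import TrainConfig, InferConfig, train_on_samples, \
    predict_sample, evaluate_samples
from sgbnet import imaging

# 4 training / 2 test synthetic fundus images with vessel + FOV masks
train, test = generate_split(SynthParams(seed=7, size=(192, 192)), 4, 2)

cfg = TrainConfig(variant="sgbnet", epochs=2, patches_per_epoch=160,
                  lr=1e-3, seed=7, val_fraction=0.0)
model, history = train_on_samples(train, cfg)

test_pre = [imaging.preprocess(s, cfg.preprocess) for s in test]
preds = [predict_sample(model, s, InferConfig(), preprocessed=True)
         for s in test_pre]
reports, agg = evaluate_samples(preds, test)
print(f"loss {history['loss'][0]:.3f} -> {history['loss'][-1]:.3f}")
print(f"held-out dice {agg.dice:.3f}  sensitivity {agg.sensitivity:.3f}  "
      f"auc {agg.auc_roc:.3f}")
```

Output from this exact script:

```
loss 1.042 -> 0.534
held-out dice 0.504  sensitivity 0.375  auc 0.894
```

Forty optimiser steps lift held-out Dice from the ~0.2 of an untrained
(all-uncertain) network to 0.50: the loss trace shows the compound
objective falling, and the aggregate report gives the FOV-restricted
Dice, sensitivity and ROC AUC over the two held-out images.

A command-line interface mirrors the library:

```
sgbnet synth --seed 1 --out-dir data          # synthetic dataset + manifest
sgbnet train --manifest data/train/manifest.txt --out-dir run
sgbnet predict --checkpoint run/best.ckpt --image img.png --out-dir preds
sgbnet evaluate --pred-dir preds --manifest data/test/manifest.txt \
    --fov-mode fov --out-dir metrics
```

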