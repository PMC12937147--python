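# mammofusion

Dual-view mammogram classification with gated cross-view fusion, multi-head
self-attention, spatial attention and Grad-CAM explainability — exercisable
end-to-end on synthetic phantom mammograms, with no dataset download.

## Who this is for

Screening mammography acquires two projections per breast: craniocaudal (CC)
and mediolateral oblique (MLO). The two views carry complementary anatomy
(the MLO adds the upper-outer quadrant and the pectoral muscle), and models
that fuse them outperform single-view classifiers. This package implements a
dual-branch convolutional classifier whose core idea is *adaptive* fusion:
instead of concatenating view features, per-element sigmoid gates weight each
view's contribution before summation,

```
g_v     = σ(W_v * F_v + b_v)            (1×1 conv per view)
F_fused = g_MLO ⊙ F_MLO + g_CC ⊙ F_CC
```

so a view that is uninformative for a particular case can be down-weighted
for that case alone. The fused 32×32×128 map passes through 4-head
self-attention over its 1024 spatial tokens (d_k = 32, residual + layer
norm), a CBAM-style spatial attention gate
`M_s = σ(f^{7×7}([mean_c(F); max_c(F)]))`, and a GAP → 64-unit → sigmoid head.
Training uses inverse-class-frequency-weighted binary cross-entropy
(w_c = N / 2N_c), Adam at 1e-4, batch 16, LR ×0.1 on a 5-epoch validation
plateau, early stopping, stratified case-level splits and 5-fold CV. The four
ablation variants (concat baseline → gated → +MHSA → +spatial) are plain
configuration flags.

Everything — the network with its backward pass, the preprocessing chain
(Otsu breast extraction, MLO pectoral suppression, CLAHE, 256×256 resize,
laterality-based pairing), the 8× flip/rotation augmentation, metrics with
fold-averaged ROC bands, and Grad-CAM — runs on numpy/scipy/scikit-image; no
deep-learning framework is required. A phantom generator produces paired
CC/MLO images with ground-truth masks so every stage is testable.

## Worked example

```python
import numpy as np
import mammofusion as mf

# 1. simulate 16 phantom cases and preprocess them to 64x64 pairs
spec = mf.PhantomSpec(seed=11, image_size=128)
records, manifest = mf.generate_dataset(spec, n_benign=16, n_malignant=16)
samples, excluded = mf.preprocess_records(
    records, mf.PreprocessConfig(target_size=64))

# 2. train the full model (gated fusion + MHSA + spatial attention)
model, log = mf.train_model(
    samples, samples,
    mf.ModelConfig(input_size=64, seed=7),
    mf.TrainConfig(max_epochs=45, seed=7,
                   early_stop_patience=45, lr_plateau_patience=45))
print(f"epoch {log[-1]['epoch']}: train_acc={log[-1]['train_acc']:.3f} "
      f"train_loss={log[-1]['train_loss']:.4f}")

# 3. evaluate and explain
probs = mf.predict(model, samples)
report = mf.EvaluationReport()
fold = report.add_fold([s.label for s in samples], probs)
print(f"acc={fold['accuracy']:.3f} auc={fold['auc']:.3f} "
      f"kappa={fold['kappa']:.3f}")

from mammofusion.explain import gradcam
sal = gradcam(model, samples[0])          # 64x64 saliency map in [0, 1]
print(sal.heatmap.shape, sal.view)
```

prints (exact numbers; the run is fully seeded):

```
epoch 44: train_acc=1.000 train_loss=0.0732
acc=1.000 auc=1.000 kappa=1.000
(64, 64) fused
```

The model drives its training loss down and separates the two phantom
classes perfectly — as it should on 32 memorised pairs; the point of the
example is the mechanics, not generalisation. The saliency map is the
Grad-CAM of the spatial-attention output, upsampled to the input frame
(`mammofusion.explain.overlay` renders the red-high jet overlay).

The same pipeline is available from the shell:

```bash
mammofusion simulate --n-benign 8 --n-malignant 8 --seed 0 --out data/
mammofusion run --seed 0 --out runs/demo     # simulate→preprocess→CV→report
mammofusion explain --checkpoint runs/demo/fold0_checkpoint.npz \
    --image-pair data/case0000_L_CC.png,data/case0000_L_MLO.png --out cam.png
```

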