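# dpsenet

A self-contained toolkit for classifying lung and colon histopathology
patches with a lightweight **dual-path convolutional network with
squeeze-and-excitation (SE) channel attention**, together with the full
surrounding workflow: dataset loading and stratified splitting, a seeded
synthetic histology-texture generator, the training protocol, a
parameter/FLOP complexity profiler, an evaluation suite, and a three-method
explainability pipeline (Grad-CAM, SE attention, Integrated Gradients).

It is aimed at researchers who want a compact, fully inspectable
implementation of this architecture family — every forward and backward pass
is plain numpy, so gradients used for training, Grad-CAM and Integrated
Gradients are exact and easy to audit.

## The model

An H×W×3 patch is processed by two parallel stacks of
`[conv → ReLU → 2×2 max-pool]` blocks with 32/64/128 filters: **Path A**
uses 3×3 kernels (fine cellular texture), **Path B** uses 5×5 kernels
(broader glandular context). Their outputs are concatenated on the channel
axis and recalibrated by an SE block:

```
z_c = (1/HW) Σ_ij X_c(i,j)                 (squeeze: global average pool)
s   = σ(W₂ · ReLU(W₁ · z))                 (excitation: C → C/r → C, r = 16)
X̃_c = s_c · X_c                            (channel-wise recalibration)
```

Global average pooling, a 128-unit ReLU dense layer and a softmax head
produce the five class probabilities. Six ablation variants are available
(`single_a`, `single_b`, `single_a_se`, `single_b_se`, `dual`, `dual_se`).

Training uses Nadam (lr 0.001), categorical cross-entropy, batch size 32,
and four callbacks: early stopping (patience 5, best-weights restore),
reduce-on-plateau (×0.5 after 3 stagnant epochs), exponential decay (×0.96
per epoch after epoch 10), and best-checkpoint tracking.

Explainability: Grad-CAM weights each channel of the recalibrated fused map
by the spatial mean of the class logit's gradient
(`α_k = (1/Z)·Σ_ij ∂y_c/∂A_k(i,j)`, map `= ReLU(Σ_k α_k A_k)`); SE attention
reports the observed gate vector; Integrated Gradients integrates logit
gradients along a straight path from a black baseline, recording the
completeness gap `|Σ IG − (F(x) − F(x′))|`.

## Worked example

Everything works without downloads via the synthetic generator, which writes
five class folders of H&E-like texture patches (shared pink cytoplasm,
class-specific nuclear density/size/colour and gland rings):

```bash
dpsenet synth --out-dir ds --images-per-class 50 --size 128 --seed 0
dpsenet train --data-dir ds --out-dir run --variant dual_se --max-epochs 25 --seed 0
dpsenet evaluate --weights run/weights.h5 --data-dir ds --out-dir eval --seed 0
dpsenet explain --weights run/weights.h5 --data-dir ds --out-dir xai --samples 5 --seed 0
dpsenet profile --variant dual_se
```

Training takes ~10 minutes on one CPU core and ends with

```
best epoch 25: val_loss 0.0144, val_acc 1.0000
```

after which `evaluate` prints

```
accuracy 1.0000  macro F1 1.0000  AUC 1.0000
```

on the held-out test split (the synthetic classes are deliberately
separable), and `explain` writes five 4-panel composites
(original | Grad-CAM | SE heatmap | Integrated Gradients) plus an
`explanations.json` with the predicted class, logit, IG completeness gap
and top SE channels per sample.

The profiler prints, for the canonical 128×128×3 configuration:

```
Metric                Value             Description
Total parameters      393,877           Trainable only
Model size            1.50 MB           Float32 representation
FLOPs per inference   1.250 GFLOPs      128 x 128 x 3 input

Functional Block          GFLOPs      Percentage
Path A                    0.331219    26.50%
Path B                    0.918422    73.49%
Squeeze-and-Excitation    0.000082    0.01%
Classifier                0.000067    0.01%
Total                     1.249790    100.00%
```

Reading: the two convolutional paths carry essentially all of the
computation; the attention block and the classifier head together cost less
than 0.02% of an inference, which is what makes the SE recalibration
"free" in practice. The 5×5 path is ~2.8× the cost of the 3×3 path (the
25/9 kernel-area ratio). Parameters are counted with biases —
e.g. the first 3×3 conv is (3·3·3+1)·32 = 896 — and model size is
parameters × 4 bytes.

`dpsenet train` writes `weights.h5` (+ JSON config sidecar), `history.csv`
and a split manifest. At the full study conditions (200 images/class) the
model is stronger per epoch — 98.5% held-out accuracy after four epochs —
which is what the end-to-end test in `tests/test_acceptance.py` asserts.
`dpsenet ablate` trains all six variants on identical splits and emits a
CSV of accuracy/precision/recall/F1 per variant.

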