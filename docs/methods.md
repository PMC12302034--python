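# Methods

## Problem and model

Histopathology image classification needs both local evidence (nuclear
morphology, chromatin texture) and global context (glandular architecture,
tissue organization). The package trains two heterogeneous backbones on the
same images and couples them so that each learns from the other *online*,
within every mini-batch, rather than distilling from a fixed teacher:

1. **CNN branch** (`ofml.cnn`). A bottleneck residual network in the
   ResNet-50 layout (stages of 3/4/6/3 bottlenecks, widths 64·2^s, stride-2
   stage transitions). Besides its logits `A1`, the branch exposes a tapped
   intermediate feature map. Residual stages are numbered 1–4 with the stem
   as stage 0; at 224 px the stage outputs are (256,56,56), (512,28,28),
   (1024,14,14), (2048,7,7). *The default tap is selected by shape, not by
   name*: whichever stage carries 512 channels — (512,28,28) at 224 px —
   because stage-naming conventions differ across descriptions of ResNet
   while the printed shape is unambiguous. A `small_stem` option (3×3/1
   convolution, no max-pool) keeps resolution for 32-px study inputs.

2. **Multi-view transformer branch** (`ofml.mvt`). Patch embedding follows
   the standard recipe: N = (H/Q)·(Z/Q) patches of side Q are flattened,
   linearly mapped to width d, a learnable class token is prepended and a
   learnable positional embedding added. (The token-count formula is
   N = (H·Z)/Q²; only that value yields a square grid consistent with a
   (512, 14, 14) tapped map at 224 px and Q = 16.) Three view-specific
   encoder stacks of *different widths* (256, 384, 512 by default; 4
   pre-norm layers each, 8 heads, GELU MLP with ratio 2) process the token
   sequence in parallel. Adjacent views are fused by single-head
   cross-view attention, CVA(x, y) = softmax(Z_Q x (Z_K y)ᵀ/√d_k) Z_V y,
   with a learnable projection Z_proj matching view (i+1)'s width down to
   view i's. The `y` argument is the second token sequence (one reading of
   the operator treats it as a free parameter matrix; that reading leaves
   the second view disconnected and is not implemented). **Fusion
   schedule**: the pairs are chained from the deepest view down —
   carry ← A_n, then carry ← CVA(A_i, Z_proj_i · carry) for i = n−1 … 1 —
   so every view and every Z_proj contributes to the fused sequence and
   receives gradient. (Fusing pairs independently and forwarding only the
   last pair was considered and rejected: it leaves all earlier pairs
   without gradient.) The fused sequence (width of view 1) is projected to
   the global width 512 and passes a depth-4 global pre-norm encoder. The
   classification head is LayerNorm + a linear map on the class token; the
   tapped map is global-encoder layer 3's patch tokens (class token
   dropped) reshaped to the (512, 14, 14) grid.

3. **Heads** (`ofml.heads`). The ensemble classifier is the element-wise
   mean (A1+A2)/2. The fusion classifier pools each tapped map adaptively
   to 1×1, concatenates channels (512+512 = 1024) and applies a single
   pointwise convolution with bias to C classes — (c1+c2)·C + C parameters,
   accepting any spatial tap sizes.

## Losses (`ofml.losses`)

Softened distributions q(x,T) = softmax(logits/T), T = 4. Per branch:
L_i = CE_i + T²·KL(q_i(T) ‖ q_f(T)), the fusion distribution detached
(knowledge transfer must not drag the teacher toward the student; the
coupling in the opposite direction has its own terms). The total is

L_f = L1 + L2 + T²·L_ensemble + w_epkt·KL(q_e(T) ‖ q_f(T)) + w_fce·CE(q_f, y),

with q_e detached in the ensemble→fusion transfer. Three deliberate
readings of ambiguous formulations, all switchable:

* The cross-entropies are standard *negative* log-likelihoods (the loss
  must be non-negative and minimized); with Mixup's soft labels the CE
  generalizes to −Σ_m ỹ_m log p_m.
* The branch transfer is KL(q_branch ‖ q_fusion) as its definition states;
  an alternative expansion mixing the ensemble distribution into the same
  sum is internally inconsistent and not used.
* The literal three-term total contains no term that trains the fusion
  head, so the default adds the EPKT term and a fusion-head cross-entropy
  (both weight 1.0); `loss.literal_total: true` (or zero weights) recovers
  the literal objective. The T² factor on L_ensemble is kept literally even
  though it scales a plain cross-entropy by 16 at T = 4.

All logs are clamped at 1e-12 (a warning is logged when the clamp engages).

## Training (`ofml.model`)

One backward pass on the summed L_f per mini-batch; a single Adam step
updates both backbones and the fusion head simultaneously. Adam maps the
recipe's "momentum 0.8" to its first-moment decay β1 (Adam has no separate
momentum; β1 is its analogue), β2 = 0.999, weight decay 5e-4 added to the
gradient. No learning-rate schedule. Divergence (any non-finite loss
component) aborts with an error naming the first bad component. Runs are
fully seeded: parameter init, batch shuffling and Mixup draw from
independent streams spawned from `config.seed`, and the engine is pure
NumPy, so reruns are bit-identical.

Paper-scale defaults (`configs/paper.yaml`): lr 0.01, batch 64, 300
epochs, 224 px, 70:30 stratified split (floor on the per-class train
count; magnification is recorded as metadata but ignored for splitting).
These are not exercised by the tests.

Desk-scale configuration (`configs/tiny.yaml`, `ofml.tiny_config`): 32-px
images, CNN width 8 with one bottleneck per stage and the small stem
(tap (32, 16, 16)), transformer views (16, 24, 32) with one layer each,
global width 32 and depth 3, 2 heads, patch size 8, batch 16, 30 epochs.
Learning rate 1e-3 — the conventional Adam setting for small transformer
stacks (0.01 is a large-batch GPU-scale choice). The end-to-end study
trains this configuration on the frozen synthetic dataset below.

### Ablation variants

`build_ablation_variant` reconstructs the component study: A = CNN alone;
B = plain single-view transformer; C = both branches, no multi-view
fusion, no heads (each branch trained by its own cross-entropy); D = C
with multi-view encoding; E = D + ensemble classifier (adds T²·L_ensemble);
F = D + fusion classifier (adds FPKT and the fusion CE, no ensemble);
G = E + F; `full` = G + Mixup. AFC1/2/3 move the tapped pair to residual
stage / global-encoder layer 1, 2 or 3 (256/512/1024-channel CNN taps).
Where no fusion head exists, branches reduce to plain supervised training;
where only one branch exists, prediction uses its logits; with both but no
heads, prediction uses the logit mean.

## Synthetic data (`ofml.data`)

The generator emulates the coarse visual statistics of H&E-stained tissue:
an eosin-pink background with Gaussian sensor noise, scattered with
darker blue-purple elliptical nuclei (random centers, semi-axes, rotation,
per-nucleus color jitter). Class k controls nucleus density (8 + 26k per
64² patch), nucleus size (semi-axes alternating between 2.0–4.5 and
3.5–6.0 px at 64-px scale) and stain darkness — mirroring how nuclear
density and hyperchromasia separate tissue grades. The frozen defaults
make classes separable even by a pixel-mean nearest-centroid rule (>0.9
training accuracy, tested), which is what lets a small network overfit
cleanly in 30 epochs.

What the generator does *not* emulate: staining variability, tissue
architecture (glands, stroma), magnification effects, scanner artifacts,
class-imbalanced long tails. Passing tests therefore demonstrate that the
architecture, losses and training loop are implemented correctly and can
extract separable texture signal — not that the model reaches benchmark
accuracy on real pathology slides. The published benchmark figures
require the real BreakHis/BACH images and GPU-scale training, both out of
scope here. (The benchmark's own benign/malignant totals are quoted
inconsistently across its descriptions; the folder reader enforces no
particular count.)

Mixup defaults: α = 0.2 (the common small-α setting; only the technique
itself, not α, is specified upstream), factor 4 read as originals + 3
mixed copies (this reproduces the published 1 736→6 944 and 70→280
expansions exactly and retains the unmodified originals), partners drawn
from the whole training set (standard Mixup; a `within_class` flag
implements the stricter "related labels" reading). The test split is never
expanded.

## Evaluation (`ofml.evaluation`)

Accuracy, macro precision/recall/F1 and one-vs-rest macro AUC (macro
averaging chosen for the multi-class case; binary results are unaffected),
all via scikit-learn; a class absent from the ground truth has an
undefined one-vs-rest AUC and is dropped from the macro with a warning.
Grad-CAM uses spatially averaged gradients of the final classifier's
target-class score as channel weights on a tapped map, rectifies,
min-max normalizes, and upsamples bilinearly; `tap="fusion-input"`
averages the two branch CAMs. t-SNE (scikit-learn) embeds the fusion
head's 1024-dimensional pooled-concatenated features; perplexity is
min(30, (n−1)/3) and a fixed seed makes the table reproducible.

## Numerical choices

* The autodiff engine (`ofml.autodiff`) computes in double precision —
  on CPU the BLAS cost difference is modest, and the loss terms then match
  an independent float64 oracle to well below 1e-6.
* Softmax and log-softmax are max-shifted; Beta and Dirichlet draws come
  from NumPy generators; all RNG flows through `numpy.random.SeedSequence`
  spawning so seeds stay independent per role.
* Batch-norm uses batch statistics in training mode with running-average
  (momentum 0.1) statistics for evaluation; evaluation mode is therefore
  deterministic.
* Ties in argmax resolve to the lowest index (NumPy convention); the
  split floors train counts, guaranteeing a non-empty test split for any
  fraction < 1; empty datasets are rejected at expansion and fitting.

## Known limitations

* Single-process CPU training only; no mixed precision, no GPU, no
  distributed training, no learning-rate schedules or early stopping.
* No stain normalization or WSI tiling; the readers expect per-image
  class-labelled folders.
* Pretrained CNN initialization is not provided (runs are reproducible
  from random init without downloads).
* The desk-scale study demonstrates mechanism, not clinical performance;
  see the synthetic-data section for what it cannot show.
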