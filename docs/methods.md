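# Methods

## Scope and design

`dsadet` implements a real-time detection transformer for five-class tea
leaf disease detection (Blister Blight, Brown Blight, Gray Blight, Red
Rust, Healthy) in two configurations: a baseline with a ResNet-18
backbone, a softmax-attention intra-scale encoder layer (AIFI) and a
CNN cross-scale fusion pyramid (CCFM), and the improved model in which a
CSP-attention backbone (DASPMNet), a linear-attention encoder block
(HSATE) and a shuffle/shift upsampler (ESCU) replace their counterparts.
Every intermediate combination of the three swaps is constructible, so
the ablation grid is a first-class API (`variant=` flag).

The whole stack runs on a compact reverse-mode autograd engine over
numpy (`dsadet.nn`).  Writing the engine in-package keeps the system
dependency-free and auditable: convolution is im2col + BLAS matmul with
an explicit col2im backward, and each dense primitive reports its
multiply–accumulate count into a process-global counter, which is what
the profiler reads.  The engine is validated against central-difference
gradients in the test suite.

## Model components

**AFEB / SAB (backbone).**  An AFEB projects its input with a 1×1 conv,
splits channels in half, passes one half through a cascade of `n`
self-attention blocks and concatenates the untouched half with the
output of *every* cascade stage before a terminal 1×1 conv, so the block
emits `(n+1)·C/2` channels into the terminal projection.  A SAB is a
prompt-guided global-context operator: a learnable prompt vector is
projected to the block width, broadcast over the grid, concatenated with
the features and reduced to one attention logit per position; a spatial
softmax turns the logits into an attention map that weights a 3×3 value
path, whose aggregate (a global context vector) is transformed by a 1×1
conv and added residually.  Two consequences are used as tests: with a
uniform attention map the block adds exactly the spatially averaged
(transformed) value path, and with zeroed value/transform weights it is
the identity.  The attention logit conv carries no bias, because the
spatial softmax is invariant to a uniform logit shift (the bias would be
a structurally gradient-free parameter).

**Polarized linear attention (encoder).**  Queries and keys are split
into positive and negative parts (`ReLU(x)`, `ReLU(−x)`); each polarity
is kernelized with `ϕ = ReLU(·)^α` and contracted against the pooled
summary `(1/N)·ϕ(K±)ᵀV` (d×d), normalized by the pooled kernelized key
mass `ϕ(Q±)·mean(ϕ(K±)) + ε` with `ε = 1e-6`, and the two polarity
terms are combined with opposite signs.  Three open choices were made
here: the sign-split definition of the polarities, the signed
combination of the two terms (a pure rectified combination would discard
all sign information carried by the negative polarity), and the
normalizing denominator (the linear-attention form is otherwise
unbounded in magnitude).  α is learnable, initialized at 1.0 (plain
rectifier kernel) and clamped to [0.5, 3].  Heads: 8 at width 256.  The
implementation never materializes an N×N matrix; the test suite verifies
both numerical equivalence with an explicit-loop evaluation and the
linear (affine-in-N) multiply–accumulate count.

**PSEN.**  The FFN replacement takes the block input plus the block's
skip tokens, expands them with a 1×1 conv into a fusion half F1 and a
gating half F2, computes a context branch by average-pooling the grid by
2, applying two 3×3 convs with GELU and restoring resolution by nearest
upsampling, then fuses `[context, F1]` through 1×1 → depthwise 3×3 →
GELU → 1×1 and gates elementwise with `sigmoid(F2)`.  Odd grids are
zero-padded on the bottom/right before pooling and cropped after.

**MAEM.**  `X + Conv1×1(Dropout(GELU(MAEMOp(Conv1×1(X·γ + LN(X)·γ_x)))))`
with `MAEMOp(X) = X + (1/3)·Σ_{k∈{3,5,7}} DWConv_k(X + Conv1×1(X))`.
γ initializes to 1 and γ_x to 0, so the layer starts as a plain residual
refinement of the unnormalized stream; dropout defaults to 0.1 and is
inert in eval mode.

**ESCU.**  Order of operations: nearest ×2 → depthwise-separable conv
(BN + SiLU) → channel shuffle → spatial shift.  Defaults `G = 4`,
`s = 1` — the smallest non-trivial mixing — and both are config values.
ESCU replaces the two lateral-conv + interpolate upsample sites of the
fusion pyramid; its pointwise conv takes over the channel-mixing role of
the removed lateral conv.

**Decoder.**  Standard deformable-attention decoder with
uncertainty-minimal query selection: a linear + layer-norm projection
scores all fused pyramid tokens, the top `num_queries` seed the object
queries, initial boxes are predicted relative to level-dependent grid
anchors, and each of the 3 layers refines boxes in inverse-sigmoid
space.  Classification heads emit `num_classes + 1` logits; the
background class serves the set-prediction loss.  No NMS anywhere.

## Structural calibration

Stage widths, cascade depths and decoder dimensions are config values.
The full preset uses ResNet-18 widths (64, 128, 256, 512), hidden dim
256, CSP fusion blocks at expansion 0.5 with 3 rep-style blocks, 3
decoder layers with 300 queries, and DASPMNet with the same stage widths
and per-stage cascade depths (1, 2, 3, 3).  These were fixed once so
that whole-model trainable-parameter counts land on the published
budgets of the ablation grid (19.9 M baseline, 13.6 M backbone-only,
21.6 M encoder-only, 20.0 M upsampler-only, 15.4 M full model); the
implementation reproduces all five within ±2.2%.  FLOPs are counted as
2 × multiply–accumulates of conv/matmul/sampling ops at 640-px input
(normalizations and elementwise ops excluded); the baseline measures
56.0 GFLOPs.  The published per-variant FLOP figures are not mutually
consistent under any fixed counting convention (the deltas of single
swaps do not compose across combined rows), so the profiler's measured
values are reported as-is rather than matched per cell.

## Synthetic data

Real annotated field imagery for this task is not redistributable, so
the generator renders procedural stand-ins: a textured brownish
background, an elliptical green leaf with low-frequency shading, and
class-specific lesions — pale circular blisters, dark irregular
blotches (angle-modulated radius), desaturated ringed patches, orange
speckle clusters, or no lesion for the healthy class (whose annotation
covers the leaf).  Boxes are tight around the rendered lesion mask.
Lesion extent is controlled by a three-way scale with guaranteed bounds:
`small` boxes stay below 1% of the image area, `large` ones cover at
least 10% (the blotch's radius modulation is capped at 15% per axis so
the bound survives).  Every image is a pure function of
(class, seed, scale, size).

What the generator does *not* emulate: occlusion, specular lighting,
leaf overlap, multiple disease classes per leaf, and the texture
statistics of real lesions.  Tests passing on this data show that the
architecture, losses and metrics are wired correctly and that the model
can memorize and localize — they say nothing about field accuracy.

Augmentations (training split only): random rotation with analytic box
remapping (axis-aligned bound of the rotated corners, validated against
mask-rotation re-fitting to ~2 px), hue shift in HSV, and additive
Gaussian noise.  The 5:1:2 split uses train = ⌊5n/8⌋, val = round(n/8),
test = remainder — the rounding that maps 4778 originals to
(2986, 597, 1195) exactly — with largest-remainder stratification per
class.  The augmentation multiplicity is a config rate (default 0: the
expansion factor behind a 4180-image training set has no published rule).

## Evaluation

Greedy same-class matching in descending score order (ties broken by
detection index), each ground truth matched at most once.  AP uses
101-point interpolation; an exact all-point variant exists for
cross-checks.  mAP50:95 averages IoU 0.50:0.05:0.95.  Dataset-level
P/R/F1 are reported at the score threshold maximizing F1 at IoU 0.5,
since the operating point behind published headline P/R values is never
stated.  The evaluator is tested to 1e-6 against a brute-force
all-cutoff PR integration that shares no code with it.

## Training

Set-prediction loss: Hungarian matching (cost 2·class + 5·L1 + 2·GIoU),
then cross-entropy over `num_classes + 1` labels with background weight
0.1, L1 on normalized cxcywh boxes (weight 5) and GIoU (weight 2),
applied to every decoder layer and to the encoder's selected proposals.
Full-scale defaults follow the published recipe (AdamW, lr 1e-4, weight
decay 1e-4, batch 4, 640 input, 2000 warm-up iterations — read as
iterations, since 2000 warm-up *epochs* against 300 max epochs is
impossible).

**Desk scale.**  CPU experiments use the `desk` preset: 64-px input,
widths (16, 32, 64, 128), hidden dim 64, 2 decoder layers, 30 queries
(~0.7 M parameters).  The overfit sanity protocol trains this preset on
16 synthetic images restricted to medium/large lesions at lr 3e-4 with
gradient clipping at norm 10: at 64-px rendering a "small" lesion box is
3–6 px, below what IoU ≥ 0.5 localization can resolve, and the
full-scale lr/clipping pair converges too slowly for a 2000-step budget.
Under this protocol the full model reaches train-set mAP50 > 0.9 within
2000 steps (~5 minutes on one CPU core).

## Numerical choices

- float32 throughout the models; float64 preserved when fed in (used by
  the gradient checks).  Stable sigmoid/SiLU forms.
- Linear-attention normalizer ε = 1e-6; GIoU denominators guarded with
  1e-9; inverse-sigmoid clamped at 1e-5.
- Deformable attention samples 4 points per head per level with the
  conventional ring-shaped offset initialization; sampling locations are
  clamped to the feature border, with zero gradient outside it.
- Score ties in evaluation break by detection index; the channel shuffle
  and spatial shift are exact permutations (tested bit-exactly).

## Known limitations

- No pretrained backbone weights; all results are from random init.
- No denoising-query training, mixed precision, or fused kernels.
- The profiler excludes normalization/elementwise FLOPs; conventions
  that include them would read a few percent higher.
- Desk-scale training demonstrates memorization, not generalization;
  full-resolution training of the 15 M-parameter model is outside the
  intended use of the numpy engine.
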