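# Methods

This note records the model as implemented, the conventions behind the
efficiency numbers, the parameter choices that were genuinely open, and
what the synthetic-data experiments do and do not show.

## Backbone geometry

All ladder variants share a four-stage multiscale skeleton: stage depths
(1, 2, 5, 2) — ten blocks — with widths (96, 192, 384, 768) and heads
(1, 2, 4, 8), stride-4 stem, 224×224 input, classification by global
average pooling and an affine head.  This is the unique published "tiny"
profile of the multiscale-ViT family with ten blocks, and with a 4-class
head its parameter count lands on the baseline budget the package
reproduces (23.40 M).

Stage transitions double the width inside attention: the first block of
stages 2–4 projects queries/keys/values from `d` to `2d` and pools
queries with stride 2.  The residual around attention then needs a width
change; it is a linear shortcut applied before pooling, and the spatial
shortcut is a parameter-free 2×2 average pool.  Keys and values are
pooled to a resolution ceiling of `image/16` (14×14 at 224), never finer
than the query grid; this keeps attention cost bounded in the early
high-resolution stages.  Queries, keys and values each pass a 3×3
depthwise pooling convolution in every block (stride 1 where no
downsampling happens).  A pooled-query residual is added inside the
mixer.  Relative positional embeddings are not used; token order enters
only through the pooling convolutions.  Pool-side layer norms are
omitted.

## DIC stem

The stem composes (1) a dynamic strided projection — K = 4 candidate
3×3 kernels blended per sample by `softmax(FC2(FC1(GAP(x))))` (two affine
maps, no intermediate nonlinearity, temperature 1) and applied as one
stride-4 convolution to 96 channels — and (2) a four-branch depthwise
mixer that splits channels 1/8 : 1/8 : 1/8 : 5/8 into a 3×3 square
branch, 1×11 and 11×1 band branches, and an identity branch, then
concatenates.  The orthogonal band pair supplies a large receptive field
at band-kernel cost; the whole stem carries 10.9 k parameters against
14.2 k for a dense 7×7 stem.  The projection kernel uses the small
(square-branch) size rather than a large kernel: sampling a stride-4
grid with 3×3 taps plus the band mixer replaces the dense 7×7 receptive
field.  Dynamic blending wraps only the projection; the depthwise
branches are static (a flag can extend blending if wanted).

## COKA block

Per block: `x' = skip(x) + Attn(ODC(Norm(x)))`, then
`y = x' + KAN(Norm(x'))` (pre-norm residual layout).

**ODC.**  A shared `GAP → FC → ReLU` trunk feeds four sigmoid heads
producing attention over spatial taps (kh·kw), per-group input channels,
output filters, and the kernel index; the effective kernel
`Σᵢ α_wᵢ·(α_fᵢ ⊙ α_cᵢ ⊙ α_sᵢ ⊙ Wᵢ)` is assembled per sample and applied
as one convolution.  All four heads are sigmoid (a softmax toggle exists
for the kernel-wise factor).  Head biases are initialised at +2 so the
gates start near open (σ(2) ≈ 0.88): with four independent gates near
0.5 the assembled kernel would be scaled by ≈ 0.5⁴ at initialisation,
which measurably starves the attention stage of signal early in
training.  The packaged profile uses n = 2 candidate kernels and grouped
convolution with 24 channels per group; the module default is n = 4,
dense.

**Linear attention.**  `σ(Q)·(σ(Kᵀ)·softmax(V))/√d_k`, right-to-left, so
the key–value summary is a d_k×d_k matrix and cost grows linearly in
tokens.  The softmax acts over each value token's **feature axis**; a
token-axis softmax would force the quadratic evaluation order and is
available only as a config switch.  The √d_k division is applied once to
the final product.

**Contrastive normalization.**  `x ← (1+s)·x − s·softmax(x xᵀ)·x`
followed by layer normalization; s = 0.1 by default and s = 0 reduces
bit-exactly to plain layer norm.  The dispersal step counteracts
dimensional collapse by repelling similar tokens.  Exactly coincident
tokens cannot separate (they receive identical updates by symmetry); the
dispersal acts on near-collapsed configurations.

**KAN feed-forward.**  Edge functions are B-spline expansions on a fixed
uniform grid over [−1, 1] (G = 5 intervals, order k = 3, hence G + k
basis functions) plus a `silu` base gate:
`φ(x) = w_b·silu(x) + w_s·Σ_m c_m B_m(x)`.  Inputs beyond the grid are
extended linearly from the boundary; the grid is static, so evaluation
is deterministic.  Three layouts exist: the full in×out edge grid, a
bottleneck pair (width tunable), and the channel-wise diagonal form (one
univariate spline per channel, G + k + 2 parameters each).  The packaged
ILViT profile uses the channel-wise form: the ablation budgets fix the
feed-forward replacement at essentially zero parameters (the V3→V4 step
removes almost exactly the MLP totals), and only the diagonal form meets
that while preserving a trainable nonlinear stage.  Since it follows
normalization, its inputs are approximately standardized, matching the
[−1, 1] grid with linear extrapolation covering the tails.

**Quantized tail.**  Training stays full precision; quantization is
simulated in the forward pass (fake-quant) with a straight-through
gradient.  The tail activation uses an 8-bit uniform quantizer with a
running min/max observer (frozen in eval mode); the final affine layer
quantizes its weights uniformly from their min/max each forward.  For
inference-style probabilities, `poly_softmax` builds the softmax from a
second-order polynomial approximation of the exponential on
[−ln 2, 0] (range reduction `e^x = 2^−z·e^r`; max relative error < 1%)
and can round the result onto the log2 exponent grid
(`code = round(−log2 p)`).  Parameter counts always report full
precision: quantization is a bit-width reduction, not an architecture
shrinkage.

## FLOP-counting convention

`count_flops` counts multiply–accumulates (1 MAC = 1 FLOP) of
convolutions and affine maps only — including the q/k/v/output
projections, pooling convolutions, shortcut projections, ODC kernels and
attention subnets, KAN edge evaluations (G + k + 2 MACs per edge), and
the head.  Attention score/value products, normalizations (including the
ContraNorm similarity products), softmaxes and element-wise gates are
excluded; `include_attention=True` adds the attention products
(2·L_q·L_kv·d for the softmax form, (L_q + L_kv)·d_k·d for the linear
form).  The default convention is what reconciles the ladder budgets
this package reproduces; profilers that hook only conv/linear modules
measure the same quantity.

Under this convention the ladder profiles at 3×224×224 with a 4-class
head are: baseline 23.40 M / 3.965 G; V0 and V1 23.40 M / 3.930 G;
V2 and V3 25.00 M / 4.215 G; V4 9.02 M / 1.913 G.  Per-module breakdowns
sum to the totals exactly, and parameters are summed from the live
modules.

## Training protocol

AdamW (lr 1e-4, eps 1e-8, betas (0.9, 0.999), decoupled weight decay
1e-4, no decay on rank-1 parameters), batch size 32, cosine annealing to
lr_min 1e-6 over the epoch budget (500 by default) with linear warmup
from 1e-6 over 20 epochs (warmup length is not part of the protocol
tables; 20 is this package's default and is configurable).  Loss is
mean cross-entropy on logits; a zero probability on the true class is
clamped at 1e-12 when probabilities are supplied directly.  No label
smoothing, mixup or weight averaging.  One integer seed derives three
independent streams (initialisation, data order, augmentation) via a
seed sequence.

Training images are rotated uniformly in ±15°, passed through the
standard 25-sub-policy IMAGENET AutoAugment table (implemented on PIL
primitives), resized to the model input and standardized with means
(0.485, 0.456, 0.406) and stds (0.229, 0.224, 0.225).  Evaluation uses
resize + standardize only.  Robustness perturbation adds zero-mean
Gaussian noise of sd σ (default 0.05) on the [0, 1] intensity scale
after resize and before standardization, clipped to [0, 1] — σ is
unitless, so the [0, 1] scale is the natural reading.  Dataset splits
are stratified 8:2 per class (stratification keeps minority classes
represented in both splits).

Micro accuracy is trace/total of the confusion matrix, which coincides
with micro recall and micro F1; per-class tables report accuracy (=
class recall), precision and recall, with zero-denominator classes set
to 0 under a warning.  A literal denominator Σ(TP+FP+FN) — which counts
every error twice — is available behind `literal=True` for comparison.

## Synthetic data

The generator draws four morphology classes on a noisy background:
fusiform (10–12 strongly elongated ellipses, aspect ≈ 6), epithelioid
(10–14 rounded blobs with darker nuclei), cobblestone (a dense jittered
polygonal tessellation, 8 cells per side), and mixed (5–6 spindles plus
≈ 6 blobs in one field — a balanced co-occurrence, so the class is not a
superset of fusiform).  Classes differ in shape statistics and hue;
deterministic per seed, byte-identical across runs.

It emulates class-conditional morphology and staining variation.  It
does **not** emulate optics (defocus, vignetting, chromatic effects),
inter-laboratory stain shifts, touching/overlapping cell clusters,
annotation noise, or class imbalance unless configured.  Tests passing
on synthetic data therefore demonstrate that the architecture, losses
and training loop are sound and that the components interact as
specified — not that real-data accuracies are reproduced.  The published
accuracies on the four public datasets require full-scale training on
external data and are out of scope here.

## Problem sizes in the test suite

Efficiency budgets are computed at the full 224×224 geometry
(construction + arithmetic only).  Training-sanity experiments run the
entire ladder at a reduced geometry chosen for desk-scale runs: 32×32
inputs, two stages (depths (1, 1), widths (16, 32), heads (1, 2)), a
kv-pooling ceiling of 4, and 64 synthetic images (16 per class); every
ladder substitution is preserved.  At this scale each variant reaches
≥ 95% training accuracy within 300 optimizer steps under the protocol
above.

## Numerical choices

- Float64 throughout; oracle equivalences hold to 1e-5–1e-9.
- Layer norm eps 1e-6; softmax computed with max-shift.
- B-spline evaluation by the Cox–de Boor recursion on the full knot
  vector; degree-0 bases are half-open interval indicators, so partition
  of unity holds strictly inside the grid.
- Uniform quantizer: `code = clamp(round(x/scale) + zero_point, 0, 2^b−1)`
  with scale/zero-point from the calibration min/max; round-trip error is
  ≤ scale/2 in range and quantize∘dequantize is idempotent.
- Eval-mode forwards are bit-deterministic; model construction from a
  config and seed is parameter-wise reproducible.

## Known limitations

- CPU-bound NumPy execution: full-size forwards cost seconds; the
  package profiles full-size models analytically and trains reduced
  geometries in its own test harness.
- The ContraNorm similarity is dense (L×L); at stage-1 resolution this
  dominates full-size forward runtime (it is excluded from the MAC
  convention, as a normalization).
- No integer-only inference kernels; quantization is simulated.
- Grid refinement / adaptive KAN grids are not implemented (static grid
  by design, for determinism).
- The baseline omits relative positional embeddings; comparisons against
  implementations that include them will differ by ≈ 0.06 M parameters.
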