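# ilvit

A lightweight vision transformer for microscopic cell classification,
built around two ideas: a **Dynamic Inception Convolution (DIC)** stem and
a **Contrastive Omni-Kolmogorov Attention (COKA)** block.  The package is
aimed at people who classify cell imagery — cultured retinal pigment
epithelium, HEp-2 immunofluorescence patterns, bone-marrow smears, blood
leukocytes — on modest hardware, where the parameter and FLOP budget of a
standard multiscale vision transformer is the binding constraint.

Everything runs on a self-contained NumPy reverse-mode autodiff core: no
GPU framework is required for building, profiling, training or testing.

## The architecture

The backbone is a four-stage multiscale transformer (stage depths
[1, 2, 5, 2], widths 96→768, heads 1→8, stride-4 stem, pooled keys and
values inside attention).  The package provides the full ablation ladder
from that baseline to ILViT:

| variant | change over the previous rung |
|---------|-------------------------------|
| baseline | 7×7 conv stem + softmax pooling attention + MLP |
| V0 | DIC stem: K softmax-blended kernels project the image, then a four-branch depthwise mixer (ks×ks square, 1×kb and kb×1 band kernels, identity; ks = 3, kb = 11) |
| V1 | activation-gated linear attention: `σ(Q)·(σ(Kᵀ)·softmax(V))/√d_k`, evaluated right-to-left so cost is linear in token count |
| V2 | omni-dimensional dynamic convolution before attention: `y = (Σᵢ α_wᵢ·α_fᵢ·α_cᵢ·α_sᵢ·Wᵢ) ∗ x` with sigmoid attention over spatial taps, input channels, filters and kernel index |
| V3 | contrastive normalization `x ← (1+s)·x − s·softmax(x xᵀ)·x` + layer norm, dispersing tokens against dimensional collapse |
| V4 = ILViT | KAN feed-forward (trainable B-spline edge functions, `φ(x) = w_b·silu(x) + w_s·Σ c_m B_m(x)`) replacing the MLP, plus a log2/uniform-quantized tail |

A `KANLayer` with the full in×out edge grid, a bottleneck pair, and the
near parameter-free channel-wise form are all available; the packaged
profile uses the channel-wise form (see `src/ilvit/profiles/ilvit_default.yaml`
for the calibration arithmetic).

## Worked example

```python
import numpy as np
from ilvit import build_model, ilvit_default_config, profile_model, tiny_test_config
from ilvit.datapipe import SyntheticDatasetSpec, generate_synthetic
from ilvit.trainkit import TrainConfig, train, evaluate

# efficiency profile of the full-size model (construction only, seconds)
report = profile_model(build_model(ilvit_default_config("V4"), seed=0))
print(report.table())

# train a reduced-geometry ILViT on 64 synthetic cell images
ds = generate_synthetic(SyntheticDatasetSpec(per_class_count=16, image_size=32, seed=7))
tc = TrainConfig(batch_size=32, epochs=500, warmup_epochs=20, seed=1, max_steps=300)
model, history = train(tiny_test_config("V4"), tc, ds)
print(f"train accuracy    {evaluate(model, ds).accuracy:.3f}")
print(f"with sigma=0.05   {evaluate(model, ds, noise_sigma=0.05).accuracy:.3f}")
```

prints

```
module              params      MFLOPs
stem                10,908        9.30
block0              84,251      186.69
...
block9           2,802,659      125.20
head                 4,612        0.00
total            9,019,662     1913.40
=> 9.02 M params, 1.91 GFLOPs
train accuracy    0.969
with sigma=0.05   0.938
```

The profile says the assembled ILViT carries 9.0 M trainable parameters
and 1.91 G multiply–accumulates for one 224×224 forward pass (conv +
affine MACs; the convention is documented in `docs/methods.md`).  The
training lines show the model overfitting a 64-image synthetic 4-class
set within 300 optimizer steps, and that its accuracy degrades only
mildly when σ = 0.05 Gaussian noise is injected into the test images.

The same operations are available from the shell:

```
ilvit profile --variant V4 --input 3x224x224
ilvit synth   --out data/ --per-class 25 --split 0.8
ilvit train   --data data/train --out run/ --variant V4
ilvit eval    --ckpt run/checkpoint.npz --data data/test --noise-sigma 0.05
```

## Layout

- `src/ilvit/tensor.py`, `nn.py` — autodiff core and layer library
- `src/ilvit/dic.py`, `odc.py`, `attention.py`, `kan.py`, `norm_quant.py` — the architecture components
- `src/ilvit/model.py` — ladder assembly + analytic profiler
- `src/ilvit/datapipe.py` — transforms, augmentation, synthetic generator, noise protocol
- `src/ilvit/trainkit.py` — loss, metrics, AdamW + cosine schedule, train/eval
- `src/ilvit/cli.py` — the `ilvit` command
- `docs/methods.md` — model assumptions, conventions, parameter choices, limitations
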