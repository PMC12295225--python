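# Packaged full-size ILViT profile (the "ilvit-default" geometry).
#
# Shared skeleton: four stages, ten blocks, stride-4 stem, 224x224 input,
# 4-class head.  The efficiency ladder it produces under the package's MAC
# convention (conv + affine multiplies only; attention products,
# normalizations and element-wise ops excluded):
#
#   baseline  23.40 M   3.965 G
#   V0 / V1   23.40 M   3.930 G
#   V2 / V3   25.00 M   4.215 G
#   V4 (ILViT) 9.02 M   1.913 G
#
# Calibration notes (done once, from the block arithmetic):
# * odc_num_kernels=2 with odc_group_width=24: the omni-dimensional dynamic
#   convolution budget is fixed by the V1->V2 increment (~ +1.7 M params,
#   +0.29 G FLOPs).  A grouped 3x3 with 24 channels/group costs
#   n*9*24*sum(d) = 1.41 M kernel params and 9*24*sum(d*L) = 0.284 G MACs,
#   which lands that increment with n = 2 candidate kernels.
# * kan_mode=channelwise: the V3->V4 step removes almost exactly the MLP
#   totals (16.02 M params / 2.31 G FLOPs), so the feed-forward replacement
#   must be near parameter-free.  One univariate spline per channel
#   (G=5, k=3 -> 10 params/channel) adds only 0.039 M params / 0.011 G.
#   Full-edge and bottleneck KAN layers remain available via kan_mode.
# * dic branch_ratios (1/8, 1/8, 1/8, 5/8) follow the Inception-style
#   depthwise-mixer convention; the dynamic stride-4 projection uses the
#   small kernel (ks=3) with K=4 candidates, so the stem costs 10.9 k
#   params versus 14.2 k for the dense 7x7 baseline stem.

variant: V4
num_classes: 4
image_size: 224
stage_depths: [1, 2, 5, 2]
embed_dims: [96, 192, 384, 768]
stage_heads: [1, 2, 4, 8]
mlp_ratio: 4.0
stem_stride: 4
baseline_stem_kernel: 7
dic:
  in_channels: 3
  embed_dim: 96
  num_kernels: 4
  small_kernel: 3
  band_kernel: 11
  branch_ratios: [0.125, 0.125, 0.125, 0.625]
  stem_stride: 4
  attn_reduction: 4
odc_num_kernels: 2
odc_group_width: 24
odc_reduction: 16
contranorm_scale: 0.1
kan_mode: channelwise
kan_width: null
kan_grid_size: 5
kan_spline_order: 3
quant_bits: 8
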