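# YOLO-WL layer manifest.
#
# Backbone: GCBS downsamples with C2f-MSDDSC context stages; the stride-32
# tail (rows 7-9) is channel-compressed to 128 (layer-wise feature
# compression). Neck: SSA-PAN over the shallow pyramid P2-P4 with SGF
# gated junctions and MLKSA spatial-attention gates feeding the head.
#
# Row 5 prints 1048 in the published table, but the gcd-grouped build of
# GCBS [64, 128, 3, 2] gives 1408, and the printed per-row sum differs
# from the printed 1,394,688 total by exactly 360 = 1408 - 1048: a
# transposition typo, carried here via corrected_params.
name: yolo-wl
num_classes: 6
reference_input: 640
summary:
  total_params: 1394688
  trainable_params: 1394672
  gflops: 9.9
msddsc:
  e: 0.75
  rates: [1, 2, 3]
  kernel: 3
  expand_ratio: 1.0
  pw_ratio: 1.0
  fuse_kernel: 3
  fuse_ratio: 1.0
  compress_bn: true
  branch_bn: true
  pw_bn: true
  fuse_bn: false
  fuse_bias: false
  gate_kernel: 7
  gate_bias: false
  residual: true
  residual_projection: false
layers:
  - {index: 0, from: -1, repeats: 1, module: GCBS, args: [3, 16, 3, 2], expected_params: 464}
  - {index: 1, from: -1, repeats: 1, module: GCBS, args: [16, 32, 3, 2], expected_params: 352}
  - {index: 2, from: -1, repeats: 1, module: C2f-MSDDSC, args: [32, 32, 1], expected_params: 11882}
  - {index: 3, from: -1, repeats: 1, module: GCBS, args: [32, 64, 3, 2], expected_params: 704}
  - {index: 4, from: -1, repeats: 2, module: C2f-MSDDSC, args: [64, 64, 2], expected_params: 82916}
  - {index: 5, from: -1, repeats: 1, module: GCBS, args: [64, 128, 3, 2], expected_params: 1048,
     corrected_params: 1408, note: transposition typo; per-row sum vs printed total differs by 360}
  - {index: 6, from: -1, repeats: 2, module: C2f-MSDDSC, args: [128, 128, 2], expected_params: 325380}
  - {index: 7, from: -1, repeats: 1, module: GCBS, args: [128, 128, 3, 2], expected_params: 1408}
  - {index: 8, from: -1, repeats: 1, module: C2f-MSDDSC, args: [128, 128, 1], expected_params: 179330}
  - {index: 9, from: -1, repeats: 1, module: SPPF, args: [128, 128, 5], expected_params: 41344}
  - {index: 10, from: -1, repeats: 1, module: Upsample, args: [null, 2, nearest], expected_params: 0}
  - {index: 11, from: [-1, 6], repeats: 1, module: SGF-2, args: [1], expected_params: 102}
  - {index: 12, from: -1, repeats: 1, module: C2f, args: [256, 128, 1], expected_params: 131840}
  - {index: 13, from: -1, repeats: 1, module: Upsample, args: [null, 2, nearest], expected_params: 0}
  - {index: 14, from: [-1, 4], repeats: 1, module: SGF-2, args: [1], expected_params: 102}
  - {index: 15, from: -1, repeats: 1, module: C2f, args: [192, 64, 1], expected_params: 37248}
  - {index: 16, from: -1, repeats: 1, module: Upsample, args: [null, 2, nearest], expected_params: 0}
  - {index: 17, from: [-1, 2], repeats: 1, module: SGF-2, args: [1], expected_params: 102}
  - {index: 18, from: -1, repeats: 1, module: C2f, args: [96, 32, 1], expected_params: 9408}
  - {index: 19, from: -1, repeats: 1, module: MLKSA, args: [32], expected_params: 990}
  - {index: 20, from: -1, repeats: 1, module: Conv, args: [32, 32, 3, 2], expected_params: 9280}
  - {index: 21, from: [-1, 4, 15], repeats: 1, module: SGF-3, args: [1], expected_params: 103}
  - {index: 22, from: -1, repeats: 1, module: C2f, args: [160, 64, 1], expected_params: 35200}
  - {index: 23, from: -1, repeats: 1, module: MLKSA, args: [64], expected_params: 990}
  - {index: 24, from: -1, repeats: 1, module: Conv, args: [64, 64, 3, 2], expected_params: 36992}
  - {index: 25, from: [-1, 6, 12], repeats: 1, module: SGF-3, args: [1], expected_params: 103}
  - {index: 26, from: -1, repeats: 1, module: C2f, args: [320, 128, 1], expected_params: 140032}
  - {index: 27, from: -1, repeats: 1, module: MLKSA, args: [128], expected_params: 990}
  - {index: 28, from: [19, 23, 27], repeats: 1, module: Detect, args: [6, [32, 64, 128]], expected_params: 346018}
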