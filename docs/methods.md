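# Methods

This note documents the modeling and numerical choices behind the kit: how
each block is realized, where the published architecture description left
freedom and how that freedom was resolved, what the synthetic generator
does and does not emulate, and known limitations.

## Parameter-count conventions

All printed per-layer budgets are reproduced under three conventions,
applied uniformly:

* a convolution immediately followed by batch normalization carries no
  bias;
* batch normalization is affine — 2 learnable parameters per channel
  (the stem row's arithmetic, 432 weights + 32 BN parameters = 464,
  requires this);
* activations are SiLU throughout the backbone and neck, ReLU inside
  MLKSA, sigmoid at every gate.

**GCBS grouping.** The table's GCBS rows are reproduced by
`groups = gcd(in, out)`: (3,16)→464, (16,32)→352, (32,64)→704,
(128,128)→1408. A "groups = in" rule is indistinguishable on these rows
(in divides out in all of them); gcd is the total function of the two and
is what the kit ships. Row 5 prints 1,048 where the rule gives 1,408; the
printed per-row sum misses the printed total 1,394,688 by exactly
360 = 1,408 − 1,048, so the printed row value is a digit transposition.
The audit reconciles rather than silently corrects: the manifest keeps the
printed value alongside `corrected_params`, and every report repeats the
reconciliation note.

* "SPFF" is read as the standard SPPF (1×1 reduce to in/2, three chained
  stride-1 max pools, concat, 1×1 expand) — the only reading consistent
  with 41,344 at (128,128,5).

## Resolving the C2f-MSDDSC wiring

The published equations fix the MSDDSC data flow (compress → parallel
dilated depthwise-separable branches → concat → 1×1-style integration →
residual) but not the compression ratio, the number of rates, the
normalization/bias placement, or how the unit sits inside the C2f
skeleton. The four printed stage budgets over-determine these choices, so
the kit treats them as a system of constraints: `search_msddsc_config`
enumerates a bounded design space (compression ratio, rate count,
per-branch pointwise pre-projection width, pointwise output width, fusion
kernel 1×1/3×3 and output width, BN/bias placement, an optional
channel-pooled spatial gate at kernel 3/5/7) — about 10⁶ configurations,
exhaustively and in a fixed order, with a deterministic plausibility
ranking among count-equivalent solutions.

Under the stock C2f skeleton (split conv to 2h, units chained on the
second half, merge conv from (2+n)h), the four budgets force the per-unit
cost to U(h) = 33h² + 40.5h + 98 for h ∈ {16, 32, 64} — note the
half-integer linear term and the width-independent constant. The narrow
space implied by the equations alone (dilated depthwise-separable branches
straight on C′) cannot produce either feature; the extended space above
contains exact solutions, and the ranked winner is:

* e = 0.75 (C′ = ⌊0.75·h⌋), rates {1, 2, 3}, depthwise kernel 3;
* per branch: linear 1×1 pre-projection C′ → h, dilated depthwise 3×3
  (BN + SiLU), pointwise 1×1 h → h (BN + SiLU);
* fusion: linear 3×3 convolution 3h → h;
* spatial gate: (mean, max) channel pool → 7×7 convolution → sigmoid,
  multiplying the fused map (exactly 98 parameters — the constant term);
* residual add with the unit input (no projection needed at these widths).

This configuration reproduces all four printed budgets with zero
deviation, and its full-width (non-compressed-tail) variant adds +416k
parameters over the stock C2f stages — matching the published ablation's
"+0.4 M" for the context stages. Observationally equivalent
configurations exist (any of them yields identical counts and near
identical FLOPs); the ranking prefers conventional wiring (bias-free
normalized convolutions, few branches, unit width ratios) and is fixed, so
the search is reproducible. The resolved configuration is serialized in
the shipped manifest's `msddsc` section; tests assert both that the search
recovers it and that a planted configuration in a toy space is recovered
exactly.

Eq-level ambiguity about the residual (the integrated feature has C′
channels but is added to a C-channel input) is exposed as
`residual_projection`: fused widths other than the input width require an
explicit linear projection, otherwise construction is rejected.

## MLKSA and SGF parameter placement

MLKSA's 990 parameters pin the bias/BN placement: branch convolutions
(2→1, kernels 5/7/9/11/13) bias-free with BN (900), the two fusion
convolutions (1×1 5→5 and 3×3 5→1) with bias *and* BN (40 + 48), the
final 1×1 logit convolution with bias only (2). The count is independent
of the input width because the first operation is a channel pool — the
three printed instances (32/64/128 channels) agree, and the tests assert
the invariance.

SGF prints 102 for the two-input junction and 103 for the three-input
one — a delta of exactly 1 per extra input. Independent per-input gates
cannot produce this (any per-input gate conv costs ≥ 19). The kit uses
the single parametric family consistent with both values: one **shared**
5×5 convolution (2→2, bias-free, 100 parameters) applied to each input's
(mean, max) descriptor, channels summed, plus a per-input scalar bias
(+1 each), sigmoid. f(n) = 100 + n gives 102 and 103 exactly. With the
gate saturated the junction degrades to plain concatenation, which the
property tests exploit as an oracle.

## FLOP accounting and the 9.9 GFLOPs figure

`count_flops` pushes a shape probe through the *same* forward code as a
real pass and accumulates, per convolution, 2 · output-elements ·
(in/groups) · k²; normalization, activation, pooling and resampling are
excluded. At 640 × 640 the assembled model costs **11.397 GFLOPs**.

The published summary prints 9.9 GFLOPs. That figure cannot be reproduced
by any realization consistent with the published per-row parameter
counts: for shape-preserving modules, a layer's FLOPs are pinned to
(2 × spatial size × its conv weights), so once the per-row budgets and
the feature resolutions are fixed, the total is forced to ≈ 11.4
regardless of internal wiring (verified over every count-exact
configuration in the search space). The likeliest origin of the printed
number is a hook-based profiler that missed functional (non-module)
convolutions inside custom blocks. The kit reports its analytic count and
states the convention in every report header.

## Detection head, decoding and metrics

The head is the stock decoupled anchor-free design: per level a box
branch (two 3×3 conv-BN-SiLU at width max(16, ch₀/4, 4·reg_max) = 64,
then 1×1 to 4·reg_max) and a class branch (two 3×3 at width
max(ch₀, min(nc, 100)) = 32, then 1×1 to nc), plus the frozen 16-weight
expectation projection — 78,470 + 106,118 + 161,414 + 16 = 346,018 for
nc = 6 over (32, 64, 128). Decoding takes the softmax expectation of each
side's bin distribution, scales by the level stride and anchors at cell
centers; each cell contributes its best class above the confidence floor.

Metric choices the published formulas leave open, fixed here and stated in
the reports: AP uses all-point monotone interpolation (the faithful
discretization of the continuous ∫P dR); matching is class-exact and
greedy by descending score with deterministic tie-breaks (equal scores by
detection index, equal IoU to the earlier ground truth); evaluation uses a
0.001 confidence floor to trace full PR curves and NMS IoU 0.45; classes
absent from the ground truth are excluded from the mean. An independent
brute-force evaluator in the tests agrees on 100 random instances.

## Synthetic scenes

The generator emulates the statistical shape of UAV wildlife imagery, not
its appearance: procedurally textured habitat palettes (desert, grassland,
beach) with multi-octave value noise; 4–16 elliptical "animals" per scene
with class-specific hue and aspect; box sides log-normal with median 22 px
(σ = 0.45, clipped to [4, size/4]) so the realized median sits near 20 px
and >80% of instances fall below 32 × 32 — the small-object regime the
architecture targets; six classes with frequencies following the strongly
imbalanced profile of aerial livestock datasets (class 0 dominant);
10% partial occlusion; mild global brightness jitter. Scenes are
bit-reproducible from (config, seed).

What it does **not** emulate: real texture statistics, perspective,
motion blur, inter-object social structure (herding), or annotation
noise. Passing tests therefore demonstrate the *mechanics* — assignment,
loss, decoding, metrics — are correct and learnable, not that the model
reaches any published accuracy on real data; those numbers require the
original datasets and GPU-scale training and are out of scope here.

## Smoke training

`smoke_train` runs SGD (lr 0.01, momentum 0.937, weight decay 5e-4 — the
architecture's published recipe defaults) on a width-scaled variant of the
manifest (0.25×, ~90k parameters) with a simplified anchor-free loss:
BCE over all cells/classes plus distribution-focal cross-entropy at
center-assigned cells, each ground truth assigned to the finest level
whose (reg_max − 1)-cell range covers its half-extent; sub-cell boxes
clamp their distance targets at zero rather than losing assignment. Loss
gradients w.r.t. the raw head outputs are closed-form and injected into
the reverse-mode engine. The acceptance run uses 200 steps on 64 scenes
at 256², batch 8 — chosen as the smallest run that shows an unambiguous
smoothed-loss decrease on one CPU in a few minutes. Floating-point
non-associativity exempts bit-level reproducibility claims across BLAS
builds; the loss series is reproducible for a fixed seed on one machine.

## Numerical notes and limitations

* The engine is float32 end-to-end; sigmoid/SiLU clip logits at ±60 to
  avoid overflow (σ(60) already rounds to 1.0 in float32).
* BatchNorm uses batch statistics in training mode, running estimates
  (momentum 0.03) in eval mode; two forward passes with fixed weights are
  bit-identical in either mode.
* Max-pool padding uses −∞ so constant inputs are fixed points of the
  SPPF pool chain.
* Inputs must have sides divisible by 32 (the backbone's deepest stride),
  even though the head only taps strides 4/8/16.
* The "362 layers" line in the published summary counts primitive modules
  of a specific framework and is not an audit target; this kit audits
  parameters, gradients and FLOPs.
* The engine is built for correctness and auditability, not throughput:
  a 640² forward pass of the full model takes seconds on CPU; training
  beyond smoke scale, quantization, re-parameterization and edge
  deployment are out of scope.
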