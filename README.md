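# yolowl

A manifest-driven, auditable NumPy model kit for **YOLO-WL**, a lightweight
anchor-free detector designed for wildlife monitoring in UAV imagery, where
most targets are smaller than 32 × 32 pixels. The package is aimed at people
who want to study, verify or extend the architecture itself — its context
blocks, attention gates and shallow neck — without GPUs or external
datasets: every layer is built from a declarative manifest, every parameter
count is checked against the architecture's published per-layer budget, and
a seeded synthetic-scene generator makes the whole pipeline testable
end-to-end on a laptop CPU.

## The architecture

YOLO-WL modifies a YOLOv8n-style backbone/neck/head in four ways:

* **MSDDSC / C2f-MSDDSC** — the backbone's cross-stage blocks carry
  Multi-Scale Dilated Depthwise Separable Convolution units: a 1×1
  compression to C′ = ⌊e·C⌋ channels, parallel dilated depthwise-separable
  branches over rates R = {1, 2, 3} (receptive fields 3/5/7 at equal
  parameter cost), concatenation and fusion, a channel-pooled spatial gate,
  and a residual add. Context at several scales helps separate visually
  similar species.
* **MLKSA** — a spatial attention gate between neck and head: per-pixel
  channel mean/max, five parallel large-kernel convolutions
  (κ = {5, 7, 9, 11, 13}), 1×1 and 3×3 fusion, sigmoid. Because the input
  collapses to two channels immediately, the block costs 990 parameters at
  *any* width.
* **SSA-PAN with SGF** — the neck aggregates the *shallow* pyramid P2–P4
  (strides 4/8/16); no stride-32 feature reaches the head. Each fusion
  junction spatially re-weights its inputs with a shared 5×5 gate
  convolution plus per-input bias (Spatial Guidance Fusion) before
  concatenation.
* **LFC** — the stride-32 backbone tail is channel-compressed (128 instead
  of 256 at deployed width); in this kit that is purely a manifest edit.

The detection head is the stock decoupled anchor-free design with
distribution-focal box regression over `reg_max = 16` bins; the expectation
projection is a frozen 16-weight convolution, which is why the model's
trainable count is exactly 16 below its total (1,394,672 vs 1,394,688).

Evaluation follows the standard protocol: P = TP/(TP+FP), R = TP/(TP+FN),
AP = ∫₀¹ P(R) dR over the monotone-interpolated PR curve, mAP the unweighted
mean over classes present in the ground truth (mAP@0.5 and mAP@0.5:0.95).

Everything — including grouped/dilated convolution, batch normalization and
the backward pass used for smoke training — runs on a small NumPy engine
inside the package (`yolowl.nn`); scipy, Pillow and PyYAML cover the
standard I/O and numerics around it.

## Worked example

```python
import numpy as np
from yolowl import (load_default_manifest, build_model, audit_parameters,
                    count_flops)

manifest = load_default_manifest()          # the published 29-row layer table
model = build_model(manifest, rng=np.random.default_rng(0))

report = audit_parameters(model)
print(report.built_total, report.built_trainable, report.mismatched_rows)
print(round(count_flops(model, 640) / 1e9, 3))
```

prints

```
1394688 1394672 []
11.397
```

meaning: the built model reproduces the published total of 1,394,688
parameters and 1,394,672 gradient-carrying parameters with *zero* per-row
mismatches (row 5 of the table prints 1,048 where the build gives 1,408;
the per-row sum differs from the printed total by exactly 360 = 1,408 −
1,048, so the audit reconciles it as a transposition typo), and one
640 × 640 forward pass costs 11.397 GFLOPs under the convention
1 MAC = 2 FLOPs, convolutions only. The architecture's published figure of
9.9 GFLOPs is *not* reachable from its own per-row parameter budgets at
these resolutions; see `docs/methods.md` for the analysis.

The internal wiring of the C2f-MSDDSC stages is not fully pinned by the
published description; `search_msddsc_config` recovers it by exhaustive,
deterministic enumeration of a bounded design space against the four
printed stage budgets (11,882 / 82,916 / 325,380 / 179,330) and lands on
the shipped default at zero deviation — run
`python examples/resolve_msddsc_config.py` to see it.

Further narrative examples live in `examples/` (one capability per script),
and a thin CLI wraps the same functions:

```bash
yolowl audit                      # row-by-row parameter diff, exit 0 iff exact
yolowl gen --n 16 --out ds/       # synthetic aerial scenes + YOLO labels
yolowl eval --dataset ds/ --detector oracle
yolowl smoke-train --steps 200 --out run/
```

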