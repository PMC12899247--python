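"""Smoke-level training of the detector on synthetic scenes.

The objective is a simplified anchor-free detection loss: each ground
truth is assigned to the grid cell containing its center at the finest
pyramid level whose regression range covers the box; classification is
binary cross-entropy over all cells and classes, and box regression is
the distribution-focal cross-entropy over the per-side bin distributions
at assigned cells. This is deliberately a smoke objective — it verifies
that the assembled network and the synthetic generator produce a
learnable signal on CPU, not that the recipe reaches benchmark accuracy.

Loss gradients with respect to the raw head outputs are closed-form
(sigmoid/softmax minus target) and are injected into the reverse-mode
engine, which backpropagates them through the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .assembly import ManifestModel, build_model
from .manifest import ModelManifest, load_default_manifest, scale_manifest
from .synthetic import SceneConfig, generate_scene

__all__ = ["detection_loss", "TrainResult", "smoke_train", "smooth"]

_CLS_WEIGHT = 0.5
_BOX_WEIGHT = 1.5


def _assign_level(w_px: float, h_px: float, strides, reg_max: int) -> int:
    """Finest level whose per-side range (reg_max-1 cells) covers the box."""
    half = max(w_px, h_px) / 2.0
    for lvl, s in enumerate(strides):
        if half <= (reg_max - 1) * s:
            return lvl
    return len(strides) - 1


def detection_loss(outputs, batch_annotations, image_size: int,
                   strides=(4, 8, 16), reg_max: int = 16, num_classes: int = 6):
    """Loss value plus per-output gradient arrays.

    ``outputs``: list of raw head Tensors (B, 4*reg_max+nc, H, W);
    ``batch_annotations``: per-image lists of normalized ground-truth boxes.
    Returns ``(loss, grads, n_pos)``.
    """
    bins = np.arange(reg_max, dtype=np.float64)
    grads = [np.zeros_like(o.data) for o in outputs]
    cls_loss = 0.0
    box_loss = 0.0
    n_pos = 0

    # classification targets default to zero everywhere
    cls_targets = [np.zeros((o.data.shape[0], num_classes) + o.data.shape[2:])
                   for o in outputs]
    pos_cells = []   # (level, image, i, j, distances[4])

    for b, boxes in enumerate(batch_annotations):
        for gt in boxes:
            w_px, h_px = gt.w * image_size, gt.h * image_size
            lvl = _assign_level(w_px, h_px, strides, reg_max)
            s = strides[lvl]
            hc, wc = outputs[lvl].data.shape[2:]
            j = min(int(gt.cx * image_size / s), wc - 1)
            i = min(int(gt.cy * image_size / s), hc - 1)
            cxp, cyp = (j + 0.5) * s, (i + 0.5) * s
            x1, y1, x2, y2 = gt.corners(image_size, image_size)
            # sub-cell boxes clamp at zero: the box edge sits on the cell
            # center rather than losing the assignment altogether
            dist = np.array([cxp - x1, cyp - y1, x2 - cxp, y2 - cyp]) / s
            dist = np.clip(dist, 0.0, reg_max - 1 - 1e-3)
            cls_targets[lvl][b, gt.class_id, i, j] = 1.0
            pos_cells.append((lvl, b, i, j, dist))
            n_pos += 1

    norm = max(n_pos, 1)

    # classification: BCE-with-logits over every cell and class
    for lvl, out in enumerate(outputs):
        logits = out.data[:, 4 * reg_max:].astype(np.float64)
        t = cls_targets[lvl]
        p = 1.0 / (1.0 + np.exp(-logits))
        eps = 1e-9
        cls_loss += -np.sum(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps))
        grads[lvl][:, 4 * reg_max:] = (_CLS_WEIGHT / norm) * (p - t)

    # box regression: distribution-focal CE at positive cells
    for lvl, b, i, j, dist in pos_cells:
        raw = outputs[lvl].data[b, :4 * reg_max, i, j].reshape(4, reg_max)
        raw = raw.astype(np.float64)
        ex = np.exp(raw - raw.max(axis=1, keepdims=True))
        probs = ex / ex.sum(axis=1, keepdims=True)
        lo = np.floor(dist).astype(int)
        hi = np.minimum(lo + 1, reg_max - 1)
        w_hi = dist - lo
        w_lo = 1.0 - w_hi
        target = np.zeros((4, reg_max))
        target[np.arange(4), lo] += w_lo
        target[np.arange(4), hi] += w_hi
        box_loss += -np.sum(target * np.log(probs + 1e-9))
        g = (_BOX_WEIGHT / norm) * (probs - target)
        grads[lvl][b, :4 * reg_max, i, j] += g.reshape(-1).astype(np.float32)

    loss = (_CLS_WEIGHT * cls_loss + _BOX_WEIGHT * box_loss) / norm
    return float(loss), grads, n_pos


def smooth(series, window: int | None = None) -> np.ndarray:
    """Centered moving-average smoothing of a loss series."""
    x = np.asarray(series, dtype=np.float64)
    if window is None:
        window = max(5, len(x) // 10)
    kernel = np.ones(window) / window
    return np.convolve(x, kernel, mode="valid")


@dataclass
class TrainResult:
    losses: list = field(default_factory=list)
    model: ManifestModel | None = None
    diverged: bool = False

    @property
    def smoothed(self) -> np.ndarray:
        return smooth(self.losses)

    def decreased(self) -> bool:
        s = self.smoothed
        return bool(len(s) >= 2 and s[-1] < s[0])


def smoke_train(steps: int = 200, n_scenes: int = 64, image_size: int = 256,
                batch_size: int = 8, width_mult: float = 0.25,
                lr: float = 0.01, momentum: float = 0.937,
                weight_decay: float = 0.0005, seed: int = 0,
                manifest: ModelManifest | None = None,
                scenes=None, progress=False) -> TrainResult:
    """Short SGD run on synthetic scenes; returns the loss series.

    Uses a width-scaled variant of the default manifest (0.25 by default)
    so the run stays in CPU smoke territory; the wiring is identical to
    the full model.
    """
    rng = np.random.default_rng(seed)
    if manifest is None:
        manifest = scale_manifest(load_default_manifest(), width_mult)
    model = build_model(manifest, rng=rng)
    if steps == 0:
        return TrainResult([], model)
    if scenes is None:
        cfg = SceneConfig(image_size=image_size, seed=seed)
        scenes = [generate_scene(
            SceneConfig(image_size=image_size, seed=seed + i))
            for i in range(n_scenes)]
    images = np.stack([s[0] for s in scenes]).astype(np.float32) / 255.0
    images = images.transpose(0, 3, 1, 2)
    annos = [s[1].boxes for s in scenes]

    opt = nn.SGD(model.parameters(trainable_only=True), lr=lr,
                 momentum=momentum, weight_decay=weight_decay)
    result = TrainResult(model=model)
    model.train(True)
    for step in range(steps):
        idx = rng.choice(len(scenes), size=min(batch_size, len(scenes)),
                         replace=False)
        x = nn.Tensor(images[idx])
        outs = model(x)
        loss, grads, _ = detection_loss(
            outs, [annos[i] for i in idx], image_size,
            strides=model.strides, num_classes=manifest.num_classes)
        if not np.isfinite(loss):
            result.diverged = True
            break
        result.losses.append(loss)
        opt.zero_grad()
        nn.backward(outs, grads)
        opt.step()
        if progress and (step + 1) % 20 == 0:
            s = result.smoothed
            print(f"step {step + 1:4d}  loss {loss:8.4f}  "
                  f"smoothed {s[-1] if len(s) else float('nan'):8.4f}")
    return result
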