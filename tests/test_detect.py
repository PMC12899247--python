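"""Decoding, NMS and AP/mAP against hand-enumerated values and an
independent brute-force reference implementation."""

import numpy as np
import pytest

from yolowl.detect import (Detection, GroundTruthBox, average_precision,
                           decode, iou, mean_ap, nms)

REG_MAX = 16
NC = 6


# --- independent brute-force reference --------------------------------------

def bf_nms(dets, thr):
    kept = []
    pool = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    removed = set()
    for i in pool:
        if i in removed:
            continue
        kept.append(i)
        for j in pool:
            if j in removed or j == i or dets[j].class_id != dets[i].class_id:
                continue
            if dets[j].score < dets[i].score or (
                    dets[j].score == dets[i].score and j > i):
                if iou(dets[i].box, dets[j].box) >= thr:
                    removed.add(j)
    return [dets[i] for i in kept]


def bf_ap(dets, gts, thr):
    """AP by explicit matching and direct right-max interpolation."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
    taken = [False] * len(gts)
    flags = []
    for i in order:
        d = dets[i]
        cands = [(g, iou(d.box, box)) for g, (c, box) in enumerate(gts)
                 if not taken[g] and c == d.class_id]
        cands = [(g, v) for g, v in cands if v >= thr]
        if cands:
            g = max(cands, key=lambda t: (t[1], -t[0]))[0]
            taken[g] = True
            flags.append(True)
        else:
            flags.append(False)
    n_gt = len(gts)
    precis, recs = [], []
    tp = fp = 0
    for f in flags:
        tp, fp = tp + f, fp + (not f)
        precis.append(tp / (tp + fp))
        recs.append(tp / n_gt)
    ap = 0.0
    prev_r = 0.0
    for k, r in enumerate(recs):
        if r > prev_r:
            ap += (r - prev_r) * max(precis[k:])
            prev_r = r
    return ap


def random_instance(rng, n_det=12, n_gt=6, n_cls=3, span=100):
    gts = []
    for _ in range(n_gt):
        x, y = rng.uniform(0, span, 2)
        w, h = rng.uniform(5, 25, 2)
        gts.append((int(rng.integers(n_cls)), (x, y, x + w, y + h)))
    dets = []
    for _ in range(n_det):
        if gts and rng.random() < 0.7:
            c, (x1, y1, x2, y2) = gts[rng.integers(len(gts))]
            jit = rng.normal(0, 3, 4)
            box = (x1 + jit[0], y1 + jit[1],
                   max(x2 + jit[2], x1 + jit[0] + 1),
                   max(y2 + jit[3], y1 + jit[1] + 1))
        else:
            c = int(rng.integers(n_cls))
            x, y = rng.uniform(0, span, 2)
            w, h = rng.uniform(5, 25, 2)
            box = (x, y, x + w, y + h)
        dets.append(Detection(int(c), float(np.round(rng.random(), 3)), box))
    return dets, gts


# --- IoU ---------------------------------------------------------------------

@pytest.mark.parametrize("a,b,expected", [
    ((0, 0, 2, 2), (0, 0, 2, 2), 1.0),
    ((0, 0, 1, 1), (5, 5, 6, 6), 0.0),
    ((0, 0, 2, 2), (1, 1, 3, 3), 1 / 7),
])
def test_iou_examples(a, b, expected):
    assert iou(a, b) == pytest.approx(expected)


# --- decoding ----------------------------------------------------------------

def _raw_level(h, w, bin_logits, cls_logits):
    raw = np.zeros((1, 4 * REG_MAX + NC, h, w), dtype=np.float32)
    raw[0, :4 * REG_MAX] = np.tile(bin_logits.reshape(-1, 1, 1), (1, h, w))
    raw[0, 4 * REG_MAX:] = cls_logits.reshape(-1, 1, 1)
    return raw


def test_uniform_bins_give_symmetric_offsets():
    bins = np.zeros((4, REG_MAX), dtype=np.float32)
    cls = np.full(NC, -10.0, dtype=np.float32)
    cls[2] = 10.0
    dets = decode([_raw_level(2, 2, bins, cls)], strides=(4,),
                  conf_threshold=0.5)
    assert len(dets) == 4
    d = dets[0]
    x1, y1, x2, y2 = d.box
    half = (REG_MAX - 1) / 2 * 4
    assert (x2 - x1) == pytest.approx(2 * half, abs=1e-4)
    assert d.class_id == 2
    # anchored at the first cell center (2, 2)
    assert (x1 + x2) / 2 == pytest.approx(2.0, abs=1e-4)


@pytest.mark.parametrize("j", [1, 3, 15])
def test_one_hot_bin_gives_integer_offset(j):
    bins = np.full((4, REG_MAX), -30.0, dtype=np.float32)
    bins[:, j] = 30.0
    cls = np.full(NC, -10.0, dtype=np.float32)
    cls[0] = 5.0
    dets = decode([_raw_level(1, 1, bins, cls)], strides=(8,),
                  conf_threshold=0.5)
    x1, y1, x2, y2 = dets[0].box
    assert x2 - x1 == pytest.approx(2 * j * 8, abs=1e-3)


def test_decode_encode_round_trip():
    """A box encoded as delta bin distributions decodes to itself."""
    stride, i, j = 8, 3, 5
    cx, cy = (j + 0.5) * stride, (i + 0.5) * stride
    l, t, r, b = 4, 2, 6, 3                      # integer bin distances
    raw = np.zeros((1, 4 * REG_MAX + NC, 8, 8), dtype=np.float32)
    raw[0, 4 * REG_MAX:] = -20.0
    for side, d in enumerate((l, t, r, b)):
        raw[0, side * REG_MAX:(side + 1) * REG_MAX, i, j] = -30.0
        raw[0, side * REG_MAX + d, i, j] = 30.0
    raw[0, 4 * REG_MAX + 1, i, j] = 8.0
    dets = decode([raw], strides=(stride,), conf_threshold=0.5)
    assert len(dets) == 1
    x1, y1, x2, y2 = dets[0].box
    np.testing.assert_allclose(
        [x1, y1, x2, y2],
        [cx - l * stride, cy - t * stride, cx + r * stride, cy + b * stride],
        atol=1e-4)


# --- NMS ---------------------------------------------------------------------

def test_nms_keeps_best_of_identical_boxes():
    dets = [Detection(0, 0.9, (0, 0, 10, 10)), Detection(0, 0.8, (0, 0, 10, 10))]
    out = nms(dets, 0.5)
    assert len(out) == 1 and out[0].score == 0.9


def test_nms_keeps_disjoint_and_cross_class():
    dets = [Detection(0, 0.9, (0, 0, 10, 10)),
            Detection(0, 0.8, (50, 50, 60, 60)),
            Detection(1, 0.7, (0, 0, 10, 10))]
    assert len(nms(dets, 0.5)) == 3


def test_nms_idempotent_and_matches_brute_force():
    rng = np.random.default_rng(7)
    for _ in range(100):
        dets, _ = random_instance(rng, n_det=int(rng.integers(1, 50)))
        ours = nms(dets, 0.45)
        ref = bf_nms(dets, 0.45)
        assert [(d.class_id, d.score, d.box) for d in ours] == \
               [(d.class_id, d.score, d.box) for d in ref]
        assert nms(ours, 0.45) == ours


# --- AP / mAP ----------------------------------------------------------------

def test_perfect_detections_give_ap_one():
    gts = [(0, (0, 0, 10, 10)), (0, (20, 20, 28, 30))]
    dets = [Detection(0, 0.9, (0, 0, 10, 10)), Detection(0, 0.8, (20, 20, 28, 30))]
    assert average_precision(dets, gts, 0.5).ap == pytest.approx(1.0)


def test_fp_then_tp_single_gt_gives_half():
    gts = [(0, (0, 0, 10, 10))]
    dets = [Detection(0, 0.9, (50, 50, 60, 60)),     # FP ranked first
            Detection(0, 0.8, (0, 0, 10, 10))]       # TP
    curve = average_precision(dets, gts, 0.5)
    assert curve.ap == pytest.approx(0.5)
    assert curve.precision[-1] == pytest.approx(0.5)


def test_trailing_false_positives_never_raise_ap():
    rng = np.random.default_rng(11)
    for _ in range(30):
        dets, gts = random_instance(rng)
        base = average_precision(dets, gts, 0.5).ap
        min_score = min((d.score for d in dets), default=1.0)
        extra = dets + [Detection(0, min_score / 2, (200, 200, 210, 210))]
        assert average_precision(extra, gts, 0.5).ap <= base + 1e-12


def test_ap_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(5)
    for _ in range(100):
        dets, gts = random_instance(rng)
        for thr in (0.3, 0.5, 0.75):
            ours = average_precision(dets, gts, thr).ap
            assert ours == pytest.approx(bf_ap(dets, gts, thr), abs=1e-9)


def test_mean_ap_examples():
    gts = [(0, (0, 0, 10, 10)), (1, (20, 20, 30, 30))]
    dets = [Detection(0, 0.9, (0, 0, 10, 10))]        # class 1 undetected
    m = mean_ap(dets, gts, thresholds=(0.5,))
    assert m["map50"] == pytest.approx(0.5)           # mean of 1.0 and 0.0
    single = mean_ap(dets, [(0, (0, 0, 10, 10))], thresholds=(0.5,))
    assert single["map50"] == single["map5095"] == pytest.approx(1.0)


def test_classes_absent_from_gt_excluded():
    gts = [(0, (0, 0, 10, 10))]
    dets = [Detection(0, 0.9, (0, 0, 10, 10)),
            Detection(3, 0.95, (50, 50, 60, 60))]     # class 3 has no GT
    m = mean_ap(dets, gts, thresholds=(0.5,))
    assert list(m["per_class"]) == [0]
    assert m["map50"] == pytest.approx(1.0)


def test_empty_ground_truth_rejected():
    with pytest.raises(ValueError):
        mean_ap([], [])


def test_per_image_matching_does_not_cross_images():
    """A detection in one image cannot match ground truth in another."""
    gts = [[(0, (0, 0, 10, 10))], [(0, (0, 0, 10, 10))]]
    dets = [[Detection(0, 0.9, (0, 0, 10, 10))], []]
    m = mean_ap(dets, gts, thresholds=(0.5,))
    assert m["map50"] == pytest.approx(0.5)           # recall capped at 1/2
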