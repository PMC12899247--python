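"""Manifest parsing, whole-model assembly, the parameter audit, the
detection head, and the analytic FLOP counter."""

import numpy as np
import pytest

from yolowl import nn
from yolowl.assembly import (AuditReport, DetectHead, audit_parameters,
                             build_model, count_flops,
                             detect_head_param_count, load_checkpoint,
                             save_checkpoint)
from yolowl.blocks import ConvBlock, ConvSpec, conv_param_count
from yolowl.manifest import (load_default_manifest, parse_manifest,
                             scale_manifest, serialize_manifest)


def test_default_manifest_parses_to_29_rows(default_manifest):
    assert len(default_manifest.rows) == 29
    assert default_manifest.rows[0].module == "GCBS"
    assert default_manifest.rows[28].module == "Detect"


def test_dangling_reference_rejected(default_manifest):
    import dataclasses
    from yolowl.manifest import ModelManifest
    rows = list(default_manifest.rows)
    rows[3] = dataclasses.replace(rows[3], sources=(99,))
    bad = ModelManifest("bad", 6, 640, rows, dict(default_manifest.summary))
    with pytest.raises(ValueError, match="dangling"):
        bad.validate()


def test_unknown_module_rejected(default_manifest):
    text = serialize_manifest(default_manifest).replace(
        "module: SPPF", "module: Sppfx")
    with pytest.raises(ValueError, match="unknown module"):
        parse_manifest(text)


def test_manifest_syntax_error_reported():
    with pytest.raises(ValueError, match="syntax|mapping"):
        parse_manifest("layers: [whoops")


def test_round_trip_identity(default_manifest):
    text = serialize_manifest(default_manifest)
    again = serialize_manifest(parse_manifest(text))
    assert text == again


def test_static_row_sum_consistency(default_manifest):
    """Per-row printed counts (row 5 corrected by +360) sum to the printed
    whole-model total — independent of any build."""
    assert default_manifest.static_consistency()
    assert default_manifest.expected_total() == 1394688
    row5 = default_manifest.rows[5]
    assert row5.expected_params == 1048 and row5.corrected_params == 1408


def test_audit_every_expected_row_exact(built_model):
    report = audit_parameters(built_model)
    assert report.mismatched_rows == []
    hard_rows = [0, 1, 3, 7, 9, 12, 15, 18, 20, 22, 24, 26, 28]
    assert set(hard_rows) <= set(report.exact_rows)
    assert any("row 5" in n for n in report.notes)


def test_audit_totals(built_model):
    report = audit_parameters(built_model)
    assert report.built_total == 1394688
    assert report.built_trainable == 1394672
    assert report.built_total - report.built_trainable == 16


def test_audit_report_json_round_trip(built_model):
    report = audit_parameters(built_model)
    again = AuditReport.from_json(report.to_json())
    assert again.rows == report.rows
    assert again.built_total == report.built_total


def test_audit_deterministic(default_manifest):
    a = audit_parameters(build_model(default_manifest))
    b = audit_parameters(build_model(default_manifest))
    assert a.rows == b.rows


def test_forward_produces_three_shallow_level_outputs(built_model, rng):
    x = nn.Tensor(rng.normal(size=(1, 3, 64, 64)).astype(np.float32))
    built_model.eval()
    outs = built_model(x)
    # strides 4/8/16 and 4*reg_max + nc = 70 channels
    assert [o.data.shape for o in outs] == [
        (1, 70, 16, 16), (1, 70, 8, 8), (1, 70, 4, 4)]


def test_no_stride_32_feature_reaches_head(default_manifest):
    """The defining property of the shallow neck: head taps sit at strides
    4/8/16 and the backbone's stride-32 tail only feeds the top-down path."""
    head_row = default_manifest.rows[28]
    taps = head_row.resolve_sources()
    assert taps == (19, 23, 27)
    probe = nn.ShapeProbe((1, 3, 640, 640))
    model = build_model(default_manifest)
    # record per-row probe shapes by replaying the graph
    outs = []
    for row, layer in zip(default_manifest.rows, model.layers):
        ins = [outs[s] for s in row.resolve_sources()] if row.index else [probe]
        y = layer(ins) if row.module.startswith(("SGF", "Detect")) else layer(ins[0])
        outs.append(y)
    for tap, side in zip(taps, (160, 80, 40)):
        assert outs[tap].shape[2] == side


def test_non_divisible_input_rejected(built_model):
    with pytest.raises(ValueError, match="divisible"):
        built_model(nn.Tensor(np.zeros((1, 3, 100, 100), dtype=np.float32)))


def test_graph_acyclic_sources_precede_rows(default_manifest):
    for row in default_manifest.rows[1:]:
        assert all(s < row.index for s in row.resolve_sources())


# --- detection head ---------------------------------------------------------

def test_detect_head_count_matches_manifest():
    assert detect_head_param_count(6, (32, 64, 128), 16) == 346018
    head = DetectHead(6, (32, 64, 128), rng=np.random.default_rng(0))
    assert head.param_count() == 346018
    assert head.param_count(trainable_only=True) == 346018 - 16


@pytest.mark.parametrize("nc", [1, 6, 20])
def test_frozen_projection_is_16_for_any_class_count(nc):
    head = DetectHead(nc, (32, 64, 128), rng=np.random.default_rng(0))
    assert head.param_count() - head.param_count(trainable_only=True) == 16


def test_detect_head_brute_force_decomposition():
    """Formula equals explicit enumeration of the head's sub-convolutions."""
    nc, ch, reg_max = 6, (32, 64, 128), 16
    c2, c3 = 64, 32
    total = 16
    for c in ch:
        total += conv_param_count(ConvSpec(c, c2, 3))
        total += conv_param_count(ConvSpec(c2, c2, 3))
        total += c2 * 4 * reg_max + 4 * reg_max
        total += conv_param_count(ConvSpec(c, c3, 3))
        total += conv_param_count(ConvSpec(c3, c3, 3))
        total += c3 * nc + nc
    assert total == detect_head_param_count(nc, ch, reg_max) == 346018


def test_single_class_head_final_conv_width(rng):
    head = DetectHead(1, (32, 64, 128), rng=rng)
    assert head.cls_branches[0][2].out_channels == 1


# --- FLOP counter -----------------------------------------------------------

def test_single_conv_flops_closed_form():
    blk = ConvBlock(ConvSpec(3, 16, 3, 2))
    probe = nn.ShapeProbe((1, 3, 640, 640))
    blk(probe)
    assert probe.counter["flops"] == 2 * 16 * 320 * 320 * 3 * 9


def test_conv_flops_quadratic_in_side():
    blk = ConvBlock(ConvSpec(8, 8, 3))
    p1 = nn.ShapeProbe((1, 8, 64, 64))
    p2 = nn.ShapeProbe((1, 8, 128, 128))
    blk(p1)
    blk(p2)
    assert p2.counter["flops"] == 4 * p1.counter["flops"]


def test_model_flops_reported_in_gflops(built_model):
    fl = count_flops(built_model, 640)
    # forced by the manifest's per-row parameter budgets at their resolutions
    assert fl / 1e9 == pytest.approx(11.397, abs=0.01)
    assert count_flops(built_model, 320) < fl


# --- checkpoints / scaling --------------------------------------------------

def test_checkpoint_round_trip(tmp_path, rng):
    manifest = scale_manifest(load_default_manifest(), 0.25)
    model = build_model(manifest, rng=rng)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, path)
    again = load_checkpoint(path)
    for a, b in zip(model.parameters(), again.parameters()):
        np.testing.assert_array_equal(a.data, b.data)


def test_scaled_manifest_builds_and_runs(rng):
    manifest = scale_manifest(load_default_manifest(), 0.25)
    model = build_model(manifest, rng=rng)
    x = nn.Tensor(rng.normal(size=(1, 3, 64, 64)).astype(np.float32))
    outs = model(x)
    assert len(outs) == 3
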