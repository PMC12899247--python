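"""MSDDSC: compression arithmetic, dilated-depthwise equivalence with
zero-inserted dense kernels, residual identity, receptive-field support,
block counts against the manifest, and the configuration search."""

import numpy as np
import pytest
from scipy import signal

from yolowl import nn
from yolowl.blocks import ConvSpec, conv_param_count
from yolowl.msddsc import (C2fMSDDSC, DEFAULT_MSDDSC, DilatedDWSeparable,
                           MSDDSC, MSDDSCConfig, c2f_msddsc_param_count,
                           compressed_channels, msddsc_param_count,
                           search_msddsc_config)

TABLE_TARGETS = [(32, 32, 1, 11882), (64, 64, 2, 82916),
                 (128, 128, 2, 325380), (128, 128, 1, 179330)]


@pytest.mark.parametrize("c,e,expect", [(16, 1.0, 16), (16, 0.5, 8),
                                        (17, 0.75, 12)])
def test_compressed_channels_floor(c, e, expect):
    assert compressed_channels(c, e) == expect


def test_compress_guard_rejects_zero_channels():
    with pytest.raises(ValueError):
        compressed_channels(3, 0.25)


def test_compress_preserves_space_and_width(rng):
    m = MSDDSC(16, rng=rng)
    x = nn.Tensor(rng.normal(size=(1, 16, 8, 8)).astype(np.float32))
    z = m.compress(x)
    assert z.data.shape == (1, 12, 8, 8)   # floor(0.75 * 16)


@pytest.mark.parametrize("rate", [1, 2, 3])
def test_dilated_dw_equals_zero_inserted_dense_kernel(rng, rate):
    """A rate-r depthwise 3x3 conv equals a dense (2r+1)x(2r+1) conv whose
    kernel has the nine taps at r-strided offsets and zeros elsewhere."""
    c = 4
    conv = nn.Conv2d(c, c, 3, groups=c, dilation=rate, bias=False, rng=rng)
    x = rng.normal(size=(1, c, 8, 8)).astype(np.float32)
    out = conv(nn.Tensor(x)).data
    span = 2 * rate + 1
    p = rate
    for ch in range(c):
        dense = np.zeros((span, span), dtype=np.float32)
        dense[::rate, ::rate] = conv.weight.data[ch, 0]
        ref = signal.correlate2d(np.pad(x[0, ch], p), dense, mode="valid")
        np.testing.assert_allclose(out[0, ch], ref, rtol=1e-5, atol=1e-5)


def test_rate_one_is_plain_separable(rng):
    blk = DilatedDWSeparable(6, 6, rate=1, rng=rng)
    ref = DilatedDWSeparable(6, 6, rate=2, rng=rng)
    assert blk.dw.conv.dilation == 1 and blk.dw.conv.padding == 1
    assert blk.param_count() == ref.param_count()   # dilation is free


def test_branch_param_arithmetic():
    """Depthwise (no norm) + pointwise (BN) on 16 channels costs 432."""
    p = (conv_param_count(ConvSpec(16, 16, 3, groups=16, has_bn=False))
         + conv_param_count(ConvSpec(16, 16, 1, has_bn=True)))
    assert p == 9 * 16 + 16 * 16 + 2 * 16 == 432


def test_residual_identity_with_zeroed_fusion(rng):
    """Zeroing the fusion conv makes the whole block the identity map."""
    m = MSDDSC(16, rng=rng)
    m.fuse.conv.weight.data[:] = 0.0
    x = nn.Tensor(rng.normal(size=(2, 16, 8, 8)).astype(np.float32))
    y = m(x)
    assert np.max(np.abs(y.data - x.data)) == 0.0


def test_forward_shape_and_finiteness(rng):
    for c in (8, 16, 32):
        m = MSDDSC(c, rng=rng)
        x = nn.Tensor(rng.normal(size=(1, c, 10, 10)).astype(np.float32))
        y = m(x)
        assert y.data.shape == x.data.shape
        assert np.isfinite(y.data).all()


def test_residual_mismatch_rejected(rng):
    cfg = MSDDSCConfig(fuse_ratio=0.5, residual_projection=False)
    with pytest.raises(ValueError, match="residual"):
        MSDDSC(16, cfg, rng=rng)
    # with projection enabled the block builds and preserves shape
    cfg = MSDDSCConfig(fuse_ratio=0.5, residual_projection=True)
    m = MSDDSC(16, cfg, rng=rng)
    x = nn.Tensor(rng.normal(size=(1, 16, 6, 6)).astype(np.float32))
    assert m(x).data.shape == x.data.shape


@pytest.mark.parametrize("rate", [1, 2, 3])
def test_receptive_field_support_of_branch(rng, rate):
    """Impulse response of the rate-r depthwise conv spans 2r+1 pixels."""
    c = 1
    conv = nn.Conv2d(c, c, 3, groups=c, dilation=rate, bias=False, rng=rng)
    conv.weight.data[:] = 1.0
    x = np.zeros((1, 1, 15, 15), dtype=np.float32)
    x[0, 0, 7, 7] = 1.0
    y = conv(nn.Tensor(x)).data[0, 0]
    ys, xs = np.nonzero(y)
    assert ys.max() - ys.min() == 2 * rate and xs.max() - xs.min() == 2 * rate


@pytest.mark.parametrize("cin,cout,n,expected", TABLE_TARGETS)
def test_c2f_msddsc_counts_match_manifest(cin, cout, n, expected):
    assert c2f_msddsc_param_count(cin, cout, n) == expected
    built = C2fMSDDSC(cin, cout, n, rng=np.random.default_rng(0))
    assert built.param_count() == expected


def test_stacking_repeats_adds_only_unit_params():
    one = c2f_msddsc_param_count(64, 64, 1)
    two = c2f_msddsc_param_count(64, 64, 2)
    unit = msddsc_param_count(32)
    merge_growth = 32 * 64          # cv2 input grows by one hidden width
    assert two - one == unit + merge_growth


def test_c2f_msddsc_forward_shape(rng):
    blk = C2fMSDDSC(32, 32, 1, rng=rng)
    x = nn.Tensor(rng.normal(size=(1, 32, 16, 16)).astype(np.float32))
    assert blk(x).data.shape == (1, 32, 16, 16)


# --- configuration search ---------------------------------------------------

def test_search_rejects_empty_targets():
    with pytest.raises(ValueError):
        search_msddsc_config([])


def test_search_plant_and_recover():
    """A space containing the generating config is recovered at zero
    deviation."""
    planted = MSDDSCConfig(e=0.5, rates=(1, 2), expand_ratio=None,
                           fuse_kernel=1, gate_kernel=0)
    targets = [(c, c, n, c2f_msddsc_param_count(c, c, n, planted))
               for c, n in ((32, 1), (64, 2), (128, 1))]
    decoys = [MSDDSCConfig(e=1.0, rates=(1, 2, 3)),
              MSDDSCConfig(e=0.5, rates=(1, 2), expand_ratio=None,
                           fuse_kernel=1, gate_kernel=3),
              planted,
              MSDDSCConfig(e=0.25, rates=(1, 2, 3, 4))]
    res = search_msddsc_config(targets, space=decoys)
    assert res.total_deviation == 0
    assert res.config == planted


def test_search_is_deterministic_and_reports_deviation():
    targets = [(32, 32, 1, 11882 + 10)]
    space = [MSDDSCConfig(), MSDDSCConfig(gate_kernel=0)]
    r1 = search_msddsc_config(targets, space=space)
    r2 = search_msddsc_config(targets, space=space)
    assert r1.config == r2.config
    assert r1.total_deviation == 10
    assert r1.deviations == (-10,)


def test_default_config_is_exact_on_all_manifest_rows():
    devs = [c2f_msddsc_param_count(ci, co, n, DEFAULT_MSDDSC) - exp
            for ci, co, n, exp in TABLE_TARGETS]
    assert devs == [0, 0, 0, 0]
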