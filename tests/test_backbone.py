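"""Backbone contracts: ECA kernel rule, channel gating, DUC oracle, pyramid
shape law."""

import numpy as np
import pytest

from vineseg import nn
from vineseg.backbone import (ECAConfig, ECAModule, DUC, DUCConfig, BackboneED,
                              ResNetStages, eca_kernel_size)


def brute_force_psi(C, gamma=2.0, b=1.0):
    """Independent application of the adaptive-kernel rule: |t| with t =
    log2(C)/gamma + b/gamma, truncated to int, bumped to the next odd."""
    t = abs(np.log2(C) / gamma + b / gamma)
    k = int(t)
    if k % 2 == 0:
        k += 1
    return max(k, 1)


class TestEcaKernelSize:
    @pytest.mark.parametrize("C,expected", [(2, 1), (256, 5), (2048, 7)])
    def test_worked_examples(self, C, expected):
        assert eca_kernel_size(C) == expected

    def test_matches_rule_for_all_channel_counts(self):
        for C in range(2, 4097):
            k = eca_kernel_size(C)
            assert k == brute_force_psi(C)
            assert k % 2 == 1 and k >= 1

    def test_monotone_in_channels(self):
        ks = [eca_kernel_size(C) for C in range(1, 4097)]
        assert all(a <= b for a, b in zip(ks, ks[1:]))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            eca_kernel_size(0)
        with pytest.raises(ValueError):
            eca_kernel_size(8, gamma=0)


class TestEcaModule:
    def test_zero_input_zero_output_and_shape(self):
        m = ECAModule(ECAConfig(16))
        x = nn.Tensor(np.zeros((2, 16, 5, 5), dtype=np.float32))
        out = m(x)
        assert out.shape == x.shape
        assert np.all(out.data == 0)

    def test_zero_kernel_halves_input(self):
        m = ECAModule(ECAConfig(8), dtype=np.float64)
        m.kernel.data[:] = 0.0
        x = nn.Tensor(np.random.default_rng(0).normal(size=(2, 8, 4, 4)))
        assert np.allclose(m(x).data, 0.5 * x.data)

    def test_pure_channel_gate(self):
        """Output/input ratio is one constant per channel, strictly in (0,1)."""
        rng = np.random.default_rng(1)
        m = ECAModule(ECAConfig(8), rng=rng, dtype=np.float64)
        x = rng.normal(size=(1, 8, 6, 6)) + 2.0   # keep away from zero
        out = m(nn.Tensor(x)).data
        ratios = out / x
        for c in range(8):
            vals = ratios[0, c]
            assert np.allclose(vals, vals.flat[0], atol=1e-12)
            assert 0.0 < vals.flat[0] < 1.0

    def test_parameter_count_is_kernel_size(self):
        for C in (64, 256, 2048):
            m = ECAModule(ECAConfig(C))
            n_params = sum(p.data.size for p in m.parameters())
            assert n_params == eca_kernel_size(C)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            ECAConfig(8, kernel_size=4)


class TestDUC:
    def test_ratio_one_is_plain_conv(self):
        duc = DUC(DUCConfig(4, 1), dtype=np.float64)
        x = nn.Tensor(np.random.default_rng(0).normal(size=(1, 4, 5, 5)))
        out = duc(x)
        assert out.shape == (1, 4, 5, 5)

    def test_shape_law_c256_r2(self):
        """4x4x256 -> intermediate 4x4x1024 -> 8x8x256."""
        duc = DUC(DUCConfig(256, 2))
        assert duc.config.intermediate_channels == 1024
        x = nn.Tensor(np.zeros((1, 256, 4, 4), dtype=np.float32))
        assert duc(x).shape == (1, 256, 8, 8)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_subpixel_oracle(self, seed):
        """Loop-based rearrangement: output pixel (c, i, j) reads intermediate
        channel c*r^2 + (i%r)*r + (j%r) at (i//r, j//r)."""
        rng = np.random.default_rng(seed)
        C, r, H = 6, 2, 5
        duc = DUC(DUCConfig(C, r), rng=rng, dtype=np.float64)
        x = nn.Tensor(rng.normal(size=(1, C, H, H)))
        mine = duc(x).data
        inter = nn.conv2d(x, duc.conv.weight, duc.conv.bias, 1, 1).data
        for c in range(C):
            for i in range(H * r):
                for j in range(H * r):
                    ref = inter[0, c * r * r + (i % r) * r + (j % r), i // r, j // r]
                    assert abs(mine[0, c, i, j] - ref) < 1e-6


class TestResNetStages:
    def test_full_geometry_shapes_and_block_count(self):
        """Full-scale: C2..C5 channels 256/512/1024/2048 at strides 4..32;
        3+4+6+3 = 16 bottlenecks."""
        from vineseg.backbone import Bottleneck
        net = ResNetStages()
        assert net.stage_channels == (256, 512, 1024, 2048)
        n_blocks = sum(1 for m in net.modules() if isinstance(m, Bottleneck))
        assert n_blocks == 16
        x = nn.Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32))
        c2, c3, c4, c5 = net(x)
        assert c2.shape == (1, 256, 16, 16)
        assert c3.shape == (1, 512, 8, 8)
        assert c4.shape == (1, 1024, 4, 4)
        assert c5.shape == (1, 2048, 2, 2)   # 64/32

    def test_input_validation(self):
        net = ResNetStages(stem_width=8, widths=(8, 8, 8, 8), blocks=(1, 1, 1, 1))
        with pytest.raises(ValueError):
            net(nn.Tensor(np.zeros((1, 1, 64, 64), dtype=np.float32)))
        with pytest.raises(ValueError):
            net(nn.Tensor(np.zeros((1, 3, 60, 60), dtype=np.float32)))


class TestPyramid:
    def test_test_scale_shape_contract(self):
        bb = BackboneED.test_scale(rng=np.random.default_rng(0))
        x = nn.Tensor(np.random.default_rng(1).normal(size=(1, 3, 128, 128))
                      .astype(np.float32))
        pyr = bb(x)
        shapes = pyr.shape_summary()
        for i, name in enumerate(("P2", "P3", "P4", "P5", "P6")):
            s = 4 * 2 ** i
            assert shapes[name] == (1, 64, 128 // s, 128 // s)
            assert pyr.strides[name] == s

    def test_zeroed_weights_give_zero_pyramid(self):
        bb = BackboneED.test_scale(rng=np.random.default_rng(0))
        for p in bb.parameters():
            p.data[:] = 0.0
        x = nn.Tensor(np.random.default_rng(2).normal(size=(1, 3, 64, 64))
                      .astype(np.float32))
        pyr = bb(x)
        for name in pyr.names:
            assert np.all(pyr[name].data == 0.0)

    def test_duc_and_nearest_agree_on_shapes_not_values(self):
        kw = dict(stem_width=8, widths=(8, 8, 8, 8), blocks=(1, 1, 1, 1),
                  fpn_channels=16, frozen_bn=True)
        x = nn.Tensor(np.random.default_rng(3).normal(size=(1, 3, 64, 64))
                      .astype(np.float32))
        duc_bb = BackboneED(use_duc=True, rng=np.random.default_rng(5), **kw)
        nn_bb = BackboneED(use_duc=False, rng=np.random.default_rng(5), **kw)
        a, b = duc_bb(x), nn_bb(x)
        assert a.shape_summary() == b.shape_summary()
        assert not np.allclose(a["P2"].data, b["P2"].data)
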