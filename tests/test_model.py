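"""Architecture contracts of the dual-branch encoder/decoder network."""

import numpy as np
import pytest

from uitrans.model import (ConfigError, ShapeError, UITransConfig, UITransNet,
                           build_model, space_to_channel, channel_to_space)
from uitrans.nn import autograd as ag
from uitrans.nn.autograd import Tensor
from uitrans.nn.layers import MultiheadSelfAttention


def _expected_parameter_count(cfg: UITransConfig) -> int:
    """Independent layer-by-layer tally from the documented schedule."""
    def conv(cin, cout, k):
        return cout * cin * k ** 3 + cout

    def double_conv(cin, cout):
        return conv(cin, cout, 3) + conv(cout, cout, 3)

    def msa(cin, cout):
        s, E = cfg.token_stride, cfg.embed_dim
        hidden = int(round(E * cfg.mlp_ratio))
        total = cin * s ** 3 * E + E              # embedding projection
        total += 2 * E + 2 * E                    # two layer norms
        total += (E * E + E) + (E * 2 * E + 2 * E) + (E * E + E)  # q, kv, proj
        total += (E * hidden + hidden) + (hidden * E + E)          # MLP
        total += E * cout * s ** 3 + cout * s ** 3  # reassembly projection
        return total

    dual = cfg.transformer_branch_enabled and cfg.conv_branch_enabled
    total = 0
    in_ch = 1
    widths = [cfg.stage_width(i) for i in range(cfg.n_stages)]
    for w in widths:
        branch = w // 2 if dual else w
        if cfg.conv_branch_enabled:
            total += double_conv(in_ch, branch) + conv(branch, branch, 2)
        if cfg.transformer_branch_enabled:
            total += 2 * msa(in_ch, branch // 2) + conv(branch, branch, 2)
        in_ch = w
    total += double_conv(widths[-1], widths[-1])  # bottleneck
    ch = widths[-1]
    for j in range(cfg.n_stages - 1, 0, -1):
        total += conv(ch, widths[j - 1], 3)
        total += double_conv(2 * widths[j - 1], widths[j - 1])
        ch = widths[j - 1]
    total += conv(ch, cfg.base_channels, 3)
    total += double_conv(cfg.base_channels, cfg.base_channels)
    total += conv(cfg.base_channels, 1, 1)
    return total


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            UITransConfig(transformer_branch_enabled=False,
                          conv_branch_enabled=False)
        with pytest.raises(ConfigError):
            UITransConfig(n_stages=0)
        with pytest.raises(ConfigError):
            UITransConfig(embed_dim=10, n_heads=4)

    def test_roundtrip_and_hash(self):
        cfg = UITransConfig.small()
        again = UITransConfig.from_dict(cfg.to_dict())
        assert again == cfg and again.hash() == cfg.hash()


class TestBuild:
    def test_seeded_init_identical(self, tiny_config):
        a = build_model(tiny_config, seed=5)
        b = build_model(tiny_config, seed=5)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.data, pb.data)
        c = build_model(tiny_config, seed=6)
        assert any(not np.array_equal(pa.data, pc.data)
                   for pa, pc in zip(a.parameters(), c.parameters()))

    def test_conv_only_ablation_has_no_attention(self):
        cfg = UITransConfig.small(transformer_branch_enabled=False)
        net = build_model(cfg, seed=0)
        assert all(s.tr_branch is None for s in net.stages)

    @pytest.mark.parametrize("kwargs", [
        {},
        {"transformer_branch_enabled": False},
        {"conv_branch_enabled": False},
        {"n_stages": 2, "base_channels": 4, "embed_dim": 8, "n_heads": 2},
    ])
    def test_parameter_count_matches_analytic_tally(self, kwargs):
        cfg = UITransConfig.small(**kwargs)
        net = build_model(cfg, seed=0)
        assert net.n_parameters() == _expected_parameter_count(cfg)


class TestTokenLayout:
    def test_space_channel_roundtrip(self, rng):
        x = rng.random((2, 3, 4, 4, 8)).astype(np.float32)
        t = space_to_channel(Tensor(x), 2)
        assert t.shape == (2, 24, 2, 2, 4)
        back = channel_to_space(t, 2, 3)
        np.testing.assert_array_equal(back.data, x)


class TestEncoder:
    def test_bottleneck_dims_64_cubed_three_stages(self):
        net = build_model(UITransConfig.small(), seed=0)
        with ag.no_grad():
            skips, bottleneck = net.encoder_forward(
                np.zeros((64, 64, 64), np.float32))
        assert len(skips) == 3
        assert bottleneck.shape[2:] == (8, 8, 8)

    def test_conv_only_bottleneck_channel_schedule(self):
        cfg = UITransConfig.small(transformer_branch_enabled=False, n_stages=3)
        net = build_model(cfg, seed=0)
        with ag.no_grad():
            _, bottleneck = net.encoder_forward(np.zeros((32, 32, 32), np.float32))
        assert bottleneck.shape[1] == cfg.base_channels * 2 ** cfg.n_stages

    def test_indivisible_dims_raise_named_shape_error(self, tiny_config):
        net = build_model(tiny_config, seed=0)
        with pytest.raises(ShapeError, match="divisible"):
            net.forward(np.zeros((63, 64, 64), np.float32))


class TestTransformerBlock:
    def test_channel_doubling_and_spatial_preservation(self, rng):
        from uitrans.model import TransformerBlock
        cfg = UITransConfig(n_stages=1, base_channels=16, n_heads=2,
                            embed_dim=8, token_stride=2)
        # twin MSAs concatenated: 16 input channels -> 32 output channels
        block = TransformerBlock(np.random.default_rng(0), 16, 32, cfg)
        x = Tensor(rng.random((1, 16, 8, 8, 8)).astype(np.float32))
        out = block(x)
        assert out.shape == (1, 32, 8, 8, 8)
        block.single_msa = True
        half = block(x)
        assert half.shape[1] == out.shape[1] // 2

    def test_msa_spatial_size_preserved(self, rng, tiny_config):
        net = build_model(tiny_config, seed=0)
        msa = net.stages[0].tr_branch.msa1
        x = Tensor(rng.random((1, 1, 8, 12, 16)).astype(np.float32))
        assert msa(x).shape[2:] == (8, 12, 16)

    def test_attention_rows_sum_to_one_every_layer(self, rng, tiny_config):
        net = build_model(tiny_config, seed=0)
        with ag.no_grad():
            net.forward(rng.random((16, 16, 16)).astype(np.float32))
        checked = 0
        for stage in net.stages:
            for msa in (stage.tr_branch.msa1, stage.tr_branch.msa2):
                w = msa.attn.last_attention
                assert w is not None
                np.testing.assert_allclose(w.sum(-1), 1.0, atol=1e-5)
                checked += 1
        assert checked == 2 * len(net.stages)

    def test_pooled_kv_attention_rows_sum_to_one(self, rng):
        att = MultiheadSelfAttention(np.random.default_rng(0), 8, 2)
        x = Tensor(rng.random((2, 16, 8)).astype(np.float32))
        kv = Tensor(rng.random((2, 4, 8)).astype(np.float32))
        att(x, kv)
        assert att.last_attention.shape == (2, 2, 16, 4)
        np.testing.assert_allclose(att.last_attention.sum(-1), 1.0, atol=1e-5)


class TestForward:
    @pytest.mark.parametrize("shape", [(16, 16, 16), (16, 24, 32), (8, 8, 8)])
    @pytest.mark.parametrize("branches", [(True, True), (True, False),
                                          (False, True)])
    def test_output_shape_equals_input_shape(self, rng, shape, branches):
        tr, conv = branches
        cfg = UITransConfig(n_stages=2, base_channels=4, n_heads=2,
                            embed_dim=8, token_stride=2,
                            transformer_branch_enabled=tr,
                            conv_branch_enabled=conv)
        net = build_model(cfg, seed=1)
        with ag.no_grad():
            out = net.forward(rng.random(shape).astype(np.float32))
        assert out.shape == (1, 1, *shape)
        assert np.all(np.isfinite(out.data))

    def test_batch_order_permutation_equivariance(self, rng, tiny_config):
        net = build_model(tiny_config, seed=0)
        a = rng.random((1, 16, 16, 16)).astype(np.float32)
        b = rng.random((1, 16, 16, 16)).astype(np.float32)
        with ag.no_grad():
            ab = net.forward(np.stack([a, b])).data
            ba = net.forward(np.stack([b, a])).data
        np.testing.assert_allclose(ab[0], ba[1], atol=1e-5)
        np.testing.assert_allclose(ab[1], ba[0], atol=1e-5)

    def test_non_finite_input_rejected(self, tiny_config):
        net = build_model(tiny_config, seed=0)
        bad = np.zeros((16, 16, 16), np.float32)
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            net.forward(bad)

    def test_clamp01_final_activation(self, rng, tiny_config):
        cfg = UITransConfig(**{**tiny_config.to_dict(),
                               "final_activation": "clamp01"})
        net = build_model(cfg, seed=0)
        out = net.restore(rng.random((16, 16, 16)).astype(np.float32))
        assert out.min() >= 0 and out.max() <= 1


def test_gradient_flow_reaches_nearly_all_parameters(rng, tiny_config):
    """Residual connections keep every path alive: >= 99% of parameters
    get a nonzero gradient from a single training step."""
    from uitrans.losses import mae_loss
    net = build_model(tiny_config, seed=3)
    x = rng.random((16, 16, 16)).astype(np.float32)
    y = rng.random((16, 16, 16)).astype(np.float32)
    net.zero_grad()
    mae_loss(y, net.forward(x)).backward()
    params = net.parameters()
    n_nonzero = sum(int(np.count_nonzero(p.grad)) for p in params
                    if p.grad is not None)
    n_total = sum(p.size for p in params)
    assert n_nonzero / n_total >= 0.99


def test_checkpoint_roundtrip_bit_identical(tmp_path, rng, tiny_config):
    net = build_model(tiny_config, seed=2)
    x = rng.random((16, 16, 16)).astype(np.float32)
    before = net.restore(x)
    path = tmp_path / "ckpt.npz"
    net.save(path, extra={"note": "test"})
    loaded = UITransNet.load(path)
    after = loaded.restore(x)
    assert np.array_equal(before, after)
    assert UITransNet.load_extra(path)["note"] == "test"
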