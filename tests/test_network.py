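"""Network assembly: shapes, ablation lattice, determinism, budget accountant."""

import numpy as np
import pytest

from conftest import tiny_config
from tgmlp import autodiff as ad
from tgmlp import nn
from tgmlp.network import (NetworkConfig, StageConfig, TGMLPUNet, budget,
                           count_macs, count_parameters, load_checkpoint,
                           reference_config, save_checkpoint)


def batch(rng, cfg, n=2):
    return ad.Tensor(rng.normal(
        size=(n, cfg.in_channels, cfg.input_size, cfg.input_size)
    ).astype(np.float32))


class TestShapes:
    def test_stem_shape_and_param_count(self, rng):
        from tgmlp.network import Stem

        stem = Stem(1, 8, rng=np.random.default_rng(0))
        out = stem(ad.Tensor(rng.normal(size=(1, 1, 32, 32)).astype(np.float32)))
        assert out.shape == (1, 8, 32, 32)
        # k^2*cin*cout + cout (bias) + 2*cout (BN affine) per layer
        want = (9 * 1 * 8 + 8 + 16) + 2 * (9 * 8 * 8 + 8 + 16)
        assert stem.num_parameters() == want

    def test_model_output_shape(self, rng, tiny_cfg):
        model = TGMLPUNet(tiny_cfg, seed=0)
        out = model(batch(rng, tiny_cfg))
        assert out.shape == (2, tiny_cfg.num_classes, 32, 32)

    def test_encoder_halves_extent(self, rng):
        from tgmlp.network import Encoder

        enc = Encoder(4, StageConfig(channels=8, downsample=2, partition_h=2),
                      extent=8, rng=np.random.default_rng(0))
        out = enc(ad.Tensor(rng.normal(size=(1, 4, 16, 16)).astype(np.float32)))
        assert out.shape == (1, 8, 8, 8)

    def test_decoder_restores_extent_and_zero_conv_passes_skip(self, rng):
        from tgmlp.network import Decoder

        dec = Decoder(8, 4, upsample=True, rng=np.random.default_rng(0))
        x = ad.Tensor(rng.normal(size=(1, 8, 8, 8)).astype(np.float32))
        skip = ad.Tensor(rng.normal(size=(1, 4, 16, 16)).astype(np.float32))
        assert dec(x, skip).shape == (1, 4, 16, 16)
        dec.conv.conv.weight.data[:] = 0.0
        dec.conv.conv.bias.data[:] = 0.0
        dec.conv.bn.beta.data[:] = 0.0
        dec.up.weight.data[:] = 0.0
        dec.up.bias.data[:] = 0.0
        np.testing.assert_array_equal(dec(x, skip).data, skip.data)

    def test_decoder_skip_mismatch_raises(self, rng):
        from tgmlp.network import Decoder

        dec = Decoder(8, 4, upsample=True, rng=np.random.default_rng(0))
        x = ad.Tensor(np.zeros((1, 8, 8, 8), dtype=np.float32))
        bad = ad.Tensor(np.zeros((1, 4, 8, 8), dtype=np.float32))
        with pytest.raises(ValueError, match="skip"):
            dec(x, bad)

    def test_config_validation(self):
        cfg = tiny_config()
        cfg.global_stages = cfg.global_stages[:1]
        with pytest.raises(ValueError, match="global"):
            cfg.validate()
        cfg = tiny_config()
        cfg.local_patch_grid = 5
        with pytest.raises(ValueError, match="divisible"):
            cfg.validate()


class TestLocalBranch:
    def test_patch_independence_and_order_invariance(self, rng, tiny_cfg):
        model = TGMLPUNet(tiny_cfg, seed=0)
        model.eval()
        lb = model.local_branch
        x = ad.Tensor(rng.normal(size=(1, 4, 32, 32)).astype(np.float32))
        folded = lb(x).data
        # per-patch loop in shuffled order must reproduce the folded result
        g, ph = lb.grid, 32 // lb.grid
        out = np.zeros_like(folded)
        order = rng.permutation(g * g)
        for k in order:
            gy, gx = divmod(int(k), g)
            patch = x.data[:, :, gy * ph:(gy + 1) * ph, gx * ph:(gx + 1) * ph]
            out[:, :, gy * ph:(gy + 1) * ph, gx * ph:(gx + 1) * ph] = \
                lb.pyramid(ad.Tensor(patch)).data
        # float32 BLAS reduction order differs between batched and per-patch
        np.testing.assert_allclose(out, folded, rtol=1e-3, atol=1e-4)

    def test_constant_input_gives_seamless_output(self, rng, tiny_cfg):
        model = TGMLPUNet(tiny_cfg, seed=0)
        model.eval()
        x = ad.Tensor(np.full((1, 4, 32, 32), 0.3, dtype=np.float32))
        out = model.local_branch(x).data[0]
        g, ph = model.local_branch.grid, 32 // model.local_branch.grid
        ref = out[:, :ph, :ph]
        for gy in range(g):
            for gx in range(g):
                np.testing.assert_allclose(
                    out[:, gy * ph:(gy + 1) * ph, gx * ph:(gx + 1) * ph], ref,
                    atol=1e-5)


class TestTrainingMechanics:
    def test_gradient_reaches_every_parameter(self, rng, tiny_cfg):
        model = TGMLPUNet(tiny_cfg, seed=0)
        x = batch(rng, tiny_cfg)
        out = model(x)
        (out ** 2.0).mean().backward()
        missing = [n for n, p in model.named_parameters() if p.grad is None]
        assert missing == []
        # the bias of an axis MLP over a unit extent is a constant shift that
        # downstream normalisation absorbs; its true gradient is ~0 and may
        # round to exactly zero in float32 — every other tensor must be live
        dead = [n for n, p in model.named_parameters()
                if not np.any(p.grad != 0)
                and not (p.size == 1 and n.endswith("mlp.bias"))]
        assert dead == []

    def test_additive_branch_fusion(self, rng, tiny_cfg):
        # the classifier consumes the plain sum of the two branch outputs
        model = TGMLPUNet(tiny_cfg, seed=0)
        model.eval()
        x = batch(rng, tiny_cfg, n=1)
        feats = model.stem(x)
        g = model.global_branch(feats)
        l = model.local_branch(feats)
        fused = model.classifier(g + l).data
        np.testing.assert_allclose(model(x).data, fused, rtol=1e-5, atol=1e-6)

    def test_deterministic_build_and_forward(self, rng, tiny_cfg):
        m1 = TGMLPUNet(tiny_cfg, seed=3)
        m2 = TGMLPUNet(tiny_cfg, seed=3)
        for (n1, p1), (n2, p2) in zip(m1.named_parameters(), m2.named_parameters()):
            assert n1 == n2
            np.testing.assert_array_equal(p1.data, p2.data)
        x = batch(rng, tiny_cfg)
        np.testing.assert_array_equal(m1(x).data, m2(x).data)


class TestAblationLattice:
    VARIANTS = [
        dict(use_tm=False, use_lgp=False, use_gate=False),  # backbone
        dict(use_tm=True, use_lgp=False, use_gate=False),   # +TM
        dict(use_tm=True, use_lgp=True, use_gate=False),    # +TM+LGP
        dict(use_tm=True, use_lgp=True, use_gate=True),     # +TM+LGP+GM
    ]

    def test_all_variants_build_and_run(self, rng):
        for kw in self.VARIANTS:
            cfg = tiny_config(**kw)
            out = TGMLPUNet(cfg, seed=0)(batch(rng, cfg, n=1))
            assert out.shape == (1, 2, 32, 32)

    def test_each_component_adds_parameters(self):
        counts = [count_parameters(tiny_config(**kw)) for kw in self.VARIANTS]
        assert counts == sorted(counts)
        assert len(set(counts)) == len(counts)
        # the gate mechanism adds exactly 3 scalars per TGMLP block (7 blocks)
        assert counts[3] - counts[2] == 3 * 7

    def test_backbone_collapse_matches_switches(self, rng):
        # zeroing every TGMLP-block learnable in the full variant reproduces
        # the backbone forward exactly
        cfg_full = tiny_config()
        cfg_bb = tiny_config(use_tm=False, use_lgp=False, use_gate=False)
        full = TGMLPUNet(cfg_full, seed=0)
        bb = TGMLPUNet(cfg_bb, seed=0)
        for branch in (full.global_branch, full.local_branch.pyramid):
            for enc in branch.encoders:
                enc.block.core.gates.values.data[:] = 0.0
                enc.block.gp.fc2.weight.data[:] = 0.0
                enc.block.gp.fc2.bias.data[:] = 0.0
                for conv in enc.block.lp.convs:
                    conv.weight.data[:] = 0.0
                    conv.bias.data[:] = 0.0
        # copy the shared (non-block) weights from the full model into the
        # backbone model so the two paths are comparable
        state = {k: v for k, v in full.state_dict().items() if "block" not in k}
        bb.load_state_dict(state)
        full.eval()
        bb.eval()
        x = batch(np.random.default_rng(0), cfg_full, n=1)
        np.testing.assert_allclose(bb(x).data, full(x).data, rtol=1e-5, atol=1e-6)


class TestBudget:
    def test_classifier_mac_closed_form(self):
        # adding one output class adds exactly stem_channels * S^2 MACs
        # (a 1x1 convolution costs c_in * c_out * H * W)
        cfg2, cfg3 = tiny_config(), tiny_config()
        cfg3.num_classes = 3
        s = cfg2.stem_channels
        assert count_macs(cfg3, 32) - count_macs(cfg2, 32) == s * 32 * 32

    def test_macs_scale_with_area_for_conv_only_config(self):
        cfg = tiny_config(use_tm=False, use_lgp=False, use_gate=False)
        assert count_macs(cfg, 64) == 4 * count_macs(cfg, 32)

    def test_param_count_independent_of_mac_input_size(self):
        cfg = tiny_config()
        p = count_parameters(cfg)
        count_macs(cfg, 64)
        assert count_parameters(cfg) == p

    def test_accountant_matches_built_model(self):
        assert count_parameters(tiny_config()) == \
            TGMLPUNet(tiny_config(), seed=1).num_parameters()

    def test_budget_positive(self):
        b = budget(tiny_config())
        assert b.parameters > 0 and b.macs > 0


class TestCheckpoint:
    def test_roundtrip(self, rng, tiny_cfg, tmp_path):
        model = TGMLPUNet(tiny_cfg, seed=0)
        x = batch(rng, tiny_cfg, n=1)
        model.eval()
        before = model(x).data
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        loaded.eval()
        np.testing.assert_array_equal(loaded(x).data, before)

    def test_hash_guard(self, tiny_cfg, tmp_path):
        model = TGMLPUNet(tiny_cfg, seed=0)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        data = dict(np.load(path, allow_pickle=False))
        import json
        meta = json.loads(bytes(data["__meta__"]).decode())
        meta["hash"] = "0" * 16
        data["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **data)
        with pytest.raises(ValueError, match="hash"):
            load_checkpoint(path)
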