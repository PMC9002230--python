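"""Partition re-layout, global perceptron, local priors and the full block."""

import numpy as np
import pytest

from _oracles import (axis_step_oracle, conv2d_oracle, gp_apply_oracle,
                      partition_index_oracle)
from tgmlp import autodiff as ad
from tgmlp.lgp import (GlobalPerceptron, LocalPriors, TGMLPBlock, gp_apply,
                       gp_weights, local_priors, partition, unpartition)


class TestPartition:
    def test_h1_is_flat_view(self, rng):
        x = rng.normal(size=(2, 3, 4, 4))
        pt = partition(x, 1)
        assert pt.shape == (2, 4, 4, 3, 1, 1)
        np.testing.assert_array_equal(unpartition(pt), x)

    def test_quadrants_example(self):
        x = np.arange(16).reshape(1, 1, 4, 4)
        pt = partition(x, 2)
        assert pt.shape == (1, 2, 2, 1, 2, 2)
        cells = {(gy, gx): sorted(pt[0, :, :, 0, gy, gx].ravel().tolist())
                 for gy in range(2) for gx in range(2)}
        assert cells[(0, 0)] == [0, 1, 4, 5]
        assert cells[(0, 1)] == [2, 3, 6, 7]
        assert cells[(1, 0)] == [8, 9, 12, 13]
        assert cells[(1, 1)] == [10, 11, 14, 15]

    @pytest.mark.parametrize("h", [2, 4])
    def test_matches_index_oracle(self, rng, h):
        x = rng.normal(size=(2, 3, 8, 8))
        np.testing.assert_array_equal(partition(x, h), partition_index_oracle(x, h))

    @pytest.mark.parametrize("h", [1, 2, 4])
    def test_roundtrip_bijection(self, rng, h):
        x = rng.normal(size=(2, 3, 8, 8))
        back = unpartition(partition(x, h))
        np.testing.assert_array_equal(back, x)
        assert back.dtype == x.dtype

    def test_single_element_placement(self):
        pt = np.zeros((1, 2, 2, 1, 2, 2))
        pt[0, 1, 0, 0, 1, 0] = 5.0  # within-cell (col=1,row=0), grid cell (1,0)
        out = unpartition(pt)
        want = partition_index_oracle(out, 2)
        assert want[0, 1, 0, 0, 1, 0] == 5.0
        # grid cell (1,0) spans rows 2-3, cols 0-1; within-cell row 0, col 1
        assert out[0, 0, 2, 1] == 5.0
        assert np.count_nonzero(out) == 1

    def test_divisibility_error(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            partition(rng.normal(size=(1, 1, 6, 6)), 4)

    def test_works_on_tensors(self, rng):
        x = rng.normal(size=(1, 2, 4, 4)).astype(np.float32)
        pt = partition(ad.Tensor(x), 2)
        np.testing.assert_array_equal(pt.data, partition(x, 2))


class TestGlobalPerceptron:
    def test_gap_of_identical_partitions(self, rng):
        # tile one partition across the grid: pooling returns that partition
        block = rng.normal(size=(1, 2, 2, 3))
        pt = np.tile(block[..., None, None], (1, 1, 1, 1, 2, 2))
        pooled = pt.mean(axis=(4, 5))
        np.testing.assert_allclose(pooled, block)

    def test_zero_fc2_gives_zero_weights(self, rng):
        gp = GlobalPerceptron(3, 2, 2, rng=np.random.default_rng(0))
        gp.fc2.weight.data[:] = 0.0
        gp.fc2.bias.data[:] = 0.0
        pt = ad.Tensor(rng.normal(size=(2, 2, 2, 3, 2, 2)).astype(np.float32))
        assert not gp_weights(pt, gp).data.any()

    def test_matches_flatten_matmul_oracle(self, rng):
        gp = GlobalPerceptron(3, 2, 2, rng=np.random.default_rng(4))
        gp.eval()  # frozen running stats make BN an affine map
        pt = rng.normal(size=(2, 2, 2, 3, 2, 2))
        got = gp_weights(ad.Tensor(pt), gp).data
        flat = pt.mean(axis=(4, 5)).reshape(2, -1)
        xhat = (flat - gp.bn.running_mean) / np.sqrt(gp.bn.running_var + gp.bn.eps)
        bn = xhat * gp.bn.gamma.data + gp.bn.beta.data
        hidden = np.maximum(bn @ gp.fc1.weight.data + gp.fc1.bias.data, 0.0)
        want = hidden @ gp.fc2.weight.data + gp.fc2.bias.data
        np.testing.assert_allclose(got, want, rtol=1e-4, atol=1e-5)

    def test_length_mismatch_raises(self, rng):
        gp = GlobalPerceptron(3, 2, 2, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="length"):
            gp_weights(ad.Tensor(rng.normal(size=(1, 2, 2, 4, 2, 2))), gp)


class TestGPApply:
    def test_zero_weights(self, rng):
        pt = rng.normal(size=(1, 2, 2, 3, 2, 2))
        x_in = rng.normal(size=(1, 3, 4, 4))
        v = np.zeros((1, 12))
        np.testing.assert_allclose(gp_apply(pt, v, x_in), unpartition(pt) + x_in)

    def test_ones_offset_constant_map(self):
        pt = np.zeros((1, 2, 2, 1, 2, 2))
        out = gp_apply(pt, np.ones((1, 4)), np.zeros((1, 1, 4, 4)))
        np.testing.assert_array_equal(out, np.ones((1, 1, 4, 4)))

    def test_matches_loop_oracle_and_shares_across_cells(self, rng):
        pt = rng.normal(size=(2, 2, 2, 3, 2, 2))
        v = rng.normal(size=(2, 12))
        x_in = rng.normal(size=(2, 3, 4, 4))
        np.testing.assert_allclose(gp_apply(pt, v, x_in),
                                   gp_apply_oracle(pt, v, x_in), rtol=1e-6)
        # the added offset is identical in all h^2 grid cells
        delta = partition(gp_apply(pt, v, x_in) - x_in, 2) - pt
        for gy in range(2):
            for gx in range(2):
                np.testing.assert_allclose(delta[..., gy, gx], delta[..., 0, 0],
                                           atol=1e-9)


class TestLocalPriors:
    def test_zero_kernels_collapse_to_s(self, rng):
        lp = LocalPriors(3, rng=np.random.default_rng(0))
        for conv in lp.convs:
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        m = ad.Tensor(rng.normal(size=(2, 3, 4, 4)).astype(np.float32))
        s = rng.normal(size=(2, 3, 4, 4)).astype(np.float32)
        np.testing.assert_array_equal(local_priors(m, lp, ad.Tensor(s)).data, s)

    def test_resolution_preserved(self, rng):
        lp = LocalPriors(2, rng=np.random.default_rng(0))
        x = ad.Tensor(rng.normal(size=(1, 2, 8, 8)).astype(np.float32))
        assert local_priors(x, lp, x).shape == (1, 2, 8, 8)

    def test_single_branch_matches_conv_oracle(self, rng):
        lp = LocalPriors(1, rng=np.random.default_rng(0))
        lp.eval()  # default running stats: BN is (nearly) the identity
        edge = np.array([[0, -1, 0], [-1, 4, -1], [0, -1, 0]], dtype=np.float32)
        for i, conv in enumerate(lp.convs):
            conv.weight.data[:] = 0.0
            conv.bias.data[:] = 0.0
        lp.convs[1].weight.data[0, 0] = edge
        ramp = np.add.outer(np.arange(5.0), np.arange(5.0))[None, None]
        s = np.zeros_like(ramp)
        got = local_priors(ad.Tensor(ramp), lp, ad.Tensor(s)).data
        want = conv2d_oracle(ramp, edge[None, None], np.zeros(1), 1)
        want /= np.sqrt(1.0 + lp.bns[1].eps)
        np.testing.assert_allclose(got, want, rtol=1e-4, atol=1e-5)

    def test_shape_mismatch_raises(self, rng):
        lp = LocalPriors(2, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="mismatch"):
            local_priors(ad.Tensor(np.zeros((1, 2, 4, 4))), lp,
                         ad.Tensor(np.zeros((1, 2, 4, 5))))


def zeroed_block(channels=2, extent=4, h=2, seed=0):
    blk = TGMLPBlock(channels, extent, extent, h, rng=np.random.default_rng(seed))
    blk.core.gates.values.data[:] = 0.0
    blk.gp.fc2.weight.data[:] = 0.0
    blk.gp.fc2.bias.data[:] = 0.0
    for conv in blk.lp.convs:
        conv.weight.data[:] = 0.0
        conv.bias.data[:] = 0.0
    return blk


class TestFullBlock:
    def test_zero_init_collapse_is_identity(self, rng):
        blk = zeroed_block()
        x = rng.normal(size=(2, 2, 4, 4)).astype(np.float32)
        np.testing.assert_array_equal(blk(ad.Tensor(x)).data, x)

    def test_shape_preserved(self, rng):
        blk = TGMLPBlock(8, 16, 16, 2, rng=np.random.default_rng(0))
        x = ad.Tensor(rng.normal(size=(2, 8, 16, 16)).astype(np.float32))
        assert blk(x).shape == (2, 8, 16, 16)

    def test_divisibility_error(self):
        with pytest.raises(ValueError, match="divisible"):
            TGMLPBlock(2, 6, 6, 4, rng=np.random.default_rng(0))

    def test_locality_of_conv_path(self, rng):
        # with MLP paths disabled, a single-pixel perturbation can only reach
        # radius 3 (the 7x7 branch) through the local-priors convolutions
        blk = TGMLPBlock(1, 16, 16, 2, rng=np.random.default_rng(3))
        blk.eval()
        blk.core.gates.values.data[:] = 0.0
        blk.gp.fc2.weight.data[:] = 0.0
        blk.gp.fc2.bias.data[:] = 0.0
        x = rng.normal(size=(1, 1, 16, 16)).astype(np.float32)
        xp = x.copy()
        xp[0, 0, 8, 8] += 1.0
        diff = np.abs(blk(ad.Tensor(xp)).data - blk(ad.Tensor(x)).data)[0, 0]
        rows, cols = np.nonzero(diff > 1e-7)
        assert np.max(np.abs(rows - 8)) <= 3 and np.max(np.abs(cols - 8)) <= 3

    def test_matches_composed_op_oracles(self, rng):
        blk = TGMLPBlock(2, 4, 4, 2, rng=np.random.default_rng(9))
        blk.eval()
        x = rng.normal(size=(1, 2, 4, 4))
        got = blk(ad.Tensor(x.astype(np.float32))).data

        core = blk.core
        s = axis_step_oracle(x, core.channel_mlp, 1.0)
        s = axis_step_oracle(s, core.high_mlp, 1.0)
        s = axis_step_oracle(s, core.wide_mlp, 1.0)

        pt = partition_index_oracle(x, 2)
        flat = pt.mean(axis=(4, 5)).reshape(1, -1)
        gp = blk.gp
        bn = ((flat - gp.bn.running_mean) / np.sqrt(gp.bn.running_var + gp.bn.eps)
              * gp.bn.gamma.data + gp.bn.beta.data)
        hidden = np.maximum(bn @ gp.fc1.weight.data + gp.fc1.bias.data, 0.0)
        v = hidden @ gp.fc2.weight.data + gp.fc2.bias.data
        m = gp_apply_oracle(pt, v, x)

        want = s.copy()
        for conv, bnorm in zip(blk.lp.convs, blk.lp.bns):
            k = conv.weight.data.shape[-1]
            branch = conv2d_oracle(m, conv.weight.data, conv.bias.data, (k - 1) // 2)
            want += branch / np.sqrt(1.0 + bnorm.eps)
        np.testing.assert_allclose(got, want, rtol=1e-3, atol=1e-4)
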