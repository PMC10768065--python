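"""Block-level contracts: shapes, forced values, loop-oracle equivalence,
attention normalisation, gate bounds and differentiability."""

import numpy as np
import pytest

from weedseg.autodiff import Tensor
from weedseg.blocks import (
    ConvBlock,
    DualAttention,
    RefinementDilatedConv,
    SpatialConnectivityAttention,
)

import oracles


def _zero_params(module):
    for _, p in module.named_parameters():
        p.data[...] = 0.0


# ---------------------------------------------------------------------------
# shape contracts
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("cin,cout,hw", [(3, 8, 16), (8, 16, 9), (24, 32, 5)])
def test_conv_block_shape_contract(rng, cin, cout, hw):
    blk = ConvBlock(cin, cout, rng, bias=True)
    y = blk(Tensor(rng.normal(size=(2, cin, hw, hw))))
    assert y.shape == (2, cout, hw, hw)
    assert np.all(np.isfinite(y.numpy()))


def test_conv_block_rejects_nonpositive_channels(rng):
    with pytest.raises(ValueError):
        ConvBlock(3, 0, rng)


@pytest.mark.parametrize("c,hw", [(8, 16), (4, 2), (16, 7)])
def test_attention_and_refinement_preserve_shapes(rng, c, hw):
    x = rng.normal(size=(2, c, hw, hw))
    da = DualAttention(c, rng)
    assert da(Tensor(x)).shape == x.shape
    rdc = RefinementDilatedConv(c, 2 * c, rng)
    y = rdc(Tensor(x))
    assert y.shape == (2, 2 * c, hw, hw)
    assert np.all(np.isfinite(y.numpy()))


@pytest.mark.parametrize("cls,args", [
    (DualAttention, (6,)),
    (RefinementDilatedConv, (6, 8)),
])
def test_blocks_reject_channels_not_divisible_by_four(rng, cls, args):
    with pytest.raises(ValueError):
        cls(*args, rng)


def test_sca_preserves_ladder_shapes(rng):
    sca = SpatialConnectivityAttention(rng)
    feats = [Tensor(rng.normal(size=(1, c, s, s)))
             for c, s in [(8, 32), (16, 16), (24, 8), (32, 4), (48, 2), (64, 1)]]
    outs = sca(feats)
    assert [o.shape for o in outs] == [f.shape for f in feats]


def test_sca_rejects_empty_and_mismatched_batches(rng):
    sca = SpatialConnectivityAttention(rng)
    with pytest.raises(ValueError):
        sca([])
    with pytest.raises(ValueError):
        sca([Tensor(np.zeros((1, 4, 4, 4))), Tensor(np.zeros((2, 4, 2, 2)))])


# ---------------------------------------------------------------------------
# values forced by zero weights
# ---------------------------------------------------------------------------

def test_conv_block_zero_weights_give_zero_output(rng):
    blk = ConvBlock(3, 8, rng, bias=True)
    _zero_params(blk)
    blk.eval()
    y = blk(Tensor(rng.normal(size=(1, 3, 6, 6)))).numpy()
    assert np.allclose(y, 0.0)


def test_dual_attention_zero_weights_give_gelu_of_1p5x(rng):
    da = DualAttention(8, rng)
    _zero_params(da)
    x = rng.normal(size=(1, 8, 4, 4))
    y = da(Tensor(x)).numpy()
    # memory branch vanishes; channel gate = sigmoid(0) = 0.5
    expected = np.vectorize(oracles.gelu_scalar)(1.5 * x)
    assert np.allclose(y, expected, atol=1e-12)


def test_rdc_zero_weights_give_zero_output(rng):
    rdc = RefinementDilatedConv(8, 12, rng)
    _zero_params(rdc)
    y = rdc(Tensor(rng.normal(size=(1, 8, 5, 5)))).numpy()
    assert np.allclose(y, 0.0)


def test_sca_zero_weights_gate_half(rng):
    sca = SpatialConnectivityAttention(rng)
    _zero_params(sca)
    x = rng.normal(size=(2, 8, 6, 6))
    (out,) = sca([Tensor(x)])
    assert np.allclose(out.numpy(), 1.5 * x)


def test_sca_parameter_count_is_99_regardless_of_stages(rng):
    sca = SpatialConnectivityAttention(rng)
    assert sum(p.data.size for p in sca.parameters()) == 2 * 7 * 7 + 1
    sca([Tensor(np.zeros((1, 4, 8, 8))) for _ in range(6)])  # six stages, one kernel
    assert sum(p.data.size for p in sca.parameters()) == 99


# ---------------------------------------------------------------------------
# loop-oracle equivalence on tiny inputs
# ---------------------------------------------------------------------------

def test_conv_block_matches_loop_oracle(rng):
    blk = ConvBlock(1, 4, rng, bias=True)
    blk.eval()  # inference-mode norm with default running stats
    x = rng.normal(size=(1, 3, 3))
    got = blk(Tensor(x[None])).numpy()[0]
    want = oracles.conv_block_eval_loops(blk, x)
    assert np.abs(got - want).max() < 1e-5


@pytest.mark.parametrize("c,hw", [(4, 2), (8, 3)])
def test_dual_attention_matches_loop_oracle(rng, c, hw):
    da = DualAttention(c, rng)
    da.eval()
    x = rng.normal(size=(c, hw, hw))
    got = da(Tensor(x[None])).numpy()[0]
    want = oracles.dual_attention_loops(da, x)
    assert np.abs(got - want).max() < 1e-5


@pytest.mark.parametrize("cin,cout", [(4, 4), (8, 4)])
def test_rdc_matches_loop_oracle(rng, cin, cout):
    rdc = RefinementDilatedConv(cin, cout, rng)
    x = rng.normal(size=(cin, 4, 4))
    got = rdc(Tensor(x[None])).numpy()[0]
    want = oracles.rdc_loops(rdc, x)
    assert np.abs(got - want).max() < 1e-5


def test_rdc_delta_kernels_identity_fuse_reduce_to_groupnorm(rng):
    rdc = RefinementDilatedConv(4, 4, rng)
    for wk in rdc.branch_weights:
        wk.data[...] = 0.0
        wk.data[0, 0, 1, 1] = 1.0  # centred delta: branch becomes identity
    rdc.fuse_weight.data[...] = np.eye(4).reshape(4, 4, 1, 1)
    rdc.out_shift.data[...] = 0.0
    x = rng.normal(size=(4, 3, 3))
    got = rdc(Tensor(x[None])).numpy()[0]
    want = np.vectorize(oracles.gelu_scalar)(oracles.groupnorm4_loops(x))
    assert np.abs(got - want).max() < 1e-10


def test_rdc_branches_use_dilation_rates_1_2_5_8(rng):
    """A one-hot tap placed at each branch's dilated offset must respond."""
    cin = 4
    rdc = RefinementDilatedConv(cin, 4, rng)
    rdc.fuse_weight.data[...] = np.eye(4).reshape(4, 4, 1, 1)
    for k, rate in enumerate((1, 2, 5, 8)):
        for wk in rdc.branch_weights:
            wk.data[...] = 0.0
        rdc.branch_weights[k].data[0, 0, 0, 0] = 1.0  # top-left tap
        size = 2 * rate + 1
        x = np.zeros((1, cin, size, size))
        x[0, k, 0, 0] = 1.0  # impulse that only the dilated tap can reach
        fused = oracles.conv2d_loops(
            np.concatenate([
                oracles.depthwise_conv2d_loops(x[0, j:j + 1],
                                               rdc.branch_weights[j].numpy(),
                                               dilation=(1, 2, 5, 8)[j],
                                               padding=(1, 2, 5, 8)[j])
                for j in range(4)], axis=0),
            rdc.fuse_weight.numpy())
        # the impulse lands exactly `rate` pixels down-right of the centre
        assert fused[k, rate, rate] == 1.0
        assert fused.sum() == 1.0


def test_sca_matches_loop_oracle_single_stage(rng):
    sca = SpatialConnectivityAttention(rng)
    sca.weight.data[...] = rng.normal(size=sca.weight.shape)
    sca.bias.data[...] = 0.3
    x = rng.normal(size=(1, 2, 2))
    (got,) = sca([Tensor(x[None])])
    want = oracles.sca_loops(sca, x)
    assert np.abs(got.numpy()[0] - want).max() < 1e-6


# ---------------------------------------------------------------------------
# invariants
# ---------------------------------------------------------------------------

def test_attention_weights_are_convex_over_memory_slots(rng):
    da = DualAttention(8, rng)
    attn = da.attention_weights(Tensor(rng.normal(size=(2, 8, 3, 3))))
    assert attn.shape == (2 * 9, 32)
    assert np.abs(attn.sum(axis=1) - 1.0).max() < 1e-6
    assert attn.min() > 0.0


def test_sca_gate_bounds_imply_output_between_x_and_2x(rng):
    sca = SpatialConnectivityAttention(rng)
    x = np.abs(rng.normal(size=(1, 8, 5, 5)))
    gate = sca.gate(Tensor(x)).numpy()
    assert np.all(gate > 0.0) and np.all(gate < 1.0)
    (out,) = sca([Tensor(x)])
    y = out.numpy()
    assert np.all(y >= x - 1e-12) and np.all(y <= 2 * x + 1e-12)


@pytest.mark.parametrize("factory", [
    lambda rng: (ConvBlock(4, 8, rng, bias=True), (2, 4, 6, 6)),
    lambda rng: (DualAttention(8, rng), (2, 8, 4, 4)),
    lambda rng: (RefinementDilatedConv(8, 8, rng), (2, 8, 6, 6)),
])
def test_blocks_are_differentiable_in_every_parameter(rng, factory):
    blk, shape = factory(rng)
    out = blk(Tensor(rng.normal(size=shape)))
    (out ** 2.0).sum().backward()
    for name, p in blk.named_parameters():
        assert p.grad is not None, name
        assert np.all(np.isfinite(p.grad)), name
        assert np.any(p.grad != 0.0), name
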