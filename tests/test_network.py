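import numpy as np
import pytest

from enhancerrl import nn
from enhancerrl.network import (EnhancerNetwork, NetworkConfig, fuse,
                                positional_encoding)
from enhancerrl.nn import Tensor


def small_config(**kw):
    defaults = dict(vocab_size=20, embed_dim=16, resnet_out_dim=8,
                    transformer_out_dim=12, n_heads=2, n_encoder_blocks=1,
                    resnet_width_factor=0.1)
    defaults.update(kw)
    return NetworkConfig(**defaults)


def batch(net, n=6, seed=0):
    rng = np.random.default_rng(seed)
    ids = rng.integers(0, net.cfg.vocab_size, (n, net.l_max))
    lengths = np.full(n, net.l_max)
    return ids, lengths


def test_default_config_layout():
    cfg = NetworkConfig()
    assert cfg.fused_dim == 192
    assert cfg.resnet_out_dim == 64
    assert cfg.embed_dim == 128 and cfg.transformer_out_dim == 128


def test_embed_dim_divisibility_enforced():
    with pytest.raises(ValueError, match="divisible"):
        NetworkConfig(embed_dim=10, n_heads=3)


def test_both_branches_dropped_rejected():
    with pytest.raises(ValueError):
        NetworkConfig(use_resnet=False, use_transformer=False)


def test_positional_encoding_row0_and_range():
    table = positional_encoding(50, 16)
    assert np.allclose(table[0, 0::2], 0.0)  # sine slots
    assert np.allclose(table[0, 1::2], 1.0)  # cosine slots
    assert np.all(np.abs(table) <= 1.0)


def test_embedding_lookup_deterministic_and_shaped():
    net = EnhancerNetwork(small_config(), l_max=10, rng=0)
    ids, _ = batch(net, n=4)
    a = net.embed(ids)
    b = net.embed(ids)
    assert a.shape == (4, 10, 16)
    assert np.array_equal(a.data, b.data)
    with pytest.raises(IndexError):
        net.embed(np.array([[999]]))


def test_fuse_layout_and_inverse():
    a = Tensor(np.ones((3, 4)))
    b = Tensor(np.arange(6.0).reshape(3, 2))
    fused = fuse(a, b)
    assert fused.shape == (3, 6)
    assert np.array_equal(fused.data[:, :4], a.data)
    assert np.array_equal(fused.data[:, 4:], b.data)
    zero = fuse(Tensor(np.zeros((3, 4))), b)
    assert np.all(zero.data[:, :4] == 0)
    with pytest.raises(ValueError):
        fuse(Tensor(np.ones((2, 4))), b)


def test_extract_shapes_and_slice_by_branch_zeroing():
    net = EnhancerNetwork(small_config(), l_max=12, rng=1)
    net.eval()
    ids, lengths = batch(net)
    fused = net.extract(ids, lengths)
    assert fused.shape == (6, 20)
    # zero the ResNet projection -> first resnet_out_dim entries vanish
    net.resnet.proj.weight.data[:] = 0
    net.resnet.proj.bias.data[:] = 0
    fused = net.extract(ids, lengths)
    assert np.all(fused.data[:, :8] == 0)
    assert np.any(fused.data[:, 8:] != 0)


def test_all_ones_mask_equals_unmasked():
    net = EnhancerNetwork(small_config(), l_max=12, rng=2)
    ids, lengths = batch(net)
    p_none = net.predict_proba(ids, lengths, None)
    p_ones = net.predict_proba(ids, lengths, np.ones(net.fused_dim))
    assert np.array_equal(p_none, p_ones)


def test_all_zero_mask_gives_constant_probability():
    net = EnhancerNetwork(small_config(), l_max=12, rng=3)
    ids, lengths = batch(net)
    p = net.predict_proba(ids, lengths, np.zeros(net.fused_dim))
    assert np.allclose(p, p[0])
    assert np.all((p > 0) & (p < 1))


def test_mask_bit_flip_changes_output():
    net = EnhancerNetwork(small_config(), l_max=12, rng=4)
    ids, lengths = batch(net)
    mask = np.ones(net.fused_dim)
    base = net.predict_proba(ids, lengths, mask)
    mask[3] = 0
    flipped = net.predict_proba(ids, lengths, mask)
    assert not np.allclose(base, flipped)
    with pytest.raises(ValueError):
        net.predict_proba(ids, lengths, np.ones(net.fused_dim + 1))


def test_probabilities_in_unit_interval_and_batch_equivariance():
    net = EnhancerNetwork(small_config(), l_max=12, rng=5)
    ids, lengths = batch(net, n=8)
    p = net.predict_proba(ids, lengths)
    assert np.all((p > 0) & (p < 1))
    perm = np.random.default_rng(0).permutation(8)
    p_perm = net.predict_proba(ids[perm], lengths[perm])
    assert np.allclose(p[perm], p_perm)


def test_attention_weights_normalised():
    cfg = small_config()
    net = EnhancerNetwork(cfg, l_max=9, rng=6)
    enc = net.transformer.encoders[0]
    x = Tensor(np.random.default_rng(1).normal(size=(2, 9, cfg.embed_dim)))
    lengths = np.array([9, 5])
    pad = np.arange(9)[None, :] >= lengths[:, None]
    key_bias = np.where(pad, -1e9, 0.0)[:, None, None, :]
    h, dh = enc.n_heads, cfg.embed_dim // enc.n_heads
    q = (enc.wq(x).reshape(2, 9, h, dh).transpose(0, 2, 1, 3)
         * (1.0 / np.sqrt(dh)))
    k = enc.wk(x).reshape(2, 9, h, dh).transpose(0, 2, 1, 3)
    attn = nn.softmax(q @ k.transpose(0, 1, 3, 2), axis=-1, bias=key_bias)
    assert np.allclose(attn.data.sum(axis=-1), 1.0)
    # pad keys receive zero attention from every query
    assert np.all(attn.data[1, :, :, 5:] < 1e-12)


def test_positional_encoding_breaks_permutation_symmetry():
    """Pure self-attention + masked mean pooling is permutation-invariant
    over sequence positions; adding the sinusoid table breaks the tie."""
    cfg = small_config()
    rng = np.random.default_rng(7)
    ids = rng.integers(0, cfg.vocab_size, 10)
    perm = rng.permutation(10)
    both = np.stack([ids, ids[perm]])
    lengths = np.full(2, 10)

    no_pe = EnhancerNetwork(cfg, l_max=10, rng=8, use_positional=False)
    no_pe.eval()
    with nn.no_grad():
        pooled = no_pe.transformer(no_pe.embed(both), lengths).data
    assert np.allclose(pooled[0], pooled[1], atol=1e-10)

    with_pe = EnhancerNetwork(cfg, l_max=10, rng=8, use_positional=True)
    with_pe.eval()
    with nn.no_grad():
        pooled = with_pe.transformer(with_pe.embed(both), lengths).data
    assert not np.allclose(pooled[0], pooled[1], atol=1e-6)


def test_residual_block_zero_weights_reduce_to_skip():
    from enhancerrl.network import ResidualBlock
    block = ResidualBlock(4, 4, 3, 1, np.random.default_rng(0))
    for conv in (block.conv1, block.conv2):
        conv.weight.data[:] = 0
        conv.bias.data[:] = 0
    block.eval()
    x = Tensor(np.random.default_rng(1).normal(size=(2, 4, 7)))
    out = block(x)
    # main path contributes only the (zero) bn output; result is relu(skip)
    assert np.allclose(out.data, np.maximum(x.data, 0))


def test_sequence_shorter_than_receptive_field_raises():
    from enhancerrl.nn.autograd import conv1d

    x = Tensor(np.zeros((1, 2, 2)))
    w = Tensor(np.zeros((3, 2, 5)))
    b = Tensor(np.zeros(3))
    with pytest.raises(ValueError, match="too short"):
        conv1d(x, w, b, stride=1, padding=0)


def test_inference_deterministic_with_dropout_configured():
    net = EnhancerNetwork(small_config(dropout=0.5, branch_dropout=0.5),
                          l_max=12, rng=10)
    ids, lengths = batch(net)
    a = net.predict_proba(ids, lengths)
    b = net.predict_proba(ids, lengths)
    assert np.array_equal(a, b)
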