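"""Architecture contracts: shape algebra, locality, independence."""

import numpy as np
import pytest

from sect2mdi.model import (AttentionPair, Discriminator, Generator,
                            ModelConfig, PatchEmbed, PatchExpand, PatchMerge,
                            load_checkpoint, save_checkpoint)
from sect2mdi.nn import Tensor

from conftest import TINY_MODEL

RNG = np.random.default_rng(0)


def test_patch_embed_shape_and_linearity():
    emb = PatchEmbed(rank=2, patch_size=2, in_channels=1, embed_dim=16,
                     rng=np.random.default_rng(1))
    out = emb(Tensor(RNG.standard_normal((1, 64, 64, 1))))
    assert out.shape == (1, 32, 32, 16)
    emb.proj.bias.data[:] = 0.0
    zero = emb(Tensor(np.zeros((1, 8, 8, 1))))
    assert np.abs(zero.data).max() == 0.0
    with pytest.raises(ValueError):
        emb(Tensor(np.zeros((1, 7, 7, 1))))


def test_patch_merge_and_expand_shape_roundtrip():
    merge = PatchMerge(rank=2, channels=16, rng=np.random.default_rng(2))
    x = Tensor(RNG.standard_normal((1, 32, 32, 16)))
    merged = merge(x)
    assert merged.shape == (1, 16, 16, 32)
    expand = PatchExpand(rank=2, channels=32, rng=np.random.default_rng(3))
    assert expand(merged).shape == (1, 32, 32, 16)
    with pytest.raises(ValueError):
        merge(Tensor(np.zeros((1, 7, 7, 16))))


def test_patch_merge_3d_doubles_channels():
    merge = PatchMerge(rank=3, channels=8, rng=np.random.default_rng(4))
    out = merge(Tensor(RNG.standard_normal((1, 8, 8, 8, 8))))
    assert out.shape == (1, 4, 4, 4, 16)


def test_attention_pair_preserves_shape_and_weight_sharing():
    pair = AttentionPair(rank=2, channels=16, heads=2, window=4,
                         mlp_ratio=2.0, rng=np.random.default_rng(5))
    small = pair(Tensor(RNG.standard_normal((1, 8, 8, 16))))
    large = pair(Tensor(RNG.standard_normal((1, 16, 16, 16))))
    assert small.shape == (1, 8, 8, 16)
    assert large.shape == (1, 16, 16, 16)  # same weights, any grid


def test_window_attention_is_window_local():
    """Swapping the contents of two windows swaps the outputs identically."""
    pair = AttentionPair(rank=2, channels=8, heads=2, window=4,
                         mlp_ratio=2.0, rng=np.random.default_rng(6))
    block = pair.blocks[0]  # unshifted block: pure within-window mixing
    x = RNG.standard_normal((1, 4, 8, 8))  # two 4x4 windows side by side
    swapped = np.concatenate([x[:, :, 4:], x[:, :, :4]], axis=2)
    out = block(Tensor(x)).data
    out_swapped = block(Tensor(swapped)).data
    assert np.allclose(out_swapped[:, :, :4], out[:, :, 4:], atol=1e-5)
    assert np.allclose(out_swapped[:, :, 4:], out[:, :, :4], atol=1e-5)


def test_encoder_pyramid_shapes():
    gen = Generator(ModelConfig(), seed=0)
    grids = gen.encoder(Tensor(RNG.standard_normal((1, 64, 64, 1))))
    assert [g.values.shape for g in grids] == [
        (1, 32, 32, 16), (1, 16, 16, 32), (1, 8, 8, 64), (1, 4, 4, 128)]
    mid = gen.bottleneck(grids[-1])
    assert mid.values.shape == (1, 8, 8, 64)


def test_generator_end_to_end_shape_and_determinism():
    gen = Generator(TINY_MODEL, seed=0)
    x = RNG.uniform(0, 256, (16, 16))
    a = gen.generate(x)
    b = gen.generate(x)
    assert a.svnc.shape == x.shape and a.siom.shape == x.shape
    assert np.array_equal(a.svnc, b.svnc)
    assert np.isfinite(a.svnc).all() and np.isfinite(a.siom).all()


def test_generator_3d_shape():
    cfg = ModelConfig(spatial_rank=3, patch_size=2, embed_dim=8,
                      head_counts=(1, 1, 2, 2), window_size=2)
    gen = Generator(cfg, seed=0)
    svnc, siom = gen(Tensor(RNG.standard_normal((1, 16, 16, 16, 1))))
    assert svnc.shape == (1, 16, 16, 16, 1)
    assert siom.shape == (1, 16, 16, 16, 1)


def test_generator_rejects_inadmissible_shape():
    gen = Generator(TINY_MODEL, seed=0)
    with pytest.raises(ValueError):
        gen(Tensor(np.zeros((1, 20, 20, 1))))


def test_decoders_share_no_parameters():
    gen = Generator(TINY_MODEL, seed=0)
    x = np.zeros((16, 16))
    before = gen.generate(x)
    for p in gen.decoder_iom.parameters():
        p.data += 0.25
    after = gen.generate(x)
    assert np.array_equal(before.svnc, after.svnc)
    assert not np.array_equal(before.siom, after.siom)


def test_every_parameter_receives_gradient():
    gen = Generator(TINY_MODEL, seed=0)
    x = Tensor(RNG.standard_normal((2, 16, 16, 1)))
    svnc, siom = gen(x)
    gen.zero_grad()
    (svnc.abs().mean() + siom.abs().mean()).backward()
    missing = [n for n, p in gen.named_parameters()
               if p.grad is None or np.abs(p.grad).max() == 0.0]
    assert missing == []


def test_discriminator_contracts():
    cfg = ModelConfig()
    d1 = Discriminator(cfg, (64, 64), seed=1)
    d2 = Discriminator(cfg, (64, 64), seed=2)
    batch = Tensor(RNG.standard_normal((3, 64, 64, 1)))
    assert d1(batch).shape == (3, 1)
    probe = RNG.standard_normal((64, 64))
    score = d1.discriminate(probe)
    assert np.isscalar(score)
    for p in d2.parameters():  # the two discriminators are independent
        p.data += 1.0
    assert d1.discriminate(probe) == score
    with pytest.raises(ValueError):
        d1(Tensor(np.zeros((1, 32, 32, 1))))


def test_window_clamps_with_warning():
    pair = AttentionPair(rank=2, channels=8, heads=2, window=8,
                         mlp_ratio=2.0, rng=np.random.default_rng(7))
    with pytest.warns(UserWarning, match="clamped"):
        out = pair(Tensor(RNG.standard_normal((1, 4, 4, 8))))
    assert out.shape == (1, 4, 4, 8)


def test_checkpoint_roundtrip(tmp_path):
    gen = Generator(TINY_MODEL, seed=0)
    dv = Discriminator(TINY_MODEL, (16, 16), seed=1)
    di = Discriminator(TINY_MODEL, (16, 16), seed=2)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, gen, dv, di, extra={"note": "test"})
    gen2, dv2, di2, extra = load_checkpoint(path)
    x = RNG.uniform(0, 256, (16, 16))
    assert np.array_equal(gen.generate(x).svnc, gen2.generate(x).svnc)
    assert dv.discriminate(x) == pytest.approx(dv2.discriminate(x))
    assert extra == {"note": "test"}


def test_memorization_capacity(memorization_run):
    """A toy generator can overfit one pair far below its initial error."""
    case, res = memorization_run
    h = res.history
    assert h.l1_vnc.iloc[-1] < 0.1 * h.l1_vnc.iloc[0]
    pred = res.predict(case)
    # final L1 under 10% of the intensity range on both maps
    assert np.abs(pred.svnc - case.vnc).mean() < 25.6
    assert np.abs(pred.siom - case.iom).mean() < 25.6
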