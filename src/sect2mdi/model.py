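"""Windowed-transformer GAN for SECT -> (sVNC, sIOM) translation.

The generator is a U-shaped pyramidal transformer: a patch-embedding block,
three encoder stages of (shifted-)window attention pairs each followed by
patch merging (halving resolution, doubling channels), a bottleneck attention
pair with a patch expansion, and two structurally identical, parameter-
independent decoders — one per material map — of three stages of attention
pairs with patch expansion and optional encoder skip fusion.  The last stage
expands by the patch size and a linear head produces the single-channel
prediction, so the generator is shape-preserving end to end.

Attention uses non-overlapping windows; the second block of every pair
shifts the windows by half a window (cyclically, treating the volume as
periodic) so information propagates across window borders.  The two
discriminators are small strided convolutional networks with a fully
connected head producing one realness logit each.

Rank 2 (2D slices) and rank 3 (volumes) are both first-class; all spatial
bookkeeping is rank-generic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from .nn import Tensor, Module, ModuleList, LayerNorm
from .nn import Linear as _EngineLinear


def Linear(in_features, out_features, rng):
    """Model-local linear: transformer-conventional 0.02 normal init."""
    return _EngineLinear(in_features, out_features, rng, init_scale=0.02)

__all__ = ["ModelConfig", "FeatureGrid", "PairedPrediction", "PatchEmbed",
           "WindowAttentionBlock", "AttentionPair", "PatchMerge", "PatchExpand",
           "Encoder", "Bottleneck", "DecoderBranch", "Generator",
           "Discriminator", "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults: 2D desk scale)."""

    spatial_rank: int = 2
    patch_size: int = 2
    embed_dim: int = 16
    encoder_depths: tuple[int, int, int, int] = (0, 1, 1, 1)
    head_counts: tuple[int, int, int, int] = (2, 2, 4, 4)
    window_size: int = 4
    decoder_depths: tuple[int, int, int] = (1, 1, 1)
    use_skips: bool = True
    disc_channels: tuple[int, int, int, int] = (16, 32, 64, 128)
    mlp_ratio: float = 4.0
    # span of the normalized intensity range; inputs are divided (and outputs
    # multiplied) by this inside the networks so features and gradients are
    # O(1) while the external interface stays in intensity units
    io_scale: float = 256.0
    seed: int = 0

    def __post_init__(self):
        if self.spatial_rank not in (2, 3):
            raise ValueError("spatial_rank must be 2 or 3")
        # attention in encoder stage i runs at embed_dim * 2**(i-1) channels
        for i in range(1, 4):
            ch = self.embed_dim * 2 ** (i - 1)
            if ch % self.head_counts[i]:
                raise ValueError(f"stage {i}: {ch} channels not divisible by "
                                 f"{self.head_counts[i]} heads")

    def validate_input_shape(self, spatial_shape: tuple[int, ...]) -> None:
        if len(spatial_shape) != self.spatial_rank:
            raise ValueError(f"expected rank {self.spatial_rank}, "
                             f"got shape {spatial_shape}")
        factor = self.patch_size * 8
        for s in spatial_shape:
            if s % factor:
                raise ValueError(f"spatial dims must be divisible by "
                                 f"patch_size*8={factor}, got {spatial_shape}")


@dataclass
class FeatureGrid:
    """A token grid: tensor of shape (B, *spatial_shape, channels)."""

    values: Tensor

    @property
    def spatial_shape(self) -> tuple[int, ...]:
        return self.values.shape[1:-1]

    @property
    def channels(self) -> int:
        return self.values.shape[-1]


@dataclass
class PairedPrediction:
    """Generator outputs for one input (synthetic VNC and iodine map)."""

    svnc: np.ndarray
    siom: np.ndarray
    case_id: str = ""


# -- token-grid rearrangements ------------------------------------------------

def _split_axes(x: Tensor, factor: int, rank: int) -> Tensor:
    """(B, s1*f, ..., sr*f, C) -> (B, s1, ..., sr, f^r * C), block-local order."""
    b = x.shape[0]
    spatial = x.shape[1:-1]
    c = x.shape[-1]
    inter = [b]
    for s in spatial:
        inter += [s // factor, factor]
    inter += [c]
    x = x.reshape(inter)
    # bring the factor axes together in front of channels
    coarse = [0] + [1 + 2 * i for i in range(rank)]
    fine = [2 + 2 * i for i in range(rank)]
    x = x.transpose(tuple(coarse + fine + [2 * rank + 1]))
    new_spatial = [s // factor for s in spatial]
    return x.reshape([b] + new_spatial + [factor ** rank * c])


def _merge_axes(x: Tensor, factor: int, rank: int, out_channels: int) -> Tensor:
    """Inverse of :func:`_split_axes`: (B, s, f^r*C) -> (B, s*f, C)."""
    b = x.shape[0]
    spatial = x.shape[1:-1]
    x = x.reshape([b] + list(spatial) + [factor] * rank + [out_channels])
    perm = [0]
    for i in range(rank):
        perm += [1 + i, 1 + rank + i]
    perm += [1 + 2 * rank]
    x = x.transpose(tuple(perm))
    return x.reshape([b] + [s * factor for s in spatial] + [out_channels])


def window_partition(x: Tensor, window: int, rank: int) -> Tensor:
    """(B, *S, C) -> (B * n_windows, window^r, C)."""
    c = x.shape[-1]
    split = _split_axes(x, window, rank)  # (B, *S/w, w^r * C)
    nw = int(np.prod(split.shape[1:-1]))
    return split.reshape((x.shape[0] * nw, window ** rank, c))


def window_reverse(tokens: Tensor, window: int, rank: int,
                   batch: int, spatial: tuple[int, ...]) -> Tensor:
    c = tokens.shape[-1]
    coarse = [s // window for s in spatial]
    x = tokens.reshape([batch] + coarse + [window ** rank * c])
    return _merge_axes(x, window, rank, c)


# -- building blocks ----------------------------------------------------------

class PatchEmbed(Module):
    """Non-overlapping p-patch partition + learned linear embedding."""

    def __init__(self, rank: int, patch_size: int, in_channels: int,
                 embed_dim: int, rng: np.random.Generator):
        self.rank = rank
        self.patch_size = patch_size
        self.proj = Linear(patch_size ** rank * in_channels, embed_dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        for s in x.shape[1:-1]:
            if s % self.patch_size:
                raise ValueError(f"spatial dim {s} not divisible by patch "
                                 f"size {self.patch_size}")
        return self.proj(_split_axes(x, self.patch_size, self.rank))


class WindowAttention(Module):
    """Multi-head self-attention within fixed windows."""

    def __init__(self, channels: int, heads: int, rng: np.random.Generator):
        if channels % heads:
            raise ValueError("channels must be divisible by heads")
        self.heads = heads
        self.head_dim = channels // heads
        self.scale = self.head_dim ** -0.5
        self.qkv = Linear(channels, 3 * channels, rng)
        self.proj = Linear(channels, channels, rng)

    def forward(self, tokens: Tensor) -> Tensor:
        n, t, c = tokens.shape
        h, d = self.heads, self.head_dim
        qkv = (self.qkv(tokens).reshape((n, t, 3, h, d))
               .transpose((2, 0, 3, 1, 4)))  # (3, N, h, T, d)
        q = qkv.select(0, 0) * self.scale
        k = qkv.select(0, 1)
        v = qkv.select(0, 2)
        attn = (q @ k.transpose((0, 1, 3, 2))).softmax(-1)
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape((n, t, c))
        return self.proj(out)


class WindowAttentionBlock(Module):
    """Pre-norm attention + MLP with residuals; optionally shifted windows."""

    def __init__(self, rank: int, channels: int, heads: int, window: int,
                 shifted: bool, mlp_ratio: float, rng: np.random.Generator):
        self.rank = rank
        self.window = window
        self.shifted = shifted
        self.norm1 = LayerNorm(channels)
        self.attn = WindowAttention(channels, heads, rng)
        self.norm2 = LayerNorm(channels)
        hidden = int(channels * mlp_ratio)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def _effective_window(self, spatial: tuple[int, ...]) -> int:
        w = self.window
        smallest = min(spatial)
        if w > smallest:
            warnings.warn(f"window {w} larger than grid {spatial}; clamped "
                          f"to {smallest}", stacklevel=3)
            w = smallest
        while smallest % w:
            w -= 1
        return w

    def forward(self, x: Tensor) -> Tensor:
        batch, *spatial, _ = x.shape
        spatial = tuple(spatial)
        w = self._effective_window(spatial)
        shift = w // 2 if (self.shifted and w > 1) else 0
        h = self.norm1(x)
        if shift:
            h = h.roll(tuple(-shift for _ in spatial), tuple(range(1, 1 + self.rank)))
        tokens = window_partition(h, w, self.rank)
        tokens = self.attn(tokens)
        h = window_reverse(tokens, w, self.rank, batch, spatial)
        if shift:
            h = h.roll(tuple(shift for _ in spatial), tuple(range(1, 1 + self.rank)))
        x = x + h
        return x + self.fc2(self.fc1(self.norm2(x)).gelu())


class AttentionPair(Module):
    """Two successive window-attention blocks, the second with shifted windows."""

    def __init__(self, rank: int, channels: int, heads: int, window: int,
                 mlp_ratio: float, rng: np.random.Generator):
        self.blocks = ModuleList([
            WindowAttentionBlock(rank, channels, heads, window, False, mlp_ratio, rng),
            WindowAttentionBlock(rank, channels, heads, window, True, mlp_ratio, rng),
        ])

    def forward(self, x: Tensor) -> Tensor:
        for block in self.blocks:
            x = block(x)
        return x


class PatchMerge(Module):
    """Halve resolution, double channels (2^r-neighbor concat + linear)."""

    def __init__(self, rank: int, channels: int, rng: np.random.Generator):
        self.rank = rank
        self.norm = LayerNorm(2 ** rank * channels)
        self.reduce = Linear(2 ** rank * channels, 2 * channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        for s in x.shape[1:-1]:
            if s % 2:
                raise ValueError(f"odd spatial dim {s} cannot be merged")
        return self.reduce(self.norm(_split_axes(x, 2, self.rank)))


class PatchExpand(Module):
    """Upscale resolution by ``factor``; linear up-projection + rearrange."""

    def __init__(self, rank: int, channels: int, rng: np.random.Generator,
                 factor: int = 2, out_channels: int | None = None,
                 normalize: bool = True):
        if out_channels is None:
            if channels % 2:
                raise ValueError("channels must be even to halve")
            out_channels = channels // 2
        self.rank = rank
        self.factor = factor
        self.out_channels = out_channels
        self.expand = Linear(channels, factor ** rank * out_channels, rng)
        # the expansion feeding the regression head keeps raw amplitudes:
        # per-voxel normalization would discard the intensity scale the
        # head must predict
        self.norm = LayerNorm(out_channels) if normalize else None

    def forward(self, x: Tensor) -> Tensor:
        out = _merge_axes(self.expand(x), self.factor, self.rank,
                          self.out_channels)
        return self.norm(out) if self.norm is not None else out


# -- encoder / bottleneck / decoders ------------------------------------------

class Encoder(Module):
    """Four-stage pyramid: embed, then (attention pairs + merge) x 3."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        r, c = config.spatial_rank, config.embed_dim
        self.embed = PatchEmbed(r, config.patch_size, 1, c, rng)
        self.stage1_pairs = ModuleList([
            AttentionPair(r, c, config.head_counts[0], config.window_size,
                          config.mlp_ratio, rng)
            for _ in range(config.encoder_depths[0])])
        self.stages = ModuleList()
        for i in range(1, 4):
            ch = c * 2 ** (i - 1)
            pairs = ModuleList([
                AttentionPair(r, ch, config.head_counts[i], config.window_size,
                              config.mlp_ratio, rng)
                for _ in range(max(1, config.encoder_depths[i]))])
            merge = PatchMerge(r, ch, rng)
            stage = Module()
            stage.pairs = pairs
            stage.merge = merge
            self.stages.append(stage)

    def forward(self, x: Tensor) -> list[FeatureGrid]:
        g = self.embed(x)
        for pair in self.stage1_pairs:
            g = pair(g)
        grids = [FeatureGrid(g)]
        for stage in self.stages:
            for pair in stage.pairs:
                g = pair(g)
            g = stage.merge(g)
            grids.append(FeatureGrid(g))
        return grids


class Bottleneck(Module):
    """One attention pair at the deepest resolution, then patch expansion."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        r = config.spatial_rank
        ch = config.embed_dim * 8
        self.pair = AttentionPair(r, ch, config.head_counts[3],
                                  config.window_size, config.mlp_ratio, rng)
        self.expand = PatchExpand(r, ch, rng)

    def forward(self, grid: FeatureGrid) -> FeatureGrid:
        return FeatureGrid(self.expand(self.pair(grid.values)))


class DecoderBranch(Module):
    """Three cascaded decoder stages ending in a one-channel head.

    Stages 1-2 expand resolution by 2 (halving channels); stage 3 performs
    the final expansion by the patch size, returning to the input resolution
    before the linear head.  Encoder grids of matching resolution are fused
    by concatenation + linear reduction when skips are enabled.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        r, c = config.spatial_rank, config.embed_dim
        heads = (config.head_counts[2], config.head_counts[1], config.head_counts[0])
        self.fuse = ModuleList()
        self.pairs = ModuleList()
        self.expands = ModuleList()
        for i, ch in enumerate((4 * c, 2 * c, c)):
            if config.use_skips:
                self.fuse.append(Linear(2 * ch, ch, rng))
            self.pairs.append(ModuleList([
                AttentionPair(r, ch, heads[i], config.window_size,
                              config.mlp_ratio, rng)
                for _ in range(max(1, config.decoder_depths[i]))]))
            if i < 2:
                self.expands.append(PatchExpand(r, ch, rng))
        self.final_expand = PatchExpand(r, c, rng, factor=config.patch_size,
                                        out_channels=c, normalize=False)
        self.head = Linear(c, 1, rng)

    def forward(self, bottleneck_out: FeatureGrid,
                encoder_grids: list[FeatureGrid]) -> Tensor:
        from .nn import concat
        g = bottleneck_out.values
        skips = (encoder_grids[2], encoder_grids[1], encoder_grids[0])
        for i in range(3):
            if self.config.use_skips:
                skip = skips[i].values
                if skip.shape != g.shape:
                    raise ValueError(f"skip shape {skip.shape} does not match "
                                     f"decoder grid {g.shape}")
                g = self.fuse[i](concat([g, skip], axis=-1))
            for pair in self.pairs[i]:
                g = pair(g)
            if i < 2:
                g = self.expands[i](g)
        return self.head(self.final_expand(g))


class Generator(Module):
    """Full encoder / bottleneck / dual-decoder generator."""

    def __init__(self, config: ModelConfig, seed: int | None = None):
        rng = np.random.default_rng(config.seed if seed is None else seed)
        self.config = config
        self.encoder = Encoder(config, rng)
        self.bottleneck = Bottleneck(config, rng)
        self.decoder_vnc = DecoderBranch(config, rng)
        self.decoder_iom = DecoderBranch(config, rng)

    @property
    def shared_layer(self):
        """Shared trunk for task-weight balancing: the patch embedding.

        With skip connections, decoder gradients can bypass the deepest
        encoder stage almost entirely (a task that relies on the skips
        leaves near-zero gradient there), which starves a gradient-norm
        comparison.  The patch-embedding projection is the one layer every
        computation path traverses, so per-task norms measured here are
        comparable.
        """
        return self.encoder.embed.proj.weight

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        self.config.validate_input_shape(x.shape[1:-1])
        s = self.config.io_scale
        grids = self.encoder(x * (1.0 / s))
        mid = self.bottleneck(grids[-1])
        svnc = self.decoder_vnc(mid, grids) * s
        siom = self.decoder_iom(mid, grids) * s
        return svnc, siom

    def generate(self, sect: np.ndarray, case_id: str = "") -> PairedPrediction:
        """Inference convenience for a single (unbatched) numpy volume."""
        x = Tensor(np.asarray(sect, dtype=np.float64)[None, ..., None])
        svnc, siom = self.forward(x)
        return PairedPrediction(svnc=svnc.data[0, ..., 0],
                                siom=siom.data[0, ..., 0], case_id=case_id)


class Discriminator(Module):
    """Four strided convolutions + fully connected realness head."""

    def __init__(self, config: ModelConfig, input_shape: tuple[int, ...],
                 seed: int | None = None):
        rng = np.random.default_rng((config.seed if seed is None else seed))
        from .nn import Parameter
        self.rank = config.spatial_rank
        self.input_shape = tuple(input_shape)
        self.io_scale = config.io_scale
        self.weights = []
        self.biases = []
        kernel, stride, pad = 4, 2, 1
        cin = 1
        shape = list(self.input_shape)
        for cout in config.disc_channels:
            wshape = (kernel,) * self.rank + (cin, cout)
            fan_in = kernel ** self.rank * cin
            self.weights.append(Parameter(
                rng.standard_normal(wshape) * np.sqrt(2.0 / fan_in)))
            self.biases.append(Parameter(np.zeros(cout)))
            shape = [(s + 2 * pad - kernel) // stride + 1 for s in shape]
            cin = cout
        self.fc = Linear(int(np.prod(shape)) * cin, 1, rng)
        self._flat = int(np.prod(shape)) * cin

    def forward(self, x: Tensor) -> Tensor:
        if tuple(x.shape[1:-1]) != self.input_shape:
            raise ValueError(f"discriminator expects spatial shape "
                             f"{self.input_shape}, got {x.shape[1:-1]}")
        x = x * (1.0 / self.io_scale)
        for w, b in zip(self.weights, self.biases):
            x = x.conv(w, b, stride=2, padding=1).leaky_relu(0.2)
        x = x.reshape((x.shape[0], self._flat))
        return self.fc(x)  # (B, 1) logits

    def discriminate(self, image: np.ndarray) -> float:
        x = Tensor(np.asarray(image, dtype=np.float64)[None, ..., None])
        return float(self.forward(x).data[0, 0])


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(path: str | Path, generator: Generator,
                    disc_vnc: Discriminator | None = None,
                    disc_iom: Discriminator | None = None,
                    extra: dict | None = None) -> None:
    """Serialize weights + ModelConfig into one .npz checkpoint."""
    payload: dict[str, np.ndarray] = {}
    meta = {"config": asdict(generator.config),
            "disc_input_shape": list(disc_vnc.input_shape) if disc_vnc else None,
            "extra": extra or {}}
    payload["__meta__"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    for prefix, module in (("gen", generator), ("dvnc", disc_vnc),
                           ("diom", disc_iom)):
        if module is None:
            continue
        for name, arr in module.state_dict().items():
            payload[f"{prefix}/{name}"] = arr
    np.savez(Path(path), **payload)


def load_checkpoint(path: str | Path):
    """Rebuild (generator, disc_vnc, disc_iom, extra) from a checkpoint."""
    with np.load(Path(path), allow_pickle=False) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        cfg_dict = meta["config"]
        for key in ("encoder_depths", "head_counts", "decoder_depths",
                    "disc_channels"):
            cfg_dict[key] = tuple(cfg_dict[key])
        config = ModelConfig(**cfg_dict)
        generator = Generator(config)
        generator.load_state_dict(
            {k[4:]: data[k] for k in data.files if k.startswith("gen/")})
        disc_vnc = disc_iom = None
        if meta["disc_input_shape"]:
            shape = tuple(meta["disc_input_shape"])
            disc_vnc = Discriminator(config, shape)
            disc_iom = Discriminator(config, shape)
            disc_vnc.load_state_dict(
                {k[5:]: data[k] for k in data.files if k.startswith("dvnc/")})
            disc_iom.load_state_dict(
                {k[5:]: data[k] for k in data.files if k.startswith("diom/")})
    return generator, disc_vnc, disc_iom, meta["extra"]
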