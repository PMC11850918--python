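"""The UI-Trans network: a dual-branch (transformer + convolutional)
hierarchical encoder with a U-type convolutional decoder.

Channel bookkeeping (base channels B, stage index i starting at 0)
------------------------------------------------------------------
Every encoder stage halves each spatial dimension and ends by
concatenating its two branch outputs along channels. The stage output
width is fixed by the schedule

    W_i = B * 2**(i + 1)

independently of which branches are enabled, so the decoder never has to
know about ablations:

    stage input   : 1 channel for i = 0, else W_{i-1}
    conv branch   : DoubleConv -> W_i/2 channels (B * 2**i), then stride-2 conv
    transformer   : two parallel MSA modules, each W_i/4 channels,
                    concatenated to W_i/2, then stride-2 conv
    single branch : the enabled branch produces all of W_i
    skip i        : the concatenated stage output, W_i channels at 1/2**(i+1) res
    bottleneck    : DoubleConv on skip[n-1]; for a 64^3 input and 3 stages the
                    bottleneck is 8^3 with B * 2**n channels.

The decoder mirrors the convolutional pathway: trilinear 2x upsampling +
convolution, concatenation with the corresponding skip, and a double
convolution, finishing with a 1x1x1 convolution to one channel.

Tokenization: each MSA embeds the volume by interval extraction —
stride-s interleaved sub-sampling (space-to-channel rearrangement with
s = token_stride per axis) followed by a linear projection — so every
token sees the full field of view. When the token grid would exceed
``max_tokens_per_axis`` per axis, keys/values are average-pooled onto a
coarser grid (queries stay at full token resolution), bounding the
quadratic attention cost while preserving output size.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import autograd as ag
from .nn.autograd import Tensor
from .nn.layers import (Adam, Conv3d, LayerNorm, Linear, MLP, Module,
                        MultiheadSelfAttention, Parameter)


class ShapeError(ValueError):
    """Input spatial dimensions incompatible with the network."""


class ConfigError(ValueError):
    """Invalid architecture configuration."""


@dataclass
class UITransConfig:
    """Architecture hyperparameters.

    The published description fixes the topology (3 stages, dual branch,
    twin MSAs, channel doubling) but not the widths; ``base_channels``,
    ``embed_dim``, ``n_heads``, ``mlp_ratio`` and ``token_stride`` are
    engineering defaults, all exposed here.
    """

    n_stages: int = 3
    base_channels: int = 16
    n_heads: int = 4
    mlp_ratio: float = 2.0
    token_stride: int = 2
    embed_dim: int = 32
    max_tokens_per_axis: int | None = 8
    transformer_branch_enabled: bool = True
    conv_branch_enabled: bool = True
    positional_embedding: bool = False
    pos_embed_grid: tuple[int, int, int] | None = None
    final_activation: str = "none"  # {"none", "clamp01"}

    def __post_init__(self):
        if self.n_stages < 1:
            raise ConfigError("n_stages must be >= 1")
        if self.base_channels < 2:
            raise ConfigError("base_channels must be >= 2")
        if not (self.transformer_branch_enabled or self.conv_branch_enabled):
            raise ConfigError("at least one encoder branch must be enabled")
        if self.token_stride < 1:
            raise ConfigError("token_stride must be >= 1")
        if self.embed_dim % self.n_heads != 0:
            raise ConfigError(
                f"embed_dim {self.embed_dim} not divisible by n_heads {self.n_heads}")
        if self.final_activation not in ("none", "clamp01"):
            raise ConfigError(f"unknown final_activation {self.final_activation!r}")
        if self.positional_embedding and self.pos_embed_grid is None:
            raise ConfigError("positional_embedding requires pos_embed_grid")

    def stage_width(self, i: int) -> int:
        return self.base_channels * 2 ** (i + 1)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["pos_embed_grid"] is not None:
            d["pos_embed_grid"] = list(d["pos_embed_grid"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "UITransConfig":
        d = dict(d)
        if d.get("pos_embed_grid") is not None:
            d["pos_embed_grid"] = tuple(d["pos_embed_grid"])
        return cls(**d)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def small(cls, **overrides) -> "UITransConfig":
        """Desk-scale preset used throughout the test/benchmark suite."""
        defaults = dict(base_channels=8, embed_dim=16, token_stride=4)
        defaults.update(overrides)
        return cls(**defaults)


# -- token layout helpers -----------------------------------------------------


def space_to_channel(x: Tensor, s: int) -> Tensor:
    """(N,C,D,H,W) -> (N, C*s^3, D/s, H/s, W/s) by interleaved sub-sampling."""
    N, C, D, H, W = x.shape
    x = ag.reshape(x, (N, C, D // s, s, H // s, s, W // s, s))
    x = ag.transpose(x, (0, 1, 3, 5, 7, 2, 4, 6))
    return ag.reshape(x, (N, C * s ** 3, D // s, H // s, W // s))


def channel_to_space(x: Tensor, s: int, out_ch: int) -> Tensor:
    """Inverse of :func:`space_to_channel`."""
    N, Cs3, d, h, w = x.shape
    x = ag.reshape(x, (N, out_ch, s, s, s, d, h, w))
    x = ag.transpose(x, (0, 1, 5, 2, 6, 3, 7, 4))
    return ag.reshape(x, (N, out_ch, d * s, h * s, w * s))


def _pool_tokens(t: Tensor, grid: tuple[int, int, int], c: int) -> Tensor:
    """Average-pool a (N,T,E) token sequence over its 3D grid by factor c."""
    N, T, E = t.shape
    gd, gh, gw = grid
    t = ag.reshape(t, (N, gd // c, c, gh // c, c, gw // c, c, E))
    t = ag.mean(t, axis=(2, 4, 6))
    return ag.reshape(t, (N, (gd // c) * (gh // c) * (gw // c), E))


# -- modules ------------------------------------------------------------------


class DoubleConv(Module):
    """Two 3x3x3 convolutions with LeakyReLU activations."""

    def __init__(self, rng, in_ch: int, out_ch: int):
        self.conv1 = Conv3d(rng, in_ch, out_ch, kernel=3)
        self.conv2 = Conv3d(rng, out_ch, out_ch, kernel=3)

    def forward(self, x: Tensor) -> Tensor:
        x = ag.leaky_relu(self.conv1(x))
        return ag.leaky_relu(self.conv2(x))


class Downsample(Module):
    """Stride-2 convolution halving each spatial dimension."""

    def __init__(self, rng, ch: int):
        self.conv = Conv3d(rng, ch, ch, kernel=2, stride=2, padding=0)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x)


class MSAModule(Module):
    """Interval-extraction embedding -> LN -> attention -> LN -> MLP,
    with two residual connections, reassembled to the input spatial size.
    """

    def __init__(self, rng, in_ch: int, out_ch: int, config: UITransConfig):
        s = config.token_stride
        E = config.embed_dim
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.stride = s
        self.max_tokens = config.max_tokens_per_axis
        self.embed = Linear(rng, in_ch * s ** 3, E)
        self.norm1 = LayerNorm(E)
        self.attn = MultiheadSelfAttention(rng, E, config.n_heads)
        self.norm2 = LayerNorm(E)
        self.mlp = MLP(rng, E, int(round(E * config.mlp_ratio)))
        self.unembed = Linear(rng, E, out_ch * s ** 3)
        self.pos_embed = None
        if config.positional_embedding:
            g = config.pos_embed_grid
            self.pos_embed = Parameter(
                np.zeros((1, g[0] * g[1] * g[2], E), dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        N, C, D, H, W = x.shape
        s = self.stride
        if any(dim % s for dim in (D, H, W)):
            raise ShapeError(
                f"spatial dims {(D, H, W)} must be divisible by token stride {s}")
        grid = (D // s, H // s, W // s)
        tok = space_to_channel(x, s)
        tok = ag.reshape(tok, (N, C * s ** 3, grid[0] * grid[1] * grid[2]))
        tok = ag.transpose(tok, (0, 2, 1))
        t = self.embed(tok)  # (N, T, E)
        if self.pos_embed is not None:
            if t.shape[1] != self.pos_embed.shape[1]:
                raise ShapeError(
                    f"token count {t.shape[1]} does not match positional "
                    f"embedding grid ({self.pos_embed.shape[1]} tokens)")
            t = t + self.pos_embed
        normed = self.norm1(t)
        kv = normed
        if self.max_tokens is not None:
            c = 1
            g = list(grid)
            while (max(g) > self.max_tokens
                   and all(v % 2 == 0 for v in g)):
                c *= 2
                g = [v // 2 for v in g]
            if c > 1:
                kv = _pool_tokens(normed, grid, c)
        t = t + self.attn(normed, kv)
        t = t + self.mlp(self.norm2(t))
        out = self.unembed(t)  # (N, T, out_ch*s^3)
        out = ag.transpose(out, (0, 2, 1))
        out = ag.reshape(out, (N, self.out_ch * s ** 3, *grid))
        return channel_to_space(out, s, self.out_ch)


class TransformerBlock(Module):
    """Two parallel MSA modules whose outputs are concatenated along
    channels, doubling (in dual-branch mode matching) the conv branch width.
    """

    def __init__(self, rng, in_ch: int, out_ch: int, config: UITransConfig):
        if out_ch % 2 != 0:
            raise ConfigError(
                f"transformer block output channels must be even, got {out_ch}")
        self.msa1 = MSAModule(rng, in_ch, out_ch // 2, config)
        self.msa2 = MSAModule(rng, in_ch, out_ch // 2, config)
        self.single_msa = False  # debug: drop msa2, halving output channels

    def forward(self, x: Tensor) -> Tensor:
        a = self.msa1(x)
        if self.single_msa:
            return a
        return ag.concat([a, self.msa2(x)], axis=1)


class EncoderStage(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, config: UITransConfig):
        dual = config.conv_branch_enabled and config.transformer_branch_enabled
        branch_ch = out_ch // 2 if dual else out_ch
        self.conv_branch = None
        self.conv_down = None
        self.tr_branch = None
        self.tr_down = None
        if config.conv_branch_enabled:
            self.conv_branch = DoubleConv(rng, in_ch, branch_ch)
            self.conv_down = Downsample(rng, branch_ch)
        if config.transformer_branch_enabled:
            self.tr_branch = TransformerBlock(rng, in_ch, branch_ch, config)
            self.tr_down = Downsample(rng, branch_ch)

    def forward(self, x: Tensor) -> Tensor:
        outs = []
        if self.tr_branch is not None:
            outs.append(self.tr_down(self.tr_branch(x)))
        if self.conv_branch is not None:
            outs.append(self.conv_down(self.conv_branch(x)))
        return outs[0] if len(outs) == 1 else ag.concat(outs, axis=1)


class UpStage(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, skip_ch: int):
        self.up_conv = Conv3d(rng, in_ch, out_ch, kernel=3)
        self.block = DoubleConv(rng, out_ch + skip_ch, out_ch)
        self.skip_ch = skip_ch

    def forward(self, x: Tensor, skip: Tensor | None) -> Tensor:
        x = self.up_conv(ag.upsample2x(x))
        if skip is not None:
            x = ag.concat([x, skip], axis=1)
        return self.block(x)


class UITransNet(Module):
    """Volume-to-volume restoration network (see module docstring)."""

    def __init__(self, config: UITransConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        n = config.n_stages
        widths = [config.stage_width(i) for i in range(n)]
        self.stages = []
        in_ch = 1
        for i in range(n):
            self.stages.append(EncoderStage(rng, in_ch, widths[i], config))
            in_ch = widths[i]
        self.bottleneck = DoubleConv(rng, widths[-1], widths[-1])
        self.up_stages = []
        ch = widths[-1]
        for j in range(n - 1, 0, -1):
            self.up_stages.append(UpStage(rng, ch, widths[j - 1], widths[j - 1]))
            ch = widths[j - 1]
        self.top = UpStage(rng, ch, config.base_channels, 0)
        self.final = Conv3d(rng, config.base_channels, 1, kernel=1, padding=0)

    # -- shape checks --------------------------------------------------------

    def _check_shape(self, shape):
        req = 2 ** self.config.n_stages
        if any(dim % req for dim in shape):
            raise ShapeError(
                f"spatial dims {tuple(shape)} must each be divisible by "
                f"2**n_stages = {req}")

    @staticmethod
    def _as_input(volume) -> Tensor:
        if isinstance(volume, Tensor):
            return volume
        arr = np.asarray(volume, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[None, None]
        elif arr.ndim == 4:
            arr = arr[:, None]
        elif arr.ndim != 5:
            raise ShapeError(f"expected 3D/4D/5D input, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("network input contains non-finite values")
        return Tensor(arr)

    # -- forward -------------------------------------------------------------

    def encoder_forward(self, volume) -> tuple[list[Tensor], Tensor]:
        """Run the encoder; returns (per-stage skip maps, bottleneck)."""
        x = self._as_input(volume)
        self._check_shape(x.shape[2:])
        skips = []
        for stage in self.stages:
            x = stage(x)
            skips.append(x)
        return skips, self.bottleneck(x)

    def forward(self, volume) -> Tensor:
        skips, x = self.encoder_forward(volume)
        for j, up in enumerate(self.up_stages):
            x = up(x, skips[len(self.stages) - 2 - j])
        x = self.top(x, None)
        return self.final(x)

    def restore(self, values: np.ndarray) -> np.ndarray:
        """Inference on a (D,H,W) array; applies final_activation."""
        with ag.no_grad():
            out = self.forward(values).data[0, 0]
        if self.config.final_activation == "clamp01":
            out = np.clip(out, 0.0, 1.0)
        return out

    # -- persistence ---------------------------------------------------------

    def save(self, path: str | Path, extra: dict | None = None):
        """Single-archive checkpoint: parameters + config + seed + hash."""
        meta = {"config": self.config.to_dict(), "seed": self.seed,
                "config_hash": self.config.hash(), "extra": extra or {}}
        arrays = {f"param_{i:04d}": p.data for i, p in enumerate(self.parameters())}
        np.savez(Path(path), meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "UITransNet":
        with np.load(Path(path), allow_pickle=False) as archive:
            meta = json.loads(str(archive["meta"]))
            config = UITransConfig.from_dict(meta["config"])
            if config.hash() != meta["config_hash"]:
                raise ValueError("checkpoint config hash mismatch")
            net = cls(config, seed=meta["seed"])
            keys = sorted(k for k in archive.files if k.startswith("param_"))
            net.load_state_arrays([archive[k] for k in keys])
        return net

    @classmethod
    def load_extra(cls, path: str | Path) -> dict:
        with np.load(Path(path), allow_pickle=False) as archive:
            return json.loads(str(archive["meta"]))["extra"]


def build_model(config: UITransConfig, seed: int = 0) -> UITransNet:
    """Build a seeded UI-Trans network (deterministic initialization)."""
    return UITransNet(config, seed)
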