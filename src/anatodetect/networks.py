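"""Encoders, feature pyramid and detection heads.

Two interchangeable encoders emit a four-level :class:`FeaturePyramid` at
strides 2/4/8/16 relative to the input:

* a CNN U-Net-style encoder (strided convolutions + instance norm), and
* a hierarchical windowed-attention (Swin-style) encoder whose stage widths
  are C, 2C, 4C, 8C.

The FPN merges the pyramid top-down with lateral 1x1 connections.  Detection
heads (anchor classification and box regression) attach to the stride-4/8/16
levels; the highest-resolution (stride-2) level feeds an auxiliary
segmentation head, mirroring the Retina U-Net layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

PYRAMID_STRIDES = (2, 4, 8, 16)


@dataclass(frozen=True)
class SwinEncoderConfig:
    """Hierarchical windowed-attention encoder (Swin-T defaults)."""

    depths: tuple[int, int, int, int] = (2, 2, 6, 2)
    embed_dim: int = 96
    window: int = 4
    heads: tuple[int, int, int, int] = (3, 6, 12, 24)
    in_channels: int = 2
    mlp_ratio: float = 4.0

    def __post_init__(self):
        if len(self.depths) != 4 or len(self.heads) != 4:
            raise ValueError("four stages required: len(depths) == len(heads) == 4")
        for i, h in enumerate(self.heads):
            if (self.embed_dim * 2**i) % h:
                raise ValueError(f"stage {i} width {self.embed_dim * 2**i} "
                                 f"not divisible by {h} heads")

    @property
    def widths(self) -> tuple[int, int, int, int]:
        c = self.embed_dim
        return (c, 2 * c, 4 * c, 8 * c)


def desk_swin_config(in_channels: int = 2) -> SwinEncoderConfig:
    """Shrunk encoder for CPU-scale experiments (full-scale values documented
    as the defaults of :class:`SwinEncoderConfig`)."""
    return SwinEncoderConfig(depths=(1, 1, 1, 1), embed_dim=24, window=2,
                             heads=(2, 4, 8, 8), in_channels=in_channels)


@dataclass(frozen=True)
class CNNEncoderConfig:
    in_channels: int = 2
    widths: tuple[int, int, int, int] = (32, 64, 128, 256)

    def __post_init__(self):
        if len(self.widths) != 4:
            raise ValueError("four stage widths required")


def desk_cnn_config(in_channels: int = 2) -> CNNEncoderConfig:
    return CNNEncoderConfig(in_channels=in_channels, widths=(8, 16, 32, 64))


@dataclass
class FeaturePyramid:
    """Ordered multi-scale features S1..S4 at strides 2, 4, 8, 16."""

    levels: list[Tensor]
    strides: tuple[int, ...] = PYRAMID_STRIDES

    def __post_init__(self):
        if len(self.levels) != len(self.strides):
            raise ValueError("one feature map per stride required")

    @property
    def widths(self) -> tuple[int, ...]:
        return tuple(l.shape[1] for l in self.levels)


def _check_divisible(shape, stride: int) -> None:
    if any(s % stride for s in shape):
        raise ValueError(f"spatial shape {tuple(shape)} not divisible by "
                         f"the maximum stride {stride}")


# ---------------------------------------------------------------------------
# CNN encoder
# ---------------------------------------------------------------------------


class _ConvBlock(nn.Module):
    def __init__(self, cin, cout, kernel, stride, padding, rng):
        self.conv = nn.Conv3d(cin, cout, kernel, stride, padding, rng=rng)
        self.norm = nn.InstanceNorm3d(cout)

    def forward(self, x):
        return self.norm(self.conv(x)).relu()


class CNNEncoder(nn.Module):
    """U-Net-style convolutional encoder emitting strides 2/4/8/16."""

    def __init__(self, cfg: CNNEncoderConfig, rng=0):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self.cfg = cfg
        self.stem = _ConvBlock(cfg.in_channels, cfg.widths[0], 3, 1, 1, rng)
        self.down = []
        self.blocks = []
        prev = cfg.widths[0]
        for w in cfg.widths:
            self.down.append(_ConvBlock(prev, w, 2, 2, 0, rng))
            self.blocks.append(_ConvBlock(w, w, 3, 1, 1, rng))
            prev = w

    def forward(self, x: Tensor) -> FeaturePyramid:
        _check_divisible(x.shape[2:], PYRAMID_STRIDES[-1])
        x = self.stem(x)
        levels = []
        for down, block in zip(self.down, self.blocks):
            x = block(down(x))
            levels.append(x)
        return FeaturePyramid(levels)


# ---------------------------------------------------------------------------
# windowed-attention encoder
# ---------------------------------------------------------------------------


def _window_partition(x: Tensor, w: int) -> tuple[Tensor, tuple[int, int, int, int]]:
    """(B, D, H, W, C) -> (B*nW, w^3, C); caller guarantees divisibility."""
    b, d, h, wd, c = x.shape
    x = x.reshape(b, d // w, w, h // w, w, wd // w, w, c)
    x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7)
    nw = (d // w) * (h // w) * (wd // w)
    return x.reshape(b * nw, w**3, c), (b, d, h, wd)


def _window_merge(x: Tensor, w: int, dims) -> Tensor:
    b, d, h, wd = dims
    c = x.shape[-1]
    x = x.reshape(b, d // w, h // w, wd // w, w, w, w, c)
    x = x.transpose(0, 1, 4, 2, 5, 3, 6, 7)
    return x.reshape(b, d, h, wd, c)


def _shift_attn_mask(dims, w: int, shift: int, dtype=np.float32) -> np.ndarray:
    """Additive (nW, T, T) mask blocking cross-region attention after a
    cyclic shift, as in shifted-window attention."""
    d, h, wd = dims
    img = np.zeros((d, h, wd), dtype=np.int32)
    cnt = 0
    segs = (slice(0, -w), slice(-w, -shift), slice(-shift, None))
    for sz in segs:
        for sy in segs:
            for sx in segs:
                img[sz, sy, sx] = cnt
                cnt += 1
    win = img.reshape(d // w, w, h // w, w, wd // w, w)
    win = win.transpose(0, 2, 4, 1, 3, 5).reshape(-1, w**3)
    diff = win[:, :, None] - win[:, None, :]
    return np.where(diff == 0, 0.0, -1e4).astype(dtype)


class WindowAttention(nn.Module):
    def __init__(self, dim: int, heads: int, rng=0):
        self.heads = heads
        self.scale = (dim // heads) ** -0.5
        self.qkv = nn.Linear(dim, 3 * dim, rng=rng, scale=0.02)
        self.proj = nn.Linear(dim, dim, rng=rng, scale=0.02)

    def forward(self, x: Tensor, mask: np.ndarray | None = None) -> Tensor:
        bnw, t, c = x.shape
        h = self.heads
        hd = c // h
        qkv = self.qkv(x).reshape(bnw, t, 3, h, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (BnW, h, T, hd)
        attn = (q @ k.transpose(0, 1, 3, 2)) * self.scale
        if mask is not None:
            nw = mask.shape[0]
            attn = attn.reshape(bnw // nw, nw, h, t, t) + Tensor(mask[None, :, None])
            attn = attn.reshape(bnw, h, t, t)
        attn = attn.softmax(axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(bnw, t, c)
        return self.proj(out)


class SwinBlock(nn.Module):
    def __init__(self, dim: int, heads: int, window: int, shift: int, rng=0):
        self.window = window
        self.shift = shift
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, rng=rng)
        self.norm2 = nn.LayerNorm(dim)
        hidden = int(dim * 4)
        self.fc1 = nn.Linear(dim, hidden, rng=rng, scale=0.02)
        self.fc2 = nn.Linear(hidden, dim, rng=rng, scale=0.02)

    def _attend(self, x: Tensor) -> Tensor:
        w = self.window
        b, d, h, wd, c = x.shape
        pads = [(0, (-s) % w) for s in (d, h, wd)]
        padded = any(r for _, r in pads)
        if padded:
            x = nn.pad(x, [(0, 0)] + pads + [(0, 0)])
        dims = x.shape[1:4]
        shift = self.shift if min(dims) > w else 0
        mask = None
        if shift:
            x = x.roll([-shift] * 3, axis=(1, 2, 3))
            mask = _shift_attn_mask(dims, w, shift)
        wins, meta = _window_partition(x, w)
        wins = self.attn(wins, mask)
        x = _window_merge(wins, w, meta)
        if shift:
            x = x.roll([shift] * 3, axis=(1, 2, 3))
        if padded:
            x = x[:, :d, :h, :wd, :]
        return x

    def forward(self, x: Tensor) -> Tensor:
        x = x + self._attend(self.norm1(x))
        y = self.fc2(self.fc1(self.norm2(x)).gelu())
        return x + y


class PatchMerging(nn.Module):
    """Concatenate 2x2x2 neighbourhoods and project 8C -> 2C."""

    def __init__(self, dim: int, rng=0):
        self.norm = nn.LayerNorm(8 * dim)
        self.reduce = nn.Linear(8 * dim, 2 * dim, bias=False, rng=rng, scale=0.02)

    def forward(self, x: Tensor) -> Tensor:
        b, d, h, w, c = x.shape
        if d % 2 or h % 2 or w % 2:
            raise ValueError(f"token grid {(d, h, w)} must be even for merging")
        x = x.reshape(b, d // 2, 2, h // 2, 2, w // 2, 2, c)
        x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7).reshape(b, d // 2, h // 2, w // 2, 8 * c)
        return self.reduce(self.norm(x))


class SwinEncoder(nn.Module):
    """Four-stage hierarchical windowed-attention encoder.

    Stage i operates at stride 2^(i+1) with width C * 2^i; blocks alternate
    plain and shifted windows.
    """

    def __init__(self, cfg: SwinEncoderConfig, rng=0):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self.cfg = cfg
        c = cfg.embed_dim
        self.patch_embed = nn.Conv3d(cfg.in_channels, c, 2, stride=2, rng=rng)
        self.embed_norm = nn.LayerNorm(c)
        self.stages = []
        self.merges = []
        for i, (depth, heads) in enumerate(zip(cfg.depths, cfg.heads)):
            dim = c * 2**i
            blocks = [SwinBlock(dim, heads, cfg.window,
                                shift=0 if b % 2 == 0 else cfg.window // 2, rng=rng)
                      for b in range(depth)]
            self.stages.append(nn.Sequential(*blocks))
            if i < 3:
                self.merges.append(PatchMerging(dim, rng=rng))

    def forward(self, x: Tensor) -> FeaturePyramid:
        _check_divisible(x.shape[2:], PYRAMID_STRIDES[-1])
        x = self.patch_embed(x)  # (B, C, D/2, H/2, W/2)
        x = self.embed_norm(x.transpose(0, 2, 3, 4, 1))  # tokens (B,D,H,W,C)
        levels = []
        for i, stage in enumerate(self.stages):
            x = stage(x)
            levels.append(x.transpose(0, 4, 1, 2, 3))
            if i < 3:
                x = self.merges[i](x)
        return FeaturePyramid(levels)


def build_encoder(kind: str, cfg=None, in_channels: int | None = None, rng=0):
    """Build a pyramid encoder: ``kind`` is ``"cnn_unet"`` or ``"swin"``."""
    if kind in ("cnn", "cnn_unet"):
        cfg = cfg or CNNEncoderConfig()
        if in_channels is not None and cfg.in_channels != in_channels:
            cfg = CNNEncoderConfig(in_channels=in_channels, widths=cfg.widths)
        return CNNEncoder(cfg, rng=rng)
    if kind == "swin":
        cfg = cfg or SwinEncoderConfig()
        if in_channels is not None and cfg.in_channels != in_channels:
            cfg = SwinEncoderConfig(cfg.depths, cfg.embed_dim, cfg.window,
                                    cfg.heads, in_channels, cfg.mlp_ratio)
        return SwinEncoder(cfg, rng=rng)
    raise ValueError(f"unknown encoder kind {kind!r}; use 'cnn_unet' or 'swin'")


# ---------------------------------------------------------------------------
# FPN and heads
# ---------------------------------------------------------------------------


class FPN(nn.Module):
    """Top-down pathway with lateral 1x1 connections, uniform output width."""

    def __init__(self, in_widths, out_width: int = 32, rng=0):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self.laterals = [nn.Conv3d(w, out_width, 1, rng=rng) for w in in_widths]
        # 3x3 smoothing on detection levels; 1x1 on the stride-2 level keeps
        # the high-resolution path cheap (it only feeds segmentation)
        self.outputs = [nn.Conv3d(out_width, out_width, 1, rng=rng)] + \
                       [nn.Conv3d(out_width, out_width, 3, padding=1, rng=rng)
                        for _ in in_widths[1:]]
        # instance norm keeps FPN feature magnitudes bounded during training
        self.norms = [nn.InstanceNorm3d(out_width) for _ in in_widths]
        self.out_width = out_width

    def forward(self, pyramid: FeaturePyramid) -> FeaturePyramid:
        if len(pyramid.levels) != len(self.laterals):
            raise ValueError(f"expected {len(self.laterals)} levels, got "
                             f"{len(pyramid.levels)}")
        laterals = [lat(lvl) for lat, lvl in zip(self.laterals, pyramid.levels)]
        merged = [None] * len(laterals)
        merged[-1] = laterals[-1]
        for i in range(len(laterals) - 2, -1, -1):
            merged[i] = laterals[i] + nn.upsample_nearest3d(merged[i + 1], 2)
        refined = [norm(out(m)) for norm, out, m
                   in zip(self.norms, self.outputs, merged)]
        return FeaturePyramid(refined, pyramid.strides)


class ConvHead(nn.Module):
    """Small shared head applied to every detection level."""

    def __init__(self, width: int, out_channels: int, rng=0, bias_init: float = 0.0):
        self.conv = nn.Conv3d(width, width, 3, padding=1, rng=rng)
        self.norm = nn.InstanceNorm3d(width)
        self.out = nn.Conv3d(width, out_channels, 1, rng=rng)
        # zero-init the projection: regression starts at the anchor itself,
        # classification at its prior bias
        self.out.weight.data[:] = 0.0
        if bias_init:
            self.out.bias.data[:] = bias_init

    def forward(self, x: Tensor) -> Tensor:
        return self.out(self.norm(self.conv(x)).relu())


class SegHead(nn.Module):
    def __init__(self, width: int, rng=0):
        self.conv = nn.Conv3d(width, max(width // 2, 4), 1, rng=rng)
        self.out = nn.Conv3d(max(width // 2, 4), 1, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.out(self.conv(x).relu())
        return nn.upsample_nearest3d(y, 2)  # stride-2 level back to input res


class DetectionNetwork(nn.Module):
    """Retina-U-Net-style detector: encoder -> FPN -> heads.

    Heads attach to the stride-4/8/16 FPN levels; the stride-2 level drives
    the auxiliary segmentation head.
    """

    def __init__(self, encoder, fpn_width: int = 32, anchors_per_loc: int = 1,
                 rng=0):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self.encoder = encoder
        widths = encoder.cfg.widths
        self.fpn = FPN(widths, fpn_width, rng=rng)
        # negative prior bias keeps early anchor probabilities low (focal-loss
        # style initialisation under extreme anchor imbalance)
        self.cls_head = ConvHead(fpn_width, anchors_per_loc, rng=rng, bias_init=-2.0)
        self.reg_head = ConvHead(fpn_width, 6 * anchors_per_loc, rng=rng)
        self.seg_head = SegHead(fpn_width, rng=rng)
        self.anchors_per_loc = anchors_per_loc

    def forward(self, x: Tensor) -> dict:
        pyr = self.fpn(self.encoder(x))
        seg_logit = self.seg_head(pyr.levels[0])
        cls_logits = [self.cls_head(l) for l in pyr.levels[1:]]
        reg_out = [self.reg_head(l) for l in pyr.levels[1:]]
        return {"cls": cls_logits, "reg": reg_out, "seg": seg_logit,
                "pyramid": pyr}
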