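"""Self-supervised pretraining: corruption transforms, losses, autoencoder.

The pretext task reconstructs corrupted PET/CT patches.  Each randomly
cropped patch is duplicated and the two copies are independently corrupted by
coarse dropout (rectangular regions replaced with random values in [0, 0.2],
or the inverted variant where the regions are retained and the remainder is
filled) followed by per-channel pixel shuffling inside random regions.  The
training objective combines a mean-absolute reconstruction loss with an
NT-Xent contrastive term over pooled bottleneck features, the contrastive
term being scaled by the reconstruction loss:

    L_total = L_rec + L_con * L_rec
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .nn import Tensor
from .networks import SwinEncoderConfig, SwinEncoder
from .phantom import CaseRecord, split_cohort

__all__ = [
    "CorruptionConfig", "SSLTrainConfig", "SSLLossTerms",
    "coarse_dropout", "pixel_shuffle", "make_view_pair",
    "reconstruction_loss", "contrastive_loss", "ssl_total_loss",
    "SSLAutoencoder", "build_ssl_autoencoder", "pretrain",
    "normalize_channels", "desk_ssl_train_config",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorruptionConfig:
    n_dropout_regions: int = 3
    dropout_size_range: tuple[int, int] = (4, 12)    # per-axis extents, voxels
    dropout_value_range: tuple[float, float] = (0.0, 0.2)
    invert_probability: float = 0.5
    n_shuffle_regions: int = 3
    shuffle_size_range: tuple[int, int] = (4, 12)

    def __post_init__(self):
        lo, hi = self.dropout_value_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("dropout_value_range must lie within [0, 1]")


@dataclass(frozen=True)
class SSLTrainConfig:
    """Adam/fixed-lr pretraining schedule.

    Full-scale defaults: 500 epochs, lr 1e-4, 96^3 patches, batch size 2.
    """

    epochs: int = 500
    learning_rate: float = 1e-4
    patch_size: int = 96
    batch_size: int = 2
    patches_per_case: int = 4
    val_fraction: float = 0.2
    temperature: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.patch_size, self.batch_size,
               self.patches_per_case) <= 0 or self.learning_rate <= 0:
            raise ValueError("all SSL training parameters must be positive")


def desk_ssl_train_config(**overrides) -> SSLTrainConfig:
    base = dict(epochs=5, patch_size=32, batch_size=2, patches_per_case=4)
    base.update(overrides)
    return SSLTrainConfig(**base)


@dataclass(frozen=True)
class SSLLossTerms:
    l_rec: float
    l_con: float
    temperature: float = 0.05

    @property
    def l_total(self) -> float:
        return ssl_total_loss(self.l_rec, self.l_con)


# ---------------------------------------------------------------------------
# corruptions
# ---------------------------------------------------------------------------


def _draw_regions(shape, n: int, size_range, rng) -> np.ndarray:
    """Union mask of n random rectangular regions over spatial dims."""
    mask = np.zeros(shape, dtype=bool)
    lo, hi = size_range
    if lo > min(shape):
        raise ValueError(f"region size {lo} exceeds patch extent {min(shape)}")
    for _ in range(n):
        ext = [int(rng.integers(lo, min(hi, s) + 1)) for s in shape]
        orig = [int(rng.integers(0, s - e + 1)) for s, e in zip(shape, ext)]
        sl = tuple(slice(o, o + e) for o, e in zip(orig, ext))
        mask[sl] = True
    return mask


def coarse_dropout(patch: np.ndarray, cfg: CorruptionConfig, seed: int) -> np.ndarray:
    """Region value replacement.

    Standard variant: voxels inside the drawn regions are replaced with
    per-voxel random values from ``dropout_value_range``; everything outside
    is untouched.  Inverted variant (probability ``invert_probability``):
    region voxels are retained and the remainder is filled.  Region geometry
    is shared across channels.
    """
    patch = np.asarray(patch, dtype=np.float32)
    out = patch.copy()
    if cfg.n_dropout_regions <= 0:
        return out
    rng = np.random.default_rng(seed)
    spatial = patch.shape[1:]
    region = _draw_regions(spatial, cfg.n_dropout_regions,
                           cfg.dropout_size_range, rng)
    inverted = rng.random() < cfg.invert_probability
    fill_mask = ~region if inverted else region
    n_fill = int(fill_mask.sum())
    for c in range(patch.shape[0]):
        out[c][fill_mask] = rng.uniform(*cfg.dropout_value_range, size=n_fill)
    return out


def pixel_shuffle(patch: np.ndarray, cfg: CorruptionConfig, seed: int) -> np.ndarray:
    """Shuffle voxel values inside random regions, independently per channel."""
    patch = np.asarray(patch, dtype=np.float32)
    out = patch.copy()
    if cfg.n_shuffle_regions <= 0:
        return out
    rng = np.random.default_rng(seed)
    spatial = patch.shape[1:]
    lo, hi = cfg.shuffle_size_range
    if lo > min(spatial):
        raise ValueError(f"region size {lo} exceeds patch extent {min(spatial)}")
    for _ in range(cfg.n_shuffle_regions):
        ext = [int(rng.integers(lo, min(hi, s) + 1)) for s in spatial]
        orig = [int(rng.integers(0, s - e + 1)) for s, e in zip(spatial, ext)]
        sl = (slice(None),) + tuple(slice(o, o + e) for o, e in zip(orig, ext))
        block = out[sl]
        flat = block.reshape(block.shape[0], -1)
        for c in range(flat.shape[0]):
            flat[c] = flat[c][rng.permutation(flat.shape[1])]
        out[sl] = flat.reshape(block.shape)
    return out


def make_view_pair(patch: np.ndarray, cfg: CorruptionConfig, seed: int):
    """Duplicate a patch and corrupt each copy independently.

    Returns (view_a, view_b, target); the uncorrupted original is the
    reconstruction target for both views.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=4)
    view_a = pixel_shuffle(coarse_dropout(patch, cfg, int(seeds[0])), cfg, int(seeds[1]))
    view_b = pixel_shuffle(coarse_dropout(patch, cfg, int(seeds[2])), cfg, int(seeds[3]))
    return view_a, view_b, np.asarray(patch, dtype=np.float32).copy()


def normalize_channels(patch: np.ndarray) -> np.ndarray:
    """Per-channel min-max normalisation to [0, 1] (constant channels -> 0)."""
    patch = np.asarray(patch, dtype=np.float32)
    out = np.zeros_like(patch)
    for c in range(patch.shape[0]):
        lo, hi = float(patch[c].min()), float(patch[c].max())
        if hi > lo:
            out[c] = (patch[c] - lo) / (hi - lo)
    return out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def reconstruction_loss(pred, target) -> float:
    """Mean absolute (L1) reconstruction error."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return float(np.abs(pred - target).mean())


def _l1_t(pred: Tensor, target: Tensor) -> Tensor:
    diff = pred - target
    return diff.maximum(-diff).mean()


def _contrastive_t(feat_a: Tensor, feat_b: Tensor, temperature: float) -> Tensor:
    """NT-Xent over 2B views; positives are sibling views."""
    b = feat_a.shape[0]
    if b < 2:
        raise ValueError("contrastive loss needs batch size >= 2 (no negatives)")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    z = nn.concatenate([feat_a, feat_b], axis=0)  # (2B, F)
    norm = ((z * z).sum(axis=1, keepdims=True) + 1e-12).sqrt()
    z = z / norm
    sim = (z @ z.transpose(1, 0)) * (1.0 / temperature)
    sim = sim + Tensor(np.diag(np.full(2 * b, -1e9, dtype=np.float32)))
    logp = (sim.softmax(axis=-1) + 1e-12).log()
    idx = np.arange(2 * b)
    pos = np.concatenate([idx[b:], idx[:b]])
    return -logp[(idx, pos)].mean()


def contrastive_loss(features_a, features_b, temperature: float = 0.05) -> float:
    """Normalized-temperature cross-entropy between two batches of views.

    For each of the 2B feature vectors the positive is its sibling view and
    the other 2B - 2 vectors are negatives; features are unit-normalised
    internally.
    """
    with nn.no_grad():
        out = _contrastive_t(Tensor(np.asarray(features_a, dtype=np.float64)),
                             Tensor(np.asarray(features_b, dtype=np.float64)),
                             temperature)
    return float(out.item())


def ssl_total_loss(l_rec, l_con):
    """Combined pretraining loss: the contrastive term is scaled by the
    reconstruction error, so a perfect reconstruction zeroes the loss."""
    if isinstance(l_rec, Tensor) or isinstance(l_con, Tensor):
        return l_rec + l_con * l_rec
    if l_rec < 0:
        raise ValueError("reconstruction loss must be nonnegative")
    return float(l_rec + l_con * l_rec)


# ---------------------------------------------------------------------------
# autoencoder
# ---------------------------------------------------------------------------


class SSLAutoencoder(nn.Module):
    """Windowed-attention encoder + two transposed-conv upsampling layers.

    The encoder bottleneck sits at stride 16; two transposed convolutions
    with factor 4 each recover the input resolution.  The globally pooled
    bottleneck doubles as the contrastive feature (no projection head).
    """

    def __init__(self, enc_cfg: SwinEncoderConfig, rng=0):
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        self.encoder = SwinEncoder(enc_cfg, rng=rng)
        c_bottleneck = enc_cfg.widths[-1]
        mid = max(enc_cfg.embed_dim // 2, 8)
        self.up1 = nn.ConvTranspose3d(c_bottleneck, mid, 4, rng=rng)
        self.up2 = nn.ConvTranspose3d(mid, enc_cfg.in_channels, 4, rng=rng)

    def forward(self, x: Tensor):
        shape = x.shape[2:]
        if any(s % 16 for s in shape):
            raise ValueError(f"patch shape {tuple(shape)} must be divisible by 16 "
                             "(stride-16 bottleneck with x16 decoder)")
        pyr = self.encoder(x)
        bottleneck = pyr.levels[-1]                      # (N, 8C, s/16 ...)
        feat = bottleneck.mean(axis=(2, 3, 4))           # pooled contrastive feature
        recon = self.up2(self.up1(bottleneck).relu())
        return recon, feat


def build_ssl_autoencoder(enc_cfg: SwinEncoderConfig, seed: int = 0) -> SSLAutoencoder:
    return SSLAutoencoder(enc_cfg, rng=np.random.default_rng(seed))


# ---------------------------------------------------------------------------
# pretraining
# ---------------------------------------------------------------------------


def _case_channels(case: CaseRecord, use_organ_channel: bool) -> np.ndarray:
    chans = [normalize_channels(case.pet.data[None])[0],
             normalize_channels(case.ct.data[None])[0]]
    if use_organ_channel:
        max_label = max(case.organs.label_table, default=1)
        chans.append(case.organs.labels.astype(np.float32) / max_label)
    return np.stack(chans)


def _random_crop(volume: np.ndarray, size: int, rng) -> np.ndarray:
    _, d, h, w = volume.shape
    if min(d, h, w) < size:
        raise ValueError(f"volume {volume.shape[1:]} smaller than patch {size}")
    oz = int(rng.integers(0, d - size + 1))
    oy = int(rng.integers(0, h - size + 1))
    ox = int(rng.integers(0, w - size + 1))
    return volume[:, oz:oz + size, oy:oy + size, ox:ox + size]


def pretrain(cases: list[CaseRecord], enc_cfg: SwinEncoderConfig,
             ssl_cfg: SSLTrainConfig, corruption_cfg: CorruptionConfig | None = None,
             use_organ_channel: bool | None = None):
    """Run the corruption-reconstruction pretraining loop.

    Returns ``(model, history)`` where ``history`` is a DataFrame with one
    row per epoch (train L_rec, train L_con, validation L_rec), mirroring the
    loss panels typically logged for this task.
    """
    if len(cases) < 2:
        raise ValueError("pretraining needs at least 2 cases")
    corruption_cfg = corruption_cfg or CorruptionConfig(
        dropout_size_range=_scaled_region_range(ssl_cfg.patch_size),
        shuffle_size_range=_scaled_region_range(ssl_cfg.patch_size))
    if use_organ_channel is None:
        use_organ_channel = enc_cfg.in_channels == 3
    rng = np.random.default_rng(ssl_cfg.seed)

    patients = [c.patient_id for c in cases]
    train_pat, val_pat = split_cohort(patients, 1.0 - ssl_cfg.val_fraction,
                                      seed=ssl_cfg.seed)
    train_cases = [c for c in cases if c.patient_id in set(train_pat)]
    val_cases = [c for c in cases if c.patient_id in set(val_pat)] or train_cases[-1:]

    vols_train = [_case_channels(c, use_organ_channel) for c in train_cases]
    vols_val = [_case_channels(c, use_organ_channel) for c in val_cases]

    model = SSLAutoencoder(enc_cfg, rng=np.random.default_rng(ssl_cfg.seed))
    opt = nn.Adam(model.parameters(), lr=ssl_cfg.learning_rate)

    # fixed validation patches with fixed corruption seeds
    val_rng = np.random.default_rng(ssl_cfg.seed + 1)
    val_items = []
    for vol in vols_val:
        patch = _random_crop(vol, ssl_cfg.patch_size, val_rng)
        va, _, tgt = make_view_pair(patch, corruption_cfg,
                                    int(val_rng.integers(0, 2**31 - 1)))
        val_items.append((va, tgt))

    history = []
    for epoch in range(1, ssl_cfg.epochs + 1):
        patches = []
        for vol in vols_train:
            for _ in range(ssl_cfg.patches_per_case):
                patches.append(_random_crop(vol, ssl_cfg.patch_size, rng))
        rng.shuffle(patches)
        rec_log, con_log = [], []
        for start in range(0, len(patches) - ssl_cfg.batch_size + 1,
                           ssl_cfg.batch_size):
            batch = patches[start:start + ssl_cfg.batch_size]
            views_a, views_b, targets = [], [], []
            for p in batch:
                va, vb, tgt = make_view_pair(p, corruption_cfg,
                                             int(rng.integers(0, 2**31 - 1)))
                views_a.append(va)
                views_b.append(vb)
                targets.append(tgt)
            x = Tensor(np.stack(views_a + views_b))
            tgt = Tensor(np.stack(targets + targets))
            recon, feat = model(x)
            l_rec = _l1_t(recon, tgt)
            bsz = len(batch)
            l_con = _contrastive_t(feat[:bsz], feat[bsz:], ssl_cfg.temperature)
            total = ssl_total_loss(l_rec, l_con)
            model.zero_grad()
            total.backward()
            opt.step()
            rec_log.append(l_rec.item())
            con_log.append(l_con.item())
        with nn.no_grad():
            val_rec = []
            for va, tgt in val_items:
                recon, _ = model(Tensor(va[None]))
                val_rec.append(reconstruction_loss(recon.data[0], tgt))
        history.append({"epoch": epoch,
                        "train_l_rec": float(np.mean(rec_log)),
                        "train_l_con": float(np.mean(con_log)),
                        "val_l_rec": float(np.mean(val_rec))})
    return model, pd.DataFrame(history)


def _scaled_region_range(patch_size: int) -> tuple[int, int]:
    # corruption regions scaled to roughly 1/8 .. 1/3 of the patch extent
    return (max(patch_size // 8, 2), max(patch_size // 3, 3))
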