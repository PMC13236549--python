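"""Training-time augmentation for aligned PET/CT/organ/lesion samples.

Geometric transforms (mirror flips, small 3D rotations, elastic deformation,
scaling) are applied identically to the imaging channels, the organ map
(nearest-neighbour) and the lesion mask; ground-truth boxes are recomputed
from the transformed mask.  Intensity transforms (Gaussian noise, blur,
brightness, contrast, gamma) touch the PET/CT channels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .boxes import LesionBox3D, boxes_from_mask

__all__ = ["AugmentConfig", "Sample", "augment"]


@dataclass(frozen=True)
class AugmentConfig:
    """Per-transform application probabilities (defaults follow common 3D
    medical detection practice: noise 10%, blur 20%, brightness 15%)."""

    p_mirror: float = 0.5
    p_rotation: float = 0.0
    rotation_max_deg: float = 15.0
    p_elastic: float = 0.0
    elastic_sigma: float = 6.0
    elastic_magnitude: float = 3.0
    p_scaling: float = 0.0
    scaling_range: tuple[float, float] = (0.85, 1.25)
    p_noise: float = 0.10
    noise_sd: float = 0.03
    p_blur: float = 0.20
    blur_sigma_range: tuple[float, float] = (0.5, 1.0)
    p_brightness: float = 0.15
    brightness_range: tuple[float, float] = (0.75, 1.25)
    p_contrast: float = 0.0
    contrast_range: tuple[float, float] = (0.75, 1.25)
    p_gamma: float = 0.0
    gamma_range: tuple[float, float] = (0.7, 1.5)
    p_gamma_inverted: float = 0.0

    def __post_init__(self):
        for name, p in vars(self).items():
            if name.startswith("p_") and not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability, got {p}")


@dataclass
class Sample:
    """One aligned training sample: intensity channels + labels + boxes."""

    image: np.ndarray       # (C, D, H, W): PET, CT intensity channels
    organs: np.ndarray      # (D, H, W) integer labels
    lesion_mask: np.ndarray  # (D, H, W) binary
    boxes: list[LesionBox3D] = field(default_factory=list)


def _warp_all(sample: Sample, coords) -> Sample:
    image = np.stack([
        ndimage.map_coordinates(ch, coords, order=1, mode="nearest")
        for ch in sample.image]).astype(np.float32)
    organs = ndimage.map_coordinates(sample.organs, coords, order=0,
                                     mode="nearest")
    mask = ndimage.map_coordinates(sample.lesion_mask, coords, order=0,
                                   mode="nearest")
    return Sample(image, organs, mask, boxes_from_mask(mask))


def _identity_coords(shape):
    return np.stack(np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                                indexing="ij"))


def augment(sample: Sample, cfg: AugmentConfig, seed: int) -> Sample:
    """Apply the configured stochastic transforms; deterministic under seed."""
    rng = np.random.default_rng(seed)
    image = sample.image.astype(np.float32, copy=True)
    organs = sample.organs.copy()
    mask = sample.lesion_mask.copy()
    boxes = list(sample.boxes)
    shape = mask.shape
    out = Sample(image, organs, mask, boxes)

    # ---- geometric: mirror flips (axis-wise coin flips) --------------------
    if cfg.p_mirror > 0:
        for ax in range(3):
            if rng.random() < cfg.p_mirror:
                out.image = np.flip(out.image, axis=ax + 1).copy()
                out.organs = np.flip(out.organs, axis=ax).copy()
                out.lesion_mask = np.flip(out.lesion_mask, axis=ax).copy()
        out.boxes = boxes_from_mask(out.lesion_mask)

    # ---- geometric: resampling transforms ---------------------------------
    need_warp = False
    coords = None
    center = (np.array(shape) - 1) / 2.0

    if rng.random() < cfg.p_rotation:
        angles = rng.uniform(-cfg.rotation_max_deg, cfg.rotation_max_deg, 3)
        rot = np.eye(3)
        for ax, ang in enumerate(np.deg2rad(angles)):
            c, s = np.cos(ang), np.sin(ang)
            plane = [i for i in range(3) if i != ax]
            r = np.eye(3)
            r[plane[0], plane[0]] = c
            r[plane[0], plane[1]] = -s
            r[plane[1], plane[0]] = s
            r[plane[1], plane[1]] = c
            rot = rot @ r
        coords = _identity_coords(shape) if coords is None else coords
        rel = coords - center[:, None, None, None]
        coords = np.einsum("ij,jdhw->idhw", rot, rel) + center[:, None, None, None]
        need_warp = True

    if rng.random() < cfg.p_scaling:
        factor = rng.uniform(*cfg.scaling_range)
        coords = _identity_coords(shape) if coords is None else coords
        coords = (coords - center[:, None, None, None]) / factor \
            + center[:, None, None, None]
        need_warp = True

    if rng.random() < cfg.p_elastic:
        coords = _identity_coords(shape) if coords is None else coords
        disp = rng.normal(0.0, 1.0, size=(3, *shape))
        for i in range(3):
            disp[i] = ndimage.gaussian_filter(disp[i], cfg.elastic_sigma)
            m = np.abs(disp[i]).max()
            if m > 0:
                disp[i] *= cfg.elastic_magnitude / m
        coords = coords + disp
        need_warp = True

    if need_warp:
        out = _warp_all(out, coords)

    # ---- intensity (imaging channels only) ---------------------------------
    img = out.image
    if rng.random() < cfg.p_noise:
        img = img + rng.normal(0.0, cfg.noise_sd, size=img.shape).astype(np.float32)
    if rng.random() < cfg.p_blur:
        sigma = rng.uniform(*cfg.blur_sigma_range)
        img = np.stack([ndimage.gaussian_filter(ch, sigma) for ch in img])
    if rng.random() < cfg.p_brightness:
        img = img * rng.uniform(*cfg.brightness_range)
    if rng.random() < cfg.p_contrast:
        factor = rng.uniform(*cfg.contrast_range)
        mean = img.mean(axis=(1, 2, 3), keepdims=True)
        img = (img - mean) * factor + mean
    if rng.random() < cfg.p_gamma:
        gamma = rng.uniform(*cfg.gamma_range)
        if rng.random() < cfg.p_gamma_inverted:
            gamma = 1.0 / gamma
        lo = img.min(axis=(1, 2, 3), keepdims=True)
        hi = img.max(axis=(1, 2, 3), keepdims=True)
        span = np.where(hi > lo, hi - lo, 1.0)
        img = ((img - lo) / span) ** gamma * span + lo
    out.image = img.astype(np.float32)
    return out
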