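"""Intensity pretext transformations, rotation pretext, and augmentation.

The pretext label space has four classes: 0 = identity (no distortion),
1 = additive Gaussian noise, 2 = Gaussian blur, 3 = contrast enhancement.
Labels are generated automatically — a volume is distorted and tagged with
the class of the distortion — so the classification head can be trained on
completely unlabeled volumes from any domain.

Magnitudes are drawn per sample from the ranges in :class:`TransformParams`.
Contrast enhancement is realised as a saturating linear stretch about
mid-grey, ``v -> clip(0.5 + k*(v - 0.5))`` with ``k > 1``: its clipped,
end-saturated histogram is a signature that no smooth acquisition difference
(gamma, bias, noise) reproduces, which keeps the class identifiable across
domains whose own shifts involve gamma and noise.  Blur is anisotropic, with
the through-slice sigma half the in-plane sigma, matching the anisotropy of
the volumes.

Geometric train-time augmentation comes in two flavours: the segmentation
stream may also perturb brightness, while the pretext stream is strictly
geometric (flip/rotation) and is applied *before* the intensity distortion so
the pretext label is untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import gaussian_filter, rotate

from .phantom import DomainSample

__all__ = ["TransformParams", "PretextSample", "INTENSITY_CLASSES",
           "apply_intensity_transform", "sample_pretext",
           "apply_rotation_pretext", "augment_segmentation",
           "augment_pretext"]

INTENSITY_CLASSES = ("identity", "gaussian_noise", "gaussian_blur",
                     "contrast_enhancement")


@dataclass(frozen=True)
class TransformParams:
    """Magnitude ranges for the intensity transformation bank.

    ``noise_sigma_range`` is in units of the [0, 1] intensity range,
    ``blur_sigma_range`` in in-plane voxels, ``contrast_strength_range`` the
    slope k of the saturating stretch about mid-grey (k = 1 is identity).
    """

    noise_sigma_range: tuple[float, float] = (0.2, 0.3)
    blur_sigma_range: tuple[float, float] = (1.2, 2.2)
    contrast_strength_range: tuple[float, float] = (2.5, 3.5)
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("noise_sigma_range", "blur_sigma_range",
                     "contrast_strength_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi < np.inf):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi < inf")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TransformParams":
        d = dict(d)
        for k in ("noise_sigma_range", "blur_sigma_range",
                  "contrast_strength_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class PretextSample:
    """A transformed volume and the class id of the applied transformation."""

    volume: np.ndarray
    label: int
    domain_id: str

    def __post_init__(self):
        if not 0 <= self.label < len(INTENSITY_CLASSES):
            raise ValueError(f"label must be in [0, {len(INTENSITY_CLASSES)})")


def apply_intensity_transform(volume: np.ndarray, class_id: int,
                              params: TransformParams,
                              draw_seed: int) -> np.ndarray:
    """Apply one transformation class; deterministic given ``draw_seed``."""
    v = np.asarray(volume, dtype=np.float32)
    if class_id == 0:
        return v.copy()
    rng = np.random.default_rng(
        np.random.SeedSequence([params.rng_seed, int(draw_seed), class_id]))
    if class_id == 1:
        sigma = rng.uniform(*params.noise_sigma_range)
        out = v + rng.standard_normal(v.shape).astype(np.float32) * sigma
    elif class_id == 2:
        sigma = rng.uniform(*params.blur_sigma_range)
        out = gaussian_filter(v, sigma=(sigma, sigma, sigma / 2))
    elif class_id == 3:
        k = rng.uniform(*params.contrast_strength_range)
        out = 0.5 + k * (v - 0.5)
    else:
        raise ValueError(f"unknown intensity class id {class_id}")
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def sample_pretext(sample: DomainSample, params: TransformParams,
                   draw_seed: int) -> PretextSample:
    """Draw a class uniformly, apply it, return volume + auto-label."""
    rng = np.random.default_rng(
        np.random.SeedSequence([params.rng_seed, int(draw_seed), 97]))
    label = int(rng.integers(0, len(INTENSITY_CLASSES)))
    volume = apply_intensity_transform(sample.volume, label, params, draw_seed)
    return PretextSample(volume=volume, label=label, domain_id=sample.domain_id)


def apply_rotation_pretext(volume: np.ndarray, k: int) -> np.ndarray:
    """Rotate every axial slice by k*90 degrees (lossless index permutation)."""
    if k not in (0, 1, 2, 3):
        raise ValueError("k must be in {0, 1, 2, 3}")
    v = np.asarray(volume)
    if k % 2 == 1 and v.shape[0] != v.shape[1]:
        raise ValueError("odd quarter-turns require square in-plane dims")
    return np.rot90(v, k=k, axes=(0, 1)).copy()


def _rotate_pair(volume, mask, angle, order=1):
    vol = rotate(volume, angle, axes=(0, 1), reshape=False, order=order,
                 mode="constant", cval=float(np.median(volume)))
    if mask is None:
        return vol.astype(np.float32), None
    m = rotate(mask, angle, axes=(0, 1), reshape=False, order=0,
               mode="constant", cval=0)
    return vol.astype(np.float32), m.astype(mask.dtype)


def augment_segmentation(sample: DomainSample, draw_seed: int,
                         prob: float = 0.5,
                         max_angle: float = 30.0,
                         max_brightness: float = 0.15) -> DomainSample:
    """Random horizontal flip, in-plane rotation and brightness shift.

    Geometric parts act identically on volume (linear interpolation) and mask
    (nearest neighbour); brightness only touches the volume.  Each transform
    fires independently with probability ``prob``.
    """
    if sample.mask is None:
        raise ValueError("segmentation augmentation requires a mask")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(draw_seed), 29]))
    vol, mask = sample.volume, sample.mask
    if rng.uniform() < prob:  # horizontal flip: mirror columns
        vol, mask = vol[:, ::-1].copy(), mask[:, ::-1].copy()
    if rng.uniform() < prob:
        angle = rng.uniform(-max_angle, max_angle)
        vol, mask = _rotate_pair(vol, mask, angle)
    if rng.uniform() < prob:
        delta = rng.uniform(-max_brightness, max_brightness)
        vol = np.clip(vol + delta, 0.0, 1.0).astype(np.float32)
    return DomainSample(volume=np.ascontiguousarray(vol, dtype=np.float32),
                        mask=np.ascontiguousarray(mask),
                        domain_id=sample.domain_id, sample_id=sample.sample_id)


def augment_pretext(volume: np.ndarray, draw_seed: int,
                    prob: float = 0.5, max_angle: float = 30.0) -> np.ndarray:
    """Random vertical flip and in-plane rotation; runs before the pretext
    transform so the label is unaffected.  Rotation resamples by nearest
    neighbour: linear interpolation would smooth the image and masquerade as
    the blur class / hide the noise class."""
    rng = np.random.default_rng(
        np.random.SeedSequence([int(draw_seed), 31]))
    vol = np.asarray(volume, dtype=np.float32)
    if rng.uniform() < prob:  # vertical flip: mirror rows
        vol = vol[::-1].copy()
    if rng.uniform() < prob:
        angle = rng.uniform(-max_angle, max_angle)
        vol, _ = _rotate_pair(vol, None, angle, order=0)
    return np.ascontiguousarray(vol, dtype=np.float32)
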