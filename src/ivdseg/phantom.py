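"""Synthetic spine phantoms: domain-shifted volumes with ground-truth masks.

Each phantom is a stack of bright ellipsoidal "discs" spaced along a gently
curved vertical axis — a cartoon of a mid-sagittal lumbar T2 acquisition in
which hydrated discs appear as compact bright bodies on a darker, textured
background.  A domain is a :class:`PhantomDomainConfig`; domains that differ
only in their intensity parameters (``noise_sigma``, ``contrast_gamma``,
``bias_amplitude``) share identical geometry for matching seeds, so the shift
between them is a pure intensity shift — the setting the domain-adaptation
method targets.

Geometry and intensity draws come from two independent seeded streams, which
is what makes the masks invariant under intensity-parameter changes.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomDomainConfig", "DomainSample", "generate_phantom",
           "generate_domain_dataset", "split_dataset"]

_PLACEMENT_ATTEMPTS = 200


@dataclass(frozen=True)
class PhantomDomainConfig:
    """Structural and intensity parameters of one synthetic domain.

    Structural fields (shape, disc geometry, curvature) determine the mask;
    intensity fields only affect the image.  ``disc_radii`` bounds the wide
    in-plane semi-axis of a disc; the semi-axis along the spine is
    ``disc_aspect`` times it (discs are wider than tall), and
    ``disc_thickness`` bounds the through-slice semi-axis.
    """

    domain_id: str = "S"
    n_discs: int = 7
    volume_shape: tuple[int, int, int] = (64, 64, 12)
    disc_radii: tuple[float, float] = (5.0, 8.0)
    disc_thickness: tuple[float, float] = (2.5, 4.0)
    disc_aspect: float = 0.4
    spine_curvature: float = 6.0
    fg_intensity: float = 0.75
    bg_intensity: float = 0.30
    texture_amplitude: float = 0.04
    noise_sigma: float = 0.03
    bias_amplitude: float = 0.0
    contrast_gamma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_discs < 1:
            raise ValueError("n_discs must be >= 1")
        if len(self.volume_shape) != 3 or any(d < 8 for d in self.volume_shape):
            raise ValueError("volume_shape components must be >= 8")
        for name in ("disc_radii", "disc_thickness"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi")
        for name in ("fg_intensity", "bg_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.fg_intensity <= self.bg_intensity:
            raise ValueError("fg_intensity must exceed bg_intensity")
        if self.noise_sigma < 0 or self.bias_amplitude < 0:
            raise ValueError("noise_sigma and bias_amplitude must be >= 0")
        if not 0 < self.contrast_gamma <= 4:
            raise ValueError("contrast_gamma must lie in (0, 4]")
        if not 0 < self.disc_aspect <= 1:
            raise ValueError("disc_aspect must lie in (0, 1]")

    def intensity_shifted(self, **kw) -> "PhantomDomainConfig":
        """A new domain differing only in intensity parameters."""
        allowed = {"domain_id", "noise_sigma", "bias_amplitude",
                   "contrast_gamma", "texture_amplitude"}
        bad = set(kw) - allowed
        if bad:
            raise ValueError(f"not intensity parameters: {sorted(bad)}")
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomDomainConfig":
        d = dict(d)
        for k in ("volume_shape", "disc_radii", "disc_thickness"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class DomainSample:
    """One volume with an optional binary mask and its domain tag."""

    volume: np.ndarray
    mask: np.ndarray | None
    domain_id: str
    sample_id: str

    def __post_init__(self):
        if self.volume.ndim != 3:
            raise ValueError("volume must be 3D")
        if self.mask is not None:
            if self.mask.shape != self.volume.shape:
                raise ValueError("mask shape must equal volume shape")
            vals = np.unique(self.mask)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask values must be in {0, 1}")


class DiscPlacementError(RuntimeError):
    """Raised when non-overlapping disc placement fails."""


def _place_discs(config: PhantomDomainConfig, rng: np.random.Generator):
    """Disc centres and semi-axes; bounding boxes kept disjoint and in-bounds."""
    nr, nc, ns = config.volume_shape
    for _ in range(_PLACEMENT_ATTEMPTS):
        a_col = rng.uniform(*config.disc_radii, size=config.n_discs)
        a_row = config.disc_aspect * a_col
        a_slc = rng.uniform(*config.disc_thickness, size=config.n_discs)
        a_slc = np.minimum(a_slc, (ns - 2) / 2)
        # evenly spaced rows with jitter, walking down the spine
        base = np.linspace(a_row[0] + 1, nr - a_row[-1] - 2, config.n_discs)
        rows = base + rng.uniform(-1.5, 1.5, size=config.n_discs)
        phase = rng.uniform(0, 2 * np.pi)
        t = (rows - rows.min()) / max(rows.max() - rows.min(), 1.0)
        cols = nc / 2 + config.spine_curvature * np.sin(np.pi * t + phase) \
            - config.spine_curvature * np.sin(phase) * (1 - t)
        cols = np.clip(cols, a_col + 1, nc - a_col - 2)
        slcs = ns / 2 + rng.uniform(-0.5, 0.5, size=config.n_discs)
        centres = np.stack([rows, cols, slcs], axis=1)
        axes = np.stack([a_row, a_col, a_slc], axis=1)
        lo = centres - axes
        hi = centres + axes
        in_bounds = (lo >= 0).all() and (hi <= np.array([nr, nc, ns]) - 1).all()
        # disjoint if the bounding intervals separate along some axis
        disjoint = True
        for i in range(config.n_discs):
            for j in range(i + 1, config.n_discs):
                if (lo[j] > hi[i]).any() or (lo[i] > hi[j]).any():
                    continue
                disjoint = False
        if in_bounds and disjoint:
            return centres, axes
    raise DiscPlacementError(
        f"could not place {config.n_discs} non-overlapping discs in "
        f"{config.volume_shape} after {_PLACEMENT_ATTEMPTS} attempts")


def _ellipsoid_mask(shape, centres, axes) -> np.ndarray:
    grid = np.indices(shape, dtype=np.float32)
    mask = np.zeros(shape, dtype=np.uint8)
    for c, a in zip(centres, axes):
        d = sum(((grid[k] - c[k]) / a[k]) ** 2 for k in range(3))
        mask |= (d <= 1.0)
    return mask


def _bias_field(shape, amplitude, rng) -> np.ndarray:
    """Smooth multiplicative field 1 + amplitude * B with max|B| = 1."""
    nr, nc, ns = shape
    r, c, s = np.meshgrid(np.linspace(0, 1, nr), np.linspace(0, 1, nc),
                          np.linspace(0, 1, ns), indexing="ij")
    b = np.zeros(shape, dtype=np.float32)
    for _ in range(3):
        kr, kc, ks = rng.uniform(0.5, 1.5, size=3)
        pr, pc, ps = rng.uniform(0, 2 * np.pi, size=3)
        w = rng.uniform(0.3, 1.0)
        b += w * np.cos(np.pi * (kr * r + pr)) * np.cos(
            np.pi * (kc * c + pc)) * np.cos(np.pi * (ks * s + ps))
    b /= max(np.abs(b).max(), 1e-8)
    return 1.0 + amplitude * b


def generate_phantom(config: PhantomDomainConfig, sample_seed: int,
                     sample_id: str | None = None) -> DomainSample:
    """One spine phantom, deterministic in (config.seed, sample_seed).

    The mask depends only on the structural parameters and seeds; the
    intensity pipeline is: ideal image (+ partial-volume smoothing and
    background texture) -> multiplicative bias -> additive Gaussian noise ->
    clamp -> gamma -> clamp.
    """
    config.validate()
    geom_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, int(sample_seed), 11]))
    int_rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, int(sample_seed), 13]))

    centres, axes = _place_discs(config, geom_rng)
    mask = _ellipsoid_mask(config.volume_shape, centres, axes)

    img = config.bg_intensity + (config.fg_intensity - config.bg_intensity) \
        * mask.astype(np.float32)
    # partial-volume effect: soften disc borders, less so through-plane
    img = gaussian_filter(img, sigma=(0.7, 0.7, 0.35))
    texture = gaussian_filter(
        int_rng.standard_normal(config.volume_shape).astype(np.float32),
        sigma=(1.5, 1.5, 0.75))
    tstd = texture.std()
    if tstd > 0:
        img = img + config.texture_amplitude * texture / tstd
    img = img * _bias_field(config.volume_shape, config.bias_amplitude, int_rng)
    img = img + int_rng.standard_normal(config.volume_shape).astype(
        np.float32) * config.noise_sigma
    img = np.clip(img, 0.0, 1.0) ** config.contrast_gamma
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    sid = sample_id or f"{config.domain_id}-{sample_seed:010d}"
    return DomainSample(volume=img, mask=mask, domain_id=config.domain_id,
                        sample_id=sid)


def generate_domain_dataset(config: PhantomDomainConfig, n: int,
                            base_seed: int) -> list[DomainSample]:
    """``n`` phantoms with distinct, reproducible per-sample seeds."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 17]))
    seeds: list[int] = []
    while len(seeds) < n:
        s = int(rng.integers(0, 2 ** 31 - 1))
        if s not in seeds:
            seeds.append(s)
    return [generate_phantom(config, s, sample_id=f"{config.domain_id}{i:03d}")
            for i, s in enumerate(seeds)]


def split_dataset(samples: list[DomainSample],
                  fractions: tuple[float, float, float],
                  seed: int = 0, tol: float = 0.05):
    """Shuffle and partition into train/val/test.

    Split sizes follow largest-remainder rounding of ``fractions``; every
    sample lands in exactly one split (no sample is dropped and no
    ``sample_id`` repeats across splits).
    """
    if not samples:
        raise ValueError("cannot split an empty dataset")
    fr = np.asarray(fractions, dtype=float)
    if fr.size != 3 or (fr < 0).any():
        raise ValueError("fractions must be three non-negative numbers")
    if abs(fr.sum() - 1.0) > tol:
        raise ValueError(f"fractions must sum to 1 within {tol}, "
                         f"got {fr.sum():.3f}")
    n = len(samples)
    quota = fr / fr.sum() * n
    sizes = np.floor(quota).astype(int)
    remainder = quota - sizes
    for k in np.argsort(-remainder)[: n - sizes.sum()]:
        sizes[k] += 1
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [samples[i] for i in order]
    a, b = sizes[0], sizes[0] + sizes[1]
    return shuffled[:a], shuffled[a:b], shuffled[b:]
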