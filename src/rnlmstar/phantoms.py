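"""Synthetic MR-like phantoms.

Noise-free test images emulating layered musculoskeletal anatomy: smooth
horizontal tissue bands with distinct mean levels separated by (optionally
blurred) edges, plus small isolated high-contrast discs standing in for the
tiny lesions whose preservation motivates particle-aware denoising. All
randomness is seeded, so a spec maps to exactly one phantom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["PhantomSpec", "make_phantom", "particle_mask"]

# amplitude of the smooth within-band gradient, in intensity units
_BAND_GRADIENT_AMP = 0.06
_MIN_SIZE = 16


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one synthetic phantom.

    ``band_levels`` optionally pins the mean intensity of each band
    (length must equal ``n_bands``); when None, levels are a seeded
    permutation of evenly spaced values in [0.2, 0.7].
    """

    size: tuple[int, int] = (64, 64)
    n_bands: int = 4
    n_particles: int = 6
    particle_radius_px: int = 2
    particle_contrast: float = 0.5
    edge_blur_sigma: float = 0.6
    seed: int = 0
    band_levels: tuple[float, ...] | None = None

    def validate(self) -> None:
        h, w = self.size
        if h < _MIN_SIZE or w < _MIN_SIZE:
            raise ValueError(f"phantom size must be >= 16x16, got {self.size}")
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")
        if self.particle_radius_px < 1:
            raise ValueError("particle_radius_px must be >= 1")
        if 2 * self.particle_radius_px + 1 > min(h, w):
            raise ValueError(
                f"particle radius {self.particle_radius_px} does not fit in {self.size}"
            )
        if not (0 < self.particle_contrast <= 1):
            raise ValueError("particle_contrast must be in (0, 1]")
        if self.edge_blur_sigma < 0:
            raise ValueError("edge_blur_sigma must be >= 0")
        if self.band_levels is not None and len(self.band_levels) != self.n_bands:
            raise ValueError(
                f"band_levels has {len(self.band_levels)} entries for {self.n_bands} bands"
            )


def _band_image(spec: PhantomSpec) -> np.ndarray:
    h, w = spec.size
    if spec.band_levels is not None:
        levels = np.asarray(spec.band_levels, dtype=float)
    elif spec.n_bands == 1:
        levels = np.array([0.45])
    else:
        rng = np.random.default_rng([spec.seed, 0])
        levels = rng.permutation(np.linspace(0.2, 0.7, spec.n_bands))
    if spec.n_bands == 1:
        # degenerate single-band case: a constant field
        return np.full((h, w), float(np.clip(levels[0], 0.0, 1.0)))
    edges = np.linspace(0, h, spec.n_bands + 1).round().astype(int)
    img = np.empty((h, w), dtype=float)
    for b in range(spec.n_bands):
        r0, r1 = edges[b], edges[b + 1]
        n = max(r1 - r0, 1)
        # smooth vertical gradient within the band around its mean level
        ramp = levels[b] + _BAND_GRADIENT_AMP * (
            (np.arange(r0, r1) - r0) / n - 0.5
        )
        img[r0:r1, :] = ramp[:, None]
    return np.clip(img, 0.0, 1.0)


def _particle_centers(spec: PhantomSpec) -> list[tuple[int, int]]:
    """Seeded rejection sampling of well-separated in-bounds disc centers."""
    if spec.n_particles == 0:
        return []
    h, w = spec.size
    r = spec.particle_radius_px
    margin = r + int(math.ceil(3 * spec.edge_blur_sigma)) + 1
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ValueError("image too small to place particles inside borders")
    min_sep2 = (4 * r + 4) ** 2
    rng = np.random.default_rng([spec.seed, 1])
    centers: list[tuple[int, int]] = []
    for _ in range(20000):
        if len(centers) == spec.n_particles:
            break
        cy = int(rng.integers(margin, h - margin))
        cx = int(rng.integers(margin, w - margin))
        if all((cy - py) ** 2 + (cx - px) ** 2 >= min_sep2 for py, px in centers):
            centers.append((cy, cx))
    if len(centers) < spec.n_particles:
        raise ValueError(
            f"could not place {spec.n_particles} separated particles in {spec.size}"
        )
    return centers


def _disc_mask(size: tuple[int, int], center: tuple[int, int], r: int) -> np.ndarray:
    yy, xx = np.ogrid[: size[0], : size[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= r * r


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Render the phantom: bands, then hard discs, then optional edge blur.

    Returns a float image in [0, 1]; identical specs (same seed) give
    bit-identical arrays.
    """
    spec.validate()
    img = _band_image(spec)
    for cy, cx in _particle_centers(spec):
        value = min(img[cy, cx] + spec.particle_contrast, 1.0)
        img[_disc_mask(spec.size, (cy, cx), spec.particle_radius_px)] = value
    if spec.edge_blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.edge_blur_sigma, mode="nearest")
    return np.clip(img, 0.0, 1.0)


def particle_mask(spec: PhantomSpec) -> np.ndarray:
    """Boolean grid, True exactly on the (unblurred) particle discs."""
    spec.validate()
    mask = np.zeros(spec.size, dtype=bool)
    for cy, cx in _particle_centers(spec):
        mask |= _disc_mask(spec.size, (cy, cx), spec.particle_radius_px)
    return mask
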