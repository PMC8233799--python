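"""Parametric noise generators and Rician utilities.

Three steerable noise families on the normalized [0,1] intensity scale:

* Rician — magnitude noise of MR images, M = sqrt((A+n1)^2 + n2^2) with
  n1, n2 i.i.d. N(0, sigma^2); biased upward at low signal
  (E[M^2] = A^2 + 2*sigma^2).
* Salt & Pepper — impulse noise of total density d, split equally between
  white (1) and black (0) pixels.
* Speckle — multiplicative granular noise J = I + n*I with a zero-mean
  multiplier of variance v (uniform by default).

Rician and Speckle outputs are deliberately not clipped to [0,1]; the
metrics operate on unclipped values. All generators are pure functions of
(image, intensity, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "NoiseSpec",
    "add_rician",
    "rician_pdf",
    "add_salt_pepper",
    "add_speckle",
    "apply_noise",
    "estimate_sigma_background",
]

_FAMILIES = ("rician", "salt_pepper", "speckle")


@dataclass(frozen=True)
class NoiseSpec:
    """A noise family plus its intensity parameter (sigma, d, or v)."""

    family: str
    intensity: float
    seed: int = 0

    def validate(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.family == "salt_pepper":
            if not (0 <= self.intensity <= 1):
                raise ValueError(f"density d must be in [0,1], got {self.intensity}")
        elif self.intensity < 0:
            raise ValueError(f"intensity must be >= 0, got {self.intensity}")


def _as_image(img) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError("image must be 2-D")
    return arr


def add_rician(img, sigma: float, seed: int) -> np.ndarray:
    """Corrupt with Rician noise: M = sqrt((A+n1)^2 + n2^2)."""
    arr = _as_image(img)
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return np.abs(arr)
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, arr.shape)
    n2 = rng.normal(0.0, sigma, arr.shape)
    return np.sqrt((arr + n1) ** 2 + n2 ** 2)


def rician_pdf(M, A, sigma: float):
    """Rician density p(M | A, sigma^2).

    (M/sigma^2) exp(-(M^2+A^2)/(2 sigma^2)) I0(A M / sigma^2) for M >= 0,
    zero otherwise. Evaluated with the exponentially scaled Bessel
    function ``ive`` so large arguments do not overflow. Reduces to the
    Rayleigh density at A = 0.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    M = np.asarray(M, dtype=float)
    A = np.asarray(A, dtype=float)
    s2 = sigma * sigma
    z = A * M / s2
    # I0(z) = ive(0, z) * exp(z); fold exp(z) into the main exponent
    with np.errstate(under="ignore"):
        dens = (M / s2) * np.exp(-((M - A) ** 2) / (2.0 * s2)) * special.ive(0, z)
    dens = np.where(M >= 0, dens, 0.0)
    if dens.ndim == 0:
        return float(dens)
    return dens


def add_salt_pepper(img, d: float, seed: int) -> np.ndarray:
    """Impulse noise: each pixel corrupted with probability d, set to 0 or 1
    with equal probability."""
    arr = _as_image(img)
    if not (0 <= d <= 1):
        raise ValueError(f"density d must be in [0,1], got {d}")
    rng = np.random.default_rng(seed)
    hit = rng.random(arr.shape) < d
    salt = rng.random(arr.shape) < 0.5
    out = arr.copy()
    out[hit & salt] = 1.0
    out[hit & ~salt] = 0.0
    return out


def add_speckle(img, v: float, seed: int) -> np.ndarray:
    """Multiplicative speckle J = I + n*I, n zero-mean uniform, Var[n] = v."""
    arr = _as_image(img)
    if v < 0:
        raise ValueError(f"variance v must be >= 0, got {v}")
    if v == 0:
        return arr.copy()
    rng = np.random.default_rng(seed)
    half_width = np.sqrt(3.0 * v)  # Var[U(-L, L)] = L^2 / 3
    n = rng.uniform(-half_width, half_width, arr.shape)
    return arr + n * arr


def apply_noise(img, spec: NoiseSpec) -> np.ndarray:
    """Dispatch to the generator named by ``spec.family``."""
    spec.validate()
    if spec.family == "rician":
        return add_rician(img, spec.intensity, spec.seed)
    if spec.family == "salt_pepper":
        return add_salt_pepper(img, spec.intensity, spec.seed)
    return add_speckle(img, spec.intensity, spec.seed)


def estimate_sigma_background(img, background_mask, min_pixels: int = 100) -> float:
    """Estimate the Rician sigma from a signal-free background region.

    In the background A = 0, so E[M^2] = 2*sigma^2 and
    sigma = sqrt(mean(M^2) / 2).
    """
    arr = _as_image(img)
    mask = np.asarray(background_mask, dtype=bool)
    if mask.shape != arr.shape:
        raise ValueError("mask shape differs from image shape")
    n = int(mask.sum())
    if n < min_pixels:
        raise ValueError(f"background mask selects {n} pixels, need >= {min_pixels}")
    return float(np.sqrt(np.mean(arr[mask] ** 2) / 2.0))
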