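"""Image-quality metrics for denoising evaluation.

MSE, SNR, PSNR, the universal quality index (Q-index), SSIM, Pearson
correlation, and descriptive statistics of the native-vs-filtered
intensity-difference distribution.

Conventions
-----------
* SNR is role-asymmetric: ``snr_db(filtered, native)`` with the filtered
  image as the signal term.
* Q-index is the product of three factors (correlation, luminance
  similarity, contrast similarity) computed from global statistics.
* SSIM defaults to global-statistics mode with l^alpha * c^beta * s^gamma,
  C1 = (0.01 L)^2, C2 = (0.03 L)^2, C3 = C2/2 on the L = 1 scale, using
  population (ddof = 0) moments; an 8x8 sliding-window mode returning the
  mean of the local map is available.
* Degenerate inputs return documented sentinels instead of raising: +inf
  for zero-error SNR/PSNR, NaN for zero-variance Q-index/correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

__all__ = [
    "MetricReport",
    "IntensityDiffStats",
    "mse",
    "snr_db",
    "psnr_db",
    "q_index",
    "ssim",
    "pearson_corr",
    "intensity_diff_stats",
    "metric_report",
]

_C1 = 0.01 ** 2
_C2 = 0.03 ** 2
_C3 = _C2 / 2.0


@dataclass(frozen=True)
class MetricReport:
    """All metrics for one (reference, test) image pair."""

    mse: float
    snr_db: float
    psnr_db: float
    q_index: float
    ssim: float
    corr: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class IntensityDiffStats:
    """Median / mode / variance of the |native - filtered| * 100 distribution."""

    median_pct: float
    mode_pct: float
    variance: float


def _pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    ax = np.asarray(x, dtype=float)
    ay = np.asarray(y, dtype=float)
    if ax.shape != ay.shape:
        raise ValueError(f"shape mismatch: {ax.shape} vs {ay.shape}")
    return ax, ay


def mse(x, y) -> float:
    ax, ay = _pair(x, y)
    return float(np.mean((ax - ay) ** 2))


def snr_db(filtered, native) -> float:
    """10 log10( sum s^2 / sum (s - s_hat)^2 ), s = filtered, s_hat = native."""
    s, s_hat = _pair(filtered, native)
    denom = float(np.sum((s - s_hat) ** 2))
    if denom == 0.0:
        return float("inf")
    num = float(np.sum(s ** 2))
    if num == 0.0:
        return float("-inf")
    return 10.0 * np.log10(num / denom)


def psnr_db(x, y, peak: float = 1.0) -> float:
    e = mse(x, y)
    if e == 0.0:
        return float("inf")
    return 10.0 * np.log10(peak * peak / e)


def q_index(x, y) -> float:
    """Universal quality index: correlation x luminance x contrast, in [-1, 1].

    NaN sentinel when either image has zero variance.
    """
    ax, ay = _pair(x, y)
    mx, my = ax.mean(), ay.mean()
    vx, vy = ax.var(), ay.var()
    if vx == 0.0 or vy == 0.0:
        return float("nan")
    sx, sy = np.sqrt(vx), np.sqrt(vy)
    sxy = float(np.mean((ax - mx) * (ay - my)))
    corr_f = sxy / (sx * sy)
    m2 = mx * mx + my * my
    if m2 > 1e-12 * (vx + vy):
        lum_f = 2.0 * mx * my / m2
    else:
        # both means (numerically) zero: the 0/0 luminance factor is taken
        # as 1 along x == y and 0 otherwise
        lum_f = 1.0 if np.array_equal(ax, ay) else 0.0
    con_f = 2.0 * sx * sy / (vx + vy)
    return float(corr_f * lum_f * con_f)


def _ssim_terms(mx, my, vx, vy, sxy, alpha, beta, gamma):
    l = (2.0 * mx * my + _C1) / (mx * mx + my * my + _C1)
    c = (2.0 * np.sqrt(vx) * np.sqrt(vy) + _C2) / (vx + vy + _C2)
    s = (sxy + _C3) / (np.sqrt(vx) * np.sqrt(vy) + _C3)
    return (l ** alpha) * (c ** beta) * (s ** gamma)


def ssim(
    x,
    y,
    alpha: float = 1.0,
    beta: float = 1.0,
    gamma: float = 1.0,
    mode: str = "global",
    win_size: int = 8,
) -> float:
    """Structural similarity l^alpha * c^beta * s^gamma.

    ``mode='global'`` (default) uses whole-image statistics;
    ``mode='window'`` averages the local map over ``win_size`` boxes.
    """
    ax, ay = _pair(x, y)
    if mode == "global":
        mx, my = ax.mean(), ay.mean()
        vx, vy = ax.var(), ay.var()
        sxy = float(np.mean((ax - mx) * (ay - my)))
        return float(_ssim_terms(mx, my, vx, vy, sxy, alpha, beta, gamma))
    if mode != "window":
        raise ValueError(f"unknown ssim mode {mode!r}")
    size = win_size
    ux = ndimage.uniform_filter(ax, size)
    uy = ndimage.uniform_filter(ay, size)
    uxx = ndimage.uniform_filter(ax * ax, size)
    uyy = ndimage.uniform_filter(ay * ay, size)
    uxy = ndimage.uniform_filter(ax * ay, size)
    vx = np.maximum(uxx - ux * ux, 0.0)
    vy = np.maximum(uyy - uy * uy, 0.0)
    sxy = uxy - ux * uy
    smap = _ssim_terms(ux, uy, vx, vy, sxy, alpha, beta, gamma)
    pad = size // 2
    core = smap[pad:-pad, pad:-pad] if min(smap.shape) > 2 * pad else smap
    return float(core.mean())


def pearson_corr(x, y) -> float:
    """Product-moment correlation over pixels; NaN on constant input."""
    ax, ay = _pair(x, y)
    if ax.std() == 0.0 or ay.std() == 0.0:
        return float("nan")
    return float(np.corrcoef(ax.ravel(), ay.ravel())[0, 1])


def intensity_diff_stats(native, filtered, n_bins: int = 256) -> IntensityDiffStats:
    """Statistics of the per-pixel intensity difference in percent.

    ID = |native - filtered| * 100 (percent of the [0,1] range); the mode
    is the center of the most populated of ``n_bins`` equal bins over
    [0, 100] (first bin on ties).
    """
    ax, ay = _pair(native, filtered)
    idiff = np.abs(ax - ay).ravel() * 100.0
    counts, edges = np.histogram(idiff, bins=n_bins, range=(0.0, 100.0))
    top = int(np.argmax(counts))
    mode = 0.5 * (edges[top] + edges[top + 1])
    return IntensityDiffStats(
        median_pct=float(np.median(idiff)),
        mode_pct=float(mode),
        variance=float(np.var(idiff)),
    )


def metric_report(reference, test, peak: float = 1.0) -> MetricReport:
    """Compute the full metric panel for one image pair.

    ``reference`` is the noise-free image, ``test`` the filtered one; SNR
    uses the (filtered, native) role assignment.
    """
    return MetricReport(
        mse=mse(reference, test),
        snr_db=snr_db(test, reference),
        psnr_db=psnr_db(reference, test, peak=peak),
        q_index=q_index(reference, test),
        ssim=ssim(reference, test),
        corr=pearson_corr(reference, test),
    )
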