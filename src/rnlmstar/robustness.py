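"""Dynamic-noise robustness characterization.

Traces quality metrics across an ordered sequence of noise intensities
(default nine levels spanning [0.1, 0.9]) for a named filter, pools
intensity-difference distributions across filter settings, and summarizes
filter-vs-filter percentage differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from . import baselines
from .metrics import IntensityDiffStats, intensity_diff_stats, metric_report
from .nlm import FilterParams, nlm_filter, rnlm_filter, rnlm_star_filter
from .noise import NoiseSpec, apply_noise

__all__ = [
    "NamedFilter",
    "RobustnessCurve",
    "DEFAULT_LEVELS",
    "identity_filter",
    "nlm_denoiser",
    "rnlm_denoiser",
    "rnlm_star_denoiser",
    "average_denoiser",
    "median_denoiser",
    "noise_sweep",
    "id_distribution_study",
    "compare_filters",
]

DEFAULT_LEVELS: tuple[float, ...] = tuple(np.round(np.linspace(0.1, 0.9, 9), 10))

_METRIC_COLS = ["ssim", "snr_db", "psnr_db", "q_index", "corr", "mse"]


@dataclass(frozen=True)
class NamedFilter:
    """A denoiser bound to its parameters.

    ``fn(noisy, level)`` receives the current noise level so Rician-aware
    filters can tie their bias correction to it.
    """

    name: str
    fn: Callable[[np.ndarray, float], np.ndarray]


@dataclass
class RobustnessCurve:
    """Per-level mean metrics for one filter under one noise family."""

    family: str
    filter_name: str
    levels: np.ndarray
    table: pd.DataFrame  # columns: level + _METRIC_COLS, one row per level
    per_image: pd.DataFrame  # columns: level, image + _METRIC_COLS


def identity_filter() -> NamedFilter:
    return NamedFilter("identity", lambda img, level: np.asarray(img, dtype=float))


def nlm_denoiser(params: FilterParams) -> NamedFilter:
    return NamedFilter("nlm", lambda img, level: nlm_filter(img, params))


def _sigma_for(sigma, level: float) -> float:
    return float(level) if sigma == "level" else float(sigma)


def rnlm_denoiser(params: FilterParams, sigma="level") -> NamedFilter:
    """Rician-corrected NLM; ``sigma='level'`` ties the correction to the
    swept noise level, a float fixes it."""
    return NamedFilter(
        "rnlm", lambda img, level: rnlm_filter(img, params, _sigma_for(sigma, level))
    )


def rnlm_star_denoiser(params: FilterParams, sigma="level") -> NamedFilter:
    return NamedFilter(
        "rnlm_star",
        lambda img, level: rnlm_star_filter(img, params, _sigma_for(sigma, level)),
    )


def average_denoiser(size: int = 5) -> NamedFilter:
    return NamedFilter(
        f"average{size}x{size}", lambda img, level: baselines.average_filter(img, size)
    )


def median_denoiser(size: int = 5) -> NamedFilter:
    return NamedFilter(
        f"median{size}x{size}", lambda img, level: baselines.median_filter(img, size)
    )


def _check_levels(family: str, levels) -> np.ndarray:
    lv = np.asarray(levels, dtype=float)
    if lv.ndim != 1 or lv.size == 0:
        raise ValueError("levels must be a non-empty 1-D sequence")
    if np.any(np.diff(lv) <= 0):
        raise ValueError("levels must be strictly increasing")
    for x in lv:
        NoiseSpec(family, float(x)).validate()
    return lv


def _corruption_seed(seed: int, image_idx: int, level_idx: int) -> int:
    return int(np.random.default_rng([seed, image_idx, level_idx]).integers(2 ** 31))


def noise_sweep(
    images: list[np.ndarray],
    family: str,
    levels,
    filt: NamedFilter,
    seed: int,
) -> RobustnessCurve:
    """Corrupt, filter, measure — per level, averaged over images."""
    if not images:
        raise ValueError("images must be non-empty")
    lv = _check_levels(family, levels)
    rows = []
    for k, level in enumerate(lv):
        for i, img in enumerate(images):
            spec = NoiseSpec(family, float(level), _corruption_seed(seed, i, k))
            noisy = apply_noise(img, spec)
            out = filt.fn(noisy, float(level))
            rep = metric_report(img, out)
            rows.append({"level": float(level), "image": i, **rep.to_dict()})
    per_image = pd.DataFrame(rows)
    table = (
        per_image.groupby("level", as_index=False)[_METRIC_COLS].mean().sort_values("level")
    ).reset_index(drop=True)
    return RobustnessCurve(
        family=family,
        filter_name=filt.name,
        levels=lv,
        table=table,
        per_image=per_image,
    )


def id_distribution_study(
    images: list[np.ndarray],
    family: str,
    levels,
    filter_bank: list[NamedFilter],
    seed: int,
) -> pd.DataFrame:
    """Pool per-pixel |native - filtered| percentages across all levels per
    filter setting; report median/mode/variance per setting."""
    if not filter_bank:
        raise ValueError("filter bank must be non-empty")
    if not images:
        raise ValueError("images must be non-empty")
    lv = _check_levels(family, levels)
    rows = []
    for filt in filter_bank:
        pooled = []
        for k, level in enumerate(lv):
            for i, img in enumerate(images):
                spec = NoiseSpec(family, float(level), _corruption_seed(seed, i, k))
                out = filt.fn(apply_noise(img, spec), float(level))
                pooled.append(np.abs(np.asarray(img, float) - out).ravel() * 100.0)
        pooled_arr = np.concatenate(pooled)
        # reuse the histogram/median machinery on the pre-scaled pool
        stats: IntensityDiffStats = intensity_diff_stats(
            pooled_arr / 100.0, np.zeros_like(pooled_arr)
        )
        rows.append(
            {
                "filter": filt.name,
                "median_pct": stats.median_pct,
                "mode_pct": stats.mode_pct,
                "variance": stats.variance,
                "n_values": pooled_arr.size,
            }
        )
    return pd.DataFrame(rows)


def compare_filters(
    images: list[np.ndarray],
    family: str,
    levels,
    filter_a: NamedFilter,
    filter_b: NamedFilter,
    seed: int,
) -> dict:
    """Percentage differences 100*(mean_A - mean_B)/mean_B of mean SSIM and
    correlation, means over levels and images (identical corruptions for
    both filters). NaN sentinel on a zero denominator."""
    curve_a = noise_sweep(images, family, levels, filter_a, seed)
    curve_b = noise_sweep(images, family, levels, filter_b, seed)
    out = {}
    for metric in ("ssim", "corr"):
        mean_a = float(curve_a.per_image[metric].mean())
        mean_b = float(curve_b.per_image[metric].mean())
        out[f"diff_{metric}_pct"] = (
            float("nan") if mean_b == 0 else 100.0 * (mean_a - mean_b) / mean_b
        )
        out[f"mean_{metric}_a"] = mean_a
        out[f"mean_{metric}_b"] = mean_b
    return out
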