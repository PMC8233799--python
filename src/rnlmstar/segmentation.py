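"""Multiregional fuzzy soft-thresholding segmentation and its evaluation.

Segmentation is histogram-domain fuzzy c-means over pixel intensities:
deterministic (quantile initialization, no random starts) and invariant
to pixel permutation. Label maps are compared through centroid-rendered
images so SSIM/SNR operate on intensity-commensurate inputs; the package
uses this to quantify how pre-filtering changes segmentation similarity
to the noise-free reference under increasing noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .metrics import snr_db, ssim
from .noise import NoiseSpec, apply_noise
from .robustness import NamedFilter, _check_levels, _corruption_seed

__all__ = [
    "SegmentationMap",
    "fuzzy_soft_threshold",
    "render_segmentation",
    "segmentation_performance",
    "segmentation_sweep",
]


@dataclass
class SegmentationMap:
    """Labels plus the ascending centroid intensities that define them."""

    labels: np.ndarray  # int class indices 0..n_classes-1
    centroids: np.ndarray  # strictly increasing representative intensities
    n_classes: int
    values: np.ndarray  # distinct intensity values (histogram domain)
    memberships: np.ndarray  # (n_classes, n_values), columns sum to 1


def _init_centroids(pixels: np.ndarray, values: np.ndarray, c: int) -> np.ndarray:
    q = (np.arange(c) + 0.5) / c
    cents = np.quantile(pixels, q)
    if len(np.unique(cents)) < c:
        # heavily skewed histograms can collapse quantiles; fall back to
        # quantiles of the distinct-value set
        cents = np.quantile(values, q)
    if len(np.unique(cents)) < c:
        cents = np.linspace(values.min(), values.max(), c + 2)[1:-1]
    return np.sort(cents.astype(float))


def _memberships(values: np.ndarray, cents: np.ndarray, m: float) -> np.ndarray:
    d = np.abs(values[None, :] - cents[:, None])
    zero = d == 0
    with np.errstate(divide="ignore"):
        inv = d ** (-2.0 / (m - 1.0))
    u = np.empty_like(inv)
    any_zero = zero.any(axis=0)
    u[:, ~any_zero] = inv[:, ~any_zero] / inv[:, ~any_zero].sum(axis=0)
    if any_zero.any():
        cols = np.where(any_zero)[0]
        u[:, cols] = 0.0
        first_zero = np.argmax(zero[:, cols], axis=0)
        u[first_zero, cols] = 1.0
    return u


def fuzzy_soft_threshold(
    img: np.ndarray,
    n_classes: int,
    fuzzifier: float = 2.0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> SegmentationMap:
    """Histogram-domain fuzzy c-means thresholding.

    Centroids start at the (j+0.5)/C quantiles of the intensity
    distribution and iterate the standard FCM updates on the distinct
    values weighted by their pixel counts until the largest centroid
    shift is below ``tol``. Each pixel is assigned its maximal-membership
    class (lowest class index on ties).
    """
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError("image must be 2-D")
    if n_classes < 2:
        raise ValueError(f"n_classes must be >= 2, got {n_classes}")
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    values, counts = np.unique(arr.ravel(), return_counts=True)
    if values.size < n_classes:
        raise ValueError(
            f"image has {values.size} distinct values, fewer than {n_classes} classes"
        )
    cents = _init_centroids(arr.ravel(), values, n_classes)
    for _ in range(max_iter):
        u = _memberships(values, cents, fuzzifier)
        w = (u ** fuzzifier) * counts[None, :]
        denom = w.sum(axis=1)
        new = np.where(denom > 0, (w * values[None, :]).sum(axis=1) / denom, cents)
        shift = float(np.max(np.abs(new - cents)))
        cents = new
        if shift < tol:
            break
    order = np.argsort(cents, kind="stable")
    cents = cents[order]
    u = _memberships(values, cents, fuzzifier)
    label_of_value = np.argmax(u, axis=0)  # ties -> lowest class
    labels = label_of_value[np.searchsorted(values, arr)]
    return SegmentationMap(
        labels=labels.astype(np.int64),
        centroids=cents,
        n_classes=n_classes,
        values=values,
        memberships=u,
    )


def render_segmentation(seg: SegmentationMap) -> np.ndarray:
    """Replace each label by its centroid intensity."""
    return seg.centroids[seg.labels]


def segmentation_performance(
    native: np.ndarray,
    corrupted: np.ndarray,
    filt: Callable[[np.ndarray], np.ndarray] | None,
    n_classes: int,
) -> tuple[float, float]:
    """(SSIM, SNR) between the segmentations of native and corrupted images.

    Both segmentations are compared as centroid renderings; ``filt``
    (optional) is applied to the corrupted image before segmenting.
    """
    nat = np.asarray(native, dtype=float)
    cor = np.asarray(corrupted, dtype=float)
    if nat.shape != cor.shape:
        raise ValueError("shape mismatch")
    ref = render_segmentation(fuzzy_soft_threshold(nat, n_classes))
    test_img = filt(cor) if filt is not None else cor
    test = render_segmentation(fuzzy_soft_threshold(test_img, n_classes))
    return ssim(ref, test), snr_db(test, ref)


def segmentation_sweep(
    images: list[np.ndarray],
    family: str,
    levels,
    filter_bank: list[NamedFilter],
    class_counts: Sequence[int] = (3, 8),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segmentation-performance curves plus percentage-difference tables.

    Returns ``(curves, diffs)``: ``curves`` holds the mean SSIM/SNR per
    (level, filter, class count); ``diffs`` holds
    100*(mean_ref - mean_f)/mean_f of the level-averaged SSIM and SNR for
    every non-reference filter, with the first bank entry as reference.
    """
    if not filter_bank:
        raise ValueError("filter bank must be non-empty")
    if not images:
        raise ValueError("images must be non-empty")
    lv = _check_levels(family, levels)
    rows = []
    for filt in filter_bank:
        for c in class_counts:
            for k, level in enumerate(lv):
                vals = []
                for i, img in enumerate(images):
                    spec = NoiseSpec(family, float(level), _corruption_seed(seed, i, k))
                    noisy = apply_noise(img, spec)
                    s, snr = segmentation_performance(
                        img, noisy, lambda x: filt.fn(x, float(level)), c
                    )
                    vals.append((s, snr))
                mean_s = float(np.mean([v[0] for v in vals]))
                mean_snr = float(np.mean([v[1] for v in vals]))
                rows.append(
                    {
                        "level": float(level),
                        "filter": filt.name,
                        "n_classes": int(c),
                        "ssim": mean_s,
                        "snr_db": mean_snr,
                    }
                )
    curves = pd.DataFrame(rows)
    ref_name = filter_bank[0].name
    diff_rows = []
    for c in class_counts:
        ref_mean = curves[(curves["filter"] == ref_name) & (curves["n_classes"] == c)][
            ["ssim", "snr_db"]
        ].mean()
        for filt in filter_bank[1:]:
            f_mean = curves[
                (curves["filter"] == filt.name) & (curves["n_classes"] == c)
            ][["ssim", "snr_db"]].mean()
            row = {"reference": ref_name, "filter": filt.name, "n_classes": int(c)}
            for metric in ("ssim", "snr_db"):
                denom = float(f_mean[metric])
                row[f"diff_{metric}_pct"] = (
                    float("nan")
                    if denom == 0
                    else 100.0 * (float(ref_mean[metric]) - denom) / denom
                )
            diff_rows.append(row)
    return curves, pd.DataFrame(diff_rows)
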