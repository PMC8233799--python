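"""Conventional local-means comparators: average and median filters.

Standard kernel sizes for benchmarking are 5x5, 7x7 and 15x15; any odd
size >= 3 is accepted. Borders use symmetric (mirror) padding for parity
with the non-local filters.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["average_filter", "median_filter"]


def _check(img, size: int) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError("image must be 2-D")
    if size < 3 or size % 2 == 0:
        raise ValueError(f"kernel size must be odd and >= 3, got {size}")
    return arr


def average_filter(img, size: int = 5) -> np.ndarray:
    """Each pixel becomes the arithmetic mean of its size x size window."""
    arr = _check(img, size)
    return ndimage.uniform_filter(arr, size=size, mode="reflect")


def median_filter(img, size: int = 5) -> np.ndarray:
    """Each pixel becomes the median of its size x size window."""
    arr = _check(img, size)
    return ndimage.median_filter(arr, size=size, mode="reflect")
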