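"""Shared morphology/filtering helpers.

Disk convention: a "(D pixel diameter) disk" structuring element is the set
of pixels whose Euclidean distance from the center pixel is <= D/2.
Square "(N x N pixel) Gaussian" kernels use sigma = N/6 (about 3 sigma of
support inside the kernel) and truncate at radius N//2.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def disk_footprint(diameter: float) -> np.ndarray:
    """Boolean disk structuring element of the given pixel diameter."""
    if diameter < 1:
        raise ValueError(f"diameter must be >= 1, got {diameter}")
    radius = diameter / 2.0
    r = int(np.floor(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= radius * radius + 1e-9


def gaussian_blur(image: np.ndarray, kernel_size: int) -> np.ndarray:
    """Blur with a square Gaussian kernel of the given side (sigma = side/6)."""
    sigma = kernel_size / 6.0
    return ndimage.gaussian_filter(
        np.asarray(image, dtype=float), sigma=sigma, radius=kernel_size // 2, mode="nearest"
    )
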