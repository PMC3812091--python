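"""Well finding: locate the assayable well region in a brightfield image.

The full-well brightfield image is blurred (30x30 Gaussian), scaled from its
declared dynamic range (12 bit in a 16 bit container) to 8 bit, and
thresholded at L*F, where L is the Otsu level of the 8-bit histogram and
F = 0.9 biases the cut toward fewer false-positive well pixels.  Holes are
filled, the largest connected region is kept as the well, and the mask is
eroded with a 30 px diameter disk; a 30 px false border is padded on before
the erosion and removed afterwards so partial wells at the image edge do not
lose their rim to boundary effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._morph import disk_footprint, gaussian_blur
from .config import PipelineConfig
from .imaging_io import FullWellImage
from .object_finder import OtsuError, otsu_with_effectiveness

_EIGHT = np.ones((3, 3), bool)  # 8-connectivity for foreground components


class WellFindingError(ValueError):
    """No well region could be located."""


@dataclass(frozen=True)
class WellMask:
    """The assayable well region: one connected boolean component."""

    mask: np.ndarray
    area_px: int
    suspicious: bool = False  # >50% of the frame is foreground after erosion

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, bool)
        object.__setattr__(self, "mask", m)
        if int(m.sum()) != self.area_px:
            raise ValueError("area_px does not match the mask")


def _scale_array_to_8bit(values: np.ndarray, bit_depth: int) -> np.ndarray:
    """Linear map of [0, 2**bit_depth - 1] onto [0, 255], round half away from zero."""
    if bit_depth == 8:
        return np.asarray(values).astype(np.uint8)
    scaled = np.asarray(values, dtype=float) * (255.0 / (2**bit_depth - 1))
    return np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)


def scale_to_8bit(image: FullWellImage) -> np.ndarray:
    """Convert an image to 8 bit, accounting for its declared dynamic range.

    A 12-bit image maps [0, 4095] linearly onto [0, 255] (rounding half away
    from zero); 8-bit inputs pass through unchanged.
    """
    return _scale_array_to_8bit(image.pixels, image.bit_depth)


def erode_with_padding(mask: np.ndarray, diameter: int, pad: int) -> np.ndarray:
    """Erode a mask with a disk after padding a false border, then crop back.

    Equivalent to eroding the infinitely zero-padded mask and restricting to
    the frame, so wells truncated by the image edge keep their interior.
    """
    padded = np.pad(np.asarray(mask, bool), pad, mode="constant", constant_values=False)
    eroded = ndimage.binary_erosion(padded, structure=disk_footprint(diameter))
    return eroded[pad:-pad, pad:-pad] if pad else eroded


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component."""
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return np.zeros_like(np.asarray(mask, bool))
    areas = np.bincount(labels.ravel())[1:]
    return labels == (int(np.argmax(areas)) + 1)


def find_well(image: FullWellImage, config: PipelineConfig | None = None) -> WellMask:
    """Locate the well in a full-well brightfield image.

    Raises
    ------
    WellFindingError
        If thresholding yields no foreground at all.
    """
    config = config or PipelineConfig()
    blurred = gaussian_blur(image.pixels, config.blur_well)
    img8 = _scale_array_to_8bit(blurred, image.bit_depth)

    hist = np.bincount(img8.ravel(), minlength=256)
    try:
        otsu = otsu_with_effectiveness(hist)
    except OtsuError as err:
        raise WellFindingError(
            f"no well found in {image.well_id or 'image'}: featureless image"
        ) from err
    cut = int(round(otsu.level * config.F * 255))
    fg = img8 > cut
    if not fg.any():
        raise WellFindingError(f"no well found in {image.well_id or 'image'}: empty threshold")

    filled = ndimage.binary_fill_holes(fg)
    well = largest_component(filled)
    eroded = erode_with_padding(well, config.erode_diameter, config.pad_border)
    if not eroded.any():
        raise WellFindingError(
            f"no well found in {image.well_id or 'image'}: erosion removed all foreground"
        )
    # erosion of a connected set can disconnect; keep the largest piece
    eroded = largest_component(eroded)
    area = int(eroded.sum())
    suspicious = area > 0.5 * eroded.size
    return WellMask(eroded, area, suspicious)
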