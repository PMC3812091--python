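"""Image and table I/O: field tiling, TIFF reading, plate layouts.

Raw microscope fields are 12-bit data stored in 16-bit TIFF containers, one
or more fields per well.  Fields are assembled into a single full-well image
by block tiling (row-major by default, no overlap or registration); the
declared bit depth is carried as metadata and pixels are never rescaled on
load.  Coordinates are (row, col), 0-based, origin top-left, throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

CHANNELS = ("brightfield", "blue_AF", "green_AF", "nile_red", "lipid_stain")

LAYOUT_COLUMNS = ["well_id", "rnai_clone", "strain", "dye", "replicate_index", "is_control"]


@dataclass(frozen=True)
class FullWellImage:
    """One tiled image of one well in one channel.

    ``pixels`` is a 2-D nonnegative integer array; ``bit_depth`` is the
    dynamic range actually used (e.g. 12), ``container_depth`` the storage
    depth (8 or 16).  All pixel values are < 2**bit_depth.
    """

    pixels: np.ndarray
    bit_depth: int
    container_depth: int
    channel: str
    well_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {px.shape}")
        if not np.issubdtype(px.dtype, np.integer):
            raise TypeError(f"pixels must be integer-typed, got {px.dtype}")
        if px.size and px.min() < 0:
            raise ValueError("pixels must be nonnegative")
        if self.bit_depth not in (8, 12, 16):
            raise ValueError(f"bit_depth must be 8, 12 or 16, got {self.bit_depth}")
        if self.container_depth not in (8, 16):
            raise ValueError(f"container_depth must be 8 or 16, got {self.container_depth}")
        if self.bit_depth > self.container_depth:
            raise ValueError("bit_depth cannot exceed container_depth")
        if px.size and px.max() >= 2 ** self.bit_depth:
            raise ValueError(
                f"pixel value {px.max()} out of declared {self.bit_depth}-bit range"
            )
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass(frozen=True)
class PlateLayout:
    """Well -> (RNAi clone, strain, dye, replicate, control flag) mapping."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"plate layout missing columns: {missing}")
        if df["well_id"].duplicated().any():
            dups = sorted(df.loc[df["well_id"].duplicated(), "well_id"].unique())
            raise ValueError(f"duplicate well_ids in plate layout: {dups}")
        if not df["is_control"].any():
            raise ValueError("plate layout has no control wells")
        if (df["replicate_index"] < 1).any():
            raise ValueError("replicate_index must be >= 1")

    @property
    def controls(self) -> pd.DataFrame:
        return self.table[self.table["is_control"]]


def tile_fields(
    fields: Sequence[np.ndarray],
    grid_shape: tuple[int, int],
    *,
    bit_depth: int = 12,
    container_depth: int = 16,
    channel: str = "brightfield",
    well_id: str = "",
    order: str = "row-major",
) -> FullWellImage:
    """Assemble raw field images into one full-well image by block tiling.

    Field ``i`` occupies block ``(i // cols, i % cols)`` in row-major order
    (or ``(i % rows, i // rows)`` column-major).  Pixel values are copied
    unmodified.

    Raises
    ------
    ValueError
        If field dimensions differ or ``len(fields) != rows*cols``.
    """
    rows, cols = grid_shape
    if len(fields) != rows * cols:
        raise ValueError(f"expected {rows * cols} fields for a {rows}x{cols} grid, got {len(fields)}")
    arrs = [np.asarray(f) for f in fields]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"fields have mismatched dimensions: {sorted(shapes)}")
    fh, fw = arrs[0].shape
    out = np.zeros((rows * fh, cols * fw), dtype=arrs[0].dtype)
    for i, a in enumerate(arrs):
        r, c = (i // cols, i % cols) if order == "row-major" else (i % rows, i // rows)
        out[r * fh : (r + 1) * fh, c * fw : (c + 1) * fw] = a
    return FullWellImage(out, bit_depth, container_depth, channel, well_id)


def extract_field(image: FullWellImage, grid_shape: tuple[int, int], r: int, c: int) -> np.ndarray:
    """Return the (r, c) field block of a tiled full-well image."""
    rows, cols = grid_shape
    h, w = image.shape
    fh, fw = h // rows, w // cols
    return image.pixels[r * fh : (r + 1) * fh, c * fw : (c + 1) * fw]


def load_image(
    path: str | Path,
    declared_bit_depth: int,
    *,
    channel: str = "brightfield",
    well_id: str = "",
) -> FullWellImage:
    """Read a single-page grayscale TIFF, validating the declared dynamic range.

    Values exceeding ``2**declared_bit_depth - 1`` raise a ValueError; pixels
    are kept exactly as stored (no rescaling).
    """
    px = tifffile.imread(str(path))
    if px.ndim != 2:
        raise ValueError(f"{path}: expected single-page grayscale TIFF, got shape {px.shape}")
    container_depth = px.dtype.itemsize * 8
    if container_depth not in (8, 16):
        raise ValueError(f"{path}: unsupported container depth {container_depth}")
    if px.size and px.max() >= 2 ** declared_bit_depth:
        raise ValueError(
            f"{path}: max pixel {px.max()} exceeds declared {declared_bit_depth}-bit range"
        )
    return FullWellImage(px, declared_bit_depth, container_depth, channel, well_id)


def write_image(image: FullWellImage, path: str | Path) -> None:
    """Write a full-well image losslessly to TIFF in its container depth."""
    dtype = np.uint8 if image.container_depth == 8 else np.uint16
    tifffile.imwrite(str(path), image.pixels.astype(dtype))


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as an 8-bit (0/255) image."""
    tifffile.imwrite(str(path), np.where(np.asarray(mask, bool), 255, 0).astype(np.uint8))


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)) > 0


def read_plate_layout(path: str | Path) -> PlateLayout:
    """Parse and validate a plate-layout CSV.

    Required columns: ``well_id,rnai_clone,strain,dye,replicate_index,is_control``.
    """
    df = pd.read_csv(path)
    missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: plate layout missing columns: {missing}")
    if df["is_control"].dtype == object:
        df["is_control"] = df["is_control"].astype(str).str.strip().str.lower().isin(
            ("1", "true", "yes")
        )
    else:
        df["is_control"] = df["is_control"].astype(bool)
    df["replicate_index"] = df["replicate_index"].astype(int)
    return PlateLayout(df[LAYOUT_COLUMNS].copy())
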