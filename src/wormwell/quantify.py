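"""Per-mask intensity summaries on the fluorescence channel.

For each of the objects, junk and background masks the intensity histogram,
mean, median and a configurable percentile (default the 90th, the statistic
exported to screen tables) are computed over exactly the masked pixels.
Because the background intensity is well approximated by a narrow normal
distribution, adjusted estimates are reported for objects and junk by
subtracting the background mean; adjusted values may be negative (dim
objects over bright background) and are reported unclipped, with a flag, so
downstream fold changes stay linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imaging_io import FullWellImage
from .object_finder import SegmentationResult


class EmptyMaskError(ValueError):
    """Statistics requested over an empty mask are undefined (never zero)."""


@dataclass(frozen=True)
class MaskStats:
    n_pixels: int
    histogram: np.ndarray  # counts per native intensity bin (2**bit_depth bins)
    mean: float
    median: float
    percentile: float  # value at the requested percentile


@dataclass(frozen=True)
class IntensitySummary:
    """Raw and background-adjusted intensity statistics for one well/channel."""

    well_id: str
    channel: str
    percentile_rank: float
    objects: MaskStats | None
    junk: MaskStats | None
    background: MaskStats | None
    adjusted: dict  # {"objects": {"mean":..,"median":..,"percentile":..}, "junk": {...}}
    flags: frozenset[str]

    @property
    def masks(self) -> dict:
        return {"objects": self.objects, "junk": self.junk, "background": self.background}

    def to_long_frame(self) -> pd.DataFrame:
        """Long-form export: well_id, channel, mask, stat, value."""
        rows = []
        for name, st in self.masks.items():
            if st is None:
                continue
            rows += [
                {"well_id": self.well_id, "channel": self.channel, "mask": name,
                 "stat": "n_pixels", "value": st.n_pixels},
                {"well_id": self.well_id, "channel": self.channel, "mask": name,
                 "stat": "mean", "value": st.mean},
                {"well_id": self.well_id, "channel": self.channel, "mask": name,
                 "stat": "median", "value": st.median},
                {"well_id": self.well_id, "channel": self.channel, "mask": name,
                 "stat": f"p{self.percentile_rank:g}", "value": st.percentile},
            ]
        for name, st in self.adjusted.items():
            for stat, value in st.items():
                label = f"p{self.percentile_rank:g}" if stat == "percentile" else stat
                rows.append(
                    {"well_id": self.well_id, "channel": self.channel, "mask": name,
                     "stat": f"adjusted_{label}", "value": value}
                )
        return pd.DataFrame(rows, columns=["well_id", "channel", "mask", "stat", "value"])


def mask_summary(
    fluor: FullWellImage, mask: np.ndarray, percentile: float = 90.0
) -> MaskStats:
    """Histogram, mean, median and percentile over exactly the masked pixels.

    The percentile uses linear interpolation between order statistics
    (quantile type 7); the histogram is binned at native integer resolution
    (256 bins for 8-bit data, 4096 for 12-bit).

    Raises
    ------
    EmptyMaskError
        If the mask selects no pixels.
    """
    m = np.asarray(mask, bool)
    if not m.any():
        raise EmptyMaskError("cannot summarize an empty mask")
    values = fluor.pixels[m]
    hist = np.bincount(values, minlength=2**fluor.bit_depth)
    return MaskStats(
        n_pixels=int(values.size),
        histogram=hist,
        mean=float(values.mean()),
        median=float(np.median(values)),
        percentile=float(np.percentile(values, percentile)),
    )


def summarize_well(
    fluor: FullWellImage,
    seg: SegmentationResult,
    percentile: float = 90.0,
) -> IntensitySummary:
    """Per-mask summaries plus background-adjusted object/junk statistics.

    Adjusted statistics subtract the background mean from the raw object and
    junk statistics (exactly; shifts of the whole image cancel out).  Empty
    masks yield missing statistics, never zeros, and an empty objects mask
    adds the low_object_count flag.
    """
    if fluor.pixels.shape != seg.well_mask.shape:
        raise ValueError("fluorescence image and segmentation shapes differ")
    flags = set(seg.flags)
    stats: dict[str, MaskStats | None] = {}
    for name, mask in (
        ("objects", seg.objects_mask),
        ("junk", seg.junk_mask),
        ("background", seg.background_mask),
    ):
        try:
            stats[name] = mask_summary(fluor, mask, percentile)
        except EmptyMaskError:
            stats[name] = None
            if name == "objects":
                flags.add("low_object_count")

    adjusted: dict[str, dict[str, float]] = {}
    bg = stats["background"]
    if bg is not None:
        for name in ("objects", "junk"):
            st = stats[name]
            if st is None:
                continue
            adj = {
                "mean": st.mean - bg.mean,
                "median": st.median - bg.mean,
                "percentile": st.percentile - bg.mean,
            }
            if any(v < 0 for v in adj.values()):
                flags.add("negative_adjusted")
            adjusted[name] = adj
    if flags:
        flags.add("manual_review")
    return IntensitySummary(
        well_id=fluor.well_id,
        channel=fluor.channel,
        percentile_rank=percentile,
        objects=stats["objects"],
        junk=stats["junk"],
        background=stats["background"],
        adjusted=adjusted,
        flags=frozenset(flags),
    )


def well_screen_value(summary: IntensitySummary, mask: str = "objects") -> float:
    """The per-well statistic exported to screen tables.

    Default: background-adjusted 90th-percentile intensity of the objects
    mask.  Returns NaN (a recorded missing value) when the mask was empty.
    """
    if mask not in summary.adjusted:
        return float("nan")
    return summary.adjusted[mask]["percentile"]
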