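"""Pipeline configuration.

All tunable parameters of the segmentation/quantification pipeline live in
:class:`PipelineConfig`.  The defaults encode the published operating point
of the assay: an empirical threshold bias F of 0.9, an Otsu-effectiveness
trigger of 0.7 below which the boxplot-outlier segmentation is added, a
whisker multiplier of 3 (about 4.7 sigma for normal background), a 30 px
well blur/erosion scale, a 20 px bottom-hat disk and 1% intensity
saturation, all at 25x magnification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass(frozen=True)
class PipelineConfig:
    """Parameters of the well-finding, object-finding and quantification stages.

    Parameters
    ----------
    F : float
        Empirical threshold factor in (0, 1].  Well finding thresholds at
        ``L*F``; object finding at ``1 - F*(1-L)`` where ``L`` is the
        normalized Otsu level.  Values below 1 bias both operations toward
        fewer false-positive foreground pixels.
    E_min : float
        Minimum acceptable Otsu effectiveness (between-class over total
        variance).  Below this the outlier segmentation is triggered in
        addition to the threshold segmentation.
    L_min : float
        Minimum acceptable normalized Otsu level; below it the threshold
        is considered unreliable and the outlier path is triggered.
    whisker : float
        Boxplot whisker multiplier: outlier pixels exceed Q3 + whisker*IQR.
    blur_well : int
        Side of the square Gaussian kernel used to blur the brightfield
        image before well thresholding (sigma = blur_well / 6).
    erode_diameter : int
        Diameter (px) of the disk used to erode the well mask.
    pad_border : int
        Width (px) of the false border padded around the well mask before
        erosion, restored afterwards, to avoid rim loss at image edges.
    bothat_diameter : int
        Diameter (px) of the bottom-hat disk structuring element.
    closure_diameter : int
        Diameter (px) of the closure disk applied after thresholding.
    saturation : float
        Fraction of pixels saturated when rescaling to 8 bit before Otsu.
    blur_outlier : int
        Side of the Gaussian kernel used by the outlier method.
    size_limits_threshold, size_limits_outlier, size_limits_small : (int, int)
        Inclusive [min, max] component areas (px) accepted as objects by the
        threshold, outlier and small-object size filters.
    small_region_trigger : int
        If the largest foreground component is smaller than this, the
        small-object size filter is applied instead.
    min_objects : int
        Fewer object regions than this raises the low_object_count flag.
    junk_ratio_max : float
        junk area / object area above this raises the high_junk_ratio flag.
    summary_percentile : float
        Percentile reported by the intensity summaries (default 90).
    tile_order : str
        "row-major" (default) or "column-major" field tiling.
    two_sided_outliers : bool
        If True the outlier method also flags the low tail
        (below Q1 - whisker*IQR); default one-sided high tail, because
        bottom-hat foreground is bright.
    """

    F: float = 0.9
    E_min: float = 0.7
    L_min: float = 0.05
    whisker: float = 3.0
    blur_well: int = 30
    erode_diameter: int = 30
    pad_border: int = 30
    bothat_diameter: int = 20
    closure_diameter: int = 3
    saturation: float = 0.01
    blur_outlier: int = 3
    size_limits_threshold: tuple[int, int] = (100, 50000)
    size_limits_outlier: tuple[int, int] = (30, 50000)
    size_limits_small: tuple[int, int] = (15, 2000)
    small_region_trigger: int = 300
    min_objects: int = 1
    junk_ratio_max: float = 5.0
    summary_percentile: float = 90.0
    tile_order: str = "row-major"
    two_sided_outliers: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.F <= 1):
            raise ValueError(f"F must be in (0, 1], got {self.F}")
        if not (0 <= self.E_min <= 1):
            raise ValueError(f"E_min must be in [0, 1], got {self.E_min}")
        if self.whisker <= 0:
            raise ValueError(f"whisker must be > 0, got {self.whisker}")
        if not (0 <= self.saturation < 1):
            raise ValueError(f"saturation must be in [0, 1), got {self.saturation}")
        for name in ("size_limits_threshold", "size_limits_outlier", "size_limits_small"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"{name}: min {lo} must be < max {hi}")
        if self.size_limits_outlier[0] > self.size_limits_threshold[0]:
            raise ValueError("outlier size minimum must not exceed the threshold minimum")
        if self.tile_order not in ("row-major", "column-major"):
            raise ValueError(f"tile_order must be row-major or column-major, got {self.tile_order!r}")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        for k in ("size_limits_threshold", "size_limits_outlier", "size_limits_small"):
            d[k] = list(d[k])
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        d = json.loads(Path(path).read_text())
        for k in ("size_limits_threshold", "size_limits_outlier", "size_limits_small"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)
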