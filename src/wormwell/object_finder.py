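"""Object finding: segment a well into objects (worms), junk and background.

The brightfield well image is bottom-hat filtered with a 20 px disk so that
dark worms become bright peaks on a flattened background, rescaled to 1%
saturation, quantized to 8 bits, and thresholded with Otsu's method applied
to the well region only.  When the Otsu level L and its effectiveness E
(between-class over total variance) are adequate, the threshold method cuts
at 1 - F*(1-L) with F = 0.9, biasing against false-positive object pixels;
when E is low (< 0.7) a boxplot-outlier method (blur, then flag pixels
beyond Q3 + 3*IQR, about 4.7 sigma for normal background) is added.
Connected regions are then size-filtered: regions inside the limits are
objects, regions that passed thresholding but fail the size filter are
junk, everything else in the well is background.  If the largest region is
very small a separate small-object size filter is used, so the threshold,
outlier and small-object paths progressively detect smaller worms while
still rejecting eggs and debris.  The three masks are exclusive and their
union is the well mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._morph import disk_footprint, gaussian_blur
from .config import PipelineConfig
from .imaging_io import FullWellImage

_EIGHT = np.ones((3, 3), bool)

FLAGS = (
    "low_effectiveness",
    "low_level",
    "low_object_count",
    "high_junk_ratio",
    "degenerate_range",
    "degenerate_spread",
    "manual_review",
)


class OtsuError(ValueError):
    """Otsu effectiveness is undefined (zero total variance)."""


@dataclass(frozen=True)
class OtsuResult:
    """Normalized Otsu level L in [0, 1] and effectiveness E = sigma2_between / sigma2_total."""

    level: float
    effectiveness: float


@dataclass(frozen=True)
class SegmentationResult:
    """Three exclusive masks whose union is the well mask, plus provenance."""

    objects_mask: np.ndarray
    junk_mask: np.ndarray
    background_mask: np.ndarray
    method: str  # "threshold" | "outlier" | "small_object"
    otsu: OtsuResult | None
    flags: frozenset[str]
    region_table: pd.DataFrame

    def __post_init__(self) -> None:
        o = np.asarray(self.objects_mask, bool)
        j = np.asarray(self.junk_mask, bool)
        b = np.asarray(self.background_mask, bool)
        if (o & j).any() or (o & b).any() or (j & b).any():
            raise ValueError("segmentation masks must be pairwise disjoint")
        object.__setattr__(self, "objects_mask", o)
        object.__setattr__(self, "junk_mask", j)
        object.__setattr__(self, "background_mask", b)
        object.__setattr__(self, "flags", frozenset(self.flags))

    @property
    def well_mask(self) -> np.ndarray:
        return self.objects_mask | self.junk_mask | self.background_mask


def bottom_hat(image: np.ndarray, diameter: float) -> np.ndarray:
    """Morphological closing minus the image, with a disk structuring element.

    Dark features narrower than the disk become bright peaks; the result is
    everywhere nonnegative and zero on constant images.
    """
    img = np.asarray(image)
    closed = ndimage.grey_closing(img, footprint=disk_footprint(diameter), mode="nearest")
    return closed - img


def saturate_and_quantize(
    image: np.ndarray, saturation: float
) -> tuple[np.ndarray, bool]:
    """Rescale so a `saturation` fraction of pixels clips at 255, quantize to 8 bits.

    The (1 - saturation) quantile q of the pixel values maps to 255 and the
    minimum to 0 (values above q clip).  Returns ``(image8, degenerate)``
    where ``degenerate`` is True for a constant (zero-range) image, which
    maps to all zeros.
    """
    if not (0 <= saturation < 1):
        raise ValueError(f"saturation must be in [0, 1), got {saturation}")
    img = np.asarray(image, dtype=float)
    lo = img.min()
    q = np.quantile(img, 1.0 - saturation)
    if q <= lo:
        return np.zeros(img.shape, dtype=np.uint8), True
    scaled = (img - lo) * (255.0 / (q - lo))
    out = np.minimum(np.floor(scaled + 1e-9), 255.0)
    return out.astype(np.uint8), False


def otsu_with_effectiveness(histogram: np.ndarray) -> OtsuResult:
    """Exhaustive Otsu threshold on a 256-bin histogram, with effectiveness.

    All 255 candidate cuts t (classes [0..t] and [t+1..255]) are scanned for
    maximal between-class variance; ties break to the lowest cut.  The level
    is returned normalized (t / 255) and the effectiveness is the maximized
    between-class variance divided by the total variance.

    Raises
    ------
    OtsuError
        If the histogram has zero total variance (all mass in one bin).
    """
    h = np.asarray(histogram, dtype=float)
    if h.shape != (256,):
        raise ValueError(f"expected a 256-bin histogram, got shape {h.shape}")
    total = h.sum()
    if total <= 0:
        raise ValueError("histogram is empty")
    p = h / total
    bins = np.arange(256, dtype=float)
    mu_total = float(np.dot(p, bins))
    var_total = float(np.dot(p, (bins - mu_total) ** 2))
    if var_total == 0:
        raise OtsuError("zero total variance: effectiveness undefined")

    w0 = np.cumsum(p)[:-1]  # weight of class [0..t], t = 0..254
    m0 = np.cumsum(p * bins)[:-1]  # unnormalized class-0 mean
    w1 = 1.0 - w0
    valid = (w0 > 0) & (w1 > 0)
    between = np.zeros(255)
    between[valid] = (mu_total * w0[valid] - m0[valid]) ** 2 / (w0[valid] * w1[valid])
    t = int(np.argmax(between))  # argmax returns the lowest maximizing cut
    return OtsuResult(level=t / 255.0, effectiveness=float(between[t] / var_total))


def threshold_segment(
    image8: np.ndarray,
    well_mask: np.ndarray,
    otsu: OtsuResult,
    F: float,
    closure_diameter: int = 3,
) -> np.ndarray:
    """Threshold at 1 - F*(1-L) (8-bit units, strictly greater), then close.

    F < 1 lowers the false-positive rate of object identification at the
    cost of some object area.  A morphological closure with a small disk
    removes pinholes.  Pixels outside the well are always False.
    """
    if not (0 < F <= 1):
        raise ValueError(f"F must be in (0, 1], got {F}")
    well = np.asarray(well_mask, bool)
    cut = int(round((1.0 - F * (1.0 - otsu.level)) * 255))
    fg = (np.asarray(image8) > cut) & well
    if fg.any():
        fg = ndimage.binary_closing(fg, structure=disk_footprint(closure_diameter))
    return fg & well


def outlier_segment(
    image: np.ndarray,
    well_mask: np.ndarray,
    whisker: float = 3.0,
    blur_kernel: int = 3,
    two_sided: bool = False,
) -> tuple[np.ndarray, bool]:
    """Flag pixels beyond the boxplot whisker as foreground.

    The image is blurred with a small Gaussian, quartiles are computed over
    the well pixels (linear interpolation between order statistics), and
    pixels above Q3 + whisker*IQR are foreground (for normal data with
    whisker 3 this cut sits ~4.7 sigma above the mean).  Returns
    ``(mask, degenerate)``; a zero IQR yields an empty mask with the
    degenerate flag set.
    """
    if whisker <= 0:
        raise ValueError(f"whisker must be > 0, got {whisker}")
    well = np.asarray(well_mask, bool)
    blurred = gaussian_blur(image, blur_kernel)
    vals = blurred[well]
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    if iqr == 0:
        return np.zeros_like(well), True
    fg = (blurred > q3 + whisker * iqr) & well
    if two_sided:
        fg |= (blurred < q1 - whisker * iqr) & well
    return fg, False


def classify_regions(
    foreground: np.ndarray,
    well_mask: np.ndarray,
    limits: tuple[int, int],
    small_limits: tuple[int, int],
    small_region_trigger: int,
    *,
    method: str = "threshold",
    otsu: OtsuResult | None = None,
    extra_flags: frozenset[str] | set[str] = frozenset(),
    config: PipelineConfig | None = None,
) -> SegmentationResult:
    """Size-filter connected foreground regions into objects and junk.

    8-connected components with min <= area <= max become objects; components
    outside the limits become junk; the remaining well pixels are background.
    If the largest component is smaller than ``small_region_trigger`` the
    small-object limits are applied instead and the method is recorded as
    ``small_object``.
    """
    config = config or PipelineConfig()
    well = np.asarray(well_mask, bool)
    fg = np.asarray(foreground, bool) & well
    labels, n = ndimage.label(fg, structure=_EIGHT)
    areas = np.bincount(labels.ravel())[1:] if n else np.array([], dtype=int)

    lo, hi = limits
    if n and areas.max() < small_region_trigger:
        lo, hi = small_limits
        method = "small_object"

    keep = np.zeros(n + 1, dtype=bool)
    rows = []
    if n:
        slices = ndimage.find_objects(labels)
        for i in range(1, n + 1):
            area = int(areas[i - 1])
            is_obj = lo <= area <= hi
            keep[i] = is_obj
            sl = slices[i - 1]
            rows.append(
                {
                    "id": i,
                    "area_px": area,
                    "min_row": sl[0].start,
                    "min_col": sl[1].start,
                    "max_row": sl[0].stop - 1,
                    "max_col": sl[1].stop - 1,
                    "class": "object" if is_obj else "junk",
                }
            )
    objects = keep[labels]
    junk = fg & ~objects
    background = well & ~fg

    flags = set(extra_flags)
    n_objects = int(keep.sum())
    if n_objects < config.min_objects:
        flags.add("low_object_count")
    obj_area = int(objects.sum())
    junk_area = int(junk.sum())
    if junk_area and (obj_area == 0 or junk_area / obj_area > config.junk_ratio_max):
        flags.add("high_junk_ratio")
    if flags:
        flags.add("manual_review")

    table = pd.DataFrame(
        rows, columns=["id", "area_px", "min_row", "min_col", "max_row", "max_col", "class"]
    )
    return SegmentationResult(objects, junk, background, method, otsu, frozenset(flags), table)


def segment_well(
    brightfield: FullWellImage,
    well,
    config: PipelineConfig | None = None,
) -> SegmentationResult:
    """Run the full object-finding cascade on one well.

    ``well`` may be a WellMask or a boolean array.  The brightfield image is
    bottom-hat filtered, saturated/quantized to 8 bits, and Otsu-thresholded
    over the well pixels; the outlier method is added when the level or
    effectiveness is inadequate, and classification uses the size limits of
    the most permissive method that fired.  QC flags mark low effectiveness
    or level, low object count and high junk-to-object area; any flag also
    sets manual_review.
    """
    config = config or PipelineConfig()
    well_mask = np.asarray(getattr(well, "mask", well), bool)
    if not well_mask.any():
        raise ValueError("well mask is empty")

    bh = bottom_hat(brightfield.pixels, config.bothat_diameter)
    img8, degenerate = saturate_and_quantize(bh, config.saturation)

    flags: set[str] = set()
    if degenerate:
        flags.add("degenerate_range")

    hist = np.bincount(img8[well_mask], minlength=256)
    try:
        otsu = otsu_with_effectiveness(hist)
    except OtsuError:
        # featureless well: everything is background, fully flagged
        empty = np.zeros_like(well_mask)
        table = pd.DataFrame(
            columns=["id", "area_px", "min_row", "min_col", "max_row", "max_col", "class"]
        )
        flags |= {"low_effectiveness", "low_level", "low_object_count", "manual_review"}
        return SegmentationResult(
            empty, empty.copy(), well_mask.copy(), "threshold", None, frozenset(flags), table
        )

    if otsu.effectiveness < config.E_min:
        flags.add("low_effectiveness")
    if otsu.level < config.L_min:
        flags.add("low_level")
    adequate = otsu.effectiveness >= config.E_min and otsu.level >= config.L_min

    if adequate:
        fg = threshold_segment(img8, well_mask, otsu, config.F, config.closure_diameter)
        method = "threshold"
        limits = config.size_limits_threshold
    else:
        # an inadequate Otsu level makes the threshold mask unreliable, so
        # the outlier method replaces it; it runs on the un-quantized
        # bottom-hat image, where the whisker cut is ~4.7 sigma of the
        # (approximately normal) background
        fg, spread_degenerate = outlier_segment(
            bh, well_mask, config.whisker, config.blur_outlier, config.two_sided_outliers
        )
        if spread_degenerate:
            flags.add("degenerate_spread")
        method = "outlier"
        limits = config.size_limits_outlier

    return classify_regions(
        fg,
        well_mask,
        limits,
        config.size_limits_small,
        config.small_region_trigger,
        method=method,
        otsu=otsu,
        extra_flags=flags,
        config=config,
    )
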