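"""Phantom wells and simulated screens with known ground truth.

The phantom generator emulates the assay's imaging geometry: a bright
circular well on a dark surround, dark elongated worm-like objects (smooth
random-walk spines dilated to constant-width tubes), small egg ellipses and
irregular debris blobs, Gaussian background noise and a linear illumination
gradient, in 12-bit intensities inside a 16-bit container.  A paired
fluorescence channel draws worms at a known mean over a known normal
background so segmentation and quantification can be scored against truth.
The screen simulator produces long-form gene x strain x replicate tables
with multiplicative log-normal noise and planted fold-change effects, and a
profile generator plants cluster structure for model-selection tests.  All
generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._morph import disk_footprint
from .imaging_io import FullWellImage
from .screen_stats import ScreenTable


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity model of a synthetic well.

    Defaults describe a single-field 12-bit well at the assay's 25x scale
    factor-of-few downsampled: a 160 px radius well holding a handful of
    adult worms (60-120 px long, 5-9 px wide tubes), a few eggs and debris
    specks, background N(2800, 60) with a 300-count linear illumination
    gradient across the brightfield frame.  Worms are 0.45x background in
    brightfield (dark) and mean 3400 in fluorescence (bright).
    """

    shape: tuple[int, int] = (360, 360)
    well_radius: int = 160
    n_worms: int = 5
    worm_length: tuple[int, int] = (60, 120)
    worm_width: tuple[int, int] = (5, 9)
    worm_darkness: float = 0.45
    worm_fluor_mean: float = 3400.0
    n_eggs: int = 6
    egg_radii: tuple[int, int] = (2, 5)
    n_debris: int = 4
    debris_size: tuple[int, int] = (10, 60)
    junk_darkness: float = 0.6
    junk_fluor_mean: float = 3000.0
    background_mean: float = 2800.0
    background_sd: float = 60.0
    gradient_amplitude: float = 300.0
    outside_fraction: float = 0.15
    bit_depth: int = 12
    fluor_channel: str = "nile_red"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.worm_fluor_mean <= self.background_mean:
            raise ValueError("worm fluorescence mean must exceed the background mean")
        if self.well_radius * 2 >= min(self.shape):
            raise ValueError("well does not fit in the image")


@dataclass(frozen=True)
class Phantom:
    """A phantom well with its ground-truth masks."""

    brightfield: FullWellImage
    fluorescence: FullWellImage
    worm_mask: np.ndarray
    junk_mask: np.ndarray
    well_mask: np.ndarray


@dataclass(frozen=True)
class ScreenSimSpec:
    """Design of a simulated replicate screen.

    value = baseline * fold * exp(N(0, noise_sd**2)); control wells have
    fold 1.  ``effects`` maps gene -> fold (scalar, applied in every
    strain) or gene -> {strain: fold}.  The default design mirrors the
    primary screen: 571 RNAi clones in one sensitized strain, 6 biological
    replicates per clone and per vector control.
    """

    n_genes: int = 571
    strains: tuple = ("eri-1",)
    n_replicates: int = 6
    n_control_replicates: int = 6
    baseline: float = 1000.0
    effects: dict = field(default_factory=dict)
    noise_sd: float = 0.2
    control_label: str = "control"
    seed: int = 0

    def __post_init__(self) -> None:
        for gene, eff in self.effects.items():
            folds = eff.values() if isinstance(eff, dict) else [eff]
            if any(f <= 0 for f in folds):
                raise ValueError(f"planted fold for {gene!r} must be > 0")


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def _worm_spine(rng, length: int, r_max: float, center) -> np.ndarray:
    """Smooth random-walk spine: unit steps with small heading noise, kept in the well."""
    start_r = rng.uniform(0, r_max * 0.7)
    start_a = rng.uniform(0, 2 * np.pi)
    pos = np.array(center, float) + start_r * np.array([np.cos(start_a), np.sin(start_a)])
    heading = rng.uniform(0, 2 * np.pi)
    pts = [pos.copy()]
    for _ in range(length):
        heading += rng.normal(0, 0.12)
        step = np.array([np.cos(heading), np.sin(heading)])
        nxt = pos + step
        if np.hypot(*(nxt - center)) > r_max:  # bounce off the well rim
            heading += np.pi / 2
            nxt = pos + np.array([np.cos(heading), np.sin(heading)])
        pos = nxt
        pts.append(pos.copy())
    spine = np.array(pts)
    # cubic-like smoothing of the coordinates
    for axis in range(2):
        spine[:, axis] = ndimage.uniform_filter1d(spine[:, axis], size=7, mode="nearest")
    return spine


def _rasterize_tube(spine: np.ndarray, width: int, shape) -> np.ndarray:
    mask = np.zeros(shape, bool)
    idx = np.round(spine).astype(int)
    idx[:, 0] = np.clip(idx[:, 0], 0, shape[0] - 1)
    idx[:, 1] = np.clip(idx[:, 1], 0, shape[1] - 1)
    mask[idx[:, 0], idx[:, 1]] = True
    return ndimage.binary_dilation(mask, structure=disk_footprint(width))


def generate_well_phantom(spec: PhantomSpec | None = None, seed: int | None = None) -> Phantom:
    """Generate one phantom well pair (brightfield + fluorescence) with truth masks.

    Deterministic for a fixed (spec, seed); ``seed`` overrides ``spec.seed``.

    Raises
    ------
    ValueError
        If the requested worms cannot plausibly fit in the well.
    """
    spec = spec or PhantomSpec()
    rng = _rng(spec.seed if seed is None else seed)
    h, w = spec.shape
    center = np.array([h / 2, w / 2])
    yy, xx = np.mgrid[0:h, 0:w]
    well = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= spec.well_radius**2

    mean_worm_area = np.mean(spec.worm_length) * np.mean(spec.worm_width)
    if spec.n_worms * mean_worm_area > 0.5 * well.sum():
        raise ValueError(f"cannot pack {spec.n_worms} worms into the well")

    margin = max(spec.worm_width) + 2
    worm_mask = np.zeros(spec.shape, bool)
    for _ in range(spec.n_worms):
        length = int(rng.integers(spec.worm_length[0], spec.worm_length[1] + 1))
        width = int(rng.integers(spec.worm_width[0], spec.worm_width[1] + 1))
        spine = _worm_spine(rng, length, spec.well_radius - margin, center)
        worm_mask |= _rasterize_tube(spine, width, spec.shape)
    worm_mask &= well

    # eggs and debris are kept clear of the worms so the ground-truth
    # object/junk distinction stays well defined (touching components would
    # merge under 8-connectivity and make the truth labels ambiguous)
    worm_halo = ndimage.binary_dilation(worm_mask, structure=disk_footprint(5))
    junk_mask = np.zeros(spec.shape, bool)
    for _ in range(spec.n_eggs):
        for _attempt in range(50):
            r = rng.uniform(0, spec.well_radius - max(spec.egg_radii) - 2)
            a = rng.uniform(0, 2 * np.pi)
            cy, cx = center + r * np.array([np.cos(a), np.sin(a)])
            ry = rng.integers(spec.egg_radii[0], spec.egg_radii[1] + 1)
            rx = rng.integers(spec.egg_radii[0], spec.egg_radii[1] + 1)
            egg = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1
            if not (egg & worm_halo).any():
                junk_mask |= egg
                break
    for _ in range(spec.n_debris):
        # irregular blob: a short dilated random walk, trimmed to the
        # requested size range
        for _attempt in range(50):
            target = int(rng.integers(spec.debris_size[0], spec.debris_size[1] + 1))
            r = rng.uniform(0, spec.well_radius - 8)
            a = rng.uniform(0, 2 * np.pi)
            pos = center + r * np.array([np.cos(a), np.sin(a)])
            blob = np.zeros(spec.shape, bool)
            for _ in range(max(1, target // 9)):
                iy, ix = np.clip(np.round(pos).astype(int), 0, [h - 1, w - 1])
                blob[iy, ix] = True
                pos = pos + rng.normal(0, 1.2, size=2)
            blob = ndimage.binary_dilation(blob, structure=disk_footprint(3))
            if blob.sum() > spec.debris_size[1]:
                keep = np.flatnonzero(blob.ravel())[: spec.debris_size[1]]
                trimmed = np.zeros(blob.size, bool)
                trimmed[keep] = True
                blob = trimmed.reshape(blob.shape)
            if not (blob & worm_halo).any():
                junk_mask |= blob
                break
    junk_mask &= well & ~worm_mask

    max_val = 2**spec.bit_depth - 1
    grad_dir = rng.uniform(0, 2 * np.pi)
    gradient = spec.gradient_amplitude * (
        ((xx - w / 2) * np.cos(grad_dir) + (yy - h / 2) * np.sin(grad_dir)) / max(h, w)
    )

    bf = np.full(spec.shape, spec.background_mean * spec.outside_fraction)
    bf[well] = spec.background_mean
    bf = bf + gradient
    bf[worm_mask] = spec.background_mean * spec.worm_darkness
    bf[junk_mask] = spec.background_mean * spec.junk_darkness
    bf = bf + rng.normal(0, spec.background_sd, spec.shape)
    bf = np.clip(np.round(bf), 0, max_val).astype(np.uint16)

    fl = np.full(spec.shape, spec.background_mean * spec.outside_fraction)
    fl[well] = spec.background_mean
    fl[worm_mask] = spec.worm_fluor_mean
    fl[junk_mask] = spec.junk_fluor_mean
    fl = fl + rng.normal(0, spec.background_sd, spec.shape)
    fl = np.clip(np.round(fl), 0, max_val).astype(np.uint16)

    return Phantom(
        brightfield=FullWellImage(bf, spec.bit_depth, 16, "brightfield", "A01"),
        fluorescence=FullWellImage(fl, spec.bit_depth, 16, spec.fluor_channel, "A01"),
        worm_mask=worm_mask,
        junk_mask=junk_mask,
        well_mask=well,
    )


def generate_screen_table(
    spec: ScreenSimSpec | None = None, seed: int | None = None
) -> tuple[ScreenTable, pd.DataFrame]:
    """Simulate a replicate screen table with planted effects.

    Returns the ScreenTable and a truth frame (gene, strain, fold,
    is_hit).  Deterministic for fixed (spec, seed).
    """
    spec = spec or ScreenSimSpec()
    rng = _rng(spec.seed if seed is None else seed)
    genes = [f"gene{i:04d}" for i in range(spec.n_genes)]
    rows, truth = [], []
    for strain in spec.strains:
        for rep in range(1, spec.n_control_replicates + 1):
            value = spec.baseline * float(np.exp(rng.normal(0, spec.noise_sd)))
            rows.append({"gene": spec.control_label, "strain": strain,
                         "replicate": rep, "value": value})
        for gene in genes:
            eff = spec.effects.get(gene, 1.0)
            fold = float(eff.get(strain, 1.0) if isinstance(eff, dict) else eff)
            truth.append({"gene": gene, "strain": strain, "fold": fold,
                          "is_hit": fold != 1.0})
            for rep in range(1, spec.n_replicates + 1):
                value = spec.baseline * fold * float(np.exp(rng.normal(0, spec.noise_sd)))
                rows.append({"gene": gene, "strain": strain,
                             "replicate": rep, "value": value})
    table = ScreenTable(pd.DataFrame(rows), control_label=spec.control_label)
    return table, pd.DataFrame(truth)


def planted_hit_spec(
    n_genes: int = 571,
    n_hits: int = 40,
    effect_sds: float = 3.0,
    noise_sd: float = 0.2,
    n_replicates: int = 6,
    n_control_replicates: int = 6,
    seed: int = 0,
    both_directions: bool = True,
) -> ScreenSimSpec:
    """A screen design with ``n_hits`` genes shifted by ``effect_sds`` noise SDs.

    The planted fold is exp(effect_sds * noise_sd) (alternating up/down when
    ``both_directions``), i.e. a mean shift of ``effect_sds`` standard
    deviations on the log scale where the noise is exactly normal.
    """
    rng = _rng(seed)
    hit_idx = rng.choice(n_genes, size=n_hits, replace=False)
    effects = {}
    for i, g in enumerate(sorted(hit_idx)):
        sign = -1 if (both_directions and i % 2) else 1
        effects[f"gene{g:04d}"] = float(np.exp(sign * effect_sds * noise_sd))
    return ScreenSimSpec(
        n_genes=n_genes, n_replicates=n_replicates,
        n_control_replicates=n_control_replicates,
        effects=effects, noise_sd=noise_sd, seed=seed,
    )


def generate_clustered_profiles(
    n_genes: int = 79,
    n_conditions: int = 7,
    k: int = 10,
    separation: float = 10.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Gene profiles with planted cluster structure.

    Cluster centroids are drawn (rejection-sampled) at pairwise Euclidean
    distance >= separation; each gene is its cluster centroid plus isotropic
    N(0, noise_sd**2) noise.  Returns (matrix, labels in [1, k]).
    """
    if k > n_genes:
        raise ValueError(f"k={k} exceeds n_genes={n_genes}")
    rng = _rng(seed)
    # near-equidistant centroids (repulsion on a sphere, then rescaled so the
    # minimum pairwise distance equals the separation).  For a regular
    # simplex the between-centroid sum of squares is linear in the number of
    # clusters, so the wss curve breaks sharply at the planted k; loosely
    # scattered centroids would hide the break under large-scale structure.
    if k == 1:
        centroids = np.zeros((1, n_conditions))
    else:
        u = rng.normal(size=(k, n_conditions))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        for _ in range(300):
            diff = u[:, None, :] - u[None, :, :]
            dist = np.linalg.norm(diff, axis=2)
            np.fill_diagonal(dist, np.inf)
            force = (diff / dist[:, :, None] ** 3).sum(axis=1)
            u += 0.1 * force
            u /= np.linalg.norm(u, axis=1, keepdims=True)
        dist = np.linalg.norm(u[:, None, :] - u[None, :, :], axis=2)
        np.fill_diagonal(dist, np.inf)
        centroids = u * (max(separation, 1e-9) / dist.min())
    labels = np.arange(n_genes) % k  # balanced cluster sizes
    rng.shuffle(labels)
    X = centroids[labels] + rng.normal(0, noise_sd, (n_genes, n_conditions))
    matrix = pd.DataFrame(
        X,
        index=[f"gene{i:03d}" for i in range(n_genes)],
        columns=[f"cond{j}" for j in range(n_conditions)],
    )
    return matrix, labels + 1
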