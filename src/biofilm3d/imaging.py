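"""Fluorescence image formation and surrogate confidence maps.

Turns a cell arrangement into a realistic photon-count volume: fluorescence
emitters are placed inside cell volumes (cytosolic labeling) or on cell
surfaces (membrane staining), convolved with a 3D point-spread function,
scaled to a target signal-to-background ratio, and corrupted with Poisson
counting noise plus Gaussian camera read-out noise.  The module also carries
the raw-data processing steps (constant background subtraction and
Richardson–Lucy deconvolution) and a surrogate confidence-map generator that
stands in for a voxel-classification CNN so that the post-processing and
evaluation stages can be exercised against exact ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage import restoration

from .arrangement import CellArrangement, GridSpec, InstanceMap, LabelMap, instances_to_classmap

__all__ = [
    "EmitterSet",
    "PSFModel",
    "NoiseModel",
    "ImageVolume",
    "ConfidenceMap",
    "place_fluorophores",
    "synthesize_psf",
    "load_psf",
    "render_noiseless",
    "sbr_masks",
    "calibrate_sbr",
    "add_noise",
    "richardson_lucy",
    "subtract_background",
    "surrogate_confidence",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class EmitterSet:
    """Point fluorophores with per-emitter cell attribution.

    ``positions`` is (n, 3) in µm (z, y, x); ``cell_ids`` is (n,) and
    ``modes`` maps each cell to its labeling mode.
    """

    positions: np.ndarray
    cell_ids: np.ndarray
    modes: dict[int, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class PSFModel:
    """A 3D point-spread function kernel with its voxel size."""

    kernel: np.ndarray
    voxel_size: tuple[float, float, float]
    provenance: str = "synthetic"

    def __post_init__(self):
        k = np.asarray(self.kernel, dtype=float)
        if k.ndim != 3:
            raise ValueError("PSF kernel must be 3D")
        if np.any(k < 0):
            raise ValueError("PSF kernel must be non-negative")
        s = k.sum()
        if s <= 0:
            raise ValueError("PSF kernel must have positive total weight")
        if any(d % 2 == 0 for d in k.shape):
            raise ValueError("PSF kernel extents must be odd along every axis")
        self.kernel = k / s


@dataclass(frozen=True)
class NoiseModel:
    """Constant photon background plus camera read noise.

    Defaults follow typical lattice light-sheet acquisition conditions:
    ~200 background photons per voxel and a read-noise standard deviation of
    3.04 photons.
    """

    background: float = 200.0
    read_noise_sd: float = 3.04
    seed: int = 0

    def __post_init__(self):
        if self.background < 0 or self.read_noise_sd < 0:
            raise ValueError("background and read_noise_sd must be non-negative")


@dataclass
class ImageVolume:
    """A 3D photon-count volume on a grid."""

    voxels: np.ndarray
    grid: GridSpec
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.shape != self.grid.shape:
            raise ValueError("voxels shape does not match grid")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("image contains non-finite values")


@dataclass
class ConfidenceMap:
    """Per-class [0, 1] confidence volumes, channel order bg, int₁, bnd₁[, int₂, bnd₂]."""

    values: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4 or self.values.shape[0] not in (3, 5):
            raise ValueError("confidence maps must be (3 or 5, nz, ny, nx)")
        if self.values.shape[1:] != self.grid.shape:
            raise ValueError("confidence shape does not match grid")
        sums = self.values.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            raise ValueError(
                "per-voxel class confidences must sum to 1 within 1e-3; "
                "renormalize the channels before constructing a ConfidenceMap"
            )

    @property
    def n_classes(self) -> int:
        return self.values.shape[0]

    def interior(self, population: int = 1) -> np.ndarray:
        return self.values[2 * population - 1]

    def boundary(self, population: int = 1) -> np.ndarray:
        return self.values[2 * population]


# ---------------------------------------------------------------------------
# emitters


def place_fluorophores(
    arr: CellArrangement,
    mode: str | Mapping[int, str] = "interior",
    count_range: tuple[int, int] = (500, 1000),
    seed: int = 0,
) -> EmitterSet:
    """Place random fluorescence emitters in or on each cell.

    Per cell the emitter count is uniform in ``count_range`` (inclusive),
    emulating expression-level variation.  ``mode`` is ``"interior"``
    (cytosolic fluorophores, uniform in the cell volume), ``"membrane"``
    (uniform on the cell surface) or ``"both"``, either globally or as a
    mapping from population label to mode.
    """
    lo, hi = count_range
    if not (0 < lo <= hi):
        raise ValueError("count_range must satisfy 0 < min <= max")
    rng = np.random.default_rng(seed)
    positions = []
    cell_ids = []
    modes: dict[int, str] = {}
    for cell in arr.cells:
        m = mode if isinstance(mode, str) else mode.get(cell.population, "interior")
        if m not in ("interior", "membrane", "both"):
            raise ValueError(f"unknown labeling mode {m!r}")
        modes[cell.cell_id] = m
        parts = []
        if m in ("interior", "both"):
            n = int(rng.integers(lo, hi + 1))
            parts.append(cell.sample_interior(n, rng))
        if m in ("membrane", "both"):
            n = int(rng.integers(lo, hi + 1))
            parts.append(cell.sample_surface(n, rng))
        pts = np.vstack(parts)
        positions.append(pts)
        cell_ids.append(np.full(len(pts), cell.cell_id, dtype=np.int32))
    if positions:
        positions = np.vstack(positions)
        cell_ids = np.concatenate(cell_ids)
    else:
        positions = np.zeros((0, 3))
        cell_ids = np.zeros(0, dtype=np.int32)
    return EmitterSet(positions=positions, cell_ids=cell_ids, modes=modes)


# ---------------------------------------------------------------------------
# PSF


def synthesize_psf(
    fwhm_lateral: float = 0.23,
    fwhm_axial: float = 0.57,
    voxel_size: Sequence[float] = (0.1, 0.1, 0.1),
    truncate: float = 4.0,
) -> PSFModel:
    """Anisotropic 3D Gaussian PSF.

    Defaults model a diffraction-limited microscope with ~230 nm lateral and
    570 nm axial full width at half maximum; each fluorophore is treated as
    an isotropic point emitter.  The kernel has odd extents and sums to 1.
    """
    if fwhm_lateral <= 0 or fwhm_axial <= 0:
        raise ValueError("FWHM values must be positive")
    vs = np.asarray(voxel_size, dtype=float)
    sigma = np.array([fwhm_axial, fwhm_lateral, fwhm_lateral]) * FWHM_TO_SIGMA / vs
    half = np.maximum(np.ceil(truncate * sigma).astype(int), 1)
    zz, yy, xx = np.meshgrid(
        *[np.arange(-h, h + 1) for h in half], indexing="ij"
    )
    arg = (zz / sigma[0]) ** 2 + (yy / sigma[1]) ** 2 + (xx / sigma[2]) ** 2
    kernel = np.exp(-0.5 * arg)
    return PSFModel(kernel=kernel, voxel_size=tuple(vs), provenance="synthetic")


def load_psf(path, voxel_size: Sequence[float] = (0.1, 0.1, 0.1)) -> PSFModel:
    """Load a measured 3D PSF from a TIFF stack and renormalize it.

    Even extents are trimmed by one trailing plane to satisfy the odd-extent
    requirement; negative values or an all-zero kernel raise a format error.
    """
    import tifffile

    kernel = np.asarray(tifffile.imread(str(path)), dtype=float)
    if kernel.ndim == 2:
        kernel = kernel[None]
    if kernel.ndim != 3:
        raise ValueError(f"PSF file must hold a 3D stack, got shape {kernel.shape}")
    if np.any(kernel < 0):
        raise ValueError("PSF file contains negative values")
    if kernel.sum() <= 0:
        raise ValueError("PSF file is all-zero")
    slices = tuple(slice(0, d - 1 if d % 2 == 0 else d) for d in kernel.shape)
    kernel = kernel[slices]
    return PSFModel(kernel=kernel, voxel_size=tuple(float(v) for v in voxel_size),
                    provenance="measured-file")


# ---------------------------------------------------------------------------
# rendering


def render_noiseless(
    emitters: EmitterSet,
    psf: PSFModel,
    grid: GridSpec,
    photons_per_emitter: float = 1.0,
) -> ImageVolume:
    """Bin emitters onto the grid and convolve with the PSF.

    Convolution uses zero-padded boundaries; flux lost over the volume edge
    is reported in ``meta["edge_loss"]`` (relative) rather than hidden.
    """
    if tuple(psf.voxel_size) != tuple(grid.voxel_size):
        raise ValueError(
            f"PSF voxel size {psf.voxel_size} does not match grid "
            f"{grid.voxel_size}; resample the PSF first"
        )
    counts = np.zeros(grid.shape, dtype=float)
    n_out = 0
    if len(emitters):
        idx = np.floor(
            (emitters.positions - np.asarray(grid.origin)) / np.asarray(grid.voxel_size)
        ).astype(int)
        inside = np.all((idx >= 0) & (idx < np.asarray(grid.shape)), axis=1)
        n_out = int((~inside).sum())
        if n_out:
            warnings.warn(f"{n_out} emitter(s) fall outside the grid", stacklevel=2)
        np.add.at(counts, tuple(idx[inside].T), 1.0)
    counts *= photons_per_emitter
    total_in = counts.sum()
    out = fftconvolve(counts, psf.kernel, mode="same")
    np.clip(out, 0.0, None, out=out)
    edge_loss = 0.0 if total_in == 0 else float(1.0 - out.sum() / total_in)
    if edge_loss > 1e-3:
        warnings.warn(f"{edge_loss:.2%} of flux lost over the volume edge", stacklevel=2)
    return ImageVolume(voxels=out, grid=grid, meta={"edge_loss": edge_loss, "n_clipped_emitters": n_out})


def sbr_masks(
    noiseless: ImageVolume,
    truth: InstanceMap,
    background_margin_voxels: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Automated signal/background region proxy for SBR work.

    Signal voxels lie inside ground-truth cells with noiseless intensity
    above the median in-cell intensity (a deterministic stand-in for
    manually selected bright signal regions); background voxels lie farther
    than ``background_margin_voxels`` from any cell.
    """
    cells = np.asarray(truth.labels) > 0
    if not cells.any():
        raise ValueError("truth contains no cells")
    in_cell = noiseless.voxels[cells]
    signal = cells & (noiseless.voxels > np.median(in_cell))
    background = ndimage.distance_transform_edt(~cells) > background_margin_voxels
    if not background.any():
        raise ValueError(
            "no background region farther than the margin from cells; enlarge the grid"
        )
    return signal, background


def calibrate_sbr(
    noiseless: ImageVolume,
    truth: InstanceMap,
    noise: NoiseModel,
    target_sbr: float,
) -> float:
    """Closed-form signal scale factor reaching a target SBR.

    Solves mean(scale·signal + background) / background = target over the
    automated signal region, enabling independent adjustment of fluorescence
    signal and background.
    """
    if target_sbr <= 1:
        raise ValueError("target_sbr must exceed 1")
    if noise.background <= 0:
        raise ValueError("SBR calibration requires a positive background")
    signal, _ = sbr_masks(noiseless, truth)
    mean_sig = float(noiseless.voxels[signal].mean())
    if mean_sig <= 0:
        raise ValueError("noiseless image has no signal in the signal region")
    return noise.background * (target_sbr - 1.0) / mean_sig


def add_noise(image: ImageVolume, noise: NoiseModel, clip: bool = True) -> ImageVolume:
    """Poisson counting noise on signal + background, plus Gaussian read noise.

    ``clip=False`` keeps the raw signed counts (as in dark-frame read-noise
    calibration, where the camera offset is subtracted before clipping);
    with a realistic background the clip never engages.
    """
    if np.any(image.voxels < 0):
        raise ValueError("expected a non-negative photon image")
    rng = np.random.default_rng(noise.seed)
    lam = image.voxels + noise.background
    out = rng.poisson(lam).astype(float)
    if noise.read_noise_sd > 0:
        out += rng.normal(0.0, noise.read_noise_sd, size=out.shape)
    if clip:
        np.clip(out, 0.0, None, out=out)
    meta = dict(image.meta)
    meta["noise"] = {"background": noise.background, "read_noise_sd": noise.read_noise_sd}
    return ImageVolume(voxels=out, grid=image.grid, meta=meta)


def richardson_lucy(image: ImageVolume, psf: PSFModel, iterations: int = 10) -> ImageVolume:
    """Richardson–Lucy deconvolution (ten iterations by default)."""
    if iterations < 1:
        raise ValueError("iterations must be at least 1")
    out = restoration.richardson_lucy(
        image.voxels, psf.kernel, num_iter=iterations, clip=False, filter_epsilon=1e-12
    )
    np.clip(out, 0.0, None, out=out)
    return ImageVolume(voxels=out, grid=image.grid, meta=dict(image.meta))


def subtract_background(
    image: ImageVolume,
    dark_mask: np.ndarray | None = None,
    percentile: float | None = None,
) -> ImageVolume:
    """Subtract a constant background estimated from dark areas.

    The constant is the mean intensity over ``dark_mask`` (areas devoid of
    cells); alternatively ``percentile`` selects the darkest voxels (those
    at or below that intensity percentile) automatically.  Output is clipped
    at zero.
    """
    if dark_mask is None:
        if percentile is None:
            percentile = 20.0
        thresh = np.percentile(image.voxels, percentile)
        dark_mask = image.voxels <= thresh
    dark_mask = np.asarray(dark_mask, dtype=bool)
    if not dark_mask.any():
        raise ValueError("dark region is empty")
    constant = float(image.voxels[dark_mask].mean())
    out = np.clip(image.voxels - constant, 0.0, None)
    meta = dict(image.meta)
    meta["background_estimate"] = constant
    return ImageVolume(voxels=out, grid=image.grid, meta=meta)


# ---------------------------------------------------------------------------
# surrogate confidence maps


def surrogate_confidence(
    inst: InstanceMap,
    populations: Mapping[int, int] | None = None,
    blur_sd: float = 1.0,
    flip_noise: float = 0.0,
    seed: int = 0,
    boundary_thickness: int = 1,
    sharpness: float = 3.0,
) -> ConfidenceMap:
    """Emulate CNN voxel-classification output from ground truth.

    The exact class map is one-hot encoded, each class channel is smoothed
    with a Gaussian of ``blur_sd`` voxels (imitating classifier uncertainty
    at class transitions), per-voxel confidences are sharpened by raising
    them to ``sharpness`` before renormalization (Dice-trained voxel
    classifiers saturate: confidence plateaus near 1 inside a class and
    drops steeply at transitions), and a ``flip_noise`` fraction of voxels
    is reassigned full background confidence.  Degenerate parameters
    (blur 0, flip 0) reproduce the one-hot map.
    """
    if not 0 <= flip_noise < 1:
        raise ValueError("flip_noise must lie in [0, 1)")
    if sharpness <= 0:
        raise ValueError("sharpness must be positive")
    classmap = instances_to_classmap(inst, populations, boundary_thickness)
    has_pop2 = bool(classmap.classes.max() > 2)
    n_classes = 5 if has_pop2 else 3
    values = np.zeros((n_classes,) + inst.grid.shape, dtype=float)
    for c in range(n_classes):
        values[c] = classmap.classes == c
    if blur_sd > 0:
        for c in range(n_classes):
            values[c] = ndimage.gaussian_filter(values[c], sigma=blur_sd)
        if sharpness != 1.0:
            np.power(values, sharpness, out=values)
    if flip_noise > 0:
        rng = np.random.default_rng(seed)
        flip = rng.random(inst.grid.shape) < flip_noise
        values[:, flip] = 0.0
        values[0, flip] = 1.0
    total = values.sum(axis=0)
    total[total == 0] = 1.0
    values /= total
    return ConfidenceMap(values=values, grid=inst.grid)
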