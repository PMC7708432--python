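"""Individual-based biofilm cell arrangements.

Generates stochastic 3D arrangements of spherocylindrical cells by a minimal
individual-based growth model (elongation, volume-threshold division, and
pairwise overlap relaxation), rescales arrangements to a target volume
density, and rasterizes them into exact voxel-level ground-truth annotation
maps (instance labels and background / cell-interior / cell-boundary class
maps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import (
    Spherocylinder,
    random_unit_vector,
    segment_segment_distance,
)

__all__ = [
    "GridSpec",
    "GrowthParams",
    "CellArrangement",
    "InstanceMap",
    "LabelMap",
    "SPECIES_PRESETS",
    "grow_biofilm",
    "rescale_density",
    "calibrate_density",
    "substitute_population",
    "rasterize_instances",
    "instances_to_classmap",
]


@dataclass(frozen=True)
class GridSpec:
    """A regular 3D voxel grid.

    ``shape`` is (nz, ny, nx); ``voxel_size`` is (dz, dy, dx) in µm;
    ``origin`` is the (z, y, x) position of the low corner of the volume.
    Default voxel size is isotropic 100 nm.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError("shape must be three positive integers")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive reals")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in self.voxel_size))
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates along one axis (0=z, 1=y, 2=x), µm."""
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.voxel_size[axis]

    @property
    def extent(self) -> np.ndarray:
        """(3, 2) world-coordinate bounds of the grid, µm."""
        lo = np.asarray(self.origin)
        hi = lo + np.asarray(self.shape) * np.asarray(self.voxel_size)
        return np.stack([lo, hi], axis=1)

    @classmethod
    def from_bounds(
        cls,
        bounds: np.ndarray,
        voxel_size: Sequence[float] = (0.1, 0.1, 0.1),
        margin: float = 0.0,
    ) -> "GridSpec":
        """Smallest grid of the given voxel size covering ``bounds`` (+margin)."""
        bounds = np.asarray(bounds, dtype=float)
        lo = bounds[:, 0] - margin
        hi = bounds[:, 1] + margin
        vs = np.asarray(voxel_size, dtype=float)
        shape = tuple(int(np.ceil((hi[i] - lo[i]) / vs[i])) for i in range(3))
        shape = tuple(max(1, s) for s in shape)
        return cls(shape=shape, voxel_size=tuple(vs), origin=tuple(lo))


@dataclass
class InstanceMap:
    """Integer-labeled 3D volume: one positive label per cell, 0 background."""

    labels: np.ndarray
    grid: GridSpec
    populations: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise ValueError("labels shape does not match grid")

    @property
    def n_objects(self) -> int:
        return int(np.count_nonzero(np.unique(self.labels)))

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class LabelMap:
    """Per-voxel class annotation map.

    Classes are 0 = background and, per population ``p``, ``2p - 1`` = cell
    interior and ``2p`` = cell boundary, so {0, 1, 2} for one population and
    {0, 1, 2, 3, 4} for two.
    """

    classes: np.ndarray
    grid: GridSpec

    @property
    def n_classes(self) -> int:
        return int(self.classes.max()) + 1 if self.classes.size else 1


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the individual-based growth model.

    ``division_length`` is the tip-to-tip cell length at which division is
    triggered (with multiplicative jitter drawn per cell at birth); the
    corresponding cylinder-segment threshold is ``division_length - diameter``.
    """

    diameter: float = 1.0
    division_length: float = 3.0
    elongation_rate: float = 0.2
    division_jitter: float = 0.1
    max_cells: int = 300
    min_gap: float = 0.0
    overlap_tolerance: float = 0.05
    relax_iterations: int = 30
    orientation_jitter_deg: float = 5.0
    max_steps: int = 2000
    # colony compaction per growth step: centroids contract laterally toward
    # the colony axis by this factor before overlap relaxation, mimicking the
    # adhesion that keeps real colonies jammed and dense
    compaction_factor: float = 0.97
    compaction_cycles: int = 3
    # surface attachment: cells settle onto the z = 0 substrate plane each
    # step, producing the flat, laterally spreading colonies of
    # coverslip-grown biofilms
    substrate: bool = True
    settling_step: float = 0.2

    def __post_init__(self):
        if self.diameter <= 0 or self.division_length <= 0:
            raise ValueError("cell dimensions must be positive")
        if self.division_length <= self.diameter:
            raise ValueError("division_length must exceed the diameter (positive cylinder segment)")
        if self.elongation_rate < 0:
            raise ValueError("elongation_rate must be non-negative")
        if self.max_cells < 1:
            raise ValueError("max_cells must be at least 1")


#: (diameter, tip-to-tip division length) in µm for common species shapes.
SPECIES_PRESETS: dict[str, GrowthParams] = {
    "e_coli": GrowthParams(diameter=1.0, division_length=3.0),
    "m_xanthus": GrowthParams(diameter=0.7, division_length=6.0),
    "s_aureus": GrowthParams(diameter=1.0, division_length=1.95, elongation_rate=0.1),
}


@dataclass
class CellArrangement:
    """An ordered collection of spherocylinder cells with an enclosing box."""

    cells: list[Spherocylinder]
    bounds: np.ndarray = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.bounds is None:
            self.bounds = self.tight_bounds()
        self.bounds = np.asarray(self.bounds, dtype=float)
        ids = [c.cell_id for c in self.cells]
        if len(ids) != len(set(ids)):
            raise ValueError("cell_id values must be unique within an arrangement")

    def __len__(self) -> int:
        return len(self.cells)

    @property
    def centroids(self) -> np.ndarray:
        if not self.cells:
            return np.zeros((0, 3))
        return np.array([c.centroid for c in self.cells])

    @property
    def total_cell_volume(self) -> float:
        return float(sum(c.volume for c in self.cells))

    def tight_bounds(self, margin: float = 0.0) -> np.ndarray:
        """Axis-aligned box just containing every cell surface (+margin)."""
        if not self.cells:
            return np.array([[0.0, 1.0]] * 3)
        lo = np.full(3, np.inf)
        hi = np.full(3, -np.inf)
        for c in self.cells:
            reach = np.abs(c.axis) * (0.5 * c.length) + c.radius
            lo = np.minimum(lo, c.centroid - reach)
            hi = np.maximum(hi, c.centroid + reach)
        return np.stack([lo - margin, hi + margin], axis=1)

    def surface_overlaps(self, cutoff: float = 0.0) -> list[tuple[int, int, float]]:
        """Pairs of cells whose surfaces overlap by more than ``cutoff`` µm.

        Returns (cell_id_i, cell_id_j, overlap) sorted by decreasing overlap.
        """
        cells = self.cells
        n = len(cells)
        if n < 2:
            return []
        cen = self.centroids
        reach = np.array([0.5 * c.length + c.radius for c in cells])
        tree = cKDTree(cen)
        pairs = sorted(tree.query_pairs(r=2.0 * float(reach.max()) + 1e-9))
        if not pairs:
            return []
        ii = np.array([p[0] for p in pairs])
        jj = np.array([p[1] for p in pairs])
        p0 = np.array([cells[i].endpoints[0] for i in ii])
        p1 = np.array([cells[i].endpoints[1] for i in ii])
        q0 = np.array([cells[j].endpoints[0] for j in jj])
        q1 = np.array([cells[j].endpoints[1] for j in jj])
        dist, _, _ = segment_segment_distance(p0, p1, q0, q1)
        radii = np.array([c.radius for c in cells])
        overlap = radii[ii] + radii[jj] - dist
        out = [
            (cells[i].cell_id, cells[j].cell_id, float(o))
            for i, j, o in zip(ii, jj, overlap)
            if o > cutoff
        ]
        return sorted(out, key=lambda t: -t[2])


# ---------------------------------------------------------------------------
# growth


def _clamp_to_floor(
    centroids: np.ndarray, axes: np.ndarray, lengths: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Keep every cell surface above the z = 0 substrate plane."""
    min_z = np.abs(axes[:, 0]) * 0.5 * lengths + radii
    centroids[:, 0] = np.maximum(centroids[:, 0], min_z)
    return centroids


def _relax_overlaps(
    centroids: np.ndarray,
    axes: np.ndarray,
    lengths: np.ndarray,
    radii: np.ndarray,
    min_gap: float,
    iterations: int,
    rng: np.random.Generator,
    floor: bool = False,
) -> np.ndarray:
    """Iterated pairwise repulsion along the minimal-distance vector."""
    n = len(centroids)
    if floor:
        centroids = _clamp_to_floor(centroids.copy(), axes, lengths, radii)
    if n < 2:
        return centroids
    reach = 0.5 * lengths + radii
    search_r = 2.0 * float(reach.max()) + min_gap + 1e-9
    for _ in range(iterations):
        tree = cKDTree(centroids)
        pairs = sorted(tree.query_pairs(r=search_r))
        if not pairs:
            break
        ii = np.array([p[0] for p in pairs])
        jj = np.array([p[1] for p in pairs])
        h = (0.5 * lengths)[:, None] * axes
        p0, p1 = centroids[ii] - h[ii], centroids[ii] + h[ii]
        q0, q1 = centroids[jj] - h[jj], centroids[jj] + h[jj]
        dist, cp, cq = segment_segment_distance(p0, p1, q0, q1)
        overlap = radii[ii] + radii[jj] + min_gap - dist
        viol = overlap > 1e-9
        if not viol.any():
            break
        ii, jj = ii[viol], jj[viol]
        overlap = overlap[viol]
        sep = cp[viol] - cq[viol]
        norm = np.linalg.norm(sep, axis=1)
        degen = norm < 1e-12
        if degen.any():
            sep[degen] = random_unit_vector(rng, int(degen.sum()))
            norm[degen] = 1.0
        step = 0.5 * (overlap / norm)[:, None] * sep
        disp = np.zeros_like(centroids)
        np.add.at(disp, ii, step)
        np.add.at(disp, jj, -step)
        centroids = centroids + disp
        if floor:
            centroids = _clamp_to_floor(centroids, axes, lengths, radii)
    return centroids


def _jittered_axis(axis: np.ndarray, max_deg: float, rng: np.random.Generator) -> np.ndarray:
    tilt = np.tan(np.radians(max_deg)) * rng.random()
    v = axis + tilt * random_unit_vector(rng)
    return v / np.linalg.norm(v)


def grow_biofilm(
    params: GrowthParams,
    seed: int,
    n_steps: int | None = None,
    seed_cells: Sequence[Spherocylinder] | None = None,
) -> CellArrangement:
    """Simulate growth and division of rod-shaped cells in a colony.

    Each step every cell elongates by ``elongation_rate``; a cell whose
    cylinder segment exceeds its per-cell division threshold splits into two
    daughters that together conserve the parent's cylinder length, placed
    end-to-end along the (slightly jittered) parent axis.  Collisions caused
    by growth are alleviated by imposing a minimum-distance criterion through
    iterated pairwise repulsion.  Deterministic for a fixed seed.

    ``n_steps=None`` grows until ``params.max_cells`` is reached.
    """
    rng = np.random.default_rng(seed)
    r = 0.5 * params.diameter
    div_cyl = params.division_length - params.diameter  # cylinder length at division

    if seed_cells is None:
        axis0 = random_unit_vector(rng)
        if params.substrate:
            # surface-attached cells start lying in the substrate plane
            axis0[0] = 0.0
            nrm = np.linalg.norm(axis0)
            axis0 = axis0 / nrm if nrm > 0 else np.array([0.0, 0.0, 1.0])
        centroids = np.array([[r if params.substrate else 0.0, 0.0, 0.0]])
        axes = axis0[None, :]
        lengths = np.array([0.5 * div_cyl])
        populations = [1]
    else:
        centroids = np.array([c.centroid for c in seed_cells])
        axes = np.array([c.axis for c in seed_cells])
        lengths = np.array([c.length for c in seed_cells], dtype=float)
        populations = [c.population for c in seed_cells]

    def new_threshold() -> float:
        j = params.division_jitter
        return div_cyl * rng.uniform(1.0 - j, 1.0 + j)

    thresholds = np.array([new_threshold() for _ in range(len(centroids))])

    steps = params.max_steps if n_steps is None else n_steps
    for _ in range(steps):
        if n_steps is None and len(centroids) >= params.max_cells:
            break
        lengths = lengths + params.elongation_rate
        # divisions (in index order, deterministic)
        ready = np.flatnonzero(lengths >= thresholds)
        for idx in ready:
            if len(centroids) >= params.max_cells:
                break
            l_parent = lengths[idx]
            a = axes[idx]
            c = centroids[idx]
            half = 0.5 * l_parent
            a1 = _jittered_axis(a, params.orientation_jitter_deg, rng)
            a2 = _jittered_axis(a, params.orientation_jitter_deg, rng)
            # daughters occupy the two halves of the parent segment
            centroids[idx] = c - 0.25 * l_parent * a
            axes[idx] = a1
            lengths[idx] = half
            thresholds[idx] = new_threshold()
            centroids = np.vstack([centroids, c + 0.25 * l_parent * a])
            axes = np.vstack([axes, a2])
            lengths = np.append(lengths, half)
            thresholds = np.append(thresholds, new_threshold())
            populations.append(populations[idx])
        radii = np.full(len(centroids), r)
        if params.substrate and params.settling_step > 0:
            centroids[:, 0] -= params.settling_step
        centroids = _relax_overlaps(
            centroids, axes, lengths, radii, params.min_gap,
            params.relax_iterations, rng, floor=params.substrate,
        )
        for _ in range(params.compaction_cycles):
            if len(centroids) < 2:
                break
            center = centroids.mean(axis=0)
            shrink = np.array(
                [1.0 if params.substrate else params.compaction_factor,
                 params.compaction_factor, params.compaction_factor]
            )
            centroids = center + shrink * (centroids - center)
            centroids = _relax_overlaps(
                centroids, axes, lengths, radii, params.min_gap,
                params.relax_iterations, rng, floor=params.substrate,
            )
        if n_steps is None and len(centroids) >= params.max_cells:
            # final relaxation pass already applied above
            break

    if len(centroids) > 1:
        radii = np.full(len(centroids), r)
        # final compaction: squeeze the finished colony until jammed, then
        # relax cleanly; this reproduces the dense, touching arrangements of
        # mature colonies
        for _ in range(5 * params.compaction_cycles):
            center = centroids.mean(axis=0)
            shrink = np.array(
                [1.0 if params.substrate else params.compaction_factor,
                 params.compaction_factor, params.compaction_factor]
            )
            centroids = center + shrink * (centroids - center)
            if params.substrate and params.settling_step > 0:
                centroids[:, 0] -= params.settling_step
            centroids = _relax_overlaps(
                centroids, axes, lengths, radii, params.min_gap,
                params.relax_iterations, rng, floor=params.substrate,
            )
        centroids = _relax_overlaps(
            centroids, axes, lengths, radii,
            params.min_gap, 4 * params.relax_iterations, rng,
            floor=params.substrate,
        )

    cells = [
        Spherocylinder(
            cell_id=i + 1,
            centroid=centroids[i],
            axis=axes[i],
            length=float(lengths[i]),
            diameter=params.diameter,
            population=populations[i],
        )
        for i in range(len(centroids))
    ]
    arr = CellArrangement(cells=cells, rng_seed=seed)
    worst = arr.surface_overlaps(cutoff=params.overlap_tolerance)
    if worst:
        warnings.warn(
            f"relaxation left {len(worst)} cell pair(s) overlapping beyond "
            f"tolerance {params.overlap_tolerance} µm (max residual "
            f"{worst[0][2]:.3f} µm)",
            stacklevel=2,
        )
    return arr


# ---------------------------------------------------------------------------
# density rescaling / calibration


def rescale_density(
    arr: CellArrangement,
    scale_factor: float,
    hard_overlap_limit: float | None = None,
) -> CellArrangement:
    """Scale all intercellular distances by a constant factor.

    Cell centroids are scaled about the centroid of all cell centroids while
    cell sizes, shapes, and orientations are left unchanged, which adjusts
    the cellular volume density without altering the arrangement topology.
    """
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    if not arr.cells or scale_factor == 1.0:
        return CellArrangement(cells=list(arr.cells), rng_seed=arr.rng_seed)
    center = arr.centroids.mean(axis=0)
    cells = [
        c.with_centroid(center + scale_factor * (c.centroid - center)) for c in arr.cells
    ]
    out = CellArrangement(cells=cells, rng_seed=arr.rng_seed)
    if hard_overlap_limit is None:
        hard_overlap_limit = 0.5 * min(c.diameter for c in arr.cells)
    bad = out.surface_overlaps(cutoff=hard_overlap_limit)
    if bad:
        pairs = ", ".join(f"({i},{j}): {o:.3f} µm" for i, j, o in bad[:10])
        raise ValueError(
            f"scale_factor {scale_factor} drives {len(bad)} cell pair(s) past the "
            f"hard overlap limit {hard_overlap_limit} µm: {pairs}"
        )
    return out


class DensityResult(NamedTuple):
    arrangement: CellArrangement
    achieved_fraction: float
    scale_factor: float


def _density_of(
    arr: CellArrangement,
    voxel_size: Sequence[float],
    metric: str,
    tile_shape: tuple[int, int, int],
    top_k: int,
) -> float:
    grid = GridSpec.from_bounds(arr.tight_bounds(), voxel_size)
    mask = rasterize_instances(arr, grid).labels > 0
    if metric == "global":
        return float(mask.mean())
    from .evaluate import DensityParams, local_density

    return local_density(mask, DensityParams(tile_shape=tile_shape, top_k=top_k), clip_tile=True)


def calibrate_density(
    arr: CellArrangement,
    target_fraction: float,
    grid: GridSpec | Sequence[float] | None = None,
    tolerance: float = 0.02,
    metric: str = "local",
    tile_shape: tuple[int, int, int] = (8, 64, 64),
    top_k: int = 10,
    max_iter: int = 40,
) -> DensityResult:
    """Bisect the centroid scale factor to reach a target volume density.

    ``metric="local"`` (default) measures density the way it is reported for
    a dataset: the mean occupancy of the ``top_k`` densest
    ``tile_shape`` tiles of the rasterized cell mask.  ``metric="global"``
    uses the plain occupied-voxel fraction of the tight bounding box.
    ``grid`` supplies the rasterization voxel size (a GridSpec or a
    (dz, dy, dx) triple); the grid extent itself follows the rescaled
    arrangement at every bisection step.
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must lie in (0, 1)")
    if isinstance(grid, GridSpec):
        voxel_size = grid.voxel_size
    elif grid is None:
        voxel_size = (0.1, 0.1, 0.1)
    else:
        voxel_size = tuple(grid)

    def density(s: float) -> tuple[float, CellArrangement]:
        a = rescale_density(arr, s) if s != 1.0 else arr
        return _density_of(a, voxel_size, metric, tile_shape, top_k), a

    rho1, _ = density(1.0)
    if abs(rho1 - target_fraction) <= tolerance:
        return DensityResult(rescale_density(arr, 1.0), rho1, 1.0)

    # bracket the target: density decreases with increasing scale factor
    if rho1 > target_fraction:
        s_lo, rho_lo = 1.0, rho1
        s_hi = 1.0
        for _ in range(20):
            s_hi *= 1.3
            rho_hi, _ = density(s_hi)
            if rho_hi <= target_fraction:
                break
        else:
            raise ValueError(
                f"target {target_fraction} unachievable: density stays above "
                f"{rho_hi:.3f} even at scale {s_hi:.2f}"
            )
    else:
        s_hi, rho_hi = 1.0, rho1
        s_lo = 1.0
        rho_lo = rho1
        s_bad = None  # smallest scale found infeasible (overlap limit)
        for _ in range(40):
            s_next = s_lo / 1.06 if s_bad is None else 0.5 * (s_lo + s_bad)
            if s_bad is not None and (s_lo - s_bad) < 1e-3:
                break
            try:
                rho_next, _ = density(s_next)
            except ValueError:
                s_bad = s_next
                continue
            s_lo, rho_lo = s_next, rho_next
            if rho_lo >= target_fraction - tolerance:
                break
        if rho_lo < target_fraction - tolerance:
            raise ValueError(
                f"target {target_fraction} unachievable without violating the "
                f"overlap limit; densest feasible packing reaches "
                f"{rho_lo:.3f} (at scale {s_lo:.3f})"
            )

    best = None
    for _ in range(max_iter):
        s_mid = 0.5 * (s_lo + s_hi)
        rho_mid, a_mid = density(s_mid)
        if best is None or abs(rho_mid - target_fraction) < abs(best[1] - target_fraction):
            best = (s_mid, rho_mid, a_mid)
        if abs(rho_mid - target_fraction) <= tolerance:
            break
        if rho_mid > target_fraction:
            s_lo = s_mid
        else:
            s_hi = s_mid
    s_best, rho_best, a_best = best
    if abs(rho_best - target_fraction) > tolerance:
        warnings.warn(
            f"density calibration stopped at {rho_best:.3f} "
            f"(target {target_fraction}, tolerance {tolerance})",
            stacklevel=2,
        )
    return DensityResult(a_best, rho_best, s_best)


def substitute_population(
    arr: CellArrangement,
    fraction: float,
    new_shape: tuple[float, float],
    seed: int,
) -> CellArrangement:
    """Replace a random fraction of cells with population-2 cells.

    ``new_shape`` is (diameter, cylinder length) in µm, e.g. ``(1.0, 0.0)``
    for spherical cells.  The chosen cells keep their centroid and axis.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    new_d, new_l = new_shape
    n = len(arr.cells)
    k = int(round(fraction * n))
    rng = np.random.default_rng(seed)
    chosen = set(rng.choice(n, size=k, replace=False).tolist()) if k else set()
    cells = []
    for i, c in enumerate(arr.cells):
        if i in chosen:
            cells.append(
                replace(c, diameter=float(new_d), length=float(new_l), population=2)
            )
        else:
            cells.append(c)
    return CellArrangement(cells=cells, rng_seed=arr.rng_seed)


# ---------------------------------------------------------------------------
# rasterization


def rasterize_instances(arr: CellArrangement, grid: GridSpec) -> InstanceMap:
    """Label every voxel whose center lies inside a cell with that cell's id.

    Voxels claimed by several overlapping cells are resolved by the smaller
    distance to the claiming cell's axis, with the lower cell_id winning
    exact ties, so the result is deterministic.
    """
    labels = np.zeros(grid.shape, dtype=np.uint16)
    best = np.full(grid.shape, np.inf, dtype=np.float64)
    if arr.cells and max(c.cell_id for c in arr.cells) > np.iinfo(np.uint16).max:
        raise ValueError("cell_id exceeds uint16 label range")

    zc = grid.axis_centers(0)
    yc = grid.axis_centers(1)
    xc = grid.axis_centers(2)
    vs = np.asarray(grid.voxel_size)
    origin = np.asarray(grid.origin)
    extent = grid.extent
    clipped = 0

    for cell in sorted(arr.cells, key=lambda c: c.cell_id):
        reach = np.abs(cell.axis) * (0.5 * cell.length) + cell.radius
        lo_w = cell.centroid - reach
        hi_w = cell.centroid + reach
        if np.any(lo_w < extent[:, 0] - 1e-9) or np.any(hi_w > extent[:, 1] + 1e-9):
            clipped += 1
        lo = np.maximum(np.floor((lo_w - origin) / vs).astype(int) - 1, 0)
        hi = np.minimum(np.ceil((hi_w - origin) / vs).astype(int) + 1, grid.shape)
        if np.any(lo >= hi):
            continue
        sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        pts = np.stack(
            np.meshgrid(zc[sl[0]], yc[sl[1]], xc[sl[2]], indexing="ij"), axis=-1
        )
        shape = pts.shape[:3]
        dist = cell.axis_distance(pts.reshape(-1, 3)).reshape(shape)
        inside = dist <= cell.radius
        win = inside & (dist < best[sl])
        labels_view = labels[sl]
        best_view = best[sl]
        labels_view[win] = cell.cell_id
        best_view[win] = dist[win]

    if clipped:
        warnings.warn(f"{clipped} cell(s) extend outside the grid and were clipped", stacklevel=2)
    populations = {c.cell_id: c.population for c in arr.cells}
    return InstanceMap(labels=labels, grid=grid, populations=populations)


_EROSION_STRUCT = ndimage.generate_binary_structure(3, 1)


def instances_to_classmap(
    inst: InstanceMap,
    populations: Mapping[int, int] | None = None,
    boundary_thickness: int = 1,
) -> LabelMap:
    """Classify voxels as background, cell interior, or cell boundary.

    Per cell, the boundary class is the outermost shell of the given voxel
    thickness of that cell's voxel set and the interior is the remainder, so
    interior and boundary exactly partition each instance.  With two
    populations the classes are {0, interior₁=1, boundary₁=2, interior₂=3,
    boundary₂=4}.
    """
    if boundary_thickness < 1:
        raise ValueError("boundary_thickness must be at least 1")
    if populations is None:
        populations = inst.populations or {}
    classes = np.zeros(inst.grid.shape, dtype=np.uint8)
    objects = ndimage.find_objects(inst.labels)
    for label, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        mask = inst.labels[sl] == label
        interior = ndimage.binary_erosion(
            mask, structure=_EROSION_STRUCT, iterations=boundary_thickness,
            border_value=0,
        )
        pop = int(populations.get(label, 1))
        view = classes[sl]
        view[mask & ~interior] = 2 * pop
        view[interior] = 2 * pop - 1
    return LabelMap(classes=classes, grid=inst.grid)
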