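"""Quantitative segmentation evaluation.

Cell-level accuracy uses one-to-one IoU matching: a predicted object is a
true positive if it can be matched to a ground-truth object with
intersection-over-union above the matching threshold (0.5 by convention);
unmatched predictions are false positives, unmatched truth objects false
negatives, and counting accuracy is TP / (TP + FP + FN).  Voxel-level
accuracy is the mean IoU over all segmented objects, with unmatched
predictions contributing zero.  The module also provides the SBR estimator,
the top-tile local-density metric, and reconstruction of 3D cells from
manually traced 2D contour annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import linear_sum_assignment
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import Point, Polygon
from sklearn.cluster import DBSCAN

__all__ = [
    "MatchResult",
    "DensityParams",
    "AnnotationContour",
    "pair_iou",
    "match_instances",
    "counting_accuracy",
    "voxel_accuracy",
    "accuracy_curve",
    "estimate_sbr",
    "local_density",
    "group_annotation_contours",
]


def _label_array(x) -> np.ndarray:
    """Accept an InstanceMap or a plain integer array."""
    return np.asarray(getattr(x, "labels", x))


@dataclass
class MatchResult:
    """One-to-one matching between predicted and ground-truth objects."""

    pairs: list[tuple[int, int, float]]
    tp: int
    fp: int
    fn: int
    iou_threshold: float
    n_pred: int
    n_truth: int

    def __post_init__(self):
        assert self.tp == len(self.pairs)


def pair_iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection-over-union (Jaccard index) of two boolean masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    union = np.count_nonzero(a | b)
    if union == 0:
        warnings.warn("IoU of two empty masks is defined as 0", stacklevel=2)
        return 0.0
    inter = np.count_nonzero(a & b)
    return inter / union


def _iou_matrix(pred: np.ndarray, truth: np.ndarray):
    """Dense IoU matrix between pred and truth labels plus the label lists."""
    pred_ids = np.unique(pred)
    pred_ids = pred_ids[pred_ids > 0]
    truth_ids = np.unique(truth)
    truth_ids = truth_ids[truth_ids > 0]
    if pred_ids.size == 0 or truth_ids.size == 0:
        return np.zeros((pred_ids.size, truth_ids.size)), pred_ids, truth_ids

    pi = np.searchsorted(pred_ids, pred.ravel())
    ti = np.searchsorted(truth_ids, truth.ravel())
    both = (pred.ravel() > 0) & (truth.ravel() > 0)
    inter = coo_matrix(
        (np.ones(int(both.sum())), (pi[both], ti[both])),
        shape=(pred_ids.size, truth_ids.size),
    ).toarray()
    area_p = np.array([(pred == l).sum() for l in pred_ids], dtype=float)
    area_t = np.array([(truth == l).sum() for l in truth_ids], dtype=float)
    union = area_p[:, None] + area_t[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou, pred_ids, truth_ids


def match_instances(
    pred,
    truth,
    iou_threshold: float = 0.5,
    method: str = "optimal",
) -> MatchResult:
    """One-to-one matching of predicted to ground-truth objects.

    ``method="optimal"`` (default) solves the assignment problem maximizing
    total IoU over pairs at or above the threshold; ``method="greedy"``
    repeatedly takes the highest-IoU unmatched pair, for comparison.
    """
    if not 0 < iou_threshold < 1:
        raise ValueError("iou_threshold must lie in (0, 1)")
    pred = _label_array(pred)
    truth = _label_array(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must share a grid")
    iou, pred_ids, truth_ids = _iou_matrix(pred, truth)

    pairs: list[tuple[int, int, float]] = []
    if iou.size:
        eligible = np.where(iou >= iou_threshold, iou, 0.0)
        if method == "optimal":
            rows, cols = linear_sum_assignment(-eligible)
            for r, c in zip(rows, cols):
                if eligible[r, c] > 0:
                    pairs.append((int(pred_ids[r]), int(truth_ids[c]), float(iou[r, c])))
        elif method == "greedy":
            order = np.dstack(np.unravel_index(np.argsort(-eligible, axis=None), iou.shape))[0]
            used_r, used_c = set(), set()
            for r, c in order:
                if eligible[r, c] <= 0:
                    break
                if r in used_r or c in used_c:
                    continue
                used_r.add(r)
                used_c.add(c)
                pairs.append((int(pred_ids[r]), int(truth_ids[c]), float(iou[r, c])))
        else:
            raise ValueError(f"unknown matching method {method!r}")
    pairs.sort()
    tp = len(pairs)
    return MatchResult(
        pairs=pairs,
        tp=tp,
        fp=int(pred_ids.size - tp),
        fn=int(truth_ids.size - tp),
        iou_threshold=iou_threshold,
        n_pred=int(pred_ids.size),
        n_truth=int(truth_ids.size),
    )


def counting_accuracy(match: MatchResult) -> float:
    """Cell counting accuracy TP / (TP + FP + FN)."""
    denom = match.tp + match.fp + match.fn
    if denom == 0:
        raise ValueError("no objects in either map")
    return match.tp / denom


def voxel_accuracy(match: MatchResult) -> float:
    """Mean IoU over all segmented (predicted) objects.

    Unmatched predictions (false positives) contribute an IoU of zero;
    missed truth objects do not enter this average.
    """
    if match.n_pred == 0:
        warnings.warn("no predicted objects; voxel accuracy is 0", stacklevel=2)
        return 0.0
    return float(sum(iou for _, _, iou in match.pairs) / match.n_pred)


def accuracy_curve(pred, truth, thresholds: Sequence[float]) -> pd.DataFrame:
    """Counting accuracy as a function of the IoU matching threshold."""
    rows = []
    for t in thresholds:
        m = match_instances(pred, truth, iou_threshold=float(t))
        rows.append(
            {
                "iou_threshold": float(t),
                "tp": m.tp,
                "fp": m.fp,
                "fn": m.fn,
                "counting_accuracy": counting_accuracy(m),
                "voxel_accuracy": voxel_accuracy(m),
            }
        )
    return pd.DataFrame(rows)


def estimate_sbr(image, signal_mask: np.ndarray, background_mask: np.ndarray) -> float:
    """Mean signal intensity divided by mean background intensity."""
    voxels = np.asarray(getattr(image, "voxels", image), dtype=float)
    signal_mask = np.asarray(signal_mask, dtype=bool)
    background_mask = np.asarray(background_mask, dtype=bool)
    if not signal_mask.any() or not background_mask.any():
        raise ValueError("signal and background masks must be nonempty")
    bg = float(voxels[background_mask].mean())
    if bg == 0:
        raise ValueError("background mean is zero")
    return float(voxels[signal_mask].mean()) / bg


@dataclass(frozen=True)
class DensityParams:
    """Tile shape (z, y, x voxels) and tile count for the local-density metric."""

    tile_shape: tuple[int, int, int] = (8, 64, 64)
    top_k: int = 10

    def __post_init__(self):
        if any(int(t) < 1 for t in self.tile_shape):
            raise ValueError("tile_shape entries must be positive")
        if self.top_k < 1:
            raise ValueError("top_k must be at least 1")


def local_density(
    mask: np.ndarray,
    params: DensityParams = DensityParams(),
    clip_tile: bool = False,
) -> float:
    """Mean occupancy of the densest tiles of a binary cell mask.

    The volume is partitioned into non-overlapping tiles from the origin;
    partial tiles at the far edges are excluded.  Returns the mean occupied
    fraction of the ``top_k`` densest tiles (all tiles, with a warning, if
    fewer exist).  ``clip_tile=True`` shrinks the tile to the volume along
    axes where the volume is smaller than one tile, instead of raising.
    """
    mask = np.asarray(_label_array(mask)) > 0
    tz, ty, tx = params.tile_shape
    if clip_tile and any(s < t for s, t in zip(mask.shape, (tz, ty, tx))):
        tz, ty, tx = (min(s, t) for s, t in zip(mask.shape, (tz, ty, tx)))
        warnings.warn(
            f"volume {mask.shape} smaller than one {params.tile_shape} tile; "
            f"using clipped tile {(tz, ty, tx)}",
            stacklevel=2,
        )
    nz, ny, nx = (s // t for s, t in zip(mask.shape, (tz, ty, tx)))
    if min(nz, ny, nx) < 1:
        raise ValueError(
            f"volume {mask.shape} is smaller than one {params.tile_shape} tile"
        )
    occ = (
        mask[: nz * tz, : ny * ty, : nx * tx]
        .reshape(nz, tz, ny, ty, nx, tx)
        .mean(axis=(1, 3, 5))
        .ravel()
    )
    k = params.top_k
    if occ.size < k:
        warnings.warn(
            f"only {occ.size} complete tiles available; using all of them", stacklevel=2
        )
        k = occ.size
    return float(np.sort(occ)[::-1][:k].mean())


# ---------------------------------------------------------------------------
# manual-annotation grouping

_AXIS_INDEX = {"z": 0, "y": 1, "x": 2}


@dataclass(frozen=True)
class AnnotationContour:
    """A hand-traced cell contour on a single 2D slice.

    ``plane_axis`` names the array axis perpendicular to the slice; the 2D
    ``vertices`` (voxel coordinates) are ordered in the two remaining array
    axes, e.g. (y, x) for a z-slice and (z, x) for a y-slice.
    """

    plane_axis: str
    slice_index: int
    vertices: np.ndarray
    annotator: str = ""

    def __post_init__(self):
        if self.plane_axis not in _AXIS_INDEX:
            raise ValueError("plane_axis must be one of 'z', 'y', 'x'")
        object.__setattr__(self, "vertices", np.asarray(self.vertices, dtype=float))
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("vertices must be an (n>=3, 2) array")

    @property
    def axis(self) -> int:
        return _AXIS_INDEX[self.plane_axis]

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def centroid3d(self) -> np.ndarray:
        """Area centroid lifted to 3D voxel coordinates (z, y, x)."""
        c2 = self.polygon().centroid
        out = np.empty(3)
        in_plane = [i for i in range(3) if i != self.axis]
        out[self.axis] = self.slice_index
        out[in_plane[0]] = c2.x
        out[in_plane[1]] = c2.y
        return out


def _contains_projected(container: AnnotationContour, centroid3d: np.ndarray) -> bool:
    """Project a 3D centroid along the container's plane axis; test enclosure."""
    in_plane = [i for i in range(3) if i != container.axis]
    pt = Point(centroid3d[in_plane[0]], centroid3d[in_plane[1]])
    return container.polygon().contains(pt)


def group_annotation_contours(
    contours: Sequence[AnnotationContour],
    grid,
    clustering_radius: float = 3.0,
):
    """Group 2D contours into 3D cells and rasterize them.

    Two contours are related when each encloses the other's projected
    centroid; related contours connect into groups via the adjacency matrix;
    groups whose centroids form several DBSCAN clusters (radius
    ``clustering_radius`` voxels, minimum cluster size 1) are split; each
    final group becomes one cell as the rasterized convex hull of its
    contours.  Returns an :class:`~biofilm3d.arrangement.InstanceMap`.
    """
    from .arrangement import InstanceMap

    valid: list[AnnotationContour] = []
    for c in contours:
        poly = c.polygon()
        if not poly.is_valid or poly.area <= 0:
            warnings.warn("skipping degenerate contour", stacklevel=2)
            continue
        valid.append(c)
    n = len(valid)
    labels = np.zeros(grid.shape, dtype=np.uint16)
    if n == 0:
        return InstanceMap(labels=labels, grid=grid)

    centroids = np.array([c.centroid3d() for c in valid])
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = valid[i], valid[j]
            if a.plane_axis == b.plane_axis and a.slice_index == b.slice_index:
                continue  # contours on the same slice are different cells
            if _contains_projected(a, centroids[j]) and _contains_projected(b, centroids[i]):
                adj[i, j] = adj[j, i] = True

    n_comp, comp = connected_components(coo_matrix(adj), directed=False)
    groups: list[list[int]] = []
    for ci in range(n_comp):
        members = np.flatnonzero(comp == ci)
        if len(members) == 1:
            groups.append(members.tolist())
            continue
        # split incorrectly merged groups by clustering their centroids
        db = DBSCAN(eps=clustering_radius, min_samples=1).fit(centroids[members])
        for lab in np.unique(db.labels_):
            groups.append(members[db.labels_ == lab].tolist())

    next_label = 0
    for g in groups:
        pts = []
        for i in g:
            c = valid[i]
            in_plane = [k for k in range(3) if k != c.axis]
            for off in (-0.49, 0.49):  # give each planar contour voxel thickness
                p3 = np.empty((len(c.vertices), 3))
                p3[:, c.axis] = c.slice_index + off
                p3[:, in_plane[0]] = c.vertices[:, 0]
                p3[:, in_plane[1]] = c.vertices[:, 1]
                pts.append(p3)
        pts = np.vstack(pts)
        try:
            tri = Delaunay(pts)
        except QhullError:
            warnings.warn("skipping degenerate contour group", stacklevel=2)
            continue
        next_label += 1
        lo = np.maximum(np.floor(pts.min(axis=0)).astype(int), 0)
        hi = np.minimum(np.ceil(pts.max(axis=0)).astype(int) + 1, grid.shape)
        if np.any(lo >= hi):
            continue
        sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        idx = np.stack(
            np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        inside = tri.find_simplex(idx.astype(float)) >= 0
        view = labels[sl].ravel()
        view[inside] = next_label
        labels[sl] = view.reshape(labels[sl].shape)
    return InstanceMap(labels=labels, grid=grid)
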