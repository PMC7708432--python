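"""Reading and writing volumes, PSFs, and arrangement tables.

Volumes travel as TIFF stacks (z as pages): instance and class label maps
as 16-bit unsigned integers, images and confidence maps as 32-bit floats;
a confidence map is a 4D stack with channel order bg, int₁, bnd₁[, int₂,
bnd₂].  The physical voxel size is stored in TIFF resolution tags and in a
JSON sidecar (``<path>.json``) that also records the object kind and, for
instance maps, the label→population mapping.  Arrangements serialize to a
CSV table (cell_id, population, centroid x/y/z µm, axis x/y/z, length µm,
diameter µm) and round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .arrangement import CellArrangement, GridSpec, InstanceMap, LabelMap
from .geometry import Spherocylinder
from .imaging import ConfidenceMap, ImageVolume

__all__ = [
    "read_volume",
    "write_volume",
    "arrangement_to_csv",
    "arrangement_from_csv",
]


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _grid_to_json(grid: GridSpec) -> dict:
    return {
        "shape": list(grid.shape),
        "voxel_size_um": list(grid.voxel_size),
        "origin_um": list(grid.origin),
    }


def _grid_from_json(d: dict, shape) -> GridSpec:
    return GridSpec(
        shape=tuple(d.get("shape", shape)),
        voxel_size=tuple(d.get("voxel_size_um", (0.1, 0.1, 0.1))),
        origin=tuple(d.get("origin_um", (0.0, 0.0, 0.0))),
    )


def write_volume(obj, path) -> None:
    """Write an ImageVolume, InstanceMap, LabelMap or ConfidenceMap as TIFF.

    Integer maps round-trip losslessly (uint16); float volumes round-trip
    within float32 precision.  The voxel size goes into the TIFF resolution
    tags (x/y, in µm) and a JSON sidecar next to the file.
    """
    path = Path(path)
    meta: dict = {"voxel": _grid_to_json(obj.grid)}
    vs = obj.grid.voxel_size
    res = (1.0 / vs[2], 1.0 / vs[1])  # pixels per µm, (x, y)
    kwargs = dict(resolution=res, metadata={"spacing": vs[0], "unit": "um"}, imagej=True)
    if isinstance(obj, InstanceMap):
        meta["kind"] = "instance"
        meta["populations"] = {str(k): int(v) for k, v in obj.populations.items()}
        tifffile.imwrite(path, np.asarray(obj.labels, dtype=np.uint16), **kwargs)
    elif isinstance(obj, LabelMap):
        meta["kind"] = "classmap"
        tifffile.imwrite(path, np.asarray(obj.classes, dtype=np.uint16), **kwargs)
    elif isinstance(obj, ConfidenceMap):
        meta["kind"] = "confidence"
        meta["channel_order"] = (
            ["bg", "int1", "bnd1"] if obj.n_classes == 3
            else ["bg", "int1", "bnd1", "int2", "bnd2"]
        )
        # pages are (z, channel) so ImageJ readers see a multi-channel stack
        data = np.asarray(obj.values, dtype=np.float32).transpose(1, 0, 2, 3)
        tifffile.imwrite(path, data, **kwargs)
    elif isinstance(obj, ImageVolume):
        meta["kind"] = "image"
        tifffile.imwrite(path, np.asarray(obj.voxels, dtype=np.float32), **kwargs)
    else:
        raise TypeError(f"cannot write object of type {type(obj).__name__}")
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_volume(path):
    """Read a TIFF volume back as the object kind it was written as.

    The kind is taken from the JSON sidecar when present; otherwise it is
    inferred from dtype and dimensionality (integer 3D → InstanceMap, float
    3D → ImageVolume, 4D with 3 or 5 channels → ConfidenceMap).  Confidence
    stacks whose per-voxel channel sums deviate from 1 are rejected with a
    renormalization hint.
    """
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}

    if data.ndim == 4:
        data = data.transpose(1, 0, 2, 3)  # (z, c, y, x) -> (c, z, y, x)
    elif data.ndim != 3:
        raise ValueError(
            f"unsupported TIFF layout {data.shape}; expected a 3D stack or a "
            "(z, channel, y, x) confidence stack"
        )
    grid = _grid_from_json(meta.get("voxel", {}), data.shape[-3:])

    kind = meta.get("kind")
    if kind is None:
        if data.ndim == 4:
            kind = "confidence"
        elif np.issubdtype(data.dtype, np.integer):
            kind = "instance"
        else:
            kind = "image"

    if kind == "confidence":
        if data.shape[0] not in (3, 5):
            raise ValueError(
                f"confidence stacks must have 3 or 5 channels in order "
                f"bg, int1, bnd1[, int2, bnd2]; got {data.shape[0]}"
            )
        sums = data.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            raise ValueError(
                "per-voxel class confidences do not sum to 1; renormalize "
                "each voxel by the channel sum before writing"
            )
        return ConfidenceMap(values=data.astype(float), grid=grid)
    if kind == "instance":
        populations = {int(k): int(v) for k, v in meta.get("populations", {}).items()}
        return InstanceMap(labels=data.astype(np.uint16), grid=grid, populations=populations)
    if kind == "classmap":
        return LabelMap(classes=data.astype(np.uint8), grid=grid)
    if kind == "image":
        return ImageVolume(voxels=data.astype(float), grid=grid)
    raise ValueError(f"unknown volume kind {kind!r} in sidecar {sidecar}")


# ---------------------------------------------------------------------------
# arrangement tables


def arrangement_to_csv(arr: CellArrangement, path) -> None:
    """Serialize an arrangement to CSV (x/y/z column order, full precision).

    Floats are written with ``repr`` so the table round-trips bit-exactly.
    """
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["cell_id", "population", "centroid_x_um", "centroid_y_um",
             "centroid_z_um", "axis_x", "axis_y", "axis_z", "length_um",
             "diameter_um"]
        )
        for c in arr.cells:
            writer.writerow(
                [c.cell_id, c.population,
                 repr(float(c.centroid[2])), repr(float(c.centroid[1])),
                 repr(float(c.centroid[0])), repr(float(c.axis[2])),
                 repr(float(c.axis[1])), repr(float(c.axis[0])),
                 repr(float(c.length)), repr(float(c.diameter))]
            )


def arrangement_from_csv(path) -> CellArrangement:
    """Read an arrangement table written by :func:`arrangement_to_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    cells = [
        Spherocylinder(
            cell_id=int(r.cell_id),
            centroid=(r.centroid_z_um, r.centroid_y_um, r.centroid_x_um),
            axis=(r.axis_z, r.axis_y, r.axis_x),
            length=float(r.length_um),
            diameter=float(r.diameter_um),
            population=int(r.population),
        )
        for r in df.itertuples()
    ]
    return CellArrangement(cells=cells)
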