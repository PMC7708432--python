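"""End-to-end orchestration: simulate → render → segment → evaluate.

Also exports CNN training pairs (image + class-label TIFF stacks with a
JSON manifest) so an external voxel-classification trainer can consume
simulated data; inference results come back in as confidence-map TIFFs via
``PipelineConfig.confidence_path``.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from .arrangement import (
    GridSpec,
    calibrate_density,
    grow_biofilm,
    instances_to_classmap,
    rasterize_instances,
    substitute_population,
)
from .config import PipelineConfig, stage_seed
from .evaluate import (
    DensityParams,
    accuracy_curve,
    counting_accuracy,
    estimate_sbr,
    local_density,
    match_instances,
    voxel_accuracy,
)
from .imaging import (
    ImageVolume,
    NoiseModel,
    add_noise,
    calibrate_sbr,
    load_psf,
    place_fluorophores,
    render_noiseless,
    richardson_lucy,
    sbr_masks,
    subtract_background,
    surrogate_confidence,
    synthesize_psf,
)
from .postprocess import segment_volume

logger = logging.getLogger("biofilm3d")

__all__ = ["run_pipeline", "export_training_set", "simulate_scene"]

# stage indices for seed fan-out
_STAGE_GROW, _STAGE_POP2, _STAGE_EMIT, _STAGE_NOISE, _STAGE_SURROGATE = range(5)


def _log_stage(log: list, stage: str, t0: float, **info) -> None:
    entry = {"stage": stage, "seconds": round(time.time() - t0, 3), **info}
    log.append(entry)
    logger.info(json.dumps(entry))


def simulate_scene(config: PipelineConfig):
    """Grow, calibrate, and rasterize the ground-truth scene.

    Returns (arrangement, grid, instance map, achieved density).
    """
    ac = config.arrangement
    arr = grow_biofilm(ac.growth_params(), seed=stage_seed(config.seed, _STAGE_GROW))
    if ac.population2_fraction > 0:
        arr = substitute_population(
            arr,
            ac.population2_fraction,
            ac.population2_shape_um,
            seed=stage_seed(config.seed, _STAGE_POP2),
        )
    achieved = None
    if ac.target_density is not None:
        result = calibrate_density(
            arr,
            ac.target_density,
            grid=config.voxel_size_um,
            tile_shape=tuple(ac.density_tile_shape),
        )
        arr, achieved = result.arrangement, result.achieved_fraction
    grid = GridSpec.from_bounds(
        arr.tight_bounds(), config.voxel_size_um, margin=config.grid_margin_um
    )
    inst = rasterize_instances(arr, grid)
    return arr, grid, inst, achieved


def render_scene(config: PipelineConfig, arr, grid, inst):
    """Noiseless render, SBR calibration, and noisy acquisition."""
    im = config.imaging
    mode = (
        im.labeling
        if config.arrangement.population2_fraction == 0
        else {1: im.labeling, 2: "interior"}
    )
    emitters = place_fluorophores(
        arr, mode, tuple(im.emitters_per_cell), seed=stage_seed(config.seed, _STAGE_EMIT)
    )
    if im.psf_path:
        psf = load_psf(im.psf_path, voxel_size=config.voxel_size_um)
    else:
        psf = synthesize_psf(
            im.psf_fwhm_lateral_um, im.psf_fwhm_axial_um, config.voxel_size_um
        )
    noiseless = render_noiseless(emitters, psf, grid, im.photons_per_emitter)
    noise = NoiseModel(
        background=im.background_photons,
        read_noise_sd=im.read_noise_sd,
        seed=stage_seed(config.seed, _STAGE_NOISE),
    )
    scale = calibrate_sbr(noiseless, inst, noise, im.target_sbr)
    scaled = ImageVolume(noiseless.voxels * scale, grid, dict(noiseless.meta))
    noisy = add_noise(scaled, noise)
    return noiseless, noisy, psf, noise, scale


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full loop and return (and optionally write) a report.

    Stages: growth + density calibration, emitter placement and PSF
    rendering, SBR calibration, noise, raw-data processing (background
    subtraction, Richardson–Lucy), confidence maps (external file or the
    surrogate generator), post-processing into single cells, and IoU-based
    evaluation against the simulated ground truth.
    """
    from . import io as b3io

    log: list = []
    report: dict = {"config": config.model_dump(mode="json")}

    t0 = time.time()
    arr, grid, inst, achieved = simulate_scene(config)
    report["n_cells"] = len(arr)
    report["achieved_density"] = achieved
    report["grid_shape"] = list(grid.shape)
    _log_stage(log, "simulate", t0, n_cells=len(arr), density=achieved)

    t0 = time.time()
    noiseless, noisy, psf, noise, scale = render_scene(config, arr, grid, inst)
    _log_stage(log, "render", t0, signal_scale=scale)

    t0 = time.time()
    im = config.imaging
    processed = subtract_background(noisy, percentile=im.background_percentile)
    if im.deconvolve:
        processed = richardson_lucy(processed, psf, im.rl_iterations)
    _log_stage(log, "process", t0, deconvolved=im.deconvolve)

    t0 = time.time()
    if config.confidence_path:
        conf = b3io.read_volume(config.confidence_path)
        conf_source = "external"
    else:
        conf = surrogate_confidence(
            inst,
            blur_sd=im.surrogate_blur_sd,
            flip_noise=im.surrogate_flip_noise,
            seed=stage_seed(config.seed, _STAGE_SURROGATE),
            sharpness=im.surrogate_sharpness,
        )
        conf_source = "surrogate"
    _log_stage(log, "confidence", t0, source=conf_source)

    t0 = time.time()
    seg_config = config.segmentation.to_segmentation_config(im.labeling)
    seg = segment_volume(conf, processed, seg_config)
    _log_stage(log, "segment", t0, n_cells=seg.instances.n_objects)

    t0 = time.time()
    ev = config.evaluation
    match = match_instances(seg.instances, inst, ev.iou_threshold)
    sig_mask, bg_mask = sbr_masks(noiseless, inst)
    report["evaluation"] = {
        "tp": match.tp,
        "fp": match.fp,
        "fn": match.fn,
        "counting_accuracy": counting_accuracy(match),
        "voxel_accuracy": voxel_accuracy(match),
        "counting_accuracy_pre_lcuts": counting_accuracy(
            match_instances(seg.pre_lcuts, inst, ev.iou_threshold)
        ),
        "accuracy_curve": accuracy_curve(seg.instances, inst, ev.curve_thresholds).to_dict(
            orient="list"
        ),
        "local_density": local_density(
            np.asarray(inst.labels) > 0,
            DensityParams(tuple(ev.density_tile_shape), ev.density_top_k),
            clip_tile=True,
        ),
        "estimated_sbr": estimate_sbr(noisy, sig_mask, bg_mask),
    }
    _log_stage(log, "evaluate", t0, **{k: report["evaluation"][k] for k in ("tp", "fp", "fn")})
    report["log"] = log

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        b3io.write_volume(noisy, out / "image.tif")
        b3io.write_volume(inst, out / "truth.tif")
        b3io.write_volume(seg.instances, out / "segmentation.tif")
        seg.table.to_csv(out / "cells.csv", index=False)
        b3io.arrangement_to_csv(arr, out / "arrangement.csv")
        (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report


def export_training_set(
    n_volumes: int,
    config: PipelineConfig,
    out_dir,
    density_range: tuple[float, float] = (0.35, 0.62),
    sbr_range: tuple[float, float] = (1.3, 3.0),
) -> dict:
    """Export paired (image, class-label) TIFF volumes for CNN training.

    Each volume uses a fresh arrangement with density and SBR drawn
    uniformly from the given ranges; the JSON manifest records the seed,
    density, SBR, species and labeling mode per volume so any volume can be
    regenerated exactly.
    """
    from . import io as b3io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(stage_seed(config.seed, 1000))
    volumes = []
    for i in range(n_volumes):
        sub = config.model_copy(deep=True)
        sub.seed = stage_seed(config.seed, 1001 + i)
        sub.arrangement.target_density = float(rng.uniform(*density_range))
        sub.imaging.target_sbr = float(rng.uniform(*sbr_range))
        try:
            arr, grid, inst, achieved = simulate_scene(sub)
        except ValueError:
            # the drawn density is outside what this colony can reach
            # (possible for very small volumes); keep its natural density
            sub.arrangement.target_density = None
            arr, grid, inst, achieved = simulate_scene(sub)
        _, noisy, _, _, _ = render_scene(sub, arr, grid, inst)
        classes = instances_to_classmap(inst)
        img_name, lab_name = f"image_{i:03d}.tif", f"labels_{i:03d}.tif"
        b3io.write_volume(noisy, out / img_name)
        b3io.write_volume(classes, out / lab_name)
        volumes.append(
            {
                "image": img_name,
                "labels": lab_name,
                "seed": sub.seed,
                "target_density": sub.arrangement.target_density,
                "achieved_density": achieved,
                "target_sbr": sub.imaging.target_sbr,
                "species": sub.arrangement.species,
                "labeling": sub.imaging.labeling,
                "n_cells": len(arr),
                "grid_shape": list(grid.shape),
                "voxel_size_um": list(sub.voxel_size_um),
            }
        )
    manifest = {"master_seed": config.seed, "n_volumes": n_volumes, "volumes": volumes}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
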