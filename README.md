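# biofilm3d

Single-cell instance segmentation in 3D fluorescence images of bacterial
biofilms — and the full in-silico loop needed to develop and validate it.

Dense biofilms are hard to segment: the axial resolution of a fluorescence
microscope (~570 nm) is comparable to a bacterium's diameter, live-cell
imaging forces low signal-to-background ratios (SBR), and voxel classifiers
trained to label *background / cell interior / cell boundary* still merge
touching cells into single connected components. `biofilm3d` addresses the
whole problem in one package:

1. **Simulation with exact ground truth.** An individual-based growth model
   produces substrate-attached colonies of spherocylindrical cells
   (*E. coli*, *M. xanthus*, *S. aureus* presets). Centroid rescaling
   calibrates the colony to a target volume density, measured the way biofilm
   datasets conventionally report it: the mean occupancy of the ten densest
   64×64×8-voxel tiles. Cells are labeled with 500–1000 point emitters
   (cytosolic or membrane), convolved with a 3D PSF, scaled to a target SBR
   against a constant background (~200 photons/voxel), and corrupted with
   Poisson counting noise plus Gaussian camera read noise (σ = 3.04
   photons). Every voxel's true instance and class label is known.

2. **Post-processing of classifier confidence maps into single cells.**
   Thresholding the cell-interior confidence channel (τ = 0.94 cytosolic /
   0.88 membrane) gives connected components; speckle is removed by the
   coefficient of variation CV_i = σ_i/μ_i > ρ (ρ = 1.1) and a 25 %-of-cell
   size filter; each object's central axis is traced by inscribed spheres
   (x_i, y_i, z_i; r_i < d/2) on the Euclidean distance transform; the axis
   points are clustered by **LCuts**, a recursive normalized-cut method
   with edge weights

       w_ij = w_D · w_T,
       w_D  = exp(−D_ij²/σ_D²)  if D_ij² ≤ r, else 0,
       w_T  = exp(−(cos θ_ij − 1)²/σ_T²),

   where D_ij is the Euclidean distance and θ_ij the relative angle between
   node directions; recursion stops when a group's estimated length is
   within the expected cell length L and the group is linear. Each group is
   rasterized back as a spherocylinder, a convex hull of its inscribed
   spheres, or a partition of the original object.

3. **Evaluation.** One-to-one IoU matching (optimal assignment), counting
   accuracy TP/(TP+FP+FN), voxel-level accuracy (mean IoU over segmented
   objects), accuracy-vs-IoU-threshold curves, the SBR estimator, the local
   density metric, and 3D reconstruction of manually traced 2D contour
   annotations (mutual centroid containment + DBSCAN + convex hulls).

A training-data bridge exports paired image/label TIFF volumes with a JSON
manifest for any external 3D U-Net trainer, and ingests the resulting
confidence maps; a built-in surrogate confidence generator emulates a
trained classifier so the post-processing and evaluation stages run without
any training.

## Worked example

```python
import dataclasses
import numpy as np
from biofilm3d import (
    SPECIES_PRESETS, GridSpec, ImageVolume, SegmentationConfig,
    calibrate_density, counting_accuracy, grow_biofilm, match_instances,
    rasterize_instances, segment_volume, surrogate_confidence, voxel_accuracy,
)

params = dataclasses.replace(SPECIES_PRESETS["e_coli"], max_cells=80)
arr = calibrate_density(grow_biofilm(params, seed=5), 0.50,
                        tile_shape=(8, 32, 32)).arrangement
grid = GridSpec.from_bounds(arr.tight_bounds(), margin=0.8)
truth = rasterize_instances(arr, grid)

conf = surrogate_confidence(truth, blur_sd=1.0, seed=6)
intensity = ImageVolume(np.full(grid.shape, 100.0), grid)
seg = segment_volume(conf, intensity, SegmentationConfig())

m = match_instances(seg.instances, truth, iou_threshold=0.5)
print(f"TP {m.tp}  FP {m.fp}  FN {m.fn}  "
      f"counting accuracy {counting_accuracy(m):.3f}  "
      f"voxel accuracy {voxel_accuracy(m):.3f}")
```

prints

```
TP 80  FP 0  FN 0  counting accuracy 1.000  voxel accuracy 0.904
```

— all 80 cells of a 50 %-density colony are recovered one-to-one at the
IoU ≥ 0.5 matching criterion, with a mean per-cell shape overlap of 0.90.
`examples/` contains one short script per capability (growth and density
calibration, image formation, segmentation, splitting fused cells,
training-set export, contour-annotation reconstruction); each prints the
numbers it computes and says what they mean.

## Command line

```bash
biofilm3d run --seed 1 --out out/          # simulate → render → segment → evaluate
biofilm3d simulate|render|export-training|segment|evaluate --help
```

All subcommands take `--config` (YAML, validated against
`PipelineConfig.model_json_schema()`), `--seed`, and `--out`; identical
inputs produce identical outputs.

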