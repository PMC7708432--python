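# Methods

This note documents the models implemented in `biofilm3d`, the parameters
that matter, the numerical choices, and what the synthetic-data loop does
and does not establish about real microscope data.

## Cell geometry and the growth model

Cells are spherocylinders (capsules): a cylinder of length *l* and diameter
*d* capped by hemispheres, with *l* = 0 describing a coccus. All physical
coordinates are (z, y, x) in µm to match array indexing; tables serialize
x/y/z columns.

Growth is a deliberately minimal individual-based model, not a port of any
particular simulator. Per step every cell's cylinder segment elongates by
`elongation_rate` (default 0.2 µm/step); a cell divides when its segment
exceeds a per-cell threshold drawn at birth as
(`division_length` − `diameter`) × U(0.9, 1.1). Daughters occupy the two
halves of the parent segment (summed cylinder length is conserved) with
axes tilted by up to `orientation_jitter_deg` (5°). Collisions are relaxed
by iterated pairwise repulsion along the minimal-distance vector between
axis segments, using a vectorized clamped segment–segment distance
(Ericson's algorithm) with a k-d tree neighbor prefilter.

Colonies are substrate-attached: cells settle toward the z = 0 plane each
step and the colony is compacted laterally (centroids contract by
`compaction_factor` = 0.97 toward the colony axis, then relax) with a
stronger final compaction stage after growth stops. This reproduces the
flat, laterally spreading, jammed arrangements of coverslip-grown biofilms;
it is also what makes the 64×64×8-voxel local-density tiles (6.4 × 6.4 ×
0.8 µm at 100 nm voxels) fit inside the colony, which a free-floating
spherical blob of ~300 cells cannot do. Species presets: (d, tip-to-tip
division length) = (1, 3) µm *E. coli*, (0.7, 6) µm *M. xanthus*,
(1, ~2) µm *S. aureus* (spherical daughters). Growth is bit-reproducible
for a fixed seed.

## Density definition and calibration

The density of a dataset is reported as the **local density**: the mean
occupancy of the `top_k` = 10 densest non-overlapping 64×64×8-voxel tiles
of the binary cell mask (partial edge tiles excluded). `calibrate_density`
bisects a centroid scale factor — positions scale about the mean centroid,
cell sizes and orientations unchanged — until this metric reaches the
target within 0.02. Compression (scale < 1) is allowed until some cell pair
would interpenetrate beyond half a diameter, which caps the achievable
density; the bracket search probes that feasibility boundary before giving
up. A `metric="global"` option measures the plain occupied-voxel fraction
of the tight bounding box instead. Suites built from ~100-cell colonies
calibrate with 32×32×8 tiles, because such colonies are smaller than one
64×64 tile footprint; the metric family is the same.

## Image formation

Per cell, the emitter count is uniform in [500, 1000] (expression-level
variation); cytosolic labeling samples uniformly in the cell volume
(composition method over cylinder and caps), membrane staining uniformly on
the surface (area-weighted; the dye's intercalation depth is unmodeled).
Emitters are binned to the voxel grid and convolved (FFT, zero-padded
boundaries; edge flux loss is reported in `meta["edge_loss"]`, not hidden)
with either a measured PSF loaded from TIFF or a synthetic anisotropic
Gaussian with 230 nm lateral / 570 nm axial FWHM.

SBR calibration is closed-form: with the signal region defined as in-cell
voxels brighter than the median in-cell noiseless intensity (a
deterministic proxy for hand-picked bright regions) and background as
voxels farther than 3 voxels from any cell, the scale is
`background·(target − 1) / mean(signal)`. Noise is
Poisson(signal + background) plus Normal(0, 3.04²) read noise, clipped at
zero; `clip=False` exposes the raw signed counts, which is how the
read-noise SD is measured in dark-frame calibration (clipping a zero-mean
Gaussian at zero would halve its SD). Raw-data processing mirrors a
microscope pipeline: constant background subtraction from dark areas, then
Richardson–Lucy deconvolution (ten iterations; delegated to
scikit-image with a 1e-12 ratio epsilon).

Default grid: isotropic 100 nm voxels (configurable per axis). Optical
aberrations and scattering are not modeled.

## The surrogate confidence generator

The surrogate stands in for a trained voxel classifier so the
post-processing and evaluation stages are testable without training. The
exact class map (background / interior / boundary per population, boundary
= the outermost 1-voxel shell of each instance) is one-hot encoded, each
channel is Gaussian-smoothed by `blur_sd` voxels, per-voxel confidences are
raised to a `sharpness` exponent (default 3) before renormalization, and a
`flip_noise` fraction of voxels is reassigned to full background
confidence. The sharpening models the saturation of Dice-trained
classifiers — confidence plateaus near 1 inside a class and falls steeply
at transitions; without it, thresholding a plain blurred one-hot map at
0.94 erodes every object by ~1.6 blur widths, which no real classifier
does. Degenerate parameters (blur 0, flip 0) reproduce the one-hot map
exactly.

What the surrogate does **not** emulate: correlated classifier errors,
SBR-dependent confidence degradation, systematic boundary bias between
touching cells, and species confusion in mixed populations. Pipeline
accuracies measured against surrogate confidences are therefore upper
bounds on real-classifier performance; they validate the post-processing
and evaluation machinery, not a classifier.

## Post-processing: from confidence maps to cells

1. **Threshold + components.** 26-connected components of
   interior ≥ τ (0.94 cytosolic / 0.88 membrane); components below one
   tenth of the expected cell volume are discarded; objects are dilated by
   1 voxel (Euclidean ball; contested voxels go to the nearest original
   object via the distance transform) to recover the boundary shell.
2. **CV + size filter.** Per object, CV = sample SD (n−1) / mean of the
   intensity over its voxels; objects with CV > ρ = 1.1 (the background's
   own coefficient of variation) are speckle and removed, then objects
   below 25 % of the expected cell volume. For 5-class maps the second
   population uses its own expected volume (default: a sphere of the
   configured diameter), otherwise a rod-sized filter would delete every
   coccus.
3. **Medial axis by inscribed spheres.** Candidates are ridge voxels of
   the Euclidean distance transform: voxels where at most 4 of the 26
   neighbors exceed the EDT smoothed by 1 voxel. A plain local-maximum
   test fails twice on real objects — it goes blind wherever the EDT has
   an along-axis gradient (caps, junctions) and it sprays spurious maxima
   from rough thresholded surfaces; the neighbor-count criterion on the
   smoothed field follows the ridge through both. An EDT floor
   (0.45·min(d/2, max EDT)) stops chains at thin cap tips. Candidates are
   thinned by non-maximum suppression at d/5 spacing — dense enough that
   5-hop graph neighborhoods stay local — and refined to the EDT-weighted
   centroid of their neighborhood (sub-voxel axis localization; recovers
   axes that fall on voxel boundaries). Radii are the raw EDT values
   capped strictly below d/2.
4. **Node directions.** Per node, the 5-hop neighborhood on a symmetric
   3-nearest-neighbor graph is collected; the provisional direction is the
   neighbor bearing with the most angle-consistent other bearings (a
   plain neighborhood PCA comes out diagonal at L-shaped junctions and
   defeats the outlier filter); neighbors off by more than 45° from that
   line are removed; the direction is the principal axis of the remainder.
   Directions are unit, sign-ambiguous.
5. **LCuts.** Edge weights w_ij = w_D·w_T with w_D = exp(−D²/σ_D²) zeroed
   when the *squared* distance exceeds r (r is in µm², exactly as the
   weight definition is usually printed; reading r as a plain distance
   would only rescale the cutoff) and w_T = exp(−(cos θ − 1)²/σ_T²), θ the
   relative angle between undirected node directions (cos θ = |d_i·d_j|).
   Defaults σ_D = 1 µm, σ_T = 0.3, r = 2.25 µm². Recursion: connected
   components split first; a group is accepted when its estimated
   tip-to-tip length — the arc length of the PC1-ordered node chain plus
   one cell diameter for the two unreachable end caps — is at most
   1.6·L *and* its linearity (variance fraction of the first principal
   component) is at least 0.95; groups no wider than one cell diameter
   (spherical cells) are accepted outright. Graphs of ≤ 15 nodes are cut
   by exact enumeration of all 2-partitions (vectorized); larger graphs by
   spectral bisection (second-smallest generalized eigenvector, minimum-
   nCut threshold sweep) followed by deterministic best-improvement
   single-node refinement, since the spectral relaxation can miss the
   discrete optimum on interleaved chains. The cap-corrected length makes
   a lone cell measure ≈ L for every species, so one accept factor covers
   short fat and long thin rods; straight end-to-end fusions are caught by
   the length rule, angled fusions by linearity (which is independent of
   σ_D, σ_T, L, d — the basis of the parameter-robustness property).
6. **Reconstruction.** Per group: a spherocylinder of diameter d along the
   group's principal axis spanning the node extent plus caps (default);
   the convex hull of the group's inscribed spheres united with the
   spheres themselves (so every inscribed-sphere voxel is covered); or a
   partition of the original object's voxels by nearest group. Contested
   voxels go to the nearest group; labels are contiguous, and label
   populations are tracked for 5-class maps.

## Evaluation

Matching is optimal one-to-one assignment on the IoU matrix restricted to
pairs at or above the threshold (0.5 by convention); a greedy-by-IoU
variant is available for comparison. Counting accuracy is TP/(TP+FP+FN).
Voxel-level accuracy averages the matched IoU over *predicted* objects,
with unmatched predictions contributing zero and missed truth objects not
entering the average — the "average IoU over all segmented objects"
reading. Accuracy curves re-match at every threshold and are non-increasing
by construction. The SBR estimator is the ratio of mean intensities over
the signal and background masks. Contour-annotation reconstruction labels
two hand-traced 2D contours as related when each encloses the other's
projected centroid, connects related contours into groups, splits wrongly
merged groups by DBSCAN on the 3D centroids (eps = the slice spacing,
minimum cluster size 1), and rasterizes each group's convex hull.

## Problem sizes and reproducibility

The shipped test-suite and calibration runs use colonies of 40–300 cells
on grids of roughly 100³–160·150·100 voxels at 100 nm; these sizes keep
every figure of merit measurable while each suite completes in seconds to
a few minutes on one CPU. A single master seed fans out to per-stage seeds
through a counter-based SeedSequence scheme, so any stage can be re-run in
isolation and every CLI subcommand is pure with respect to config + seed.

## Known limitations

- The growth model is a stand-in: no viscous drag, EPS, nutrient fields, or
  motility; colony architecture beyond "jammed, substrate-attached" is not
  claimed to be realistic.
- The surrogate confidence generator bounds, but does not predict,
  trained-classifier behavior (see above); headline accuracies against
  real microscope data require a trained classifier and annotated ground
  truth, neither of which this package provides.
- Density calibration by pure centroid scaling cannot exceed the packing
  achievable under the interpenetration cap (~0.60–0.62 local density for
  the *E. coli* preset); targets beyond that raise an error naming the
  achievable range.
- Anisotropic voxels are supported throughout, but the default suites are
  isotropic; medial-axis behavior at strong anisotropy (> 3:1) is untested.
- The 3D skeletonization in the installed scikit-image returns empty
  volumes, so the `method="skeleton"` option of `extract_medial_axis`
  falls back to the ridge criterion when that happens.
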