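"""Thresholding, CV filter, medial axis, LCuts, and reconstruction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biofilm3d.arrangement import (
    CellArrangement,
    GridSpec,
    InstanceMap,
    rasterize_instances,
)
from biofilm3d.geometry import Spherocylinder
from biofilm3d.imaging import ConfidenceMap, ImageVolume, surrogate_confidence
from biofilm3d.postprocess import (
    AxisNode,
    CVFilterParams,
    LCutsParams,
    SegmentationConfig,
    cv_filter,
    dilate_instances,
    estimate_node_directions,
    expected_cell_volume,
    extract_medial_axis,
    lcuts_cluster,
    lcuts_weight_matrix,
    lcuts_weights,
    normalized_cut_value,
    reconstruct_cells,
    segment_volume,
    threshold_and_label,
)
from biofilm3d.evaluate import counting_accuracy, match_instances, pair_iou


def _confidence_from_interior(interior: np.ndarray, grid: GridSpec) -> ConfidenceMap:
    """3-class confidence with the given interior channel (rest background)."""
    values = np.zeros((3,) + grid.shape)
    values[1] = interior
    values[0] = 1.0 - interior
    return ConfidenceMap(values=values, grid=grid)


class TestThresholdAndLabel:
    def test_three_disjoint_cells_recovered_exactly(self, grid_small):
        cells = [
            Spherocylinder(i + 1, (2.0, 1.0 + i, 1.5 + 2.0 * i), (0, 0, 1), 1.0, 0.8)
            for i in range(3)
        ]
        inst = rasterize_instances(CellArrangement(cells), grid_small)
        conf = surrogate_confidence(inst, blur_sd=0.0, flip_noise=0.0)
        out = threshold_and_label(conf, tau=0.5, min_volume_fraction=0.01)
        assert out.n_objects == 3
        from biofilm3d.arrangement import instances_to_classmap

        cm = instances_to_classmap(inst)
        np.testing.assert_array_equal(out.labels > 0, cm.classes == 1)

    def test_low_tau_covers_all_interior_dominant_voxels(self, colony_sparse):
        _, grid, inst = colony_sparse
        conf = surrogate_confidence(inst, blur_sd=1.0, flip_noise=0.0, seed=0)
        out = threshold_and_label(conf, tau=1e-6, min_volume_fraction=0.001)
        dominant = conf.values.argmax(axis=0) == 1
        assert np.all(out.labels[dominant] > 0)

    def test_small_speckle_removed_by_size_filter(self):
        grid = GridSpec((20, 20, 20), (0.1, 0.1, 0.1))
        interior = np.zeros(grid.shape)
        interior[5:10, 5:10, 5:10] = 1.0  # 125 voxels, a real object
        interior[15, 15, 15:20] = 1.0  # 5-voxel blob, below 10% of a cell
        conf = _confidence_from_interior(interior, grid)
        # expected volume 2.88 µm³ -> 10% is ~288 voxels... use a smaller
        # reference so the 125-voxel object is kept and the 5-voxel one is not
        out = threshold_and_label(
            conf, tau=0.94, min_volume_fraction=0.1,
            expected_volume=100 * grid.voxel_volume,
        )
        assert out.n_objects == 1
        assert (out.labels > 0).sum() == 125

    def test_labels_contiguous_from_one(self, colony_sparse):
        _, _, inst = colony_sparse
        conf = surrogate_confidence(inst, blur_sd=1.0, flip_noise=0.0, seed=0)
        out = threshold_and_label(conf, tau=0.94)
        ids = np.unique(out.labels)
        np.testing.assert_array_equal(ids, np.arange(len(ids)))


class TestDilate:
    def test_empty_map_unchanged(self):
        grid = GridSpec((8, 8, 8))
        inst = InstanceMap(np.zeros(grid.shape, dtype=np.uint16), grid)
        out = dilate_instances(inst, 1)
        assert out.labels.max() == 0

    def test_single_label_grows_and_keeps_support(self):
        grid = GridSpec((16, 16, 16))
        labels = np.zeros(grid.shape, dtype=np.uint16)
        labels[6:10, 6:10, 6:10] = 1
        out = dilate_instances(InstanceMap(labels, grid), 1)
        assert (out.labels == 1).sum() > 64
        assert np.all(out.labels[labels == 1] == 1)

    def test_nearby_labels_do_not_merge(self):
        grid = GridSpec((16, 16, 16))
        labels = np.zeros(grid.shape, dtype=np.uint16)
        labels[4:8, 4:12, 4:7] = 1
        labels[4:8, 4:12, 9:12] = 2  # 2-voxel gap along x
        out = dilate_instances(InstanceMap(labels, grid), 1)
        assert set(np.unique(out.labels)) == {0, 1, 2}
        # contested midline voxels split by nearest original object
        assert np.all(out.labels[4:8, 4:12, 7] == 1)
        assert np.all(out.labels[4:8, 4:12, 8] == 2)


class TestCVFilter:
    def _tiny_map(self, intensities_per_object):
        """One flat object per row of intensities, in a small volume."""
        grid = GridSpec((3, 4, 8), (0.1, 0.1, 0.1))
        labels = np.zeros(grid.shape, dtype=np.uint16)
        image = np.zeros(grid.shape)
        for i, vals in enumerate(intensities_per_object):
            labels[1, i, : len(vals)] = i + 1
            image[1, i, : len(vals)] = vals
        params = CVFilterParams(
            rho=1.1, min_size_fraction=0.25,
            expected_cell_volume=8 * grid.voxel_volume,
        )
        return InstanceMap(labels, grid), ImageVolume(image, grid), params

    def test_hand_computed_cv_keeps_moderate_object(self):
        """Intensities {50, 150, 250}: mean 150, sample SD 100, CV = 0.667."""
        inst, img, params = self._tiny_map([[50.0, 150.0, 250.0]])
        vals = img.voxels[inst.labels == 1]
        assert vals.std(ddof=1) / vals.mean() == pytest.approx(2.0 / 3.0)
        out = cv_filter(inst, img, params)
        assert (out.labels == 1).sum() == 3

    def test_hand_computed_cv_removes_speckle(self):
        """Intensities {1, 1, 1, 30}: CV ≈ 1.74 > ρ = 1.1, removed."""
        inst, img, params = self._tiny_map([[1.0, 1.0, 1.0, 30.0]])
        vals = img.voxels[inst.labels == 1]
        assert vals.std(ddof=1) / vals.mean() == pytest.approx(1.7576, abs=1e-3)
        out = cv_filter(inst, img, params)
        assert out.labels.max() == 0

    def test_uniform_intensity_kept(self):
        inst, img, params = self._tiny_map([[80.0, 80.0, 80.0]])
        out = cv_filter(inst, img, params)
        assert (out.labels == 1).sum() == 3

    def test_zero_mean_object_removed_with_warning(self):
        inst, img, params = self._tiny_map([[0.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="zero mean"):
            out = cv_filter(inst, img, params)
        assert out.labels.max() == 0

    def test_size_filter_after_cv(self):
        # a 1-voxel object survives CV (zero variance) but fails the
        # 25%-of-expected-volume size criterion (2 of 8 voxels)
        inst, img, params = self._tiny_map([[90.0]])
        out = cv_filter(inst, img, params)
        assert out.labels.max() == 0


class TestMedialAxis:
    def test_digital_ball_dominant_sphere_at_center(self, grid_small):
        ball = Spherocylinder(1, (2.0, 2.0, 2.0), (0, 0, 1), 0.0, 1.0)
        mask = rasterize_instances(CellArrangement([ball]), grid_small).labels == 1
        spheres = extract_medial_axis(mask, 1.0, grid_small)
        dominant = max(spheres, key=lambda s: s.radius)
        assert np.linalg.norm(dominant.center - 2.0) < 0.1
        assert 0.35 < dominant.radius < 0.5

    def test_rod_centers_on_axis(self, grid_small, single_rod):
        _, mask = single_rod
        spheres = extract_medial_axis(mask, 1.0, grid_small)
        pos = np.array([s.center for s in spheres])
        # all centers within one voxel of the analytic axis line (z=y=2)
        assert np.abs(pos[:, :2] - 2.0).max() <= 0.1
        # chain ordered along x and covering most of the cylinder segment
        assert np.all(np.diff(pos[:, 2]) > 0)
        assert pos[-1, 2] - pos[0, 2] > 1.5

    def test_radius_cap_strictly_below_half_diameter(self, grid_small, single_rod):
        _, mask = single_rod
        for d in (1.0, 0.6):
            spheres = extract_medial_axis(mask, d, grid_small)
            assert max(s.radius for s in spheres) < d / 2

    def test_thin_object_returns_chain_with_warning(self):
        grid = GridSpec((5, 5, 20), (0.1, 0.1, 0.1))
        mask = np.zeros(grid.shape, bool)
        mask[2, 2, 3:17] = True
        with pytest.warns(UserWarning, match="thin"):
            spheres = extract_medial_axis(mask, 1.0, grid)
        assert len(spheres) >= 1
        assert all(s.radius <= 0.11 for s in spheres)

    def test_empty_mask_rejected(self, grid_small):
        with pytest.raises(ValueError):
            extract_medial_axis(np.zeros(grid_small.shape, bool), 1.0, grid_small)


class TestNodeDirections:
    def test_collinear_points_get_line_direction(self):
        pts = np.stack([np.zeros(20), np.zeros(20), np.linspace(0, 4, 20)], axis=1)
        nodes = estimate_node_directions(pts, hops=5)
        for n in nodes:
            assert abs(n.direction @ np.array([0, 0, 1.0])) == pytest.approx(1.0, abs=1e-6)

    def test_l_shape_mid_arm_directions_match_filtered_pca(self):
        """Mid-arm nodes vs a brute-force PCA on the angle-filtered set."""
        arm_y = np.stack([np.zeros(10), np.linspace(0, 1.8, 10), np.zeros(10)], axis=1)
        arm_x = np.stack(
            [np.zeros(10), np.full(10, 2.0), np.linspace(0.2, 2.0, 10)], axis=1
        )
        pts = np.vstack([arm_y, arm_x])
        nodes = estimate_node_directions(pts, hops=5, angle_cutoff_deg=45.0)
        # brute-force oracle for one mid-arm node of the y-arm (index 4)
        i = 4
        bearings = pts - pts[i]
        norms = np.linalg.norm(bearings, axis=1)
        keep = norms > 0
        unit = bearings[keep] / norms[keep, None]
        ydir = np.array([0, 1.0, 0])
        inliers = np.abs(unit @ ydir) >= np.cos(np.radians(45.0))
        subset = np.vstack([pts[i], pts[keep][inliers]])
        c = subset - subset.mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        assert abs(nodes[i].direction @ vt[0]) == pytest.approx(1.0, abs=0.05)
        assert abs(nodes[i].direction @ ydir) > 0.98

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            estimate_node_directions(np.zeros((1, 3)))


class TestWeights:
    def test_analytic_values(self):
        p = LCutsParams(sigma_d=1.0, sigma_t=0.3, r=2.25)
        mk = lambda pos, d: AxisNode(position=pos, direction=d)
        a = mk((0, 0, 0), (0, 0, 1))
        assert lcuts_weights(a, mk((0, 0, 0), (0, 0, 1)), p) == pytest.approx(1.0)
        # beyond the squared-distance cutoff the weight is exactly zero
        far = mk((0, 0, 1.6), (0, 0, 1))  # D² = 2.56 > r = 2.25
        assert lcuts_weights(a, far, p) == 0.0
        # D = σ_D within cutoff, aligned directions -> e⁻¹
        assert lcuts_weights(a, mk((0, 0, 1.0), (0, 0, 1)), p) == pytest.approx(
            np.exp(-1.0)
        )
        # orthogonal directions at zero distance -> exp(-1/σ_T²)
        assert lcuts_weights(a, mk((0, 0, 0), (0, 1, 0)), p) == pytest.approx(
            np.exp(-1.0 / 0.3**2)
        )

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 3, (8, 3))
        dirs = rng.normal(size=(8, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        nodes = [AxisNode(p, d) for p, d in zip(pos, dirs)]
        p = LCutsParams()
        w = lcuts_weight_matrix(nodes, p)
        np.testing.assert_allclose(w, w.T)
        assert w.min() >= 0 and w.max() <= 1
        for i, j in [(0, 3), (2, 7)]:
            assert w[i, j] == pytest.approx(lcuts_weights(nodes[i], nodes[j], p))


def _chain(n, start, direction, spacing=0.2, ddir=None):
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    pts = np.asarray(start, float) + np.arange(n)[:, None] * spacing * direction
    return [AxisNode(p, ddir if ddir is not None else direction) for p in pts]


def _brute_force_min_ncut(w):
    n = len(w)
    best, best_val = None, np.inf
    for r in range(1, n // 2 + 1):
        for comb in itertools.combinations(range(n), r):
            m = np.zeros(n, bool)
            m[list(comb)] = True
            v = normalized_cut_value(w, m)
            if v < best_val:
                best_val, best = v, m
    return best, best_val


class TestLCutsCluster:
    def test_single_short_chain_is_one_group(self):
        nodes = _chain(10, (0, 0, 0), (0, 0, 1))
        assert lcuts_cluster(nodes, LCutsParams()) == [list(range(10))]

    def test_single_node(self):
        nodes = [AxisNode((0, 0, 0), (0, 0, 1))]
        assert lcuts_cluster(nodes, LCutsParams()) == [[0]]

    def test_disconnected_chains_split_by_distance_cutoff(self):
        nodes = _chain(8, (0, 0, 0), (0, 0, 1)) + _chain(8, (0, 3.0, 0), (0, 0, 1))
        groups = lcuts_cluster(nodes, LCutsParams())
        assert sorted(map(sorted, groups)) == [list(range(8)), list(range(8, 16))]

    def test_long_uniform_chain_splits_near_midpoint(self):
        # chain spanning twice the expected cell length with uniform direction
        nodes = _chain(31, (0, 0, 0), (0, 0, 1), spacing=0.2)  # 6 µm span
        groups = lcuts_cluster(nodes, LCutsParams(cell_length=3.0))
        assert len(groups) == 2
        sizes = sorted(len(g) for g in groups)
        assert sizes[0] >= 12  # balanced split, not an end sliver

    def test_elbow_first_cut_equals_brute_force(self, fused_grid):
        """First recursion's cut equals the exhaustive minimum nCut."""
        from tests.conftest import make_fused_pair
        from biofilm3d.postprocess import _spectral_bisect

        _, fused = make_fused_pair(90.0, fused_grid)
        mask = np.asarray(fused.labels) == 1
        spheres = extract_medial_axis(mask, 1.0, fused_grid, min_spacing=0.45)
        nodes = estimate_node_directions(spheres)
        assert len(nodes) <= 12
        w = lcuts_weight_matrix(nodes, LCutsParams())
        in_a = _spectral_bisect(w)
        assert in_a is not None
        _, best_val = _brute_force_min_ncut(w)
        assert normalized_cut_value(w, in_a) == pytest.approx(best_val, abs=1e-9)

    def test_deterministic_for_fixed_input(self):
        nodes = _chain(25, (0, 0, 0), (0, 1, 1), spacing=0.25)
        p = LCutsParams()
        assert lcuts_cluster(nodes, p) == lcuts_cluster(nodes, p)


class TestReconstruct:
    def test_clean_rod_round_trip_iou(self, grid_small, single_rod):
        _, mask = single_rod
        spheres = extract_medial_axis(mask, 1.0, grid_small)
        nodes = estimate_node_directions(spheres)
        groups = lcuts_cluster(nodes, LCutsParams())
        assert len(groups) == 1
        rec = reconstruct_cells(groups, nodes, grid_small, "spherocylinder", d=1.0)
        assert pair_iou(rec.labels == 1, mask) >= 0.8

    def test_convex_hull_contains_inscribed_spheres(self, grid_small, single_rod):
        _, mask = single_rod
        spheres = extract_medial_axis(mask, 1.0, grid_small)
        groups = [list(range(len(spheres)))]
        rec = reconstruct_cells(groups, spheres, grid_small, "convex_hull", d=1.0)
        # every voxel center inside any inscribed sphere is labeled
        zc = grid_small.axis_centers(0)
        yc = grid_small.axis_centers(1)
        xc = grid_small.axis_centers(2)
        pts = np.stack(np.meshgrid(zc, yc, xc, indexing="ij"), axis=-1).reshape(-1, 3)
        covered = np.zeros(len(pts), bool)
        for s in spheres:
            covered |= np.linalg.norm(pts - s.center, axis=1) <= s.radius
        labels = np.asarray(rec.labels).reshape(-1)
        assert np.all(labels[covered] == 1)

    def test_two_groups_make_disjoint_labels(self):
        grid = GridSpec((20, 20, 60), (0.1, 0.1, 0.1))
        nodes = _chain(8, (1.0, 1.0, 0.6), (0, 0, 1)) + _chain(
            8, (1.0, 1.0, 3.6), (0, 0, 1)
        )
        rec = reconstruct_cells(
            [list(range(8)), list(range(8, 16))], nodes, grid, "spherocylinder", d=1.0
        )
        assert set(np.unique(rec.labels)) == {0, 1, 2}


class TestSegmentVolume:
    def test_sparse_ideal_confidence_counts_perfectly(self, colony_sparse):
        _, grid, inst = colony_sparse
        conf = surrogate_confidence(inst, blur_sd=1.0, flip_noise=0.0, seed=1)
        intensity = ImageVolume(np.full(grid.shape, 100.0), grid)
        seg = segment_volume(conf, intensity, SegmentationConfig())
        m = match_instances(seg.instances, inst, 0.5)
        assert counting_accuracy(m) == 1.0

    def test_fused_pair_split_into_two_cells(self, fused_grid):
        from tests.conftest import make_fused_pair

        truth, fused = make_fused_pair(90.0, fused_grid)
        conf = surrogate_confidence(fused, blur_sd=1.0, flip_noise=0.0, seed=1)
        intensity = ImageVolume(np.full(fused_grid.shape, 100.0), fused_grid)
        seg = segment_volume(conf, intensity, SegmentationConfig())
        assert seg.pre_lcuts.n_objects == 1  # undersegmented before LCuts
        m = match_instances(seg.instances, truth, 0.5)
        assert m.tp == 2 and m.fp == 0 and m.fn == 0

    def test_high_cv_speckle_removed(self):
        grid = GridSpec((24, 24, 24), (0.1, 0.1, 0.1))
        interior = np.zeros(grid.shape)
        interior[8:16, 8:16, 8:16] = 1.0  # 512-voxel blob
        values = np.zeros((3,) + grid.shape)
        values[1] = interior
        values[0] = 1.0 - interior
        conf = ConfidenceMap(values, grid)
        # speckle intensity: one bright voxel on a near-zero background
        img = np.full(grid.shape, 0.01)
        img[12, 12, 12] = 1000.0
        seg = segment_volume(conf, ImageVolume(img, grid), SegmentationConfig())
        assert seg.instances.n_objects == 0

    def test_two_population_map_processes_channels_independently(self, grid_small):
        cells = [
            Spherocylinder(1, (2.0, 1.0, 2.0), (0, 0, 1), 1.5, 1.0, population=1),
            Spherocylinder(2, (2.0, 3.0, 5.5), (0, 0, 1), 0.0, 1.0, population=2),
        ]
        inst = rasterize_instances(CellArrangement(cells), grid_small)
        conf = surrogate_confidence(inst, blur_sd=1.0, flip_noise=0.0, seed=2)
        assert conf.n_classes == 5
        intensity = ImageVolume(np.full(grid_small.shape, 100.0), grid_small)
        seg = segment_volume(conf, intensity, SegmentationConfig())
        pops = set(seg.instances.populations.values())
        assert pops == {1, 2}
        m = match_instances(seg.instances, inst, 0.5)
        assert m.tp == 2
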