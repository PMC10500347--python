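"""Segmentation-stage contracts: filtering against a dense convolution
oracle, thresholding, watershed splitting, erosion and labelling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from octraman.octseg import (
    GaussianFilterSpec,
    SegmentationConfig,
    auto_threshold_mean,
    crop_reflection_planes,
    erode_inplane,
    gaussian_filter_3d,
    label_objects,
    segment_cells,
    stitch_grid,
    watershed_split,
)
from octraman.synth import (
    SyntheticCellParams,
    add_reflection_planes,
    generate_cell_volume,
    generate_multicell_volume,
)
from octraman.types import Volume3D

SPACING = (0.45, 0.45, 0.2)


def brute_force_gaussian(data, spec):
    """Independent oracle: build the dense 3D kernel as the outer product of
    the truncated, renormalised 1D kernels and convolve by explicit shifts
    over a reflect-padded array."""
    kernels = []
    for sigma in (spec.sigma_z_px, spec.sigma_r_px, spec.sigma_r_px):
        radius = int(np.ceil(spec.truncation_radius * sigma))
        x = np.arange(-radius, radius + 1, dtype=float)
        k = np.exp(-(x**2) / (2 * sigma**2))
        kernels.append(k / k.sum())
    kz, ky, kx = kernels
    rz, ry, rx = (k.size // 2 for k in kernels)
    padded = np.pad(data, ((rz, rz), (ry, ry), (rx, rx)), mode="symmetric")
    out = np.zeros_like(data, dtype=float)
    nz, ny, nx = data.shape
    for iz in range(kz.size):
        for iy in range(ky.size):
            for ix in range(kx.size):
                w = kz[iz] * ky[iy] * kx[ix]
                out += w * padded[iz : iz + nz, iy : iy + ny, ix : ix + nx]
    return out


class TestGaussianFilter:
    def test_constant_volume_unchanged(self):
        vol = Volume3D(np.full((12, 10, 10), 7.5), SPACING)
        out = gaussian_filter_3d(vol, GaussianFilterSpec())
        assert np.allclose(out.data, 7.5, atol=1e-12)

    def test_impulse_mass_conserved(self):
        data = np.zeros((40, 30, 30))
        data[20, 15, 15] = 1.0
        out = gaussian_filter_3d(Volume3D(data, SPACING), GaussianFilterSpec())
        assert out.data.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_dense_convolution_oracle(self):
        rng = np.random.default_rng(42)
        data = rng.uniform(size=(16, 16, 16))
        spec = GaussianFilterSpec(sigma_r_px=2.0, sigma_z_px=4.5)
        out = gaussian_filter_3d(Volume3D(data, SPACING), spec)
        oracle = brute_force_gaussian(data, spec)
        assert np.max(np.abs(out.data - oracle)) < 1e-10

    def test_total_intensity_preserved(self):
        rng = np.random.default_rng(3)
        data = rng.uniform(size=(20, 18, 18))
        out = gaussian_filter_3d(Volume3D(data, SPACING), GaussianFilterSpec())
        assert out.data.sum() == pytest.approx(data.sum(), rel=1e-6)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            GaussianFilterSpec(sigma_r_px=0.0)
        with pytest.raises(ValueError):
            GaussianFilterSpec(truncation_radius=2.0)


class TestMeanThreshold:
    def test_half_and_half(self):
        data = np.zeros((2, 10, 10))
        data[1] = 100.0
        mask, t = auto_threshold_mean(Volume3D(data, SPACING))
        assert t == 50.0
        assert np.array_equal(mask, data == 100.0)

    def test_constant_volume_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            auto_threshold_mean(Volume3D(np.full((4, 4, 4), 3.0), SPACING))

    def test_sphere_mask_dice_vs_truth(self):
        p = SyntheticCellParams(radius_um=6.0, interior_mean=100.0, background_sd=5.0)
        vol, truth = generate_cell_volume(p, SPACING, (70, 34, 34), seed=2)
        mask, _ = auto_threshold_mean(vol)
        gt = truth.label_map.labels == 1
        dice = 2 * (mask & gt).sum() / (mask.sum() + gt.sum())
        assert dice >= 0.9


def two_sphere_mask():
    z = np.arange(90) * 0.2
    y = np.arange(80) * 0.45
    x = np.arange(80) * 0.45
    Z, Y, X = np.meshgrid(z, y, x, indexing="ij")
    R = 6.0
    m1 = (X - 12.0) ** 2 + (Y - 18.0) ** 2 + (Z - 9.0) ** 2 <= R * R
    m2 = (X - 21.0) ** 2 + (Y - 18.0) ** 2 + (Z - 9.0) ** 2 <= R * R
    return m1, m2


class TestWatershed:
    def test_single_sphere_one_label(self):
        m1, _ = two_sphere_mask()
        assert watershed_split(m1, SPACING).n_objects == 1

    def test_overlapping_spheres_split_between_centers(self):
        m1, m2 = two_sphere_mask()
        lm = watershed_split(m1 | m2, SPACING)
        assert lm.n_objects == 2
        cx = sorted(
            np.nonzero(lm.labels == i)[2].mean() * 0.45 for i in lm.ids
        )
        # centroids fall on either side of the midpoint between sphere centres
        assert cx[0] < 16.5 < cx[1]

    def test_empty_mask_zero_labels(self):
        lm = watershed_split(np.zeros((5, 5, 5), bool), SPACING)
        assert lm.n_objects == 0

    def test_labels_partition_the_mask(self):
        m1, m2 = two_sphere_mask()
        mask = m1 | m2
        lm = watershed_split(mask, SPACING)
        assert np.array_equal(lm.labels > 0, mask)


class TestErosion:
    def test_isolated_voxel_removed(self):
        m = np.zeros((3, 7, 7), bool)
        m[1, 3, 3] = True
        assert not erode_inplane(m).any()

    def test_solid_5x5_shrinks_to_3x3(self):
        m = np.zeros((1, 9, 9), bool)
        m[0, 2:7, 2:7] = True
        out = erode_inplane(m)
        expect = np.zeros_like(m)
        expect[0, 3:6, 3:6] = True
        assert np.array_equal(out, expect)

    def test_full_slice_loses_border_ring(self):
        m = np.ones((1, 6, 8), bool)
        out = erode_inplane(m)
        expect = np.zeros_like(m)
        expect[0, 1:5, 1:7] = True
        assert np.array_equal(out, expect)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(arrays(bool, (3, 9, 9), elements=st.booleans()))
    def test_anti_extensive(self, m):
        assert not (erode_inplane(m) & ~m).any()


class TestLabelObjects:
    def test_two_disjoint_spheres(self):
        m1, _ = two_sphere_mask()
        m2 = np.roll(m1, 30, axis=2)  # second copy, 13.5 µm away: not touching
        lm = label_objects(m1 | m2, SPACING)
        assert lm.n_objects == 2

    def test_small_speck_filtered(self):
        m1, _ = two_sphere_mask()
        m = m1.copy()
        m[0, 0, 0:3] = True  # 3-voxel speck
        lm = label_objects(m, SPACING, min_object_voxels=10)
        assert lm.n_objects == 1

    def test_empty_mask(self):
        assert label_objects(np.zeros((4, 4, 4), bool), SPACING).n_objects == 0

    def test_relabelled_by_decreasing_size(self):
        m = np.zeros((3, 20, 20), bool)
        m[1, 1:3, 1:3] = True     # 4 voxels
        m[1, 10:16, 10:16] = True  # 36 voxels
        lm = label_objects(m, SPACING)
        assert (lm.labels[1, 10:16, 10:16] == 1).all()
        assert (lm.labels[1, 1:3, 1:3] == 2).all()


class TestCrop:
    @pytest.fixture()
    def cell_volume(self):
        p = SyntheticCellParams(radius_um=4.5, interior_mean=80.0, background_sd=1.0)
        vol, _ = generate_cell_volume(p, SPACING, (60, 26, 26), seed=8)
        return vol

    def test_no_bright_plane_identity(self, cell_volume):
        out = crop_reflection_planes(cell_volume, z_score_cutoff=5.0)
        assert out.shape == cell_volume.shape
        assert np.array_equal(out.data, cell_volume.data)

    def test_bright_plane_removed_exactly(self, cell_volume):
        bright = add_reflection_planes(cell_volume, [2], 50.0 * 1.0 * 80.0)
        out = crop_reflection_planes(bright, z_score_cutoff=5.0)
        assert out.meta["removed_z"] == [2]
        assert out.shape[0] == cell_volume.shape[0] - 1

    def test_manual_range_full_is_identity(self, cell_volume):
        nz = cell_volume.shape[0]
        out = crop_reflection_planes(cell_volume, manual_range=(0, nz - 1))
        assert np.array_equal(out.data, cell_volume.data)

    def test_all_slices_flagged_errors(self):
        data = np.zeros((5, 4, 4))
        data[:] = np.arange(5)[:, None, None] * 1000.0
        vol = Volume3D(data, SPACING)
        with pytest.raises(ValueError):
            crop_reflection_planes(vol, z_score_cutoff=-10.0)


class TestSegmentCells:
    def make_multicell(self, seed, n_rows=2, n_cols=3):
        rng = np.random.default_rng(seed)
        cells = []
        for r in range(n_rows):
            for c in range(n_cols):
                cells.append(
                    (
                        SyntheticCellParams(
                            radius_um=rng.uniform(5.0, 6.0),
                            protrusion_count=4,
                            protrusion_amplitude_um=rng.uniform(0.3, 0.8),
                            interior_mean=110.0,
                            interior_sd=12.0,
                            center_um=(17.0 * c + 11.0, 17.0 * r + 11.0, 9.0),
                        ),
                        "cell",
                    )
                )
        shape = (
            91,
            int((17.0 * (n_rows - 1) + 22.0) / 0.45) + 1,
            int((17.0 * (n_cols - 1) + 22.0) / 0.45) + 1,
        )
        return generate_multicell_volume(cells, SPACING, shape, seed=seed, background_sd=3.0)

    def test_recovers_cell_count(self):
        vol, truth = self.make_multicell(0)
        labels, report = segment_cells(vol)
        assert report["n_objects"] == truth.label_map.n_objects == 6

    def test_deterministic(self):
        vol, _ = self.make_multicell(1)
        a, _ = segment_cells(vol)
        b, _ = segment_cells(vol)
        assert np.array_equal(a.labels, b.labels)

    def test_debris_only_volume_zero_objects(self):
        """Bright debris specks but no cells: with a size floor below any
        plausible cell (~200 µm³ ≈ 5000 voxels, cells are >1000 µm³) the
        min-size filter must leave nothing — while an actual cell passes."""
        rng = np.random.default_rng(0)
        data = rng.normal(0.0, 0.5, size=(30, 40, 40)).clip(0)
        for _ in range(20):
            z, y, x = rng.integers(2, 28), rng.integers(2, 38), rng.integers(2, 38)
            data[z, y : y + 2, x : x + 2] = 100.0
        cfg = SegmentationConfig(min_object_voxels=5000)
        labels, report = segment_cells(Volume3D(data, SPACING), cfg)
        assert report["n_objects"] == 0
        # a genuine cell is far above the same floor
        p = SyntheticCellParams(radius_um=5.5, interior_mean=110.0, background_sd=2.0)
        cell_vol, _ = generate_cell_volume(p, SPACING, (70, 32, 32), seed=4)
        _, rep2 = segment_cells(cell_vol, cfg)
        assert rep2["n_objects"] == 1

    def test_stage_error_names_stage(self):
        vol = Volume3D(np.full((10, 8, 8), 5.0), SPACING)
        with pytest.raises(RuntimeError, match="threshold"):
            segment_cells(vol)


class TestStitch:
    def tiles(self, value=None):
        rng = np.random.default_rng(0)
        out = []
        for i in range(4):
            d = np.full((5, 8, 8), value) if value is not None else rng.uniform(size=(5, 8, 8))
            out.append(Volume3D(d.astype(float), SPACING))
        return out

    def test_single_tile_identity(self):
        t = self.tiles()[0]
        out = stitch_grid([t], (1, 1))
        assert np.array_equal(out.data, t.data)

    def test_2x2_no_overlap_dims(self):
        out = stitch_grid(self.tiles(), (2, 2), overlap_px=(0, 0))
        assert out.shape == (5, 16, 16)

    def test_constant_tiles_average_to_constant(self):
        out = stitch_grid(self.tiles(value=3.0), (2, 2), overlap_px=(2, 3))
        assert np.allclose(out.data, 3.0)

    def test_wrong_tile_count(self):
        with pytest.raises(ValueError, match="expected 4 tiles"):
            stitch_grid(self.tiles()[:3], (2, 2))
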