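import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import disk

from mtubesim import geometry as geo


def _disk_image(radius=20, shape=(64, 64), value=1.0):
    img = np.zeros(shape)
    rr, cc = disk((shape[0] // 2, shape[1] // 2), radius, shape=shape)
    img[rr, cc] = value
    return img


class TestBottomShape:
    def test_disk_recovered(self):
        img = _disk_image()
        mask = geo.bottom_shape(geo.Image2D(img))
        assert np.array_equal(mask.voxels, img > 0)

    def test_interior_hole_filled(self):
        img = _disk_image(radius=20)
        img[30:34, 30:34] = 0.0
        mask = geo.bottom_shape(geo.Image2D(img))
        assert np.array_equal(mask.voxels, _disk_image(radius=20) > 0)

    def test_largest_component_kept(self):
        img = _disk_image(radius=20)
        img[2:4, 2:4] = 1.0  # small satellite blob
        mask = geo.bottom_shape(geo.Image2D(img))
        assert np.array_equal(mask.voxels, _disk_image(radius=20) > 0)

    def test_empty_image_raises(self):
        with pytest.raises(ValueError, match="empty cell"):
            geo.bottom_shape(geo.Image2D(np.zeros((10, 10))))

    def test_idempotent(self):
        img = _disk_image()
        mask = geo.bottom_shape(geo.Image2D(img))
        again = geo.bottom_shape(geo.Image2D(mask.voxels.astype(float)))
        assert np.array_equal(mask.voxels, again.voxels)


class TestAreaProfile:
    @pytest.mark.parametrize(
        "area,z,expected", [(1000, 0.0, 1000.0), (1000, 1.0, 500.0), (1000, 2.0, 250.0)]
    )
    def test_exponential_decay(self, area, z, expected):
        assert geo.area_profile(area, z) == pytest.approx(expected)

    def test_negative_z_raises(self):
        with pytest.raises(ValueError):
            geo.area_profile(1000, -0.1)


class TestInterpolateShape:
    @staticmethod
    def _disks():
        big = geo.Mask2D(_disk_image(radius=40, shape=(100, 100)) > 0)
        small = geo.Mask2D(_disk_image(radius=10, shape=(100, 100)) > 0)
        return big, small

    def test_endpoints_exact(self):
        big, small = self._disks()
        assert np.array_equal(
            geo.interpolate_shape(big, small, big.area_px).voxels, big.voxels
        )
        assert np.array_equal(
            geo.interpolate_shape(big, small, small.area_px).voxels, small.voxels
        )

    def test_intermediate_area_within_tolerance(self):
        big, small = self._disks()
        target = np.pi * 25**2
        out = geo.interpolate_shape(big, small, target)
        assert abs(out.area_px - target) <= 0.01 * target

    def test_target_out_of_range_raises(self):
        big, small = self._disks()
        with pytest.raises(ValueError):
            geo.interpolate_shape(big, small, big.area_px * 2)

    def test_area_monotone_in_t_random_blobs(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            base = rng.random((48, 48)) > 0.6
            base = ndimage.binary_dilation(base, iterations=3)
            base = ndimage.binary_fill_holes(base)
            lab, n = ndimage.label(base)
            if n == 0:
                continue
            sizes = ndimage.sum_labels(base, lab, index=np.arange(1, n + 1))
            blob = geo.Mask2D(lab == 1 + int(np.argmax(sizes)))
            inner = geo.Mask2D(ndimage.binary_erosion(blob.voxels, iterations=4))
            if not inner.voxels.any():
                continue
            targets = np.linspace(blob.area_px, inner.area_px, 6)
            areas = [
                geo.interpolate_shape(blob, inner, t).area_px for t in targets
            ]
            # decreasing targets give (weakly) decreasing achieved areas
            assert all(a >= b - 1 for a, b in zip(areas, areas[1:]))


class TestBuildVolume:
    def test_slice_count_height_1p6(self):
        bottom = geo.Mask2D(_disk_image(radius=25, shape=(64, 64)) > 0)
        vol = geo.build_volume(bottom, height_um=1.6, z_step_um=0.2)
        assert vol.n_slices == 8

    def test_single_slice_equals_bottom(self):
        bottom = geo.Mask2D(_disk_image(radius=25, shape=(64, 64)) > 0)
        vol = geo.build_volume(bottom, height_um=0.2, z_step_um=0.2)
        assert vol.n_slices == 1
        assert np.array_equal(vol.voxels[0], bottom.voxels)

    def test_area_sequence_follows_profile(self):
        bottom = geo.Mask2D(_disk_image(radius=28, shape=(72, 72)) > 0)
        vol = geo.build_volume(bottom, height_um=1.2, z_step_um=0.2)
        areas = vol.slice_areas()
        for k, a in enumerate(areas):
            expected = geo.area_profile(bottom.area_px, k * 0.2)
            assert abs(a - expected) <= 0.05 * expected

    def test_areas_weakly_decreasing(self):
        rng = np.random.default_rng(1)
        blob = rng.random((60, 60)) > 0.5
        blob = ndimage.binary_fill_holes(ndimage.binary_dilation(blob, iterations=4))
        vol = geo.build_volume(geo.Mask2D(blob), height_um=1.6, z_step_um=0.2)
        areas = vol.slice_areas()
        assert all(a >= b for a, b in zip(areas, areas[1:]))


def _two_cell_field():
    tub = np.zeros((80, 140))
    nuc = np.zeros_like(tub)
    rr, cc = disk((40, 35), 28, shape=tub.shape)
    tub[rr, cc] = 5.0
    rr, cc = disk((40, 105), 28, shape=tub.shape)
    tub[rr, cc] = 5.0
    rr, cc = disk((40, 35), 8, shape=tub.shape)
    nuc[rr, cc] = 10.0
    rr, cc = disk((40, 105), 8, shape=tub.shape)
    nuc[rr, cc] = 10.0
    return geo.Image2D(tub), geo.Image2D(nuc)


class TestSegmentField:
    def test_single_cell(self):
        tub = geo.Image2D(_disk_image(radius=25, value=5.0))
        nuc = geo.Image2D(_disk_image(radius=8, value=10.0))
        regions = geo.segment_field(tub, nuc)
        assert len(regions) == 1
        cell, nucleus = regions[0]
        assert nucleus.voxels.sum() > 0
        assert not np.any(nucleus.voxels & ~cell.voxels)

    def test_two_cells_disjoint_and_contain_seeds(self):
        tub, nuc = _two_cell_field()
        regions = geo.segment_field(tub, nuc)
        assert len(regions) == 2
        a, b = regions
        assert not np.any(a[0].voxels & b[0].voxels)
        for cell, nucleus in regions:
            assert nucleus.voxels.any()
            assert not np.any(nucleus.voxels & ~cell.voxels)

    def test_no_nuclei_warns_and_returns_empty(self):
        tub = geo.Image2D(_disk_image(radius=25, value=5.0))
        nuc = geo.Image2D(np.zeros_like(tub.pixels))
        with pytest.warns(UserWarning):
            assert geo.segment_field(tub, nuc) == []


class TestCentrosomeDetection:
    @staticmethod
    def _cell_with_spot(spot_yx):
        img = _disk_image(radius=30, shape=(80, 80), value=1.0)
        yy, xx = np.mgrid[0:80, 0:80]
        img += 10.0 * np.exp(
            -((yy - spot_yx[0]) ** 2 + (xx - spot_yx[1]) ** 2) / (2 * 3.0**2)
        ) * (img > 0)
        nucleus = geo.Mask2D(_disk_image(radius=8, shape=(80, 80)) > 0)
        return geo.Image2D(img), nucleus

    def test_bright_spot_near_nucleus_found(self):
        img, nucleus = self._cell_with_spot((40, 55))
        x, y = geo.detect_centrosome_xy(img, nucleus)
        assert abs(x - 55) <= 1 and abs(y - 40) <= 1

    def test_out_of_vicinity_spot_ignored(self):
        img, nucleus = self._cell_with_spot((40, 52))
        # much brighter spot far outside the vicinity of the nucleus
        img.pixels[5, 5] = 1000.0
        x, y = geo.detect_centrosome_xy(img, nucleus)
        assert abs(x - 52) <= 2 and abs(y - 40) <= 2

    def test_uniform_image_row_major_tie_break(self):
        img = geo.Image2D(_disk_image(radius=30, shape=(80, 80), value=1.0))
        nucleus = geo.Mask2D(_disk_image(radius=8, shape=(80, 80)) > 0)
        x1, y1 = geo.detect_centrosome_xy(img, nucleus)
        x2, y2 = geo.detect_centrosome_xy(img, nucleus)
        assert (x1, y1) == (x2, y2)  # deterministic first row-major argmax


class TestCentrosomeZ:
    def test_no_model_returns_central_slice(self):
        img = geo.Image2D(np.ones((10, 10)))
        assert geo.estimate_centrosome_z(img, (5, 5), None, 8) == 4

    def test_intercept_only_model(self):
        img = geo.Image2D(np.random.default_rng(0).random((10, 10)))
        model = geo.CentrosomeZModel((2.0, 0.0, 0.0, 0.0))
        assert geo.estimate_centrosome_z(img, (3, 3), model, 8) == 2

    def test_regression_recovers_planted_relation(self, rng):
        # least squares on noiseless synthetic (image stats -> z) pairs
        true = np.array([1.0, 0.5, -2.0, 0.1])
        X, y = [], []
        for _ in range(50):
            img = rng.random((12, 12)) * 10
            feats = np.array([1.0, img.max(), img.mean(), img[4, 7]])
            X.append(feats)
            y.append(feats @ true)
        coef, *_ = np.linalg.lstsq(np.array(X), np.array(y), rcond=None)
        resid = np.array(X) @ coef - np.array(y)
        ss_tot = np.var(y) * len(y)
        assert 1 - resid @ resid / ss_tot > 0.99
        model = geo.CentrosomeZModel(tuple(coef))
        img = geo.Image2D(np.full((12, 12), 2.0))
        pred = geo.estimate_centrosome_z(img, (7, 4), model, 100)
        expected = np.clip(round(np.array([1, 2, 2, 2]) @ true), 0, 99)
        assert pred == expected


class TestAssembleGeometry:
    @staticmethod
    def _masks():
        cell = np.zeros((4, 30, 30), dtype=bool)
        cell[:, 5:25, 5:25] = True
        nuc = np.zeros_like(cell)
        nuc[:, 12:18, 12:18] = True
        return geo.Mask3D(cell), geo.Mask3D(nuc)

    def test_valid_inputs(self):
        cell, nuc = self._masks()
        g = geo.assemble_geometry(cell, nuc, (7, 7, 1))
        assert g.centrosome == (7, 7, 1)
        assert g.height_um == pytest.approx(0.8)

    def test_centrosome_in_nucleus_relocated_to_nearest_cytosol(self):
        cell, nuc = self._masks()
        g = geo.assemble_geometry(cell, nuc, (14, 14, 1))
        x, y, z = g.centrosome
        cytosol = g.cytosol
        assert cytosol[z, y, x]
        # brute-force nearest cytosolic voxel in physical distance
        zz, yy, xx = np.nonzero(cytosol)
        d2 = (
            ((xx - 14) * 0.2) ** 2
            + ((yy - 14) * 0.2) ** 2
            + ((zz - 1) * 0.2) ** 2
        )
        best = d2.min()
        got = ((x - 14) * 0.2) ** 2 + ((y - 14) * 0.2) ** 2 + ((z - 1) * 0.2) ** 2
        assert got == pytest.approx(best)

    def test_nucleus_outside_cell_raises(self):
        cell, nuc = self._masks()
        bad = nuc.voxels.copy()
        bad[:, 0:3, 0:3] = True
        with pytest.raises(ValueError, match="nucleus"):
            geo.assemble_geometry(cell, geo.Mask3D(bad), (7, 7, 1))
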