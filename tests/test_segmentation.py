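"""Segmentation operators: Otsu, morphology, Laplacian veins, composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import xrfquant as xq

from xrfquant.segmentation import SegmentationParams, laplacian_kernels

from conftest import make_uniform_bundle


def brute_force_otsu(values: np.ndarray) -> int:
    """Exhaustive 256-threshold minimization of intra-class variance."""
    best_t, best = 0, np.inf
    for t in range(256):
        lo = values[values <= t]
        hi = values[values > t]
        within = 0.0
        if lo.size:
            within += lo.size * lo.astype(float).var()
        if hi.size:
            within += hi.size * hi.astype(float).var()
        within /= values.size
        if within < best - 1e-12:
            best, best_t = within, t
    return best_t


class TestOtsu:
    def test_two_valued_raster_separated_exactly(self):
        arr = np.full((10, 10), 10, dtype=np.uint8)
        arr[:, 5:] = 200
        mask = xq.otsu_mask(xq.IntensityRaster(arr, "Zn"))
        np.testing.assert_array_equal(mask, arr == 200)

    def test_constant_raster_gives_empty_mask(self, caplog):
        arr = np.full((6, 6), 42, dtype=np.uint8)
        with caplog.at_level("WARNING"):
            mask = xq.otsu_mask(xq.IntensityRaster(arr, "K"))
        assert not mask.any()
        assert "no Otsu threshold" in caplog.text

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        # bimodal-ish raster: mixture of two bands plus outliers
        arr = np.concatenate([
            rng.integers(0, 90, 600),
            rng.integers(120, 256, 400),
            rng.integers(0, 256, 24),
        ]).astype(np.uint8)
        rng.shuffle(arr)
        raster = xq.IntensityRaster(arr.reshape(32, 32), "Ca")
        assert xq.otsu_threshold(raster) == brute_force_otsu(arr)

    def test_16bit_uses_minmax_scaled_histogram(self):
        arr = np.full((10, 10), 1000, dtype=np.uint16)
        arr[:, 5:] = 30000
        mask = xq.otsu_mask(xq.IntensityRaster(arr, "Zn"))
        np.testing.assert_array_equal(mask, arr == 30000)


class TestPlantMask:
    def test_union_of_identical_masks_is_that_mask(self):
        arr = np.zeros((12, 12), dtype=np.uint8)
        arr[3:9, 3:9] = 200
        rasters = {e: xq.IntensityRaster(arr, e) for e in xq.ELEMENTS}
        bundle = xq.ScanBundle(rasters=rasters, sample_id="s")
        np.testing.assert_array_equal(xq.plant_mask(bundle), arr == 200)

    def test_disjoint_single_pixels_union_to_four(self):
        rasters = {}
        for i, e in enumerate(xq.METALS):
            arr = np.zeros((8, 8), dtype=np.uint8)
            arr[i, i] = 255
            rasters[e] = xq.IntensityRaster(arr, e)
        rasters["Compton"] = xq.IntensityRaster(
            np.zeros((8, 8), dtype=np.uint8), "Compton"
        )
        bundle = xq.ScanBundle(rasters=rasters, sample_id="s")
        assert int(xq.plant_mask(bundle).sum()) == 4

    def test_plant_mask_superset_of_each_element_mask(self, one_plant):
        bundle, _ = one_plant
        plant = xq.plant_mask(bundle)
        for e in xq.METALS:
            assert np.all(plant | ~xq.otsu_mask(bundle[e]))


class TestBladePetioleMargin:
    params = SegmentationParams()

    def test_opening_removes_strip_keeps_square(self):
        plant = np.zeros((80, 120), bool)
        plant[10:60, 10:60] = True          # 50x50 blade
        plant[30:35, 60:110] = True         # 5-px strip
        blade = xq.blade_mask(plant, self.params)
        assert blade[10:60, 10:60].all()
        assert not blade[30:35, 62:110].any()

    def test_opening_kills_entirely_thin_blob(self):
        plant = np.zeros((40, 40), bool)
        plant[10:14, 5:35] = True
        assert not xq.blade_mask(plant, self.params).any()

    def test_opening_idempotent(self, one_plant):
        bundle, _ = one_plant
        plant = xq.plant_mask(bundle)
        once = xq.blade_mask(plant, self.params)
        twice = xq.blade_mask(once, self.params)
        np.testing.assert_array_equal(once, twice)

    def test_plant_equal_blade_gives_empty_petiole(self):
        plant = np.zeros((30, 30), bool)
        plant[5:25, 5:25] = True
        blade = plant.copy()
        assert not xq.petiole_mask(plant, blade, self.params).any()

    def test_small_component_area_threshold(self):
        # 1000x1000 image: 0.001% of area = 10 px; a 5-px residual drops,
        # an 11-px residual stays
        plant = np.zeros((1000, 1000), bool)
        blade = np.zeros_like(plant)
        plant[0:1, 0:5] = True            # 5 px component
        plant[10:11, 0:11] = True         # 11 px component
        petiole = xq.petiole_mask(plant, blade, self.params)
        assert not petiole[0, :].any()
        assert petiole[10, :11].all()

    def test_t_shaped_fixture_recovers_strip(self):
        plant = np.zeros((100, 100), bool)
        plant[20:60, 20:60] = True          # blade
        plant[60:95, 37:42] = True          # 5-px-wide stem
        blade = xq.blade_mask(plant, self.params)
        petiole = xq.petiole_mask(plant, blade, self.params)
        # the stem's lower part is pure petiole
        assert petiole[70:95, 37:42].all()
        assert not petiole[20:50, 20:60].any()

    def test_margin_band_on_20px_square(self):
        blade = np.zeros((40, 40), bool)
        blade[10:30, 10:30] = True
        margin = xq.margin_mask(blade, self.params)
        assert int(margin.sum()) == 20**2 - 14**2  # 204
        inner = np.zeros_like(blade)
        inner[13:27, 13:27] = True
        np.testing.assert_array_equal(margin, blade & ~inner)

    def test_margin_of_empty_blade_is_empty(self):
        assert not xq.margin_mask(np.zeros((10, 10), bool), self.params).any()

    def test_thin_blade_becomes_all_margin(self):
        blade = np.zeros((30, 30), bool)
        blade[10:15, 5:25] = True  # 5 px < 7 kernel
        np.testing.assert_array_equal(
            xq.margin_mask(blade, self.params), blade
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_erosion_is_anti_extensive(self, seed):
        rng = np.random.default_rng(seed)
        blade = rng.random((30, 30)) > 0.4
        margin = xq.margin_mask(blade, self.params)
        assert np.all(blade | ~margin)  # margin subset of blade


class TestLaplacian:
    params = SegmentationParams()

    def _raster(self, arr):
        return xq.IntensityRaster(np.asarray(arr, dtype=np.uint8), "Compton")

    def test_constant_image_gives_zero_response(self):
        lap = xq.laplacian(self._raster(np.full((20, 20), 77)), self.params)
        np.testing.assert_allclose(lap, 0.0)

    def test_linear_ramp_gives_zero_away_from_borders(self):
        ramp = np.tile(np.arange(30, dtype=np.uint8) * 4, (30, 1))
        lap = xq.laplacian(self._raster(ramp), self.params)
        np.testing.assert_allclose(lap[5:-5, 5:-5], 0.0, atol=1e-9)

    def test_bright_ridge_most_negative_on_crest(self):
        img = np.full((30, 30), 100, dtype=np.uint8)
        img[:, 14:17] = 220
        lap = xq.laplacian(self._raster(img), self.params)
        crest_col = np.argmin(lap[15])
        assert crest_col in (14, 15, 16)
        assert lap[15, 15] < -1000

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ValueError, match="aperture"):
            xq.laplacian(self._raster(np.zeros((5, 5))), self.params)

    def test_aperture3_kernels_are_classic(self):
        d2, sm = laplacian_kernels(3)
        np.testing.assert_array_equal(d2, [1, -2, 1])
        np.testing.assert_array_equal(sm, [1, 2, 1])


class TestSkeletonAndVeins:
    params = SegmentationParams()

    def test_one_px_line_unchanged(self):
        mask = np.zeros((20, 20), bool)
        mask[10, 2:18] = True
        np.testing.assert_array_equal(xq.skeletonize(mask), mask)

    def test_solid_bar_thins_to_medial_line(self):
        mask = np.zeros((15, 60), bool)
        mask[5:10, 5:55] = True
        skel = xq.skeletonize(mask)
        assert np.all(mask | ~skel)
        # roughly one pixel per column across the bar's length
        cols = skel[:, 10:50].sum(axis=0)
        assert np.all(cols <= 2) and cols.mean() <= 1.2
        assert skel[:, 10:50].any(axis=0).all()

    def test_empty_mask_skeleton_empty(self):
        assert not xq.skeletonize(np.zeros((5, 5), bool)).any()

    def test_flat_compton_gives_empty_vein_mask(self):
        compton = xq.IntensityRaster(np.full((30, 30), 50, np.uint8), "Compton")
        blade = np.ones((30, 30), bool)
        margin = np.zeros((30, 30), bool)
        vein = xq.vein_mask(compton, blade, margin, self.params)
        assert not vein.any()

    def test_vein_pixels_inside_blade_interior(self, one_plant):
        bundle, _ = one_plant
        plant = xq.plant_mask(bundle)
        blade = xq.blade_mask(plant, self.params)
        margin = xq.margin_mask(blade, self.params)
        vein = xq.vein_mask(bundle["Compton"], blade, margin, self.params)
        assert np.all((blade & ~margin) | ~vein)

    def test_vein_recall_on_noiseless_fixture(self, noiseless_plant):
        bundle, truth = noiseless_plant
        labels = xq.segment(bundle)
        true_vein = truth.mask("vein")
        pred_vein = labels.mask("vein")
        recall = (true_vein & pred_vein).sum() / true_vein.sum()
        assert recall >= 0.8


class TestSegment:
    def _partition_ok(self, labels, plant, blade):
        margin = labels.mask("margin")
        vein = labels.mask("vein")
        tissue = labels.mask("tissue")
        petiole = labels.mask("petiole")
        union = margin | vein | tissue
        assert np.array_equal(union, blade)
        assert not (margin & vein).any()
        assert not (margin & tissue).any()
        assert not (vein & tissue).any()
        assert not (petiole & blade).any()
        assert np.all(plant | ~labels.plant)

    def test_partition_invariants_on_synthetic_rosette(self, segmented_plant):
        bundle, _, labels = segmented_plant
        plant = xq.plant_mask(bundle)
        blade = xq.blade_mask(plant, SegmentationParams())
        self._partition_ok(labels, plant, blade)

    def test_all_zero_bundle_is_all_background(self):
        bundle = make_uniform_bundle(value=0)
        labels = xq.segment(bundle)
        assert not labels.plant.any()

    def test_segment_is_deterministic(self, one_plant):
        bundle, _ = one_plant
        a = xq.segment(bundle)
        b = xq.segment(bundle)
        np.testing.assert_array_equal(a.classes, b.classes)

    def test_per_class_f1_on_noiseless_fixture(self, noiseless_plant):
        bundle, truth = noiseless_plant
        labels = xq.segment(bundle)
        for cls in xq.SUBSTRUCTURES:
            t = truth.mask(cls)
            p = labels.mask(cls)
            tp = (t & p).sum()
            prec = tp / max(p.sum(), 1)
            rec = tp / max(t.sum(), 1)
            f1 = 2 * prec * rec / max(prec + rec, 1e-12)
            assert f1 >= 0.8, f"{cls}: F1={f1:.3f}"

    def test_tiny_plant_classified_as_petiole(self, caplog):
        arr = np.zeros((40, 40), dtype=np.uint8)
        arr[18:24, 18:24] = 200  # 6x6 blob, smaller than opening kernel
        rasters = {e: xq.IntensityRaster(arr, e) for e in xq.ELEMENTS}
        bundle = xq.ScanBundle(rasters=rasters, sample_id="tiny")
        with caplog.at_level("WARNING"):
            labels = xq.segment(bundle)
        assert labels.mask("petiole").sum() == 36
        assert "petiole" in caplog.text

    def test_opening_monotonicity_in_petiole_area(self, one_plant):
        bundle, _ = one_plant
        plant = xq.plant_mask(bundle)
        areas = []
        for k in (7, 11, 15, 19, 23):
            params = SegmentationParams(opening_kernel=k)
            blade = xq.blade_mask(plant, params)
            areas.append(int(xq.petiole_mask(plant, blade, params).sum()))
        assert areas == sorted(areas)
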