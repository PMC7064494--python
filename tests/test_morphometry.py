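"""Entropy filter, Canny edges, region geometry and the 24-feature vector."""
from dataclasses import replace

import numpy as np
import pytest
from scipy.ndimage import binary_erosion

import blastomorph as bm
from blastomorph.containers import Micrograph, RegionMasks
from blastomorph.morphometry import (FEATURE_NAMES, FEATURE_UNITS, N_FEATURES,
                                     FeatureConfig, canny_edges,
                                     extract_features, local_entropy_map,
                                     normalize_resolution, region_geometry)

from conftest import zero_noise_spec
import oracles


def _micrograph(pixels, mpp=1.0):
    return Micrograph(pixels=np.asarray(pixels, dtype=np.uint8),
                      microns_per_pixel=mpp)


def _disk_mask(shape, cy, cx, r):
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    return (ys - cy) ** 2 + (xs - cx) ** 2 <= r * r


class TestNormalizeResolution:
    def test_identity_when_target_matches(self):
        m = _micrograph(np.random.default_rng(0).integers(0, 256, (64, 64)))
        out = normalize_resolution(m, 1.0)
        assert out is m

    def test_downscale_preserves_physical_area(self):
        mask = _disk_mask((128, 128), 64, 64, 40)
        masks = RegionMasks(zp=mask, te=np.zeros_like(mask),
                            inner=np.zeros_like(mask))
        m = _micrograph(np.full((128, 128), 100), mpp=0.5)
        area_before = mask.sum() * 0.5 ** 2
        _, resampled = normalize_resolution(m, 1.0, masks)
        area_after = resampled.zp.sum() * 1.0 ** 2
        assert abs(area_after - area_before) / area_before < 0.05

    def test_constant_image_stays_constant(self):
        m = _micrograph(np.full((64, 64), 77), mpp=0.5)
        out = normalize_resolution(m, 1.0)
        assert (out.pixels == 77).all()
        assert out.microns_per_pixel == 1.0

    def test_nonpositive_target_is_an_error(self):
        m = _micrograph(np.zeros((32, 32)))
        with pytest.raises(ValueError):
            normalize_resolution(m, 0.0)


class TestLocalEntropy:
    def test_constant_image_has_zero_entropy(self):
        m = _micrograph(np.full((64, 64), 50))
        assert (local_entropy_map(m, 5) == 0).all()

    def test_balanced_two_level_neighbourhood_is_one_bit(self):
        """A neighbourhood split evenly between two intensities: 1 bit."""
        img = np.zeros((64, 64))
        img[:, 32:] = 200
        m = _micrograph(img)
        ent = local_entropy_map(m, 5)
        # at the step, the disk holds both intensities in equal counts
        col = 32  # disk centred just right of the step: 30 px either side
        assert ent[40, 31] == pytest.approx(1.0, abs=0.15)

    def test_matches_direct_histogram_oracle_on_noise(self):
        rng = np.random.default_rng(12)
        img = rng.integers(0, 256, (80, 80)).astype(np.uint8)
        m = _micrograph(img)
        ent = local_entropy_map(m, 9)
        pts = [(int(r), int(c)) for r, c in
               zip(rng.integers(15, 65, 20), rng.integers(15, 65, 20))]
        ours = np.array([ent[r, c] for r, c in pts])
        oracle = np.array([oracles.disk_histogram_entropy(img, 9, r, c)
                           for r, c in pts])
        assert (ours > 0).all() and (ours <= 8).all()
        assert abs(ours.mean() - oracle.mean()) <= 0.05

    def test_oversized_radius_is_an_error(self):
        m = _micrograph(np.zeros((40, 40)))
        with pytest.raises(ValueError, match="half-extent"):
            local_entropy_map(m, 30)


class TestCanny:
    def test_constant_image_has_no_edges(self):
        m = _micrograph(np.full((64, 64), 90))
        assert not canny_edges(m).any()

    def test_vertical_step_yields_one_pixel_wide_edge(self):
        img = np.zeros((64, 64))
        img[:, 32:] = 180
        m = _micrograph(img)
        edges = canny_edges(m, sigma=1.0)
        count = int(edges.sum())
        assert abs(count - 64) <= 0.1 * 64
        cols = np.flatnonzero(edges.any(axis=0))
        assert len(cols) <= 2  # ~1 px wide, possibly straddling the step

    def test_zero_noise_phantom_edges_lie_on_interfaces(self):
        sample = bm.generate_phantom(
            zero_noise_spec(microns_per_pixel=1.0, image_size=None), seed=2)
        edges = canny_edges(sample.micrograph)
        # ground-truth boundary band: 3 px around each region interface
        from scipy.ndimage import binary_dilation
        band = np.zeros(sample.masks.shape, dtype=bool)
        for _, mask in sample.masks.items():
            band |= binary_dilation(mask, iterations=3) & \
                ~binary_erosion(mask, iterations=3)
        assert edges.any()
        assert (edges & ~band).sum() == 0

    def test_invalid_thresholds_are_errors(self):
        m = _micrograph(np.zeros((32, 32)))
        with pytest.raises(ValueError):
            canny_edges(m, sigma=0.0)
        with pytest.raises(ValueError):
            canny_edges(m, low=0.9, high=0.5)


class TestRegionGeometry:
    @staticmethod
    def _masks_with(zp):
        inner = np.zeros_like(zp)
        inner[2:5, 2:5] = True
        te = np.zeros_like(zp)
        te[2:5, 8:11] = True
        return RegionMasks(zp=zp, te=te, inner=inner)

    def test_square_area_and_perimeter(self):
        zp = np.zeros((64, 64), dtype=bool)
        zp[20:30, 20:30] = True
        geom = region_geometry(self._masks_with(zp), 1.0)
        area, perim = geom["zp"]
        assert area == 100.0
        assert abs(perim - 40.0) / 40.0 < 0.10

    def test_disk_area_matches_pixel_count(self):
        zp = _disk_mask((64, 64), 32, 32, 20)
        geom = region_geometry(self._masks_with(zp), 0.5)
        area, _ = geom["zp"]
        assert area == zp.sum() * 0.25
        assert abs(area - np.pi * 10 ** 2) / (np.pi * 100) < 0.02

    def test_area_stable_across_rescaling(self):
        mask = _disk_mask((128, 128), 64, 64, 40)
        masks = RegionMasks(zp=mask, te=np.zeros_like(mask),
                            inner=np.zeros_like(mask))
        m = _micrograph(np.full((128, 128), 128), mpp=1.0)
        area_native = mask.sum() * 1.0
        _, half = normalize_resolution(m, 2.0, masks)
        area_rescaled = half.zp.sum() * 2.0 ** 2
        assert abs(area_rescaled - area_native) / area_native < 0.05

    def test_empty_region_is_an_error(self):
        zp = np.zeros((64, 64), dtype=bool)
        zp[1:10, 1:10] = True
        masks = RegionMasks(zp=zp, te=np.zeros_like(zp),
                            inner=np.zeros_like(zp))
        with pytest.raises(ValueError, match="te"):
            region_geometry(masks, 1.0)


class TestExtractFeatures:
    def test_exactly_24_named_finite_features(self, small_cohort):
        for sample in small_cohort.samples[:4]:
            fv = extract_features(sample.micrograph, sample.masks)
            assert len(fv.values) == N_FEATURES == 24
            assert fv.names == FEATURE_NAMES
            assert np.isfinite(fv.values).all()
            assert set(fv.units) == set(FEATURE_NAMES)

    def test_zero_noise_phantom_is_textureless(self):
        sample = bm.generate_phantom(
            zero_noise_spec(microns_per_pixel=1.0, image_size=None), seed=6)
        fv = extract_features(sample.micrograph, sample.masks)
        ent = local_entropy_map(sample.micrograph, 9)
        for region, mask in sample.masks.items():
            assert fv[f"sd_intensity_{region}"] == 0.0
            # Chebyshev erosion by 10 px clears the 9-px entropy disk
            interior = binary_erosion(mask, structure=np.ones((3, 3)),
                                      iterations=10)
            if interior.any():
                assert ent[interior].mean() == pytest.approx(0.0, abs=1e-9)

    def test_geometry_stable_across_calibration_regimes(self):
        """Same physical phantom at 0.5 vs 0.25 µm/px: µm features agree."""
        spec20 = bm.PhantomSpec(microns_per_pixel=0.5)
        spec40 = replace(spec20, microns_per_pixel=0.25, image_size=None)
        f20 = extract_features(*_sample_pair(spec20, seed=14))
        f40 = extract_features(*_sample_pair(spec40, seed=14))
        for region in ("zp", "te", "inner"):
            for feat in ("area", "perimeter"):
                a, b = f20[f"{feat}_{region}"], f40[f"{feat}_{region}"]
                assert abs(a - b) / a < 0.05, (feat, region, a, b)

    def test_identical_inputs_identical_vectors(self, small_cohort):
        s = small_cohort.samples[0]
        a = extract_features(s.micrograph, s.masks)
        b = extract_features(s.micrograph, s.masks)
        assert np.array_equal(a.values, b.values)

    def test_mismatched_grid_is_an_error(self, small_cohort):
        s = small_cohort.samples[0]
        other = _micrograph(np.zeros((64, 64)))
        with pytest.raises(ValueError, match="shape"):
            extract_features(other, s.masks)


def _sample_pair(spec, seed):
    s = bm.generate_phantom(spec, seed)
    return s.micrograph, s.masks


def test_feature_units_are_stable():
    assert FEATURE_UNITS["area_zp"] == "um^2"
    assert FEATURE_UNITS["mean_entropy_te"] == "bits"
    assert FEATURE_UNITS["edge_density_inner"] == "per_um"
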