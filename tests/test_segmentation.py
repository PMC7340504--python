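"""Spot and site segmentation against rendered ground truth."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from burstfish import segmentation as seg
from burstfish.stack import ImageStack3D, spot_diameter_pixels
from burstfish.synthetic import SceneSpec, render_stack


def make_stack(data):
    return ImageStack3D(np.asarray(data, dtype=float), role="fish")


def obj(x, y, z, n):
    coords = np.zeros((n, 2), dtype=int)
    return seg.Object2D(x=x, y=y, z=z, coords=coords, n_pixels=n)


def test_diffraction_limited_diameter_is_8_pixels():
    assert spot_diameter_pixels(600.0, 76.0) == 8
    assert seg.DEFAULT_MIN_PIXELS == 8


class TestThresholdScan:
    def test_plateau_found_and_count_accurate(self, standard_scene,
                                              cutoff_grid):
        _, fish, _, truth = standard_scene
        scan = seg.scan_thresholds(fish, cutoff_grid)
        assert scan.ok
        lo, hi = scan.plateau_cutoffs
        assert lo <= scan.selected_cutoff <= hi
        spots = seg.segment_mature(fish, scan.require())
        n_true = len(truth.mature_centroids) + len(truth.site_centroids)
        assert abs(len(spots) - n_true) / n_true <= 0.05

    def test_plateau_counts_are_flat(self, standard_scene, cutoff_grid):
        _, fish, _, _ = standard_scene
        scan = seg.scan_thresholds(fish, cutoff_grid)
        i, j = scan.plateau
        counts = scan.counts[i:j + 1].astype(float)
        assert counts.max() / counts.min() <= 1.05

    def test_spot_count_insensitive_within_plateau(self, standard_scene,
                                                   cutoff_grid):
        _, fish, _, _ = standard_scene
        scan = seg.scan_thresholds(fish, cutoff_grid)
        lo, hi = scan.plateau_cutoffs
        n_lo = len(seg.segment_mature(fish, lo))
        n_hi = len(seg.segment_mature(fish, hi))
        assert abs(n_lo - n_hi) / n_lo <= 0.05

    def test_blank_stack_fails_quality_control(self):
        spec = SceneSpec(shape=(10, 128, 128), n_mature_spots=0, seed=3)
        fish, _, _ = render_stack(spec)
        grid = np.arange(102.0, 240.0, 6.0)
        scan = seg.scan_thresholds(fish, grid)
        assert not scan.ok
        assert np.all(np.diff(scan.counts) <= 0)
        with pytest.raises(seg.QualityError, match="plateau"):
            scan.require()

    def test_invalid_grids_rejected(self, standard_scene):
        _, fish, _, _ = standard_scene
        with pytest.raises(ValueError):
            seg.scan_thresholds(fish, [])
        with pytest.raises(ValueError):
            seg.scan_thresholds(fish, [200.0, 150.0])


class TestFindObjects2D:
    def test_blob_below_size_floor_ignored(self):
        img = np.zeros((1, 32, 32))
        img[0, 5, 5:12] = 10.0          # 7 pixels in a row
        assert seg.find_objects_2d(make_stack(img), 5.0) == []

    def test_twenty_pixel_blob_centroid_is_pixel_mean(self):
        img = np.zeros((1, 32, 32))
        img[0, 10:14, 10:15] = 10.0     # 4x5 = 20 pixels
        objects = seg.find_objects_2d(make_stack(img), 5.0)
        assert len(objects) == 1
        assert objects[0].n_pixels == 20
        assert objects[0].x == pytest.approx(12.0)
        assert objects[0].y == pytest.approx(11.5)

    def test_fixture_centroids_within_two_pixels(self, standard_scene,
                                                 cutoff_grid):
        _, fish, _, truth = standard_scene
        scan = seg.scan_thresholds(fish, cutoff_grid)
        spots = seg.segment_mature(fish, scan.require())
        got = np.array([[s.x, s.y] for s in spots])
        true_xy = np.vstack([truth.mature_centroids[:, :2],
                             truth.site_centroids[:, :2]])
        d, _ = cKDTree(true_xy).query(got)
        assert np.mean(d) <= 2.0


class TestLinking:
    def test_largest_object_of_chain_wins(self):
        objects = [obj(10.0, 10.0, 1, 10), obj(10.0, 10.0, 2, 12),
                   obj(10.0, 10.0, 3, 9)]
        spots = seg.link_objects_3d(objects)
        assert len(spots) == 1
        assert spots[0].z == 2
        assert spots[0].sections == (1, 2, 3)

    def test_isolated_single_section_object_is_not_a_spot(self):
        objects = [obj(10.0, 10.0, 1, 20), obj(30.0, 30.0, 2, 15)]
        assert seg.link_objects_3d(objects) == []

    def test_link_radius_is_respected(self):
        near = [obj(10.0, 10.0, 1, 10), obj(13.0, 10.0, 2, 12)]
        far = [obj(10.0, 10.0, 1, 10), obj(15.0, 10.0, 2, 12)]
        assert len(seg.link_objects_3d(near, link_radius=4.0)) == 1
        assert seg.link_objects_3d(far, link_radius=4.0) == []

    def test_long_chains_are_flagged_not_dropped(self):
        objects = [obj(5.0, 5.0, z, 10 + z) for z in range(5)]
        spots = seg.link_objects_3d(objects)
        assert len(spots) == 1
        assert spots[0].long_chain

    def test_member_objects_are_disjoint(self, standard_scene,
                                         cutoff_grid):
        _, fish, _, _ = standard_scene
        scan = seg.scan_thresholds(fish, cutoff_grid)
        objects = seg.find_objects_2d(fish, scan.require())
        spots = seg.link_objects_3d(objects)
        seen = set()
        for s in spots:
            for o in s.objects:
                key = id(o)
                assert key not in seen
                seen.add(key)

    def test_recall_and_fdr_on_fixture(self, standard_scene,
                                       cutoff_grid):
        _, fish, _, truth = standard_scene
        scan = seg.scan_thresholds(fish, cutoff_grid)
        spots = seg.segment_mature(fish, scan.require())
        got = np.array([[s.x, s.y, s.z] for s in spots], dtype=float)
        true_pts = np.vstack([truth.mature_centroids,
                              truth.site_centroids])
        d, idx = cKDTree(true_pts[:, :2]).query(got[:, :2])
        close = (d <= 4.0) & (np.abs(true_pts[idx, 2] - got[:, 2]) <= 2)
        recall = len(set(idx[close])) / len(true_pts)
        fdr = 1.0 - close.mean()
        assert recall >= 0.95
        assert fdr <= 0.05

    def test_matches_brute_force_enumeration_on_small_stack(self):
        """On a small noise-free stack, linking must agree with a
        direct exhaustive application of the two linking criteria."""
        spec = SceneSpec(shape=(10, 96, 96), n_mature_spots=8,
                         noise_sigma=0.0, seed=21)
        fish, _, _ = render_stack(spec)
        cutoff = spec.background + spec.mature_amplitude / 3
        objects = seg.find_objects_2d(fish, cutoff)
        spots = seg.link_objects_3d(objects)

        # oracle: brute-force pairwise linkage, then size maxima
        def linked(a, b):
            return (abs(a.z - b.z) == 1
                    and np.hypot(a.x - b.x, a.y - b.y) <= 4.0)

        oracle = []
        for a in objects:
            partners = [b for b in objects if b is not a and linked(a, b)]
            if not partners:
                continue
            if all(a.n_pixels > b.n_pixels
                   or (a.n_pixels == b.n_pixels
                       and (a.z, a.y, a.x) < (b.z, b.y, b.x))
                   for b in partners):
                oracle.append((a.z, round(a.y, 6), round(a.x, 6)))
        got = {(s.z, round(s.y, 6), round(s.x, 6)) for s in spots}
        assert got == set(oracle)


class TestIntensity:
    def test_uniform_image_sums_disk_pixels(self):
        img = np.full((3, 32, 32), 7.0)
        spot = seg.Spot3D(x=15.0, y=15.0, z=1)
        assert seg.measure_intensity(make_stack(img), spot) == \
            pytest.approx(7.0 * seg.disk_pixel_count())
        assert seg.disk_pixel_count(4) == 49

    def test_intensity_is_linear_in_pixel_values(self, standard_scene,
                                                 cutoff_grid):
        _, fish, _, _ = standard_scene
        scan = seg.scan_thresholds(fish, cutoff_grid)
        spots = seg.segment_mature(fish, scan.require())[:20]
        doubled = ImageStack3D(fish.data.astype(float) * 2.0)
        for s in spots:
            before = s.intensity
            assert seg.measure_intensity(doubled, s) == \
                pytest.approx(2.0 * before)

    def test_two_spot_amplitude_ratio_preserved(self):
        spec = SceneSpec(shape=(8, 64, 64), n_mature_spots=0,
                         background=0.0, noise_sigma=0.0)
        img = np.zeros(spec.shape)
        from burstfish.synthetic import _add_gaussian_blob
        _add_gaussian_blob(img, 16.0, 16.0, 4.0, 300.0,
                           spec.psf_sigma_xy_px, 1.25)
        _add_gaussian_blob(img, 48.0, 48.0, 4.0, 100.0,
                           spec.psf_sigma_xy_px, 1.25)
        stack = make_stack(img)
        bright = seg.measure_intensity(
            stack, seg.Spot3D(x=16.0, y=16.0, z=4))
        dim = seg.measure_intensity(
            stack, seg.Spot3D(x=48.0, y=48.0, z=4))
        assert bright / dim == pytest.approx(3.0, rel=0.02)

    def test_border_clipping_is_flagged(self):
        img = np.full((2, 32, 32), 5.0)
        spot = seg.Spot3D(x=1.0, y=16.0, z=0)
        seg.measure_intensity(make_stack(img), spot)
        assert spot.clipped


@pytest.fixture(scope="module")
def site_scene():
    spec = SceneSpec(shape=(16, 384, 384), n_mature_spots=150,
                     n_transcription_sites=6, n_nuclei=12,
                     nucleus_radius=16.0,
                     site_multiplier_range=(4.0, 4.0), seed=17)
    return spec, *render_stack(spec)


class TestSites:
    def test_4x_site_detected_with_about_4_units(self, site_scene):
        spec, fish, _, truth = site_scene
        scan = seg.scan_thresholds(fish, np.arange(120.0, 360.0, 10.0))
        mature = seg.segment_mature(fish, scan.require())
        sites = seg.segment_sites(fish, mature)
        assert len(sites) == len(truth.site_centroids)
        units = np.array([s.nascent_units for s in sites])
        np.testing.assert_allclose(units, 4.0, rtol=0.15)

    def test_sites_below_detection_cutoff_not_reported(self):
        spec = SceneSpec(shape=(16, 384, 384), n_mature_spots=150,
                         n_transcription_sites=6, n_nuclei=12,
                         nucleus_radius=16.0,
                         site_multiplier_range=(1.5, 1.5), seed=18)
        fish, _, _ = render_stack(spec)
        scan = seg.scan_thresholds(fish, np.arange(120.0, 360.0, 10.0))
        mature = seg.segment_mature(fish, scan.require())
        assert seg.segment_sites(fish, mature) == []

    def test_site_units_scale_invariant(self, site_scene):
        """Multiplying the whole stack by a constant changes no
        normalized unit value (normalization cancels gain)."""
        spec, fish, _, _ = site_scene
        grid = np.arange(120.0, 360.0, 10.0)
        scan = seg.scan_thresholds(fish, grid)
        mature = seg.segment_mature(fish, scan.require())
        units = sorted(s.nascent_units
                       for s in seg.segment_sites(fish, mature))

        scaled = ImageStack3D(fish.data.astype(float) * 1.7)
        scan2 = seg.scan_thresholds(scaled, np.asarray(grid) * 1.7)
        mature2 = seg.segment_mature(scaled, scan2.require())
        units2 = sorted(s.nascent_units
                        for s in seg.segment_sites(scaled, mature2))
        np.testing.assert_allclose(units2, units, rtol=1e-3)

    def test_no_mature_spots_aborts_normalization(self, site_scene):
        _, fish, _, _ = site_scene
        with pytest.raises(seg.QualityError, match="normaliz"):
            seg.segment_sites(fish, [])

    def test_mature_spots_rarely_misclassified_as_sites(self):
        """Mature-only scene: the 2.5x cutoff should reject (almost)
        every mature spot as a site candidate."""
        spec = SceneSpec(shape=(16, 512, 512), n_mature_spots=500,
                         n_nuclei=0, seed=19)
        fish, _, _ = render_stack(spec)
        scan = seg.scan_thresholds(fish, np.arange(120.0, 360.0, 10.0))
        mature = seg.segment_mature(fish, scan.require())
        sites = seg.segment_sites(fish, mature)
        # scaled version of the 7-in-4066 benchmark rate
        assert len(sites) <= max(1, int(np.ceil(7 / 4066 * len(mature))))
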