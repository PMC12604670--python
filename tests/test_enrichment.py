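"""Segmentation, boundary extraction, distances and the enrichment ratio."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from kdnatools import enrichment as enr
from kdnatools import synth

from conftest import make_disk_mask, make_ellipse_mask, make_crescent_mask


class TestSegmentRegion:
    def test_noiseless_disk_recovers_geometry(self):
        mask = make_disk_mask(radius=50)
        img = np.where(mask, 100.0, 1.0)
        region = enr.segment_region(img, blur_sigma=2)
        assert abs(region.mask.sum() - np.pi * 50 ** 2) / (np.pi * 50 ** 2) < 0.05
        # every boundary pixel within 1 px of the true circle
        c = (mask.shape[1] - 1) / 2
        r = np.hypot(region.boundary[:, 1] - c, region.boundary[:, 0] - c)
        assert np.all(np.abs(r - 50) <= 1.5)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            enr.segment_region(np.ones((64, 64)))

    def test_largest_component_kept(self):
        img = np.ones((200, 200))
        yy, xx = np.mgrid[0:200, 0:200]
        big = (xx - 70) ** 2 + (yy - 70) ** 2 <= 40 ** 2
        small = (xx - 170) ** 2 + (yy - 170) ** 2 <= 12 ** 2
        img[big] = 100
        img[small] = 100
        region = enr.segment_region(img, blur_sigma=1)
        assert region.mask[70, 70]
        assert not region.mask[170, 170]


class TestExtractBoundary:
    def test_3x3_square_gives_perimeter(self):
        mask = np.zeros((7, 7), bool)
        mask[2:5, 2:5] = True
        bnd = {tuple(p) for p in enr.extract_boundary(mask)}
        expected = {(r, c) for r in range(2, 5) for c in range(2, 5)} - {(3, 3)}
        assert bnd == expected

    def test_single_pixel(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 3] = True
        assert enr.extract_boundary(mask).tolist() == [[2, 3]]

    def test_disk_boundary_count_near_perimeter(self):
        bnd = enr.extract_boundary(make_disk_mask(radius=50))
        assert abs(len(bnd) - 2 * np.pi * 50) / (2 * np.pi * 50) < 0.15

    def test_no_interior_pixels(self):
        mask = make_disk_mask(radius=20)
        bnd = enr.extract_boundary(mask)
        # every boundary pixel has a background 8-neighbour (or image border)
        padded = np.pad(mask, 1)
        for r, c in bnd:
            window = padded[r:r + 3, c:c + 3]
            assert not window.all()


class TestDetectSpots:
    def test_known_emitters_recovered(self):
        movie, truth = synth.make_kdna_image(
            n_emitters=10, seed=3,
            noise=synth.NoiseParams(photons=3000, background=2))
        region = enr.segment_region(movie.dna_channel[0])
        spots = enr.detect_spots(movie.qd_channel[0], region=region)
        true_px = truth.emitter_positions[0] / movie.pixel_size
        found = spots[["x_px", "y_px"]].to_numpy()
        # emitters can coincide by chance; every detection near some truth
        assert len(spots) >= 8
        d = np.linalg.norm(found[:, None, :] - true_px[None, :, :], axis=2)
        # centroid windows of overlapping emitters bias each other slightly
        assert np.all(d.min(axis=1) < 1.5)
        assert np.median(d.min(axis=1)) < 0.5

    def test_blank_image_gives_empty_table(self):
        spots = enr.detect_spots(np.zeros((64, 64)), threshold=1.0)
        assert len(spots) == 0

    def test_close_pair_merges(self):
        img = np.zeros((64, 64))
        for x, y in [(30.0, 30.0), (32.0, 30.0)]:
            yy, xx = np.mgrid[0:64, 0:64]
            img += np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * 1.5 ** 2))
        spots = enr.detect_spots(img, min_separation=5, threshold=0.1)
        assert len(spots) == 1


class TestDistanceToBoundary:
    def test_disk_centre_distance_is_radius(self, disk_region):
        c = disk_region.centroid
        d = enr.distance_to_boundary(np.array([c]), disk_region)
        assert d[0] == pytest.approx(50, abs=1.5)

    def test_boundary_pixel_distance_zero(self, disk_region):
        p = disk_region.boundary[0][::-1]
        assert enr.distance_to_boundary(np.array([p], float), disk_region)[0] == 0

    def test_matches_bruteforce_everywhere(self):
        """KDTree distances equal the exhaustive minimum for all interior
        pixels of a 128² mask."""
        yy, xx = np.mgrid[0:128, 0:128]
        mask = (((xx - 60) / 45.0) ** 2 + ((yy - 66) / 30.0) ** 2) <= 1.0
        region = enr.KdnaRegion.from_mask(mask)
        rows, cols = np.nonzero(mask)
        pts = np.column_stack([cols, rows]).astype(float)
        fast = enr.distance_to_boundary(pts, region)
        bnd = region.boundary[:, ::-1].astype(float)
        brute = np.sqrt(
            ((pts[:, None, :] - bnd[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
        assert np.array_equal(fast, brute)


class TestSampleNull:
    def test_annulus_fraction_matches_area_law(self):
        # fine grid so pixelation bias is small: P(r/r0<=0.1) = 1-0.9^2
        yy, xx = np.mgrid[0:421, 0:421]
        region = enr.KdnaRegion.from_mask(
            (xx - 210) ** 2 + (yy - 210) ** 2 <= 200 ** 2)
        d = enr.sample_null(region, 1000, multiplier=100, seed=0)
        frac = np.mean(d / region.r0 <= 0.1)
        assert frac == pytest.approx(0.19, abs=0.015)

    def test_zero_spots_empty(self, disk_region):
        assert enr.sample_null(disk_region, 0, multiplier=5, seed=0).size == 0

    def test_seed_reproducible(self, disk_region):
        a = enr.sample_null(disk_region, 50, seed=7)
        b = enr.sample_null(disk_region, 50, seed=7)
        assert np.array_equal(a, b)


class TestEnrichmentProfile:
    def test_pdfs_sum_to_one(self, disk_region):
        obs = enr.sample_null(disk_region, 30, multiplier=10, seed=1)
        null = enr.sample_null(disk_region, 30, multiplier=100, seed=2)
        prof = enr.enrichment_profile(obs, null, disk_region.r0)
        assert prof.observed_pdf.sum() == pytest.approx(1, abs=1e-12)
        assert prof.null_pdf.sum() == pytest.approx(1, abs=1e-12)

    @pytest.mark.parametrize("mask_fn", [make_disk_mask, make_ellipse_mask,
                                         make_crescent_mask])
    def test_null_vs_null_is_flat(self, mask_fn):
        """Observed drawn from the null itself gives ratio 1 in every bin,
        within 3 binomial standard errors, for any mask shape."""
        region = enr.KdnaRegion.from_mask(mask_fn())
        n = 10_000
        obs = enr.sample_null(region, n, multiplier=1, seed=3)
        null = enr.sample_null(region, n, multiplier=10, seed=4)
        prof = enr.enrichment_profile(obs, null, region.r0)
        for p_obs, p_null, ratio in zip(prof.observed_pdf, prof.null_pdf,
                                        prof.relative_frequency):
            if np.isnan(ratio):
                continue
            se = np.sqrt(p_null * (1 - p_null) / n
                         + p_null * (1 - p_null) / (10 * n)) / p_null
            assert abs(ratio - 1) < 3 * max(se, 1e-3) + 0.05

    def test_rim_concentration_matches_annulus_oracle(self):
        """All observations in the outer shell give a first-bin ratio close
        to 1/0.19 and (near-)zero elsewhere."""
        yy, xx = np.mgrid[0:421, 0:421]
        region = enr.KdnaRegion.from_mask(
            (xx - 210) ** 2 + (yy - 210) ** 2 <= 200 ** 2)
        null = enr.sample_null(region, 1000, multiplier=100, seed=5)
        obs = null[null / region.r0 <= 0.1][:5000]
        prof = enr.enrichment_profile(obs, null, region.r0)
        assert prof.relative_frequency[0] == pytest.approx(1 / 0.19, rel=0.1)
        assert np.nansum(prof.relative_frequency[1:]) < 0.05

    def test_peripheral_law_enriches_rim_only(self):
        movie, truth = synth.make_kdna_image(
            n_emitters=2000, seed=6,
            radial_law=synth.RadialLaw.peripheral(p_outer=0.5,
                                                  shell_fraction=0.2),
            noise=synth.NoiseParams(poisson=False))
        # ground-truth support mask: segmentation bias is tested separately
        _, mask = synth._dna_profile(synth.RegionGeometry())
        region = enr.KdnaRegion.from_mask(mask)
        pos_px = truth.emitter_positions[0] / movie.pixel_size
        obs = enr.distance_to_boundary(pos_px, region)
        null = enr.sample_null(region, len(obs), multiplier=100, seed=7)
        prof = enr.enrichment_profile(obs, null, region.r0)
        assert prof.relative_frequency[0] > 1.1
        assert prof.relative_frequency[1] > 1.1
        # central bins with adequate null mass are depleted (the topmost
        # bins of a non-circular mask hold almost no area -> noisy ratios)
        central = (np.arange(10) >= 4) & (prof.null_pdf > 0.01)
        assert np.nanmean(prof.relative_frequency[central]) < 1.0

    def test_aggregate_mean_and_sd(self, disk_region):
        profs = []
        for s in range(4):
            obs = enr.sample_null(disk_region, 500, multiplier=1, seed=10 + s)
            null = enr.sample_null(disk_region, 500, multiplier=20, seed=50 + s)
            profs.append(enr.enrichment_profile(obs, null, disk_region.r0))
        agg = enr.aggregate_profiles(profs)
        assert agg.n_kdna == 4
        stacked = np.vstack([p.relative_frequency for p in profs])
        assert np.allclose(agg.relative_frequency, np.nanmean(stacked, axis=0),
                           equal_nan=True)
        assert agg.sd is not None and (agg.sd[~np.isnan(agg.sd)] >= 0).all()

    def test_distance_beyond_r0_clipped_with_warning(self, disk_region):
        null = enr.sample_null(disk_region, 100, multiplier=10, seed=1)
        with pytest.warns(UserWarning, match="clipped"):
            prof = enr.enrichment_profile(
                np.array([disk_region.r0 * 1.2]), null, disk_region.r0)
        assert prof.observed_pdf[-1] == 1.0
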