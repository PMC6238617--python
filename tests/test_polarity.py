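import math

import numpy as np
import pytest

from cellpol.image_ops import LabelMap, label_clusters
from cellpol.polarity import (
    CellGeometry,
    PolarityError,
    PolarityMetrics,
    asymmetry,
    classify_polarised,
    cluster_half_width,
    compute_polarity_metrics,
    estimate_cell_center,
    intensity_centroid,
    spot_stats,
)
from cellpol.synthetic import NoiseSpec, PunctaChannelSpec, SceneSpec, simulate_cell

from .conftest import auto_geometry

PX = 0.1


def disk_image(shape, center, radius_px, value=10.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return value * (((xx - center[0]) ** 2 + (yy - center[1]) ** 2) <= radius_px**2)


class TestEstimateCellCenter:
    def test_filled_disk_centre(self):
        img = disk_image((64, 64), (32, 32), 10)
        geom = estimate_cell_center(img, pixel_size=PX)
        assert math.hypot(geom.center[0] - 32, geom.center[1] - 32) < 0.5
        assert geom.source == "nucleus_auto"

    def test_manual_circle_is_echoed(self):
        geom = estimate_cell_center(manual=(10, 12, 3.5))
        assert geom.center == (10.0, 12.0)
        assert geom.radius == 3.5
        assert geom.source == "manual_circle"

    def test_equal_area_radius(self):
        # mask area 400 px² at 0.1 μm/px → radius ≈ 1.128 μm
        img = np.zeros((64, 64))
        img[10:30, 10:30] = 5.0  # 400 px square
        geom = estimate_cell_center(img, pixel_size=PX)
        assert geom.radius == pytest.approx(math.sqrt(400 / math.pi) * PX, rel=1e-6)

    def test_constant_nucleus_raises(self):
        with pytest.raises(PolarityError, match="constant"):
            estimate_cell_center(np.ones((16, 16)), pixel_size=PX)


class TestIntensityCentroid:
    def test_single_pixel(self):
        img = np.zeros((16, 16))
        img[9, 5] = 4.0  # (x=5, y=9)
        assert intensity_centroid(img, PX, subtract_background=False) == (5.0, 9.0)

    def test_two_equal_pixels_midpoint(self):
        img = np.zeros((4, 16))
        img[0, 0] = img[0, 10] = 1.0
        assert intensity_centroid(img, PX, subtract_background=False) == (5.0, 0.0)

    def test_weighted_mean_hand_computed(self):
        # weights 1 and 3 at x = 0 and x = 10 → x̄ = 7.5
        img = np.zeros((4, 16))
        img[0, 0], img[0, 10] = 1.0, 3.0
        x, y = intensity_centroid(img, PX, subtract_background=False)
        assert x == pytest.approx(7.5)
        assert y == 0.0

    def test_symmetric_pattern_centroid_at_centre(self):
        yy, xx = np.mgrid[0:41, 0:41]
        img = np.exp(-((xx - 20.0) ** 2 + (yy - 20.0) ** 2) / 18.0)
        x, y = intensity_centroid(img, PX, subtract_background=False)
        assert abs(x - 20.0) < 1e-6 and abs(y - 20.0) < 1e-6

    def test_empty_channel_error(self):
        with pytest.raises(PolarityError, match="empty channel"):
            intensity_centroid(np.zeros((32, 32)), PX)

    def test_all_background_error(self):
        with pytest.raises(PolarityError, match="all-background"):
            intensity_centroid(np.full((64, 64), 9.0), PX, background_radius=1.0)


class TestAsymmetry:
    GEOM = CellGeometry(center=(10.0, 32.0), radius=3.5)

    def test_zero_at_centre(self):
        assert asymmetry((10.0, 32.0), self.GEOM, PX) == 0.0

    def test_three_pixels(self):
        assert asymmetry((13.0, 32.0), self.GEOM, PX) == pytest.approx(0.3)

    def test_normalised_by_radius(self):
        val = asymmetry((13.0, 32.0), self.GEOM, PX, normalise=True)
        assert val == pytest.approx(0.3 / 3.5)

    def test_translation_invariance(self):
        shift = (7.0, -3.0)
        moved = CellGeometry(
            center=(self.GEOM.center[0] + shift[0], self.GEOM.center[1] + shift[1]),
            radius=self.GEOM.radius,
        )
        a0 = asymmetry((13.0, 30.0), self.GEOM, PX)
        a1 = asymmetry((13.0 + shift[0], 30.0 + shift[1]), moved, PX)
        assert a0 == pytest.approx(a1)


class TestClusterHalfWidth:
    def test_single_pixel_cluster_is_zero(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[3, 3] = 1
        lm = LabelMap(labels=labels, n_clusters=1)
        img = np.ones((8, 8))
        assert cluster_half_width(lm, img, PX) == 0.0

    def test_two_pixels_closed_form(self):
        # two equal pixels 10 px apart on one row → (5 + 0)/2 px = 0.25 μm
        labels = np.zeros((4, 16), dtype=int)
        labels[1, 2] = labels[1, 12] = 1
        lm = LabelMap(labels=labels, n_clusters=1)
        img = np.ones((4, 16))
        assert cluster_half_width(lm, img, PX) == pytest.approx(0.25)

    def test_label_splitting_invariance(self, rng):
        labels = np.zeros((16, 16), dtype=int)
        labels[4:8, 4:8] = 1
        img = rng.random((16, 16)) + 0.1
        lm1 = LabelMap(labels=labels, n_clusters=1)
        split = labels.copy()
        split[6:8, 4:8] = 2
        lm2 = LabelMap(labels=split, n_clusters=2)
        assert cluster_half_width(lm1, img, PX) == pytest.approx(
            cluster_half_width(lm2, img, PX)
        )

    def test_no_clusters_gives_nan(self):
        lm = LabelMap(labels=np.zeros((8, 8), dtype=int), n_clusters=0)
        assert math.isnan(cluster_half_width(lm, np.ones((8, 8)), PX))

    def test_intensity_rescaling_invariance(self, rng):
        labels = (rng.random((16, 16)) > 0.6).astype(int)
        lm = LabelMap(labels=labels, n_clusters=1)
        img = rng.random((16, 16)) + 0.5
        assert cluster_half_width(lm, img, PX) == pytest.approx(
            cluster_half_width(lm, 7.3 * img, PX)
        )

    @pytest.mark.parametrize("sigma_px", [2.0, 3.0, 4.0])
    def test_gaussian_cluster_approaches_sigma(self, sigma_px):
        # as the segmentation threshold → 0, the weighted SD of an
        # isotropic Gaussian approaches its σ
        yy, xx = np.mgrid[0:81, 0:81]
        img = np.exp(-((xx - 40.0) ** 2 + (yy - 40.0) ** 2) / (2 * sigma_px**2))
        lm = label_clusters(img > 1e-9, min_area=1)
        hw = cluster_half_width(lm, img, PX)
        assert hw == pytest.approx(sigma_px * PX, rel=0.02)


class TestSpotStats:
    def test_uniform_cluster(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[2:4, 2:4] = 1  # 4 px
        lm = LabelMap(labels=labels, n_clusters=1)
        img = np.where(labels > 0, 10.0, 0.0)
        mi, ma = spot_stats(lm, img, PX)
        assert mi == pytest.approx(10.0)
        assert ma == pytest.approx(0.04)

    def test_mean_over_clusters(self):
        labels = np.zeros((8, 8), dtype=int)
        labels[1, 1] = 1
        labels[5, 5] = 2
        lm = LabelMap(labels=labels, n_clusters=2)
        img = np.zeros((8, 8))
        img[1, 1], img[5, 5] = 10.0, 30.0
        mi, _ = spot_stats(lm, img, PX)
        assert mi == pytest.approx(20.0)

    def test_no_clusters_gives_nan(self):
        lm = LabelMap(labels=np.zeros((8, 8), dtype=int), n_clusters=0)
        mi, ma = spot_stats(lm, np.ones((8, 8)), PX)
        assert math.isnan(mi) and math.isnan(ma)

    def test_matches_per_label_loop(self, rng):
        labels = label_clusters(rng.random((32, 32)) > 0.6, min_area=1)
        img = rng.random((32, 32)) * 100
        mi, ma = spot_stats(labels, img, PX)
        per_cluster_means, per_cluster_areas = [], []
        for lab in range(1, labels.n_clusters + 1):
            m = labels.labels == lab
            per_cluster_means.append(img[m].mean())
            per_cluster_areas.append(m.sum() * PX**2)
        assert mi == pytest.approx(np.mean(per_cluster_means))
        assert ma == pytest.approx(np.mean(per_cluster_areas))


class TestComputePolarityMetrics:
    def test_cage_like_cell_low_asymmetry(self, scene):
        img, _ = simulate_cell(
            scene,
            [PunctaChannelSpec(n_puncta=30, polarisation_offset=0.0)],
            NoiseSpec(seed=3),
        )
        m = compute_polarity_metrics(img, "puncta", auto_geometry(img, scene))
        assert m.asymmetry < 0.5

    def test_well_separated_puncta_counted(self, scene):
        img, gt = simulate_cell(
            scene,
            [PunctaChannelSpec(n_puncta=8, min_separation=1.0, placement_spread=2.0)],
            NoiseSpec(seed=5),
        )
        m = compute_polarity_metrics(img, "puncta", auto_geometry(img, scene))
        assert m.cluster_count == gt.true_cluster_count == 8

    def test_deterministic(self, polarised_cell, scene):
        img, _ = polarised_cell
        geom = auto_geometry(img, scene)
        m1 = compute_polarity_metrics(img, "puncta", geom)
        m2 = compute_polarity_metrics(img, "puncta", geom)
        assert m1 == m2

    def test_intensity_rescaling_leaves_asymmetry(self, polarised_cell, scene):
        from cellpol.image_ops import MultiChannelImage

        img, _ = polarised_cell
        geom = auto_geometry(img, scene)
        scaled = MultiChannelImage(
            channels=img.channels * 3.0,
            pixel_size=img.pixel_size,
            channel_names=img.channel_names,
        )
        a0 = compute_polarity_metrics(img, "puncta", geom).asymmetry
        a1 = compute_polarity_metrics(scaled, "puncta", geom).asymmetry
        assert a0 == pytest.approx(a1, rel=1e-6)

    def test_stage_name_in_error(self, scene):
        # constant channel: Otsu stage must fail with its stage named
        from cellpol.image_ops import MultiChannelImage

        img = MultiChannelImage(
            channels=np.full((2, 64, 64), 5.0),
            pixel_size=scene.pixel_size,
            channel_names=("nucleus", "puncta"),
        )
        geom = CellGeometry(center=(32, 32), radius=2.0)
        with pytest.raises(PolarityError, match="stage"):
            compute_polarity_metrics(img, "puncta", geom)


class TestClassifyPolarised:
    def _metrics(self, asym):
        return PolarityMetrics(
            cluster_count=1,
            asymmetry=asym,
            half_width=0.1,
            area_coverage=0.1,
            mean_spot_intensity=1.0,
            mean_spot_area=0.01,
        )

    def test_zero_asymmetry_not_polarised(self):
        assert classify_polarised(self._metrics(0.0), 0.5) is False

    def test_tie_is_not_polarised(self):
        assert classify_polarised(self._metrics(0.5), 0.5) is False

    def test_above_threshold_polarised(self):
        assert classify_polarised(self._metrics(0.51), 0.5) is True

    def test_nan_asymmetry_raises(self):
        with pytest.raises(PolarityError, match="undefined"):
            classify_polarised(self._metrics(float("nan")), 0.5)


def test_monotone_asymmetry_recovery_small(scene):
    """Mean recovered asymmetry increases with the planted offset."""
    means = []
    for offset in (0.0, 1.0, 2.0):
        vals = []
        for seed in range(8):
            img, _ = simulate_cell(
                scene,
                [
                    PunctaChannelSpec(
                        n_puncta=30,
                        polarisation_offset=offset,
                        placement_spread=1.0,
                    )
                ],
                NoiseSpec(seed=seed),
            )
            m = compute_polarity_metrics(img, "puncta", auto_geometry(img, scene))
            vals.append(m.asymmetry)
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2]
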