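import numpy as np
import pytest

from sporoquant import (
    GrayImage,
    apply_threshold,
    count_auto,
    count_semi,
    find_maxima,
    segment_from_maxima,
)
from sporoquant.synthetic import SceneParams, generate_micro_scene
from .conftest import blurred_disk
from .oracles import count_prominent_maxima


class TestApplyThreshold:
    def test_zero_threshold_identity(self):
        rng = np.random.default_rng(0)
        img = GrayImage(rng.integers(1, 256, (10, 10), dtype=np.uint8))
        assert np.array_equal(apply_threshold(img, 0).pixels, img.pixels)

    def test_out_of_domain_rejected(self):
        img = GrayImage(np.zeros((3, 3), dtype=np.uint8))
        with pytest.raises(ValueError):
            apply_threshold(img, 256)
        with pytest.raises(ValueError):
            apply_threshold(img, -1)

    def test_two_valued_image(self):
        px = np.where(np.eye(6, dtype=bool), 200, 50).astype(np.uint8)
        out = apply_threshold(GrayImage(px), 100)
        assert np.array_equal(out.pixels == 200, np.eye(6, dtype=bool))
        assert (out.pixels[~np.eye(6, dtype=bool)] == 0).all()

    def test_foreground_area_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        img = GrayImage(rng.integers(0, 256, (30, 30), dtype=np.uint8))
        areas = [(apply_threshold(img, t).pixels > 0).sum() for t in (1, 50, 120, 200, 255)]
        assert areas == sorted(areas, reverse=True)


class TestFindMaxima:
    def test_single_disk_one_maximum_at_center(self):
        img = blurred_disk((25, 30), 8, (50, 60))
        maxima = find_maxima(img, t=50, prominence=20)
        assert maxima.count == 1
        row = maxima.points.iloc[0]
        assert abs(row["y_px"] - 25) <= 1 and abs(row["x_px"] - 30) <= 1

    def test_two_separated_disks_two_maxima(self):
        from scipy.ndimage import gaussian_filter
        from skimage import draw

        canvas = np.zeros((50, 90))
        for c in ((25, 25), (25, 65)):
            rr, cc = draw.disk(c, 8)
            canvas[rr, cc] = 200
        img = GrayImage.from_float(gaussian_filter(canvas, 2))
        assert find_maxima(img, t=50, prominence=20).count == 2

    def test_count_non_increasing_in_prominence(self):
        p = SceneParams(patch_size_px=(120, 120), n_conidia=6, cluster_fraction=0.5, seed=21)
        img, _ = generate_micro_scene(p)
        counts = [find_maxima(img, t=95, prominence=pr).count for pr in (2, 5, 8, 15, 30, 60, 120)]
        assert counts == sorted(counts, reverse=True)

    def test_matches_brute_force_prominence_oracle(self):
        """Flood-fill persistence oracle on small crops, several prominences."""
        rng = np.random.default_rng(7)
        for _ in range(4):
            crop = rng.integers(0, 100, (16, 16)).astype(np.uint8)
            img = GrayImage(crop)
            for prom in (5, 12, 25, 60):
                ours = find_maxima(img, t=10, prominence=prom).count
                oracle = count_prominent_maxima(crop, t=10, prominence=prom)
                assert ours == oracle, f"prom={prom}"

    def test_empty_image_no_maxima(self):
        img = GrayImage(np.zeros((10, 10), dtype=np.uint8))
        assert find_maxima(img, t=10, prominence=5).count == 0

    def test_positive_prominence_required(self):
        img = GrayImage(np.zeros((5, 5), dtype=np.uint8))
        with pytest.raises(ValueError):
            find_maxima(img, t=0, prominence=0)


class TestSegmentFromMaxima:
    def test_one_marker_covers_disk(self):
        img = blurred_disk((20, 20), 7, (40, 40))
        maxima = find_maxima(img, t=60, prominence=20)
        labels = segment_from_maxima(img, maxima)
        assert labels.max() == 1
        fg = img.pixels >= 60
        covered = (labels > 0) | (fg & (labels == 0))
        assert (covered == fg).all()

    def test_dumbbell_two_labels_split_near_neck(self):
        from scipy.ndimage import gaussian_filter

        # two overlapping radial domes: peak 200 at each center, dimmer rim
        yy, xx = np.mgrid[0:50, 0:70]
        canvas = np.zeros((50, 70))
        for cy, cx in ((25, 25), (25, 44)):
            rho2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / 10.0**2
            dome = np.where(rho2 <= 1, 200 * (1 - 0.4 * rho2), 0.0)
            canvas = np.maximum(canvas, dome)
        img = GrayImage.from_float(gaussian_filter(canvas, 1))
        maxima = find_maxima(img, t=60, prominence=10)
        assert maxima.count == 2
        labels = segment_from_maxima(img, maxima)
        assert labels.max() == 2
        boundary = (img.pixels >= 60) & (labels == 0)
        xs = np.nonzero(boundary)[1]
        assert abs(np.median(xs) - 34.5) <= 2.0   # neck halfway between centers

    def test_labels_partition_thresholded_region(self, clustered_scene):
        _, img, _ = clustered_scene
        maxima = find_maxima(img, t=95, prominence=8)
        labels = segment_from_maxima(img, maxima)
        fg = img.pixels >= 95
        assert not (labels[~fg] > 0).any()
        unlabeled = fg & (labels == 0)
        assert unlabeled.sum() < 0.15 * fg.sum()

    def test_empty_maxima_zero_labels(self):
        img = blurred_disk((10, 10), 3, (20, 20))
        from sporoquant import MaximaSet

        labels = segment_from_maxima(img, MaximaSet(threshold=60, prominence=5))
        assert labels.max() == 0


class TestCountSemi:
    def test_empty_patch_zero(self):
        rng = np.random.default_rng(0)
        patch = GrayImage.from_float(rng.normal(10, 3, (150, 150)), scale_um_per_px=1.0)
        assert count_semi(patch, t=95, prominence=8).count == 0

    def test_resolves_clusters_at_least_as_well_as_auto(self, clustered_scene):
        _, img, truth = clustered_scene
        semi = count_semi(img, t=95, prominence=8).count
        auto = count_auto(img).count
        assert semi >= auto
        assert semi <= truth.true_count + 2

    def test_equivalence_on_disjoint_scene(self, disjoint_scene):
        """No touching conidia: semi = auto = truth for mid thresholds."""
        _, img, truth = disjoint_scene
        assert count_semi(img, t=95, prominence=8).count == truth.true_count
        assert count_auto(img).count == truth.true_count

    def test_remnants_rejected_above_their_intensity(self):
        p = SceneParams(n_conidia=12, secondary_fraction=0.5, seed=31)
        img, truth = generate_micro_scene(p)
        # threshold well above remnant intensity (0.2 * ~180 = ~36)
        result = count_semi(img, t=95, prominence=8)
        assert result.count == truth.true_count
        remnant_rows = truth.particles[truth.particles["type"] == "remnant"]
        centroids = result.particles[["centroid_y", "centroid_x"]].to_numpy()
        for _, r in remnant_rows.iterrows():
            d = np.linalg.norm(centroids - np.array([r["y_px"], r["x_px"]]), axis=1)
            assert d.min() > 5  # no counted particle sits on a remnant
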