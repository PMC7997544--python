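import numpy as np
import pytest
from scipy.spatial import cKDTree

from vogquant.detect import (
    bandpass,
    compute_features,
    filter_detections,
    locate,
    measure_at,
)
from tests.conftest import interior_truth

PX = 0.108


def gaussian_spot(shape, y, x, sigma, flux):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    g = np.exp(-((yy - y) ** 2 + (xx - x) ** 2) / (2 * sigma**2))
    return flux * g / (2 * np.pi * sigma**2)


class TestBandpass:
    def test_constant_image_zeroed(self):
        out = bandpass(np.full((64, 64), 37.0), 1.0, 7.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-6)

    def test_spot_mass_retained(self):
        img = gaussian_spot((64, 64), 32.0, 32.0, 1.0, 5000.0)
        out = bandpass(img, 1.0, 7.0)
        mask = (np.hypot(*(np.mgrid[:64, :64] - 32.0)) <= 3.5)
        assert out[mask].sum() > 0.8 * img.sum()

    def test_slow_gradient_suppressed(self):
        xx = np.arange(256)
        img = 100.0 + 50.0 * np.sin(2 * np.pi * xx / 140.0)
        img2d = np.tile(img, (64, 1))
        out = bandpass(img2d, 1.0, 7.0)
        # compare peak-to-peak response in the interior
        core = out[:, 32:-32]
        assert np.ptp(core) < 0.1 * 100.0

    def test_scale_ordering_enforced(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros((8, 8)), 7.0, 1.0)


class TestLocate:
    def test_blank_image_gives_empty_table(self):
        table = locate(np.zeros((64, 64)), PX)
        assert len(table) == 0

    def test_subpixel_centroid_recovery(self, rng):
        # SNR >= 10 spot at a known sub-pixel position
        truth_y, truth_x = 41.70, 20.30
        img = gaussian_spot((64, 64), truth_y, truth_x, 1.0, 8000.0) + 10.0
        noisy = rng.poisson(img).astype(float)
        table = locate(noisy, PX, min_mass=100)
        assert len(table) == 1
        assert table.df.x_px[0] == pytest.approx(truth_x, abs=0.1)
        assert table.df.y_px[0] == pytest.approx(truth_y, abs=0.1)

    def test_separation_suppression(self):
        base = np.zeros((96, 96))
        # two spots 14 px apart (2x separation): both kept
        far = base + gaussian_spot((96, 96), 40, 30, 1.0, 5000) + gaussian_spot((96, 96), 40, 44, 1.0, 4000)
        assert len(locate(far, PX, min_mass=100)) == 2
        # 3.5 px apart (0.5x separation): only the brighter survives
        near = base + gaussian_spot((96, 96), 40, 30, 1.0, 5000) + gaussian_spot((96, 96), 40, 33.5, 1.0, 4000)
        table = locate(near, PX, min_mass=100)
        assert len(table) == 1

    def test_edge_detections_discarded(self):
        img = gaussian_spot((64, 64), 2.0, 32.0, 1.0, 8000.0)
        assert len(locate(img, PX, min_mass=100)) == 0

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            locate(np.zeros((16, 16)), PX, diameter_px=6)
        with pytest.raises(ValueError):
            locate(np.zeros((16, 16)), PX, diameter_px=7, separation_px=5)

    def test_translation_equivariance(self, rng):
        img = np.full((96, 96), 10.0)
        for y, x in [(30.0, 40.0), (60.0, 22.0)]:
            img += gaussian_spot((96, 96), y, x, 1.0, 6000.0)
        img = rng.poisson(img).astype(float)
        shifted = np.roll(img, (5, -3), axis=(0, 1))
        t0 = locate(img, PX, min_mass=100)
        t1 = locate(shifted, PX, min_mass=100)
        assert len(t0) == len(t1) == 2
        p0 = np.sort(t0.df[["y_px", "x_px"]].to_numpy(), axis=0)
        p1 = np.sort(t1.df[["y_px", "x_px"]].to_numpy(), axis=0)
        np.testing.assert_allclose(p1 - p0, [[5, -3], [5, -3]], atol=0.02)

    def test_multi_spot_count_and_accuracy(self, rng):
        img = np.full((160, 160), 10.0)
        true_pos = []
        for i in range(4):
            for j in range(4):
                y, x = 20.0 + 36 * i + rng.uniform(-0.5, 0.5), 20.0 + 36 * j + rng.uniform(-0.5, 0.5)
                true_pos.append((y, x))
                img += gaussian_spot((160, 160), y, x, 1.0, 6000.0)
        noisy = rng.poisson(img).astype(float)
        table = locate(noisy, PX, min_mass=500)
        assert len(table) == 16
        d, _ = cKDTree(table.df[["y_px", "x_px"]].to_numpy()).query(np.array(true_pos))
        assert d.max() < 0.15


class TestComputeFeatures:
    def test_circular_spot_low_eccentricity(self):
        img = gaussian_spot((32, 32), 16.0, 16.0, 1.5, 5000.0)
        _, _, ecc = compute_features(img, (16, 16), 5.0, PX, background="none")
        assert ecc < 0.1

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        img = gaussian_spot((32, 32), 16.2, 15.7, 1.5, 5000.0) + rng.random((32, 32))
        m1, s1, e1 = compute_features(img, (16, 16), 5.0, PX, background="none")
        m2, s2, e2 = compute_features(2 * img, (16, 16), 5.0, PX, background="none")
        assert m2 == pytest.approx(2 * m1)
        assert s2 == pytest.approx(s1)
        assert e2 == pytest.approx(e1)

    def test_degenerate_mask(self):
        mass, size, ecc = compute_features(np.zeros((32, 32)), (16, 16), 3.5, PX)
        assert mass == 0.0
        assert np.isnan(size) and np.isnan(ecc)

    def test_annulus_background_subtracted(self):
        img = gaussian_spot((48, 48), 24.0, 24.0, 1.2, 4000.0) + 50.0
        mass, _, _ = compute_features(img, (24, 24), 4.0, PX, background="annulus")
        assert mass == pytest.approx(4000.0, rel=0.05)

    def test_mask_outside_image_refused(self):
        with pytest.raises(ValueError):
            compute_features(np.zeros((16, 16)), (1, 8), 3.5, PX)


class TestMeasureAt:
    def test_unbiased_photometry_on_flat_background(self, rng):
        img = np.full((96, 96), 30.0)
        positions = [(30.0, 30.0), (30.0, 64.0), (64.0, 47.0)]
        for y, x in positions:
            img += gaussian_spot((96, 96), y, x, 1.0, 900.0)
        noisy = rng.poisson(img).astype(float)
        table = measure_at(noisy, np.array(positions), PX)
        assert len(table) == 3
        # annulus background + no pixel floor keeps dim masses unbiased
        assert table.df.mass.mean() == pytest.approx(900.0, rel=0.1)

    def test_edge_positions_dropped(self):
        table = measure_at(np.zeros((32, 32)), np.array([(1.0, 16.0), (16.0, 16.0)]), PX)
        assert len(table) == 1
        assert table.params["n_dropped_edge"] == 1


class TestFilterDetections:
    def test_empty_predicates_identity(self, standard_detections):
        _, _, _, tables = standard_detections
        table = tables["green"]
        out = filter_detections(table, {})
        assert len(out) == len(table)

    def test_infinite_min_mass_empties(self, standard_detections):
        _, _, _, tables = standard_detections
        out = filter_detections(tables["green"], {"mass": (np.inf, None)})
        assert len(out) == 0

    def test_unknown_attribute_rejected(self, standard_detections):
        _, _, _, tables = standard_detections
        with pytest.raises(KeyError):
            filter_detections(tables["green"], {"bogus": (0, 1)})

    def test_percentile_mass_filter_keeps_true_positives(self, standard_detections):
        field, truth, _, tables = standard_detections
        table = tables["green"]
        sel = interior_truth(truth, field, "green")
        d, idx = cKDTree(table.positions_um).query(sel[["x_um", "y_um"]].to_numpy())
        matched = table.df.iloc[idx[d < 2 * field.pixel_size_um]]
        cutoff = np.percentile(matched.mass, 5)
        kept = filter_detections(table, {"mass": (cutoff, None)})
        lost = 1 - len(kept.df[kept.df.mass >= cutoff]) / len(matched)
        assert lost < 0.06


class TestDetectionQuality:
    def test_recall_precision_rmse_on_standard_field(self, standard_detections):
        """At SNR >= 10 and density 0.02/um^2: recall and precision >= 0.95,
        centroid RMSE <= 0.05 um against ground truth (2 px match radius)."""
        field, truth, _, tables = standard_detections
        for channel in ("farred", "green"):
            table = tables[channel]
            sel = interior_truth(truth, field, channel)
            d, _ = cKDTree(table.positions_um).query(sel[["x_um", "y_um"]].to_numpy())
            match = d < 2 * field.pixel_size_um
            recall = match.mean()
            all_true = truth[truth[f"photons_{channel}"] > 0][["x_um", "y_um"]].to_numpy()
            dd, _ = cKDTree(all_true).query(table.positions_um)
            precision = (dd < 2 * field.pixel_size_um).mean()
            rmse = np.sqrt((d[match] ** 2).mean())
            assert recall >= 0.95, channel
            assert precision >= 0.95, channel
            assert rmse <= 0.05, channel

    def test_detection_metadata_recorded(self, standard_detections):
        _, _, _, tables = standard_detections
        params = tables["green"].params
        assert params["diameter_px"] == 7
        assert params["min_mass_used"] > 0
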