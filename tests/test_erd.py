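"""Feature vectors, RBF kernelization, RD targets, and the ERD model."""

import numpy as np
import pytest

import fastscan as fs
from conftest import brute_features, random_measurements
from fastscan.erd import default_coverage_levels


class TestFeatures:
    def test_constant_reconstruction_zeroes_variation_features(self):
        img = fs.SampleImage(np.full((12, 12), 0.5))
        m = random_measurements((12, 12), 15, 0, image=img)
        recon = fs.idw_reconstruct(m)
        pix = tuple(np.argwhere(~m.mask)[0])
        v = fs.compute_features(m, recon, pix)
        assert v[0] == v[1] == 0.0  # gradients
        assert v[2] == v[3] == 0.0  # sigma1, sigma2

    def test_nearest_distance_of_adjacent_neighbor(self):
        m = fs.MeasurementSet([[4, 4]], [0.3], (9, 9))
        recon = fs.idw_reconstruct(m)
        v = fs.compute_features(m, recon, (4, 5))
        assert v[4] == 1.0

    def test_density_by_disc_enumeration(self):
        """Everything inside radius r measured except P itself."""
        rows = cols = 11
        cfg = fs.FeatureConfig(neighborhood_radius=3.0)
        mask = np.zeros((rows, cols), bool)
        center = (5, 5)
        in_disc = []
        for r in range(rows):
            for c in range(cols):
                if (r - 5) ** 2 + (c - 5) ** 2 <= 9:
                    in_disc.append((r, c))
                    mask[r, c] = True
        mask[center] = False
        img = fs.SampleImage(np.random.default_rng(0).random((rows, cols)))
        m = fs.MeasurementSet.from_mask(mask, img)
        recon = fs.idw_reconstruct(m)
        v = fs.compute_features(m, recon, center, cfg)
        assert v[5] == pytest.approx((len(in_disc) - 1) / len(in_disc))

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        img = fs.SampleImage(rng.random((18, 14)))
        m = random_measurements((18, 14), int(rng.integers(5, 60)), seed, image=img)
        recon = fs.idw_reconstruct(m)
        cfg = fs.FeatureConfig()
        unm = np.argwhere(~m.mask)
        for pix in unm[rng.choice(len(unm), 15, replace=False)]:
            fast = fs.compute_features(m, recon, tuple(pix), cfg)
            slow = brute_features(m, recon, tuple(pix), cfg)
            np.testing.assert_allclose(fast, slow, atol=1e-10)

    def test_measured_pixel_is_error(self):
        m = fs.MeasurementSet([[2, 2]], [0.5], (6, 6))
        recon = fs.idw_reconstruct(m)
        with pytest.raises(ValueError):
            fs.compute_features(m, recon, (2, 2))


class TestKernelize:
    def test_deterministic_and_length(self):
        cfg = fs.FeatureConfig()
        v = np.array([0.1, -0.2, 0.3, 0.4, 2.0, 0.5])
        a, b = fs.kernelize(v, cfg), fs.kernelize(v, cfg)
        assert a.shape == (50,)
        np.testing.assert_array_equal(a, b)

    def test_approximates_gaussian_kernel(self):
        """Dot products of mapped vectors track exp(-gamma ||u-v||^2)."""
        cfg = fs.FeatureConfig(rbf_gamma=1.0)
        rng = np.random.default_rng(0)
        u = rng.normal(size=(1000, 6)) * 0.4
        v = rng.normal(size=(1000, 6)) * 0.4
        ku, kv = fs.kernelize(u, cfg), fs.kernelize(v, cfg)
        approx = (ku * kv).sum(axis=1)
        exact = np.exp(-cfg.rbf_gamma * ((u - v) ** 2).sum(axis=1))
        assert np.abs(approx - exact).mean() < 0.15


class TestComputeRD:
    def test_zero_when_reconstruction_already_exact(self):
        img = fs.SampleImage(np.full((10, 10), 0.6))
        m = random_measurements((10, 10), 20, 0, image=img)
        pix = tuple(np.argwhere(~m.mask)[0])
        assert fs.compute_rd(img, m, pix) == pytest.approx(0.0, abs=1e-12)

    def test_single_hole_closed_form(self):
        """With every other pixel measured, RD equals the squared IDW error
        at the hole."""
        rng = np.random.default_rng(1)
        img = fs.SampleImage(rng.random((9, 9)))
        mask = np.ones((9, 9), bool)
        hole = (4, 4)
        mask[hole] = False
        m = fs.MeasurementSet.from_mask(mask, img)
        recon = fs.idw_reconstruct(m)
        delta = img.values[hole] - recon.values[hole]
        assert fs.compute_rd(img, m, hole) == pytest.approx(delta**2, rel=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_full_window_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        img = fs.SampleImage(rng.random((20, 20)))
        m = random_measurements((20, 20), int(rng.integers(8, 90)), seed, image=img)
        unm = np.argwhere(~m.mask)
        pix = tuple(unm[rng.integers(len(unm))])
        rd = fs.compute_rd(img, m, pix, window_halfwidth=40)
        before = fs.distortion(img, fs.idw_reconstruct(m))
        after = fs.distortion(
            img, fs.idw_reconstruct(m.extend([pix], [img.values[pix]]))
        )
        assert rd == pytest.approx(before - after, abs=1e-10)

    def test_windowed_tracks_full_rd(self):
        """The locality window keeps the dominant share of the full-image
        RD: strong rank agreement and bounded bulk deviation."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(9)
        img = fs.SampleImage(rng.random((20, 20)))
        m = random_measurements((20, 20), 40, 9, image=img)
        unm = np.argwhere(~m.mask)
        full = np.array(
            [fs.compute_rd(img, m, tuple(p), window_halfwidth=40) for p in unm]
        )
        windowed = np.array([fs.compute_rd(img, m, tuple(p)) for p in unm])
        assert spearmanr(full, windowed).statistic > 0.9
        denom = max(np.abs(full).max(), 1e-12)
        assert np.median(np.abs(full - windowed)) / denom < 0.05

    def test_measured_pixel_is_error(self):
        img = fs.SampleImage(np.zeros((6, 6)))
        m = fs.MeasurementSet([[1, 1]], [0.0], (6, 6))
        with pytest.raises(ValueError):
            fs.compute_rd(img, m, (1, 1))


class TestTrainingSet:
    def test_default_levels_span_one_to_eighty_percent(self):
        levels = default_coverage_levels()
        assert len(levels) == 10
        assert levels[0] == pytest.approx(0.01)
        assert levels[-1] == pytest.approx(0.80)

    def test_pair_counting_and_determinism(self):
        img = fs.generic_training_image(32)
        kwargs = dict(
            coverage_levels=[0.05, 0.3],
            masks_per_level=2,
            pairs_per_mask=50,
            rng=3,
        )
        pairs_a = fs.build_training_set(img, **kwargs)
        pairs_b = fs.build_training_set(img, **kwargs)
        assert len(pairs_a) == 2 * 2 * 50
        for a, b in zip(pairs_a, pairs_b):
            np.testing.assert_array_equal(a.features, b.features)
            assert a.rd == b.rd

    def test_degenerate_coverage_rejected(self):
        img = fs.generic_training_image(32)
        for bad in ([0.0], [1.0]):
            with pytest.raises(ValueError):
                fs.build_training_set(img, coverage_levels=bad)


class TestERDModel:
    def test_training_reduces_loss(self, quick_model):
        hist = quick_model.loss_history
        assert hist[-1] <= hist[0]

    def test_recovers_synthetic_linear_rule(self):
        """Trained on rd = 2*L + noise, the model must explain held-out
        variance (R^2 > 0.8)."""
        rng = np.random.default_rng(0)
        n = 6000
        feats = np.column_stack(
            [
                rng.normal(0, 0.05, n),
                rng.normal(0, 0.05, n),
                rng.uniform(0, 0.2, n),
                rng.uniform(0, 0.05, n),
                rng.uniform(0.5, 8.0, n),
                rng.uniform(0, 1, n),
            ]
        )
        rd = 2 * feats[:, 4] + rng.normal(0, 0.3, n)
        pairs = [fs.TrainingPair(f, r) for f, r in zip(feats, rd)]
        model = fs.train_erd_model(pairs[:5000], epochs=60, seed=0)
        pred = model.predict_features(feats[5000:])
        resid = rd[5000:] - pred
        r2 = 1 - resid.var() / rd[5000:].var()
        assert r2 > 0.8

    def test_default_hyperparameters(self):
        import inspect

        sig = inspect.signature(fs.train_erd_model)
        assert sig.parameters["epochs"].default == 100
        assert sig.parameters["learning_rate"].default == 0.001

    def test_requires_enough_pairs(self):
        with pytest.raises(ValueError):
            fs.train_erd_model([])
        with pytest.raises(ValueError):
            fs.train_erd_model(
                [fs.TrainingPair(np.zeros(6), 0.0)] * 50
            )

    def test_save_load_round_trip(self, quick_model, tmp_path):
        path = tmp_path / "model.npz"
        quick_model.save(path)
        back = fs.ERDModel.load(path)
        X = np.random.default_rng(0).normal(size=(20, 6))
        np.testing.assert_allclose(
            back.predict_features(X), quick_model.predict_features(X), atol=1e-12
        )


class TestPredictERD:
    def test_domain_is_exactly_the_unmeasured_pixels(self, quick_model):
        img = fs.SampleImage(np.random.default_rng(0).random((8, 8)))
        mask = np.ones((8, 8), bool)
        mask[3, 5] = False
        m = fs.MeasurementSet.from_mask(mask, img)
        emap = fs.predict_erd(quick_model, m, fs.idw_reconstruct(m))
        assert emap.defined.sum() == 1
        assert emap.defined[3, 5]
        assert np.isnan(emap.values[mask]).all()

    def test_nonnegative_after_clipping(self, quick_model, flake_image):
        m = random_measurements(flake_image.shape, 200, 1, image=flake_image)
        emap = fs.predict_erd(quick_model, m, fs.idw_reconstruct(m))
        assert np.all(emap.values[emap.defined] >= 0)

    def test_batch_equals_pointwise(self, quick_model):
        rng = np.random.default_rng(2)
        img = fs.SampleImage(rng.random((10, 10)))
        m = random_measurements((10, 10), 30, 2, image=img)
        recon = fs.idw_reconstruct(m)
        emap = fs.predict_erd(quick_model, m, recon)
        cfg = quick_model.feature_config
        for pix in np.argwhere(~m.mask)[:10]:
            v = fs.compute_features(m, recon, tuple(pix), cfg)
            single = max(float(quick_model.predict_features(v)[0]), 0.0)
            assert emap.values[tuple(pix)] == pytest.approx(single, abs=1e-10)

    def test_fully_measured_grid_is_error(self, quick_model):
        img = fs.SampleImage(np.random.default_rng(0).random((5, 5)))
        m = fs.MeasurementSet.from_mask(np.ones((5, 5), bool), img)
        with pytest.raises(ValueError):
            fs.predict_erd(quick_model, m, fs.idw_reconstruct(m))
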