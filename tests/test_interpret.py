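"""Significance maps, occlusion oracle and latent-feature export."""

import numpy as np
import pytest

import capm7g as c
from capm7g.interpret import _band_sizes


class TestRegionTiling:
    def test_64_over_9_band_sizes(self):
        assert _band_sizes(64, 9) == [7, 7, 7, 7, 7, 7, 7, 7, 8]

    def test_32_over_9_band_sizes_cover_everything(self):
        assert sum(_band_sizes(32, 9)) == 32

    @pytest.mark.parametrize("shape,grid", [((64, 64), 9), ((32, 32), 9),
                                            ((16, 16), 4)])
    def test_slices_partition_all_pixels(self, shape, grid):
        covered = np.zeros(shape, dtype=int)
        for row in c.region_slices(shape, grid):
            for rs, cs in row:
                covered[rs, cs] += 1
        assert np.all(covered == 1)


class TestSignificanceMap:
    def test_all_zero_image_gets_zero_attribution(self, strong_model):
        img = np.zeros(strong_model.trained.config.image_shape)
        smap = c.significance_map(strong_model.trained, img, n_samples=32, seed=0)
        np.testing.assert_allclose(smap.grid, 0.0, atol=1e-9)

    def test_seeded_reproducibility(self, strong_model):
        w = strong_model.split.test[0]
        img = strong_model.trained.encode([w])[0]
        a = c.significance_map(strong_model.trained, img, n_samples=64, seed=3)
        b = c.significance_map(strong_model.trained, img, n_samples=64, seed=3)
        np.testing.assert_allclose(a.grid, b.grid, atol=1e-6)

    def test_upsampled_is_piecewise_constant_expansion(self, strong_model):
        w = strong_model.split.test[0]
        img = strong_model.trained.encode([w])[0]
        smap = c.significance_map(strong_model.trained, img, n_samples=32, seed=1)
        slices = c.region_slices(img.shape, smap.grid.shape[0])
        for r, row in enumerate(slices):
            for col, (rs, cs) in enumerate(row):
                block = smap.upsampled[rs, cs]
                assert np.all(block == smap.grid[r, col])

    def test_wrong_image_shape_is_error(self, strong_model):
        with pytest.raises(ValueError):
            c.significance_map(strong_model.trained, np.zeros((8, 8)))

    def test_attribution_sums_track_probability_drop(self, strong_model):
        """Sum of region scores correlates with p(full) - p(fully masked)."""
        trained = strong_model.trained
        windows = strong_model.split.test[:50]
        sums, drops = [], []
        for i, w in enumerate(windows):
            img = trained.encode([w])[0]
            smap = c.significance_map(trained, img, target_class=1,
                                      n_samples=64, seed=i)
            p_full = trained.model.predict_proba(img[None])[0, 1]
            sums.append(smap.grid.sum())
            drops.append(p_full - smap.baseline_probability)
        r = np.corrcoef(sums, drops)[0, 1]
        assert r > 0

    def test_top_region_masking_beats_random_region(self, strong_model):
        """Occluding the top-attributed region hurts p(target) at least as
        often as occluding a random region (paired over 50 images)."""
        trained = strong_model.trained
        rng = np.random.default_rng(0)
        windows = strong_model.split.test[:50]
        slices = c.region_slices(trained.config.image_shape, 9)
        top_wins = rand_wins = 0
        for i, w in enumerate(windows):
            img = trained.encode([w])[0]
            smap = c.significance_map(trained, img, target_class=1,
                                      n_samples=64, seed=i)
            top = np.unravel_index(np.argmax(smap.grid), smap.grid.shape)
            rand = (rng.integers(9), rng.integers(9))
            p_full = trained.model.predict_proba(img[None])[0, 1]
            masked = []
            for region in (top, rand):
                m = img.copy()
                rs, cs = slices[region[0]][region[1]]
                m[rs, cs] = 0.0
                masked.append(m)
            p_top, p_rand = trained.model.predict_proba(np.stack(masked))[:, 1]
            top_wins += p_top < p_full
            rand_wins += p_rand < p_full
        assert top_wins >= rand_wins

    def test_occlusion_agrees_in_sign_on_strong_regions(self, strong_model):
        trained = strong_model.trained
        w = [x for x in strong_model.split.test if x.label == 1][0]
        img = trained.encode([w])[0]
        sampled = c.significance_map(trained, img, target_class=1,
                                     n_samples=256, seed=5)
        occluded = c.occlusion_map(trained, img, target_class=1)
        top = np.argsort(np.abs(sampled.grid).ravel())[-5:]
        s1 = np.sign(sampled.grid.ravel()[top])
        s2 = np.sign(occluded.grid.ravel()[top])
        assert np.all(s1 == s2)


class TestLatentExport:
    def test_digit_layer_shape(self, strong_model):
        windows = strong_model.split.test[:10]
        df = c.export_latent_features(strong_model.trained, windows, layer="digit")
        J = strong_model.trained.config.num_digit_capsules
        D = strong_model.trained.config.digit_capsule_dim
        assert df.shape == (10, 2 + J * D)
        assert list(df.columns[:2]) == ["id", "label"]

    def test_primary_layer_shape(self, strong_model):
        windows = strong_model.split.test[:4]
        df = c.export_latent_features(strong_model.trained, windows, layer="primary")
        cfg = strong_model.trained.config
        assert df.shape == (4, 2 + cfg.num_primary_capsules * cfg.primary_capsule_dim)

    def test_identical_inputs_identical_tables(self, strong_model):
        windows = strong_model.split.test[:5]
        a = c.export_latent_features(strong_model.trained, windows)
        b = c.export_latent_features(strong_model.trained, windows)
        assert a.equals(b)

    def test_unknown_layer_is_error(self, strong_model):
        with pytest.raises(ValueError):
            c.export_latent_features(strong_model.trained,
                                     strong_model.split.test[:1], layer="conv")

    def test_latent_space_separates_classes(self, strong_model):
        """Digit-capsule features of a trained model separate the classes:
        the mean distance to the own-class centroid is smaller than to the
        other-class centroid for most test windows."""
        df = c.export_latent_features(strong_model.trained,
                                      strong_model.split.test, layer="digit")
        X = df.drop(columns=["id", "label"]).to_numpy()
        y = df["label"].to_numpy()
        cent = {lab: X[y == lab].mean(axis=0) for lab in (0, 1)}
        own = np.array([np.linalg.norm(x - cent[lab]) for x, lab in zip(X, y)])
        other = np.array([np.linalg.norm(x - cent[1 - lab]) for x, lab in zip(X, y)])
        assert (own < other).mean() > 0.8
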