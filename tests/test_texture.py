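import numpy as np
import pandas as pd
import pytest

from _oracles import skimage_window_glcm, stats_from_matrix
from smcfusion.errors import (
    ConfigurationError,
    DomainError,
    SearchError,
    UndefinedValueError,
)
from smcfusion.texture import (
    DIRECTIONS,
    FEATURES,
    TI_FORMS,
    GLCMMatrix,
    band_texture_image,
    glcm_window,
    identity_names,
    plot_texture,
    quantize_band,
    search_texture_indices,
    texture_images,
    texture_index,
    texture_stats,
)

class TestQuantize:
    def test_constant_maps_to_zero(self):
        assert (quantize_band(np.full((5, 5), 0.7), 32) == 0).all()

    def test_endpoints(self):
        q = quantize_band(np.array([[0.0, 1.0], [1.0, 0.0]]), 2)
        assert set(q.ravel()) == {0, 1}

    def test_uniform_ramp_fills_bins_evenly(self):
        ramp = np.linspace(0, 1, 400).reshape(20, 20)
        q = quantize_band(ramp, 4)
        counts = np.bincount(q.ravel(), minlength=4)
        assert counts == pytest.approx(np.full(4, 100), abs=1)

    def test_too_few_levels(self):
        with pytest.raises(ConfigurationError):
            quantize_band(np.zeros((3, 3)), 1)


class TestGLCMWindow:
    def test_hand_enumerated_2x2(self):
        m = glcm_window(np.array([[0, 0], [0, 1]]), direction=0, levels=2)
        np.testing.assert_allclose(m.P, [[0.5, 0.25], [0.25, 0.0]])

    def test_constant_window(self):
        m = glcm_window(np.zeros((3, 3), dtype=int), direction=90, levels=2)
        assert m.P[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_normalized_and_symmetric(self, direction, rng):
        q = rng.integers(0, 6, (5, 5))
        m = glcm_window(q, direction=direction, levels=6)
        assert m.P.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(m.P, m.P.T)
        assert (m.P >= 0).all()

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_matches_skimage(self, direction, rng):
        q = rng.integers(0, 5, (4, 4))
        ours = glcm_window(q, direction=direction, levels=5).P
        ref = skimage_window_glcm(q, direction, 5)
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_degenerate_window(self):
        with pytest.raises(DomainError):
            glcm_window(np.array([[0]]), direction=0, levels=2)


class TestTextureStats:
    def test_constant_window_identities(self):
        m = glcm_window(np.zeros((3, 3), dtype=int), direction=0, levels=2)
        s = texture_stats(m)
        assert s["Con"] == pytest.approx(0.0)
        assert s["Dis"] == pytest.approx(0.0)
        assert s["Hom"] == pytest.approx(1.0)
        assert s["Sec"] == pytest.approx(1.0)
        assert s["Ent"] == pytest.approx(0.0)
        assert s["Cor"] == 0.0  # degenerate sentinel

    def test_hand_values(self):
        P = np.array([[0.5, 0.25], [0.25, 0.0]])
        s = texture_stats(GLCMMatrix(P, 2, 0))
        assert s["Con"] == pytest.approx(0.5)
        assert s["Sec"] == pytest.approx(0.375)
        assert s["Hom"] == pytest.approx(0.75)

    def test_bounds_on_random_glcms(self, rng):
        for _ in range(20):
            q = rng.integers(0, 8, (6, 6))
            s = texture_stats(glcm_window(q, direction=45, levels=8))
            assert 0.0 < s["Sec"] <= 1.0
            assert 0.0 < s["Hom"] <= 1.0
            assert s["Ent"] >= 0.0


class TestSlidingImages:
    def test_constant_raster(self):
        imgs = texture_images(np.zeros((6, 6), dtype=int), levels=4)
        np.testing.assert_allclose(imgs["Con"], 0.0)
        np.testing.assert_allclose(imgs["Hom"], 1.0)

    def test_geometry(self, rng):
        q = rng.integers(0, 4, (3, 3))
        img = band_texture_image(q, "Con", levels=4)
        assert img.shape == (1, 1)

    def test_average_equals_mean_of_directions(self, rng):
        q = rng.integers(0, 8, (10, 10))
        avg = texture_images(q, levels=8)
        singles = [texture_images(q, levels=8, directions=(d,))
                   for d in DIRECTIONS]
        for feat in FEATURES:
            np.testing.assert_allclose(
                avg[feat], np.mean([s[feat] for s in singles], axis=0),
                atol=1e-12)

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_sliding_matches_per_window_oracle(self, direction, rng):
        """Each sliding value equals skimage GLCM + formula on that window."""
        q = rng.integers(0, 6, (6, 7))
        imgs = texture_images(q, levels=6, directions=(direction,))
        for r in range(q.shape[0] - 2):
            for c in range(q.shape[1] - 2):
                ref = stats_from_matrix(
                    skimage_window_glcm(q[r:r + 3, c:c + 3], direction, 6))
                for feat in FEATURES:
                    assert imgs[feat][r, c] == pytest.approx(ref[feat], abs=1e-10)

    def test_too_small_raster(self):
        with pytest.raises(DomainError):
            texture_images(np.zeros((2, 5), dtype=int))


class TestPlotTexture:
    def test_cardinality_and_keys(self, small_experiment):
        scenes, _ = small_experiment
        tab = plot_texture(scenes[0], scenes[0].canopy_mask, levels=16)
        assert len(tab) == 48
        assert tab["identity"].is_unique
        assert set(tab["feature"]) == set(FEATURES)
        assert set(tab["band"]) == set(range(1, 7))

    def test_full_mask_equals_unmasked_mean(self, small_experiment):
        scenes, _ = small_experiment
        scene = scenes[1]
        full = np.ones(scene.thermal.shape, dtype=bool)
        tab = plot_texture(scene, full, levels=16)
        q = quantize_band(scene.reflectance[0], 16)
        expected = texture_images(q, 16)["Con"].mean()
        got = tab.loc[(tab.band == 1) & (tab.feature == "Con"), "value"].item()
        assert got == pytest.approx(expected, abs=1e-12)

    def test_empty_mask_raises(self, small_experiment):
        scenes, _ = small_experiment
        mask = np.zeros(scenes[0].thermal.shape, dtype=bool)
        mask[0, 0] = True  # survives nothing after edge crop
        with pytest.raises(DomainError):
            plot_texture(scenes[0], mask)


class TestTextureIndex:
    def test_identity_pairs(self):
        t = 2.5
        assert texture_index("DTI", t, t) == pytest.approx(0.0)
        assert texture_index("RTI", t, t) == pytest.approx(1.0)
        assert texture_index("RDTI", t, t) == pytest.approx(0.0)
        assert texture_index("RATI", t, t) == pytest.approx(2.0 / t)

    def test_direct_values(self):
        assert texture_index("NDTI", 3.0, 1.0) == pytest.approx(0.5)
        assert texture_index("RDTI", 2.0, 4.0) == pytest.approx(0.25)
        assert texture_index("NTI", 2.0, 4.0) == pytest.approx(0.0)

    @pytest.mark.parametrize("form, t1, t2", [
        ("NDTI", 1.0, -1.0), ("RTI", 1.0, 0.0), ("NTI", 0.0, 0.0),
        ("RDTI", 0.0, 1.0), ("RATI", 1.0, 0.0),
    ])
    def test_zero_denominators(self, form, t1, t2):
        with pytest.raises(UndefinedValueError):
            texture_index(form, t1, t2)


class TestSearch:
    def brute_force(self, table, y, form):
        best = None
        names = list(table.columns)
        for a in names:
            for b in names:
                try:
                    v = np.array([texture_index(form, x1, x2)
                                  for x1, x2 in zip(table[a], table[b])])
                except UndefinedValueError:
                    continue
                if np.std(v) == 0 or not np.isfinite(v).all():
                    continue
                r = np.corrcoef(v, y)[0, 1]
                if best is None or abs(r) > abs(best[2]) + 1e-15:
                    best = (a, b, r)
        return best

    @pytest.mark.parametrize("n_ident", [2, 4])
    def test_equals_brute_force(self, n_ident, rng):
        names = identity_names()[:n_ident]
        table = pd.DataFrame(rng.uniform(0.5, 3.0, (20, n_ident)), columns=names)
        y = rng.uniform(0.1, 0.3, 20)
        res = search_texture_indices(table, y).set_index("form")
        for form in TI_FORMS:
            a, b, r = self.brute_force(table, y, form)
            assert abs(res.loc[form, "r"]) >= abs(r) - 1e-12
            assert res.loc[form, "r"] == pytest.approx(r, abs=1e-12)

    def test_planted_perfect_pair(self, rng):
        y = rng.uniform(0.1, 0.3, 30)
        table = pd.DataFrame({
            "Mea1": y * 2.0 + 1.0,          # DTI(Mea1, Var1) = 2y exactly... noise below
            "Var1": np.full(30, 1.0) + rng.normal(0, 1e-6, 30),
        })
        res = search_texture_indices(table, y).set_index("form")
        assert abs(res.loc["DTI", "r"]) == pytest.approx(1.0, abs=1e-6)
        assert res.loc["DTI", "t1"] == "Mea1"

    def test_identical_pair_can_win(self, rng):
        """RATI(x, x) = 2/x may beat every cross pair."""
        y = rng.uniform(0.1, 0.3, 40)
        table = pd.DataFrame({
            "Mea1": 2.0 / y,                      # RATI(Mea1, Mea1) == y
            "Var1": rng.uniform(0.5, 2.0, 40),    # unrelated
        })
        res = search_texture_indices(table, y).set_index("form")
        assert res.loc["RATI", "t1"] == "Mea1"
        assert res.loc["RATI", "t2"] == "Mea1"
        assert res.loc["RATI", "r"] == pytest.approx(1.0, abs=1e-12)

    def test_all_degenerate_raises(self):
        table = pd.DataFrame({"Mea1": np.ones(10), "Var1": np.ones(10)})
        with pytest.raises(SearchError), pytest.warns(UserWarning):
            search_texture_indices(table, np.linspace(0, 1, 10))
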