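import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from conftest import brute_force_glcm
from qusrad.maps import ParametricMap
from qusrad.texture import (
    GLCMConfig,
    glcm,
    glcm_features,
    quantize,
    region_texture,
    texture_derivative,
    texture_map,
)

HORIZONTAL = GLCMConfig(grey_levels=2, angles_deg=(0.0,))


def _pmap(values, valid=None, step=1.0):
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    return ParametricMap(
        values=values,
        validity_mask=valid,
        centres_z=np.arange(values.shape[0]) * step,
        centres_x=np.arange(values.shape[1]) * step,
        window_size=2.0,
        step=step,
        parameter_name="MBF",
        region="core",
    )


class TestQuantize:
    def test_constant_map_all_zero(self):
        levels, valid = quantize(np.full((5, 5), 3.7), GLCMConfig())
        assert np.all(levels == 0) and valid.all()

    def test_top_bin_right_closed(self):
        cfg = GLCMConfig(grey_levels=16, quantization_range=(0.0, 1.0))
        levels, _ = quantize(np.array([[0.0, 1.0]]), cfg)
        assert levels[0, 0] == 0 and levels[0, 1] == 15

    def test_monotone(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(8, 8))
        levels, _ = quantize(values, GLCMConfig())
        order = np.argsort(values.ravel())
        assert np.all(np.diff(levels.ravel()[order].astype(int)) >= 0)


class TestGLCM:
    def test_two_row_image_hand_counts(self):
        """[[0,0],[1,1]] at distance 1, angle 0: the two horizontal pairs
        give P(0,0)=P(1,1)=0.5."""
        P = glcm(np.array([[0, 0], [1, 1]]), HORIZONTAL)
        np.testing.assert_allclose(P, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_image(self):
        P = glcm(np.zeros((4, 4), dtype=int), GLCMConfig(grey_levels=4))
        assert P[0, 0] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    def test_normalized_and_symmetric(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 8, size=(10, 10))
        P = glcm(img, GLCMConfig(grey_levels=8))
        assert P.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(P, P.T, atol=1e-12)

    def test_invalid_pixels_excluded(self):
        img = np.array([[0, 1], [1, 1]])
        valid = np.array([[False, True], [True, True]])
        P = glcm(img, HORIZONTAL, valid)
        # only the bottom-row pair (1,1) remains
        np.testing.assert_allclose(P, [[0.0, 0.0], [0.0, 1.0]])

    def test_no_valid_pairs_rejected(self):
        img = np.zeros((2, 2), dtype=int)
        valid = np.array([[True, False], [False, True]])
        with pytest.raises(ValueError, match="pair"):
            glcm(img, HORIZONTAL, valid)


class TestFeatures:
    def test_constant_image_features(self):
        P = glcm(np.zeros((4, 4), dtype=int), GLCMConfig(grey_levels=4))
        f = glcm_features(P)
        assert (f.contrast, f.homogeneity, f.energy, f.correlation) == (0.0, 1.0, 1.0, 0.0)

    def test_two_level_diagonal(self):
        """P(0,0)=P(1,1)=0.5: CON 0, ENE 0.5, HOM 1, COR 1."""
        f = glcm_features(np.array([[0.5, 0.0], [0.0, 0.5]]))
        assert f.contrast == 0.0
        assert f.energy == pytest.approx(0.5)
        assert f.homogeneity == pytest.approx(1.0)
        assert f.correlation == pytest.approx(1.0)

    def test_checkerboard(self):
        """0/1 checkerboard, distance 1, angle 0: every pair is (0,1) or
        (1,0), so CON 1, ENE 0.5, HOM 0.5 (and COR -1)."""
        img = np.indices((6, 6)).sum(axis=0) % 2
        f = glcm_features(glcm(img, HORIZONTAL))
        assert f.contrast == pytest.approx(1.0)
        assert f.energy == pytest.approx(0.5)
        assert f.homogeneity == pytest.approx(0.5)
        assert f.correlation == pytest.approx(-1.0)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            glcm_features(np.ones((3, 3)))


@st.composite
def small_images(draw):
    levels = draw(st.integers(min_value=2, max_value=8))
    shape = (
        draw(st.integers(min_value=2, max_value=12)),
        draw(st.integers(min_value=2, max_value=12)),
    )
    img = draw(hnp.arrays(np.int64, shape, elements=st.integers(0, levels - 1)))
    valid = draw(hnp.arrays(np.bool_, shape, elements=st.booleans()))
    return img, valid, levels


@given(small_images())
@settings(max_examples=150, deadline=None, derandomize=True)
def test_glcm_matches_brute_force_oracle(case):
    """Implementation equals independent pair enumeration on random small
    images with random validity masks (symmetric, four angles)."""
    img, valid, levels = case
    cfg = GLCMConfig(grey_levels=levels)
    expected = brute_force_glcm(img, valid, levels, cfg.distances, cfg.angles_deg, True)
    if expected is None:
        with pytest.raises(ValueError):
            glcm(img, cfg, valid)
        return
    P = glcm(img, cfg, valid)
    np.testing.assert_allclose(P, expected, atol=1e-12)
    ours = glcm_features(P)
    theirs = glcm_features(expected)
    assert ours.as_dict() == pytest.approx(theirs.as_dict(), abs=1e-12)


def test_rotation_consistency():
    """Angle-averaged features agree between an image and its 90° rotation."""
    rng = np.random.default_rng(2)
    img = rng.integers(0, 8, size=(9, 9))
    cfg = GLCMConfig(grey_levels=8)
    a = glcm_features(glcm(img, cfg))
    b = glcm_features(glcm(np.rot90(img), cfg))
    assert a.as_dict() == pytest.approx(b.as_dict(), abs=1e-12)


class TestTextureMaps:
    def test_constant_map_energy_one(self):
        pmap = _pmap(np.full((8, 8), 2.5))
        tmaps = texture_map(pmap, GLCMConfig(), texture_window=5, step=1)
        ene = tmaps["ENE"]
        assert np.all(ene.values[ene.validity_mask] == 1.0)

    def test_tiling_arithmetic(self):
        pmap = _pmap(np.random.default_rng(3).normal(size=(11, 9)))
        tmaps = texture_map(pmap, GLCMConfig(), texture_window=5, step=2)
        assert tmaps["CON"].values.shape == ((11 - 5) // 2 + 1, (9 - 5) // 2 + 1)

    def test_noisier_map_has_higher_contrast(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(10, 10))
        smooth = _pmap(0.1 * base)
        noisy = _pmap(base + rng.normal(0, 1, size=(10, 10)))
        cfg = GLCMConfig(quantization_range=(-5, 5))
        con_smooth = np.nanmean(texture_map(smooth, cfg)["CON"].values)
        con_noisy = np.nanmean(texture_map(noisy, cfg)["CON"].values)
        assert con_noisy > con_smooth

    def test_window_too_large_rejected(self):
        with pytest.raises(ValueError, match="larger"):
            texture_map(_pmap(np.zeros((4, 4))), GLCMConfig(), texture_window=5)


class TestTextureDerivative:
    def test_constant_propagation(self):
        """Constant texture maps give derivative ENE=1, CON=0 for all four."""
        pmap = _pmap(np.full((10, 10), 1.0))
        tmaps = texture_map(pmap, GLCMConfig())
        deriv = texture_derivative(tmaps)
        assert len(deriv) == 16
        for first in ("CON", "COR", "HOM", "ENE"):
            assert deriv[f"MBF-{first}-ENE"] == 1.0
            assert deriv[f"MBF-{first}-CON"] == 0.0

    def test_shift_invariance_of_binning(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=(10, 10))
        d1 = texture_derivative(texture_map(_pmap(values), GLCMConfig()))
        d2 = texture_derivative(texture_map(_pmap(values + 100.0), GLCMConfig()))
        assert d1 == pytest.approx(d2, abs=1e-9)

    def test_sensitive_to_spatial_arrangement(self):
        """Two maps with identical histograms but different arrangement give
        different second-pass features."""
        rng = np.random.default_rng(6)
        values = np.sort(rng.normal(size=100)).reshape(10, 10)  # smooth gradient
        shuffled = rng.permutation(values.ravel()).reshape(10, 10)
        d1 = texture_derivative(texture_map(_pmap(values), GLCMConfig()))
        d2 = texture_derivative(texture_map(_pmap(shuffled), GLCMConfig()))
        assert any(abs(d1[k] - d2[k]) > 1e-3 for k in d1)


def test_region_texture_on_masked_map():
    rng = np.random.default_rng(7)
    values = rng.normal(size=(9, 9))
    valid = np.ones((9, 9), dtype=bool)
    valid[:, :3] = False
    feats = region_texture(_pmap(values, valid), GLCMConfig())
    assert 0.0 < feats.energy <= 1.0
    assert 0.0 < feats.homogeneity <= 1.0
    assert -1.0 <= feats.correlation <= 1.0
    assert feats.contrast >= 0.0
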