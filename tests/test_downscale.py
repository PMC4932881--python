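import numpy as np
import pytest

from chronoclim.downscale import (
    apply_gamma,
    bilinear_regrid,
    downscale_additive,
    downscale_factor,
    normalize_shortwave,
    shortwave_gamma,
)
from chronoclim.grids import make_grid


@pytest.fixture(scope="module")
def grids():
    coarse = make_grid(0, 10, 0, 10, 2.5)
    fine = make_grid(0, 10, 0, 10, 0.5)
    return coarse, fine


class TestBilinear:
    def test_constant_field(self, grids):
        coarse, fine = grids
        out = bilinear_regrid(np.full(coarse.shape, 7.3), coarse, fine)
        np.testing.assert_allclose(out, 7.3)

    def test_exact_on_planes_inside_hull(self, grids):
        coarse, fine = grids
        clon, clat = np.meshgrid(coarse.lons, coarse.lats)
        flon, flat = np.meshgrid(fine.lons, fine.lats)
        out = bilinear_regrid(2 * clon + 3 * clat, coarse, fine)
        inside = (
            (flon >= coarse.lons[0]) & (flon <= coarse.lons[-1])
            & (flat >= coarse.lats[0]) & (flat <= coarse.lats[-1])
        )
        np.testing.assert_allclose(out[inside], (2 * flon + 3 * flat)[inside])

    def test_single_point_matches_hand_weights(self, rng):
        coarse = make_grid(0, 3, 0, 3, 1.0)
        field = rng.normal(size=(3, 3))
        fine = make_grid(0.6, 1.6, 1.2, 2.2, 1.0)  # single center (1.1, 1.7)
        out = bilinear_regrid(field, coarse, fine)
        # surrounding centers: lons 0.5,1.5 (cols 0,1), lats 1.5,2.5 (rows 1,2)
        dx, dy = (1.1 - 0.5) / 1.0, (1.7 - 1.5) / 1.0
        expected = (
            field[1, 0] * (1 - dx) * (1 - dy)
            + field[1, 1] * dx * (1 - dy)
            + field[2, 0] * (1 - dx) * dy
            + field[2, 1] * dx * dy
        )
        assert out[0, 0] == pytest.approx(expected, rel=1e-12)

    def test_monotone_within_neighbours(self, grids, rng):
        coarse, fine = grids
        field = rng.normal(size=coarse.shape)
        out = bilinear_regrid(field, coarse, fine)
        assert out.min() >= field.min() - 1e-12
        assert out.max() <= field.max() + 1e-12

    def test_no_extension_flags_outside(self, grids, rng):
        coarse, fine = grids
        out = bilinear_regrid(rng.normal(size=coarse.shape), coarse, fine, extend=False)
        assert np.isnan(out[0, 0])  # fine corner is outside the center hull


class TestChangeFactor:
    def test_additive_identity_when_no_change(self, grids, rng):
        coarse, fine = grids
        model = rng.normal(size=coarse.shape)
        obs = rng.normal(size=fine.shape)
        out = downscale_additive(model, model, obs, coarse, fine)
        np.testing.assert_allclose(out, obs)

    def test_additive_constant_shift(self, grids, rng):
        coarse, fine = grids
        model = rng.normal(size=coarse.shape)
        obs = rng.normal(size=fine.shape)
        out = downscale_additive(model + 2, model, obs, coarse, fine)
        np.testing.assert_allclose(out, obs + 2)

    def test_additive_composes_with_regrid_oracle(self, grids, rng):
        coarse, fine = grids
        m0 = rng.normal(size=coarse.shape)
        m1 = m0 + rng.normal(size=coarse.shape)
        obs = rng.normal(size=fine.shape)
        expected = obs + bilinear_regrid(m1 - m0, coarse, fine)
        np.testing.assert_allclose(
            downscale_additive(m1, m0, obs, coarse, fine), expected
        )

    def test_additive_grid_mismatch_rejected(self, grids, rng):
        coarse, fine = grids
        with pytest.raises(ValueError, match="share a grid"):
            downscale_additive(
                np.zeros(coarse.shape), np.zeros((2, 2)),
                np.zeros(fine.shape), coarse, fine,
            )

    def test_factor_identity_and_doubling(self, grids, rng):
        coarse, fine = grids
        model = rng.uniform(1, 5, size=coarse.shape)
        obs = rng.uniform(0, 10, size=fine.shape)
        np.testing.assert_allclose(
            downscale_factor(model, model, obs, coarse, fine), obs
        )
        np.testing.assert_allclose(
            downscale_factor(2 * model, model, obs, coarse, fine), 2 * obs
        )

    def test_factor_matches_ratio_then_regrid_oracle(self, grids, rng):
        coarse, fine = grids
        ref = rng.uniform(1, 5, size=coarse.shape)
        alt = rng.uniform(0.5, 8, size=coarse.shape)
        obs = rng.uniform(0, 10, size=fine.shape)
        expected = obs * bilinear_regrid(alt / ref, coarse, fine)
        np.testing.assert_allclose(
            downscale_factor(alt, ref, obs, coarse, fine), expected
        )

    def test_factor_rejects_negative_inputs(self, grids):
        coarse, fine = grids
        with pytest.raises(ValueError, match="non-negative"):
            downscale_factor(
                -np.ones(coarse.shape), np.ones(coarse.shape),
                np.ones(fine.shape), coarse, fine,
            )

    def test_factor_zero_reference_rules(self, grids):
        coarse, fine = grids
        ref = np.zeros(coarse.shape)
        alt = np.zeros(coarse.shape)
        obs = np.full(fine.shape, 3.0)
        # both zero -> factor 1 (no change)
        np.testing.assert_allclose(
            downscale_factor(alt, ref, obs, coarse, fine), obs
        )
        # wet over dry -> capped factor
        out = downscale_factor(alt + 1, ref, obs, coarse, fine, max_factor=10)
        np.testing.assert_allclose(out, 30.0)


class TestShortwaveGamma:
    def test_gamma_one_when_unchanged(self):
        B = np.full((3, 3), 400.0)
        S = 0.5 * B
        np.testing.assert_allclose(shortwave_gamma(S, S, B, B), 1.0)

    def test_square_relation(self):
        B = np.full((2, 2), 400.0)
        g = shortwave_gamma(0.25 * B, 0.5 * B, B, B)
        np.testing.assert_allclose(g, 2.0)

    def test_roundtrip_recovers_alt(self, rng):
        B = np.full((4, 4), 350.0)
        shat0 = rng.uniform(0.1, 0.9, size=(4, 4))
        shat_alt = rng.uniform(0.1, 0.9, size=(4, 4))
        g = shortwave_gamma(shat_alt * B, shat0 * B, B, B)
        out = apply_gamma(shat0, g, B)
        np.testing.assert_allclose(out, shat_alt * B, atol=1e-9)

    def test_apply_gamma_examples(self):
        B = np.array([400.0])
        np.testing.assert_allclose(apply_gamma(np.array([0.6]), np.array([1.0]), B), 240.0)
        np.testing.assert_allclose(
            apply_gamma(np.array([0.6]), np.array([0.5]), B), 400 * np.sqrt(0.6)
        )
        # huge power drives normalized shortwave to zero
        assert apply_gamma(np.array([0.6]), np.array([500.0]), B)[0] < 1e-6 * 400

    def test_bounds_and_polar_night(self, rng):
        B = np.array([0.0, 0.5, 300.0])
        shat = normalize_shortwave(np.array([0.0, 0.2, 150.0]), B)
        assert np.isnan(shat[0]) and np.isnan(shat[1])  # polar night flagged
        out = apply_gamma(np.array([0.5, 0.5, 0.5]), np.array([2.0, 2.0, 2.0]), B)
        assert out[0] == 0.0 and out[1] == 0.0
        assert 0 <= out[2] <= 300.0

    def test_nonpositive_gamma_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            apply_gamma(np.array([0.5]), np.array([-1.0]), np.array([300.0]))
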