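import numpy as np
import pytest

from scorpcam.photometry import (
    ConeCatch,
    GreyStandard,
    ROIMeasurement,
    catch_from_values,
    fit_channel_to_cone_map,
    luminance,
    normalize_to_standard,
    normalize_two_point,
    quantum_catch,
    roi_mean,
)
from scorpcam.spectral import DEFAULT_GRID, Spectrum, WavelengthGrid, pigment_template


def flat(value, grid=DEFAULT_GRID):
    return Spectrum(grid, np.full(len(grid), value), kind="reflectance")


def bumpy(rng, grid=DEFAULT_GRID):
    lam = grid.wavelengths
    centre = rng.uniform(380, 650)
    width = rng.uniform(40, 150)
    amp = rng.uniform(0.1, 0.7)
    base = rng.uniform(0.02, 0.25)
    vals = np.clip(base + amp * np.exp(-(((lam - centre) / width) ** 2)), 1e-4, 1.0)
    return Spectrum(grid, vals, kind="reflectance")


class TestQuantumCatch:
    def test_zero_reflectance_gives_zero_catch(self, scorpionfish, d65):
        q = quantum_catch(flat(0.0), d65, scorpionfish)
        np.testing.assert_array_equal(q.catches, 0.0)

    def test_linearity_in_reflectance(self, scorpionfish, d65, rng):
        r = bumpy(rng)
        q1 = quantum_catch(r, d65, scorpionfish)
        q2 = quantum_catch(r.scaled(0.5), d65, scorpionfish)
        np.testing.assert_allclose(q1.catches, 2.0 * q2.catches, rtol=1e-12)
        assert q1.luminance == pytest.approx(2.0 * q2.luminance, rel=1e-12)

    def test_flat_spectra_catch_ratio_exact(self, triplefin, d65):
        qa = quantum_catch(flat(0.5), d65, triplefin)
        qb = quantum_catch(flat(0.25), d65, triplefin)
        np.testing.assert_allclose(qa.catches / qb.catches, 2.0, rtol=1e-12)

    def test_grid_mismatch_rejected(self, scorpionfish, d65):
        grid2 = WavelengthGrid(300, 700, 2)
        r2 = Spectrum(grid2, np.full(len(grid2), 0.5))
        with pytest.raises(ValueError, match="grid"):
            quantum_catch(r2, d65, scorpionfish)


class TestLuminance:
    def test_scorpionfish_long_wavelength_cone(self, scorpionfish):
        c = catch_from_values([0.2, 0.6], scorpionfish)
        assert luminance(c, scorpionfish) == 0.6

    def test_triplefin_mean_of_long_cones(self, triplefin):
        c = catch_from_values([0.1, 0.4, 0.6], triplefin)
        assert luminance(c, triplefin) == pytest.approx(0.5)

    def test_equal_catches_any_definition(self, scorpionfish, triplefin):
        for obs in (scorpionfish, triplefin):
            c = catch_from_values([0.7] * obs.n_receptors, obs)
            assert luminance(c, obs) == pytest.approx(0.7)

    def test_receptor_count_mismatch_rejected(self, triplefin):
        c = ConeCatch(np.array([0.1, 0.2]), 0.2, "x")
        with pytest.raises(ValueError):
            luminance(c, triplefin)


class TestGreyStandardNormalisation:
    def test_standard_maps_to_nominal(self):
        m = ROIMeasurement("p1", "roi", np.array([120.0, 120.0]), 10)
        std = GreyStandard(0.09, np.array([120.0, 120.0]))
        out = normalize_to_standard(m, std)
        np.testing.assert_allclose(out.channel_means, 0.09)

    def test_double_the_standard_doubles_reflectance(self):
        m = ROIMeasurement("p1", "roi", np.array([240.0]), 10)
        std = GreyStandard(0.09, np.array([120.0]))
        assert normalize_to_standard(m, std).channel_means[0] == pytest.approx(0.18)

    def test_zero_standard_rejected(self):
        m = ROIMeasurement("p1", "roi", np.array([1.0]), 1)
        with pytest.raises(ValueError):
            normalize_to_standard(m, GreyStandard(0.09, np.array([0.0])))

    def test_two_point_fit_recovers_both_standards(self):
        lo = GreyStandard(0.12, np.array([100.0, 90.0]))
        hi = GreyStandard(0.72, np.array([520.0, 500.0]))
        out_lo = normalize_two_point(ROIMeasurement("p", "lo", lo.measured_values, 1), lo, hi)
        out_hi = normalize_two_point(ROIMeasurement("p", "hi", hi.measured_values, 1), lo, hi)
        np.testing.assert_allclose(out_lo.channel_means, 0.12, rtol=1e-12)
        np.testing.assert_allclose(out_hi.channel_means, 0.72, rtol=1e-12)


class TestRoiMean:
    def test_constant_image(self):
        img = np.full((4, 4), 7.0)
        mask = np.zeros((4, 4), bool)
        mask[1:3, 1:3] = True
        out = roi_mean(img, mask)
        assert out.channel_means[0] == 7.0
        assert out.n_pixels == 4

    def test_two_pixel_mean(self):
        img = np.array([[1.0, 3.0], [99.0, 99.0]])
        mask = np.array([[True, True], [False, False]])
        assert roi_mean(img, mask).channel_means[0] == 2.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi_mean(np.ones((2, 2)), np.zeros((2, 2), bool))

    def test_pixel_order_invariance(self, rng):
        img = rng.uniform(0, 1, (6, 6, 3))
        mask = rng.uniform(size=(6, 6)) > 0.4
        base = roi_mean(img, mask).channel_means
        perm = rng.permutation(36)
        img_p = img.reshape(36, 3)[perm].reshape(6, 6, 3)
        mask_p = mask.reshape(36)[perm].reshape(6, 6)
        np.testing.assert_allclose(roi_mean(img_p, mask_p).channel_means, base, rtol=1e-12)


class TestImageRoute:
    def test_sixteen_bit_image_and_mask_round_trip(self, tmp_path):
        import imageio.v3 as iio

        from scorpcam.photometry import read_image, read_mask

        img = np.zeros((8, 8), dtype=np.uint16)
        img[2:5, 2:5] = 40000
        iio.imwrite(tmp_path / "tile.png", img)
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2:5, 2:5] = 255
        iio.imwrite(tmp_path / "mask.png", mask)
        loaded = read_image(tmp_path / "tile.png")
        m = read_mask(tmp_path / "mask.png")
        out = roi_mean(loaded, m, photo_id="tile", label="roi")
        assert out.channel_means[0] == pytest.approx(40000.0)
        assert out.n_pixels == 9


class TestChannelToConeMap:
    def training_set(self, rng, n=15):
        return [bumpy(rng) for _ in range(n)]

    def test_self_mapping_is_identity(self, scorpionfish, d65, rng):
        sens = scorpionfish.sensitivities()
        m = fit_channel_to_cone_map(self.training_set(rng), sens, scorpionfish, d65)
        off_diag = m.matrix - np.diag(np.diag(m.matrix))
        assert np.max(np.abs(off_diag)) < 1e-6
        np.testing.assert_allclose(np.diag(m.matrix), 1.0, atol=1e-6)

    def test_held_out_prediction_within_5_percent(self, scorpionfish, d65, rng):
        # synthetic 3-channel camera viewing a dichromat's world
        camera = [pigment_template(p) for p in (450.0, 520.0, 570.0)]
        m = fit_channel_to_cone_map(self.training_set(rng, 20), camera, scorpionfish, d65)
        for value in (0.2, 0.45, 0.7):
            r = flat(value)
            cam_catches = [
                float(np.sum(r.values * d65.values * s.values) * DEFAULT_GRID.step)
                for s in camera
            ]
            predicted = m.apply(cam_catches, scorpionfish)
            direct = quantum_catch(r, d65, scorpionfish)
            np.testing.assert_allclose(predicted.catches, direct.catches, rtol=0.05)

    def test_single_training_spectrum_rejected(self, scorpionfish, d65, rng):
        with pytest.raises(ValueError):
            fit_channel_to_cone_map([bumpy(rng)], scorpionfish.sensitivities(), scorpionfish, d65)

    def test_rank_deficient_training_rejected(self, scorpionfish, d65):
        same = [flat(0.5)] * 12  # all identical: rank 1
        with pytest.raises(ValueError, match="rank"):
            fit_channel_to_cone_map(same, scorpionfish.sensitivities(), scorpionfish, d65)

    def test_grey_standard_route_agrees_with_spectral_route(self, scorpionfish, d65, rng):
        """Normalise-then-map agrees with the direct spectral route within 5%."""
        camera = [pigment_template(p) for p in (460.0, 540.0)]
        m = fit_channel_to_cone_map(self.training_set(rng, 20), camera, scorpionfish, d65)
        std_refl = flat(0.09)
        std_catches = np.array(
            [float(np.sum(std_refl.values * d65.values * s.values) * DEFAULT_GRID.step) for s in camera]
        )
        standard = GreyStandard(0.09, std_catches * 1000.0)  # camera counts, arbitrary gain
        stim = flat(0.4)
        stim_counts = np.array(
            [float(np.sum(stim.values * d65.values * s.values) * DEFAULT_GRID.step) for s in camera]
        ) * 1000.0
        measurement = ROIMeasurement("p", "stim", stim_counts, 5)
        reflectances = normalize_to_standard(measurement, standard).channel_means
        # reflectance estimate drives per-channel catches of the flat standard
        cam_catches = reflectances / 0.09 * std_catches
        predicted = m.apply(cam_catches, scorpionfish)
        direct = quantum_catch(stim, d65, scorpionfish)
        np.testing.assert_allclose(predicted.catches, direct.catches, rtol=0.05)
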