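"""Grey calibration, ruler rescaling and the RGB-to-cone-catch mapping."""

import numpy as np
import pytest
from skimage.transform import rescale as sk_rescale

from ovicrypt import calibrate
from ovicrypt.imageio_masks import MaskSet, RawScene


def _flat_scene(grey_rgb=(0.30, 0.24, 0.18), shape=(64, 64)):
    image = np.empty((*shape, 3))
    image[:] = 0.5
    grey = np.zeros(shape, dtype=bool)
    grey[2:10, 2:10] = True
    image[grey] = grey_rgb
    eggs = []
    for i in range(3):
        m = np.zeros(shape, dtype=bool)
        m[20 + 8 * i: 24 + 8 * i, 20:24] = True
        eggs.append(m)
    ruler = np.zeros(shape, dtype=bool)
    ruler[60:62, 4:52] = True
    masks = MaskSet.with_default_exclusion(eggs, ruler, grey)
    return RawScene(image=image, masks=masks, nest_id="t", habitat_label="beach")


class TestGreyCalibrate:
    def test_gains_are_target_over_channel_means(self):
        out = calibrate.grey_calibrate(_flat_scene())
        assert np.allclose(out.gains, [0.20 / 0.30, 0.20 / 0.24, 0.20 / 0.18])
        grey = out.image[out.masks.grey_mask]
        assert np.allclose(grey.mean(axis=0), 0.20, atol=1e-12)

    def test_already_calibrated_scene_untouched(self):
        scene = _flat_scene(grey_rgb=(0.20, 0.20, 0.20))
        out = calibrate.grey_calibrate(scene)
        assert np.allclose(out.gains, 1.0)
        assert np.allclose(out.image, scene.image)

    def test_idempotence(self):
        once = calibrate.grey_calibrate(_flat_scene())
        twice = calibrate.grey_calibrate(once)
        assert np.allclose(once.image, twice.image, atol=1e-12)

    def test_zero_channel_rejected(self):
        with pytest.raises(calibrate.SaturationError):
            calibrate.grey_calibrate(_flat_scene(grey_rgb=(0.3, 0.0, 0.2)))


class TestRescaleToStandard:
    def test_scene_already_at_standard_resolution_unchanged(self, scene_pair):
        scene = scene_pair[0]
        raw = RawScene(image=scene.image, masks=scene.masks, nest_id="x",
                       habitat_label="beach")
        out = calibrate.rescale_to_standard(raw)
        assert out.image.shape == scene.image.shape
        assert calibrate.ruler_extent_px(out.masks.ruler_mask) == 480

    def test_five_percent_oversampled_scene_lands_at_480px_ruler(self, scene_pair):
        scene = scene_pair[0]
        up = sk_rescale(scene.image, 1.05, order=0, channel_axis=2,
                        anti_aliasing=False)

        def nnm(m):
            return sk_rescale(m, 1.05, order=0, anti_aliasing=False).astype(bool)

        masks = MaskSet([nnm(m) for m in scene.masks.egg_masks],
                        nnm(scene.masks.ruler_mask), nnm(scene.masks.grey_mask),
                        nnm(scene.masks.exclusion_mask), up.shape[:2])
        raw = RawScene(image=up, masks=masks, nest_id="x", habitat_label="beach")
        out = calibrate.rescale_to_standard(raw)
        extent = calibrate.ruler_extent_px(out.masks.ruler_mask)
        assert abs(extent - 480) <= 2
        # nearest-neighbour keeps masks boolean and egg masks disjoint
        assert out.masks.egg_masks[0].dtype == bool
        assert not (out.masks.egg_masks[0] & out.masks.egg_masks[1]).any()

    def test_upscaling_requires_explicit_override(self, scene_pair):
        scene = scene_pair[0]
        down = sk_rescale(scene.image, 0.95, order=0, channel_axis=2,
                          anti_aliasing=False)

        def nnm(m):
            return sk_rescale(m, 0.95, order=0, anti_aliasing=False).astype(bool)

        masks = MaskSet([nnm(m) for m in scene.masks.egg_masks],
                        nnm(scene.masks.ruler_mask), nnm(scene.masks.grey_mask),
                        nnm(scene.masks.exclusion_mask), down.shape[:2])
        raw = RawScene(image=down, masks=masks, nest_id="x", habitat_label="beach")
        with pytest.raises(calibrate.FiducialError, match="upscal"):
            calibrate.rescale_to_standard(raw)
        out = calibrate.rescale_to_standard(raw, allow_upscale=True)
        assert abs(calibrate.ruler_extent_px(out.masks.ruler_mask) - 480) <= 2


class TestQuantumCatch:
    def test_perfect_reflector_catches_one(self, spectral_system):
        wl = spectral_system.wavelengths_nm
        for curve in spectral_system.sensor_sensitivities.values():
            assert calibrate.quantum_catch(np.ones(len(wl)), curve,
                                           spectral_system.illuminant) == pytest.approx(1.0)

    def test_flat_spectrum_catches_its_reflectance(self, spectral_system):
        wl = spectral_system.wavelengths_nm
        flat = np.full(len(wl), 0.2)
        for cones in spectral_system.cone_sets.values():
            for curve in cones.values():
                catch = calibrate.quantum_catch(flat, curve, spectral_system.illuminant)
                assert catch == pytest.approx(0.2)

    def test_single_band_indicator_equals_band_weight(self, spectral_system):
        wl = spectral_system.wavelengths_nm
        sens = spectral_system.cone_sets["avian"]["L"]
        illum = spectral_system.illuminant
        band = (wl >= 550) & (wl < 560)
        refl = band.astype(float)
        expected = (sens * illum)[band].sum() / (sens * illum).sum()
        assert calibrate.quantum_catch(refl, sens, illum) == pytest.approx(expected)

    def test_scale_invariance(self, spectral_system):
        wl = spectral_system.wavelengths_nm
        rng = np.random.default_rng(0)
        refl = rng.uniform(0, 1, len(wl))
        sens = spectral_system.cone_sets["carnivore"]["S"]
        base = calibrate.quantum_catch(refl, sens, spectral_system.illuminant)
        for k in (0.25, 0.5, 0.9):
            assert calibrate.quantum_catch(k * refl, sens, spectral_system.illuminant) \
                == pytest.approx(k * base)

    def test_grid_mismatch_rejected(self, spectral_system):
        with pytest.raises(calibrate.SpectralGridError):
            calibrate.quantum_catch(np.ones(10),
                                    spectral_system.sensor_sensitivities["R"],
                                    spectral_system.illuminant)


class TestMapping:
    def test_cone_equal_to_sensor_maps_perfectly(self, spectral_system):
        import dataclasses
        system = dataclasses.replace(
            spectral_system,
            cone_sets={"toy": {"G": spectral_system.sensor_sensitivities["G"]}})
        bank = calibrate.synthetic_spectra_bank(120, seed=3,
                                                wavelengths=system.wavelengths_nm)
        model = calibrate.fit_rgb_to_cone_map(bank, system, seed=0)
        assert model.training_fit["toy"]["G"] == pytest.approx(1.0, abs=1e-10)

    def test_default_bank_avian_heldout_r2_above_099(self, mapping_model):
        for cone, r2 in mapping_model.training_fit["avian"].items():
            assert r2 > 0.99, f"avian {cone} held-out R^2 {r2}"

    def test_quadratic_fit_at_least_as_good_as_linear(self, spectral_system):
        bank = calibrate.synthetic_spectra_bank(200, seed=1,
                                                wavelengths=spectral_system.wavelengths_nm)
        m1 = calibrate.fit_rgb_to_cone_map(bank, spectral_system, degree=1, seed=2)
        m2 = calibrate.fit_rgb_to_cone_map(bank, spectral_system, degree=2, seed=2)
        # nesting guarantees the ordering in-sample; on the held-out split a
        # small sampling slack is allowed
        for sysname in m1.training_fit:
            for cone in m1.training_fit[sysname]:
                assert m2.training_fit[sysname][cone] >= \
                    m1.training_fit[sysname][cone] - 1e-3

    def test_training_bank_mapping_consistency(self, spectral_system, mapping_model):
        bank = calibrate.synthetic_spectra_bank(200, seed=1,
                                                wavelengths=spectral_system.wavelengths_nm)
        camera = np.stack([calibrate.quantum_catch(
            bank, spectral_system.sensor_sensitivities[ch], spectral_system.illuminant)
            for ch in "RGB"], axis=-1)
        X = calibrate._design_matrix(camera, 2)
        for sysname, cones in spectral_system.cone_sets.items():
            pred = X @ mapping_model.coefficients[sysname]
            for j, cname in enumerate(mapping_model.cone_names[sysname]):
                direct = calibrate.quantum_catch(bank, cones[cname],
                                                 spectral_system.illuminant)
                ss_res = float(np.sum((pred[:, j] - direct) ** 2))
                ss_tot = float(np.sum((direct - direct.mean()) ** 2))
                assert 1 - ss_res / ss_tot > 0.999

    def test_apply_map_plane_counts_and_constancy(self, mapping_model):
        image = np.full((8, 8, 3), 0.4)
        scene = calibrate.CalibratedScene(image=image, masks=None, nest_id="t",
                                          habitat_label="beach")
        avian = calibrate.apply_map(scene, mapping_model, "avian")
        carn = calibrate.apply_map(scene, mapping_model, "carnivore")
        assert set(avian.planes) == {"D", "L", "M", "S"}
        assert set(carn.planes) == {"L", "S"}
        for plane in avian.planes.values():
            assert np.ptp(plane) == 0.0

    def test_mapped_pixels_match_integration_oracle(self, spectral_system, mapping_model):
        bank = calibrate.synthetic_spectra_bank(200, seed=1,
                                                wavelengths=spectral_system.wavelengths_nm)
        spectrum = bank[7]
        camera = np.array([calibrate.quantum_catch(
            spectrum, spectral_system.sensor_sensitivities[ch],
            spectral_system.illuminant) for ch in "RGB"])
        image = np.tile(camera, (4, 4, 1))
        scene = calibrate.CalibratedScene(image=image, masks=None, nest_id="t",
                                          habitat_label="beach")
        catches = calibrate.apply_map(scene, mapping_model, "avian")
        for cname in ("D", "L", "M", "S"):
            direct = calibrate.quantum_catch(
                spectrum, spectral_system.cone_sets["avian"][cname],
                spectral_system.illuminant)
            assert catches.planes[cname][0, 0] == pytest.approx(direct, rel=0.01)

    def test_unfitted_system_rejected(self, mapping_model):
        scene = calibrate.CalibratedScene(image=np.full((4, 4, 3), 0.3), masks=None,
                                          nest_id="t", habitat_label="beach")
        with pytest.raises(KeyError):
            calibrate.apply_map(scene, mapping_model, "mantis_shrimp")
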