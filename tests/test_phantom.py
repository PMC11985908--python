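import numpy as np
import pytest

from multiscint.absorption import (EnergyBinning, ReconstructionMatrix,
                                   energy_grid, reconstruction_matrix)
from multiscint.errors import ValidationError
from multiscint.phantom import (PhantomSpec, RegionSpec,
                                effective_attenuation, forward_image,
                                identify_materials, image_accuracy,
                                make_phantom, pseudocolor,
                                surrogate_tissue_presets)

from .oracles import image_accuracy_bruteforce


def _identity_matrix():
    return ReconstructionMatrix(np.eye(3) / 3.0, EnergyBinning())


@pytest.fixture(scope="module")
def small_phantom():
    return make_phantom(PhantomSpec(grid=48))


class TestMakePhantom:
    def test_uniform_background_without_regions(self):
        pha = make_phantom(PhantomSpec(grid=16, regions=()), equalize=False)
        assert np.all(pha.labels == 0)
        np.testing.assert_allclose(pha.mix["adipose"], 10.0)

    def test_thicknesses_sum_to_total(self, small_phantom):
        total = sum(small_phantom.mix.values())
        np.testing.assert_allclose(total, 10.0, atol=1e-9)

    def test_equal_contrast_under_energy_integration(self, small_phantom):
        """All regions transmit identically to an energy-integrating detector."""
        _, e_eval, w_e, _ = energy_grid(EnergyBinning(), 0.25)
        n_vals = np.full(e_eval.size, 1.0 / 51.0)
        mu = {k: np.asarray(m.mu(e_eval))
              for k, m in small_phantom.materials.items()}
        trans = []
        for lab in range(1, 5):
            iy, ix = np.argwhere(small_phantom.labels == lab)[0]
            mu_path = sum(mu[k] * small_phantom.mix[k][iy, ix]
                          for k in small_phantom.mix)
            trans.append((n_vals * np.exp(-mu_path)) @ w_e)
        assert np.ptp(trans) < 1e-6

    def test_overlapping_regions_rejected(self):
        spec = PhantomSpec(grid=32, regions=(
            RegionSpec("a", (0.5, 0.5), 0.3, "muscle", 0.5),
            RegionSpec("b", (0.55, 0.5), 0.3, "bone", 0.2)))
        with pytest.raises(ValidationError):
            make_phantom(spec, equalize=False)

    def test_all_pixels_labeled(self, small_phantom):
        assert set(np.unique(small_phantom.labels)) == {0, 1, 2, 3, 4}


class TestForwardImage:
    def test_empty_phantom_equals_flat_field(self):
        pha = make_phantom(PhantomSpec(grid=8, regions=(),
                                       thickness_mm=1e-9), equalize=False)
        imgs = forward_image(pha, _identity_matrix(), noise=0.0)
        for m in range(3):
            np.testing.assert_allclose(imgs.images[m], imgs.flat[m],
                                       rtol=1e-9)

    def test_identity_matrix_gives_ideal_binned_transmission(self):
        pha = make_phantom(PhantomSpec(grid=8, regions=()), equalize=False)
        imgs = forward_image(pha, _identity_matrix(), noise=0.0)
        binning = EnergyBinning()
        _, e_eval, w_e, bin_idx = energy_grid(binning, 0.25)
        mu = np.asarray(surrogate_tissue_presets()["adipose"].mu(e_eval))
        trans = np.exp(-mu * 10.0) / 51.0
        for m in range(3):
            expected = (trans * w_e)[bin_idx == m].sum()
            np.testing.assert_allclose(imgs.images[m], expected, rtol=1e-9)

    def test_more_contrast_agent_darkens_middle_bin(self, surrogate):
        matrix = reconstruction_matrix(surrogate, n_z=400, de=0.5)
        intensities = []
        for frac in (0.2, 0.4):
            spec = PhantomSpec(grid=16, regions=(
                RegionSpec("iod", (0.5, 0.5), 0.25, "iodinated_blood",
                           frac),))
            pha = make_phantom(spec, equalize=False)
            imgs = forward_image(pha, matrix, noise=0.0)
            intensities.append(imgs.images[1][pha.labels == 1].mean())
        assert intensities[1] < intensities[0]

    def test_negative_noise_rejected(self, small_phantom, surrogate):
        matrix = reconstruction_matrix(surrogate, n_z=200, de=1.0)
        with pytest.raises(ValidationError):
            forward_image(small_phantom, matrix, noise=-0.1)

    def test_noiseless_deterministic(self, small_phantom):
        i1 = forward_image(small_phantom, _identity_matrix(), noise=0.0,
                           rng=1)
        i2 = forward_image(small_phantom, _identity_matrix(), noise=0.0,
                           rng=2)
        np.testing.assert_array_equal(i1.images, i2.images)


class TestEffectiveAttenuation:
    def test_flat_field_gives_zero(self):
        pha = make_phantom(PhantomSpec(grid=8, regions=(),
                                       thickness_mm=1e-9), equalize=False)
        imgs = forward_image(pha, _identity_matrix(), noise=0.0)
        mu = effective_attenuation(imgs, 10.0)
        np.testing.assert_allclose(mu, 0.0, atol=1e-9)

    def test_uniform_slab_matches_spectral_average(self):
        pha = make_phantom(PhantomSpec(grid=8, regions=()), equalize=False)
        imgs = forward_image(pha, _identity_matrix(), noise=0.0)
        mu_eff = effective_attenuation(imgs, 10.0)
        binning = EnergyBinning()
        _, e_eval, w_e, bin_idx = energy_grid(binning, 0.25)
        mu = np.asarray(surrogate_tissue_presets()["adipose"].mu(e_eval))
        for m in range(3):
            sel = bin_idx == m
            expected = -np.log((np.exp(-mu[sel] * 10.0) @ w_e[sel])
                               / w_e[sel].sum()) / 10.0
            np.testing.assert_allclose(mu_eff[m], expected, rtol=1e-9)

    def test_halving_intensity_adds_ln2(self):
        pha = make_phantom(PhantomSpec(grid=4, regions=()), equalize=False)
        imgs = forward_image(pha, _identity_matrix(), noise=0.0)
        mu1 = effective_attenuation(imgs, 10.0)
        imgs.images = imgs.images / 2.0
        mu2 = effective_attenuation(imgs, 10.0)
        np.testing.assert_allclose(mu2 - mu1, np.log(2.0) / 10.0, rtol=1e-9)

    def test_missing_flat_field_rejected(self, small_phantom):
        imgs = forward_image(small_phantom, _identity_matrix(), noise=0.0)
        imgs.flat = np.zeros(3)
        with pytest.raises(ValidationError):
            effective_attenuation(imgs, 10.0)


class TestIdentifyMaterials:
    def test_single_material_single_cluster(self):
        mu = np.full((3, 24, 24), 0.05)
        mu += np.random.default_rng(0).normal(0, 1e-6, mu.shape)
        mm = identify_materials(mu, seed=0)
        assert mm.n_materials == 0          # background only

    def test_two_separated_materials(self):
        rng = np.random.default_rng(1)
        mu = np.full((3, 24, 24), 0.05) + rng.normal(0, 1e-4, (3, 24, 24))
        truth = np.zeros((24, 24), dtype=int)
        truth[8:16, 8:16] = 1
        mu[:, truth == 1] += 0.5
        mm = identify_materials(mu, seed=0)
        assert mm.n_materials == 1
        assert image_accuracy(truth, mm.labels) == pytest.approx(1.0)

    def test_background_is_border_cluster(self):
        rng = np.random.default_rng(2)
        mu = np.full((3, 24, 24), 0.02) + rng.normal(0, 1e-4, (3, 24, 24))
        inner = np.zeros((24, 24), dtype=bool)
        inner[7:17, 7:17] = True
        mu[:, inner] += 0.3
        mm = identify_materials(mu, seed=0)
        assert not inner[mm.labels == mm.background_label].any()


class TestImageAccuracy:
    def test_identical_maps(self):
        labels = np.arange(12).reshape(3, 4) % 3
        assert image_accuracy(labels, labels) == 1.0

    def test_label_swap_invariance(self):
        labels = np.arange(12).reshape(3, 4) % 3
        assert image_accuracy(labels, (labels + 1) % 3) == 1.0

    def test_known_confusion(self):
        truth = np.array([0] * 4 + [1] * 4)
        pred = np.array([0, 0, 0, 1, 1, 1, 1, 1])
        assert image_accuracy(truth, pred) == pytest.approx(7.0 / 8.0)

    def test_matches_bruteforce_permutations(self):
        rng = np.random.default_rng(9)
        for k in (2, 4, 6):
            truth = rng.integers(0, k, 60)
            pred = rng.integers(0, k, 60)
            assert image_accuracy(truth, pred) == pytest.approx(
                image_accuracy_bruteforce(truth, pred), abs=1e-12)

    def test_mismatched_label_counts_padded(self):
        truth = np.array([0, 0, 1, 1, 2, 2])
        pred = np.array([0, 0, 0, 0, 1, 1])
        assert image_accuracy(truth, pred) == pytest.approx(4.0 / 6.0)

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            image_accuracy(np.zeros(4), np.zeros(5))


def test_pseudocolor_png(tmp_path):
    labels = np.arange(16).reshape(4, 4) % 5
    img = pseudocolor(labels, tmp_path / "map.png")
    assert img.shape == (4, 4, 3)
    assert (tmp_path / "map.png").exists()
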