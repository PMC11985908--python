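from dataclasses import replace

import numpy as np
import pytest

from multiscint.absorption import (EnergyBinning, absorption_per_length,
                                   analytic_eta, depth_grid, energy_grid,
                                   eta, optimize_thicknesses, p_abs, p_det,
                                   reconstruction_matrix)
from multiscint.errors import RangeError, ValidationError
from multiscint.materials import (AttenuationModel, Layer, LayerStack,
                                  ScintillatorProps, surrogate_stack)


def _mono_layer(mu_const: float, thickness: float, channel="R",
                name="const") -> Layer:
    """Layer with an energy-independent attenuation coefficient."""
    return Layer(name, AttenuationModel.parametric(0.0, np.log(mu_const)),
                 ScintillatorProps(50.0, 100.0, 1.8, channel), thickness)


class TestAbsorptionPerLength:
    def test_surface_value_is_top_mu(self, surrogate):
        for e in (20.0, 45.0, 60.0):
            assert absorption_per_length(surrogate, 0.0, e) == \
                pytest.approx(surrogate.layers[0].mu(e))

    def test_single_layer_integral_closed_form(self):
        stack = LayerStack((_mono_layer(3.0, 0.5),))
        z, ev, w = depth_grid(stack, 2000)
        total = absorption_per_length(stack, ev, 40.0) @ w
        assert total == pytest.approx(1.0 - np.exp(-3.0 * 0.5), abs=1e-7)

    def test_stacking_identity(self):
        one = LayerStack((_mono_layer(2.0, 0.4),))
        two = LayerStack((_mono_layer(2.0, 0.2, "R"),
                          _mono_layer(2.0, 0.2, "G")))
        z = np.linspace(0, 0.4, 31)
        np.testing.assert_allclose(absorption_per_length(two, z, 30.0),
                                   absorption_per_length(one, z, 30.0),
                                   rtol=1e-12)

    def test_depth_out_of_range(self, surrogate):
        with pytest.raises(RangeError):
            absorption_per_length(surrogate, 0.5, 30.0)


class TestPabs:
    def test_normalization(self, surrogate):
        z, ev, w = depth_grid(surrogate, 2000)
        for e in (20.0, 40.0, 60.0):
            assert p_abs(surrogate, ev, e) @ w == pytest.approx(1.0, abs=1e-6)

    def test_single_layer_closed_form(self):
        mu, L = 2.5, 0.6
        stack = LayerStack((_mono_layer(mu, L),))
        z = np.linspace(0, L, 11)
        expected = mu * np.exp(-mu * z) / (1.0 - np.exp(-mu * L))
        np.testing.assert_allclose(p_abs(stack, z, 30.0), expected,
                                   rtol=1e-10)

    def test_opaque_limit(self):
        mu, L = 100.0, 0.5   # mu L = 50 >> 30
        stack = LayerStack((_mono_layer(mu, L),))
        z = np.linspace(0, 0.2, 9)
        np.testing.assert_allclose(p_abs(stack, z, 30.0),
                                   mu * np.exp(-mu * z), rtol=1e-9)


class TestPdet:
    def test_uniform_for_energy_independent_mu(self):
        stack = LayerStack((_mono_layer(3.0, 0.3),))
        e = np.linspace(16, 67, 21)
        out = p_det(stack, [0.05, 0.2], e)
        np.testing.assert_allclose(out, 1.0 / 51.0, rtol=1e-9)

    def test_normalization(self, surrogate):
        binning = EnergyBinning()
        _, ev_e, w_e, _ = energy_grid(binning, 0.25)
        for z in (0.0, 0.15, 0.29):
            assert p_det(surrogate, z, ev_e) @ w_e == \
                pytest.approx(1.0, abs=1e-9)

    def test_mean_energy_grows_with_depth(self):
        # strictly decreasing mu(E): deeper depths see harder spectra
        stack = LayerStack((Layer(
            "soft", AttenuationModel.parametric(-2.5, 9.5),
            ScintillatorProps(50.0, 100.0, 1.8, "R"), 1.0),))
        _, ev_e, w_e, _ = energy_grid(EnergyBinning(), 0.25)
        means = [(p_det(stack, z, ev_e) * ev_e) @ w_e
                 for z in (0.0, 0.3, 0.6, 0.99)]
        assert np.all(np.diff(means) > 0)


class TestReconstructionMatrix:
    def test_total_and_row_sums(self, surrogate):
        m = reconstruction_matrix(surrogate)
        assert m.p.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(m.row_sums, 1.0 / 3.0, atol=1e-9)

    def test_energy_independent_mu_gives_uniform_matrix(self):
        stack = LayerStack((_mono_layer(3.0, 0.3),))
        m = reconstruction_matrix(stack)
        np.testing.assert_allclose(m.p, 1.0 / 9.0, atol=1e-9)

    def test_perfect_isolation_stack_is_near_diagonal(self):
        # each layer totally opaque to exactly one bin, transparent elsewhere
        def boxy(lo, hi):
            e = np.array([16.0, lo - 1e-6, lo, hi - 1e-6, hi, 67.0])
            v = np.array([1e-4, 1e-4, 4e3, 4e3, 1e-4, 1e-4])
            keep = np.unique(e, return_index=True)[1]
            return AttenuationModel.tabulated(e[keep], v[keep], 1.0,
                                              k_edges=(lo, hi))

        props = [ScintillatorProps(50.0, 100.0, 1.8, ch) for ch in "RGB"]
        stack = LayerStack((
            Layer("bin1", boxy(16.5, 33.0), props[0], 1.0),
            Layer("bin3", boxy(50.0, 66.9), props[1], 1.0),
            Layer("bin2", boxy(33.0, 50.0), props[2], 1.0)))
        m = reconstruction_matrix(stack)
        assert eta(m) > 0.9
        assert np.trace(m.p) > 2.0 * (m.p.sum() - np.trace(m.p))

    def test_unnormalized_spectrum_warns_and_normalizes(self, surrogate,
                                                        caplog):
        with caplog.at_level("WARNING"):
            m = reconstruction_matrix(surrogate, spectrum=lambda e: 5.0 + 0 * e)
        assert m.p.sum() == pytest.approx(1.0, abs=1e-9)
        assert any("normaliz" in r.message for r in caplog.records)

    def test_csv_export(self, surrogate, tmp_path):
        m = reconstruction_matrix(surrogate, n_z=200, de=1.0)
        path = tmp_path / "matrix.csv"
        m.to_csv(path)
        text = path.read_text()
        assert "16-33keV" in text and "50-67keV" in text


class TestEta:
    def test_diagonal_matrix(self):
        from multiscint.absorption import ReconstructionMatrix
        m = ReconstructionMatrix(np.eye(3) / 3.0, EnergyBinning())
        assert eta(m) == pytest.approx(1.0)

    def test_uniform_matrix(self):
        assert eta(np.full((3, 3), 1.0 / 9.0)) == pytest.approx(1.0 / 3.0)

    def test_scale_invariance(self):
        """eta depends only on the products mu * z (dimensional check)."""
        s = 4.0
        base = surrogate_stack(0.1)
        scaled_layers = tuple(
            replace(l, attenuation=AttenuationModel.parametric(
                l.attenuation.a, l.attenuation.b + np.log(s),
                l.attenuation.c, l.attenuation.e_k),
                thickness_mm=l.thickness_mm / s)
            for l in base.layers)
        assert analytic_eta(LayerStack(scaled_layers), n_z=800, de=0.5) == \
            pytest.approx(analytic_eta(base, n_z=800, de=0.5), abs=1e-9)

    def test_quadrature_convergence(self, surrogate):
        coarse = analytic_eta(surrogate, n_z=2000, de=0.25)
        fine = analytic_eta(surrogate, n_z=4000, de=0.125)
        assert abs(fine - coarse) < 1e-3


class TestOptimizeThicknesses:
    def test_monotone_single_layer_hits_bound(self):
        stack = surrogate_stack(0.1)
        single = LayerStack(stack.layers[:1])
        # 1-D sweep oracle: eta is monotone in thickness for this material
        sweep = [analytic_eta(single.with_thicknesses([d]), n_z=400, de=0.5)
                 for d in np.linspace(0.05, 1.2, 8)]
        assert np.all(np.diff(sweep) > 0)
        d_opt, _ = optimize_thicknesses(single, total_bound=1.2,
                                        box=(0.01, 1.2), n_starts=4, seed=0,
                                        n_z=400, de=0.5)
        assert d_opt[0] == pytest.approx(1.2, abs=0.01)

    def test_beats_equal_split_and_deterministic(self, surrogate):
        d1, eta1 = optimize_thicknesses(surrogate, total_bound=0.3,
                                        n_starts=3, seed=7, n_z=300, de=0.5)
        d2, eta2 = optimize_thicknesses(surrogate, total_bound=0.3,
                                        n_starts=3, seed=7, n_z=300, de=0.5)
        np.testing.assert_array_equal(d1, d2)
        assert eta1 == eta2
        assert eta1 >= analytic_eta(surrogate.with_thicknesses([0.1] * 3),
                                    n_z=2000, de=0.25) - 1e-6

    def test_infeasible_bound_rejected(self, surrogate):
        with pytest.raises(ValidationError):
            optimize_thicknesses(surrogate, total_bound=0.02)
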