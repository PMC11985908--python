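import numpy as np
import pytest

from multiscint.errors import RangeError, ValidationError
from multiscint.materials import (AttenuationModel, Layer, LayerStack,
                                  MassAttenuationCurve, ScintillatorProps,
                                  linear_attenuation,
                                  mixture_mass_attenuation,
                                  surrogate_material_presets, surrogate_stack)


class TestParametricModel:
    @pytest.mark.parametrize("a,b,c,e_k,e,expected", [
        (0.0, 0.0, 0.0, None, 30.0, 1.0),          # all exponents vanish
        (0.0, 0.0, np.log(2.0), 50.0, 49.0, 1.0),  # pre-edge branch
        (0.0, 0.0, np.log(2.0), 50.0, 51.0, 2.0),  # post-edge branch
        (0.0, 0.0, np.log(2.0), 50.0, 50.0, 2.0),  # edge energy is post-edge
    ])
    def test_closed_form(self, a, b, c, e_k, e, expected):
        model = AttenuationModel.parametric(a, b, c, e_k)
        assert model.mu(e) == pytest.approx(expected, rel=1e-12)

    def test_pure_power_law_halves(self):
        model = AttenuationModel.parametric(-1.0, 0.0)
        assert model.mu(40.0) / model.mu(20.0) == pytest.approx(0.5)

    def test_log_linear_on_each_side_of_edge(self):
        model = AttenuationModel.parametric(-2.3, 8.0, 1.1, 50.0)
        for lo, hi in [(16.0, 49.9), (50.0, 67.0)]:
            e = np.linspace(lo, hi, 40)
            y = np.log(model.mu(e))
            coeff = np.polyfit(np.log(e), y, 1)
            resid = y - np.polyval(coeff, np.log(e))
            assert np.max(np.abs(resid)) < 1e-10
            assert coeff[0] == pytest.approx(-2.3)

    def test_energy_out_of_range_rejected(self):
        model = AttenuationModel.parametric(-2.0, 5.0)
        with pytest.raises(RangeError):
            model.mu(10.0)
        with pytest.raises(RangeError):
            model.mu(80.0)

    def test_edge_jump_requires_edge_energy(self):
        with pytest.raises(ValidationError):
            AttenuationModel.parametric(-2.0, 5.0, c=1.0)


class TestTabulatedModel:
    def test_interpolation_brackets_between_edges(self):
        ref = AttenuationModel.parametric(-2.5, 9.0, 1.2, 50.0)
        tab = ref.to_tabulated(density=4.0, de=1.0)
        rng = np.random.default_rng(3)
        for e in rng.uniform(16, 67, 50):
            lo = tab.energy[tab.energy <= e].max()
            hi = tab.energy[tab.energy >= e].min()
            lo_mu, hi_mu = ref.mu(lo), ref.mu(hi)
            assert min(lo_mu, hi_mu) - 1e-12 <= tab.mu(e) <= \
                max(lo_mu, hi_mu) + 1e-12

    def test_edge_not_bridged(self):
        ref = AttenuationModel.parametric(-2.5, 9.0, np.log(5.0), 33.0)
        tab = ref.to_tabulated(de=0.5)
        # just below the edge the tabulated value follows the pre-edge branch
        assert tab.mu(32.9999) == pytest.approx(ref.mu(32.9999), rel=1e-3)
        assert tab.mu(33.0) == pytest.approx(ref.mu(33.0), rel=1e-6)
        assert tab.mu(33.0) / tab.mu(32.9999) > 4.5

    def test_negative_table_values_rejected(self):
        with pytest.raises(ValidationError):
            AttenuationModel.tabulated([16, 40, 67], [1.0, -0.5, 0.1], 1.0)

    def test_density_scales_linearly(self):
        tab = AttenuationModel.parametric(-2.0, 8.0).to_tabulated(density=2.0)
        assert linear_attenuation(tab, 4.0, 30.0) == \
            pytest.approx(2.0 * linear_attenuation(tab, 2.0, 30.0))


class TestMixtureRule:
    def _curve(self, values, edges=()):
        e = np.array([16.0, 30.0, 50.0, 67.0])
        return MassAttenuationCurve(e, np.full(4, values), edges)

    def test_single_component_identity(self):
        c = self._curve(2.0)
        out = mixture_mass_attenuation([(1.0, c)])
        np.testing.assert_allclose(out.values, c.values)

    def test_weighted_sum_of_constants(self):
        out = mixture_mass_attenuation([(0.5, self._curve(2.0)),
                                        (0.5, self._curve(4.0))])
        np.testing.assert_allclose(out.values, 3.0)

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            mixture_mass_attenuation([(0.7, self._curve(2.0)),
                                      (0.4, self._curve(4.0))])

    def test_equal_components_reproduce_curve_exactly(self):
        c = MassAttenuationCurve(np.array([16.0, 33.0, 50.0, 67.0]),
                                 np.array([5.0, 2.0, 1.0, 0.5]), (33.0,))
        out = mixture_mass_attenuation([(0.25, c)] * 4)
        np.testing.assert_array_equal(out.values, c.values)

    def test_edge_union_and_resampling(self, caplog):
        c1 = MassAttenuationCurve(np.linspace(16, 67, 52), np.full(52, 2.0),
                                  (33.0,))
        c2 = MassAttenuationCurve(np.linspace(16, 67, 18), np.full(18, 4.0),
                                  (50.0,))
        with caplog.at_level("WARNING"):
            out = mixture_mass_attenuation([(0.5, c1), (0.5, c2)])
        assert out.k_edges == (33.0, 50.0)
        assert any("resampling" in r.message for r in caplog.records)
        np.testing.assert_allclose(out.interp(np.array([20.0, 60.0])), 3.0,
                                   rtol=1e-9)


class TestPresets:
    def test_design_rules(self):
        presets = surrogate_material_presets()
        top = presets["surrogate_top"]
        mid = presets["surrogate_middle"]
        bot = presets["surrogate_bottom"]
        assert mid.mu(51.0) > mid.mu(49.0)          # Gd-like edge jump
        assert bot.mu(34.0) > bot.mu(32.0)          # I-like edge jump
        e = np.linspace(16, 67, 200)
        assert np.all(np.diff(top.mu(e)) < 0)       # no edge, decreasing
        assert top.attenuation.e_k is None

    def test_channels_blueshift_top_to_bottom(self):
        stack = surrogate_stack()
        assert stack.channels == ("R", "G", "B")


class TestLayerStack:
    def test_boundaries_and_total(self, surrogate):
        assert surrogate.total_thickness == pytest.approx(0.3)
        np.testing.assert_allclose(surrogate.boundaries, [0, 0.1, 0.2, 0.3])

    def test_layer_index_boundary_belongs_below(self, surrogate):
        assert surrogate.layer_index(0.0) == 0
        assert surrogate.layer_index(0.1) == 1
        assert surrogate.layer_index(0.3) == 2

    def test_delta_mu_sign_in_high_bin(self, surrogate):
        # the middle layer out-absorbs the top layer above the Gd edge
        assert np.all(surrogate.delta_mu(2, 1, np.linspace(51, 67, 10)) > 0)

    def test_distinct_channels_required(self):
        layer = surrogate_stack().layers[0]
        with pytest.raises(ValidationError):
            LayerStack((layer, layer))

    def test_with_thicknesses(self, surrogate):
        thick = surrogate.with_thicknesses([0.2, 0.3, 0.4])
        assert thick.total_thickness == pytest.approx(0.9)
        with pytest.raises(ValidationError):
            surrogate.with_thicknesses([0.1])

    def test_yaml_round_trip(self, tmp_path):
        table = tmp_path / "top.txt"
        e = np.linspace(16, 67, 52)
        np.savetxt(table, np.column_stack([e, 20.0 * (e / 16) ** -2.5]),
                   header="energy_keV mass_atten_cm2_g")
        cfg = tmp_path / "stack.yaml"
        cfg.write_text(f"""
layers:
  - material: tab_top
    thickness_mm: 0.15
    yield_per_keV: 55
    channel: R
    table: {{path: {table}, density: 5.4}}
  - material: param_bottom
    thickness_mm: 0.2
    yield_per_keV: 38
    channel: B
    parametric: {{a: -2.6, b: 9.0, c: 1.7, e_k: 33.0}}
""")
        stack = LayerStack.from_yaml(cfg)
        assert [l.name for l in stack.layers] == ["tab_top", "param_bottom"]
        assert stack.total_thickness == pytest.approx(0.35)
        assert stack.layers[0].mu(16.0) == pytest.approx(20.0 * 5.4 / 10.0)

    def test_scintillator_props_validation(self):
        with pytest.raises(ValidationError):
            ScintillatorProps(-1.0, 100.0, 1.8, "R")
        with pytest.raises(ValidationError):
            ScintillatorProps(10.0, 100.0, 1.8, "X")
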