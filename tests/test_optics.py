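"""Fresnel coefficients, layered synthesis, and the skin model."""

import math

import numpy as np
import pytest

import thzpad as tp
from thzpad.materials import OpticalMaterial, complex_index_at
from thzpad.optics import Layer, LayerStack

from conftest import tmm_reflection_p


BAND = np.linspace(0.1, 2.0, 77)


class TestSnell:
    def test_quartz_worked_example_rounds_to_20_degrees(self):
        theta1 = tp.snell_angle(45.0, 1.0, 2.10)
        assert theta1 == pytest.approx(19.68, abs=0.01)
        assert round(theta1) == 20

    def test_index_matched_passthrough(self):
        assert tp.snell_angle(37.3, 1.42, 1.42) == pytest.approx(37.3)

    def test_closed_form(self):
        assert tp.snell_angle(30.0, 1.0, 1.5) == \
            pytest.approx(math.degrees(math.asin(0.5 / 1.5)), abs=1e-9)

    def test_total_internal_reflection_names_critical_angle(self):
        with pytest.raises(ValueError, match="28.4"):
            tp.snell_angle(45.0, 2.10, 1.0)


class TestFresnelP:
    def test_no_interface_means_no_reflection(self):
        assert tp.fresnel_p(2.10 + 0j, 2.10 + 0j, 20.0) == pytest.approx(0.0)

    def test_quartz_to_air_positive(self):
        r = tp.fresnel_p(2.10 + 0j, 1.0 + 0j, 20.0)
        assert r.real > 0 and abs(r.imag) < 1e-12

    def test_quartz_to_dense_sample_negative(self):
        r = tp.fresnel_p(2.10 + 0j, 2.5 + 0j, 20.0)
        assert r.real < 0

    def test_normal_incidence_closed_form(self):
        for n in (1.0, 1.44, 1.9, 2.7):
            assert tp.fresnel_p(2.10 + 0j, n + 0j, 0.0) == \
                pytest.approx((2.10 - n) / (2.10 + n), rel=1e-12)

    def test_against_zero_thickness_transfer_matrix(self):
        """Single interface checked against the independent matrix oracle."""
        nu = np.array([0.5])
        for N_s in (1.5 + 0j, 2.5 + 0.4j, 1.2 + 1.1j):
            mine = tp.fresnel_p(2.10 + 0j, N_s, 19.677)
            oracle = tmm_reflection_p(2.10, [], np.array([N_s]), 19.677, nu)[0]
            assert mine == pytest.approx(oracle, rel=1e-12)

    def test_energy_bound_over_library(self, library, geometry):
        theta1 = geometry.theta1_deg
        for mat in library.values():
            N = complex_index_at(mat, BAND)
            r = tp.fresnel_p(np.full_like(BAND, 2.10, dtype=complex), N, theta1)
            assert np.all(np.abs(r) <= 1.0 + 1e-12), mat.name


class TestRelativeReflection:
    def test_air_reference_is_unity(self, library, geometry):
        r = tp.relative_reflection(library["air"], geometry, BAND)
        assert np.allclose(r, 1.0)

    def test_dispersion_free_sample_is_flat(self):
        """With a lossless window, a lossless flat-index sample reflects
        identically at every frequency."""
        window = OpticalMaterial("quartz0", "window", np.array([0.05, 3.0]),
                                 np.array([2.10, 2.10]), np.array([0.0, 0.0]))
        geometry = tp.Geometry(window=window)
        mat = OpticalMaterial("flat", "group1", np.array([0.05, 3.0]),
                              np.array([1.6, 1.6]), np.array([0.0, 0.0]))
        r = tp.relative_reflection(mat, geometry, BAND)
        assert np.ptp(np.abs(r)) < 1e-12

    def test_can_exceed_unity_against_air_reference(self, library, geometry):
        """High-index lossy media out-reflect the air reference."""
        r = tp.relative_reflection(library["water"], geometry, np.array([0.1]))
        assert abs(r[0]) > 1.0


class TestSimulateThick:
    def test_air_sample_returns_reference(self, reference, library, geometry):
        out = tp.simulate_thick_reflection(reference, library["air"], geometry)
        assert np.allclose(out.amplitude, reference.amplitude, atol=1e-10)

    @pytest.mark.parametrize("name, sign", [
        ("silicone", +1), ("latex", +1), ("plasticine", +1),
        ("playdoh", -1), ("water", -1),
    ])
    def test_main_peak_phase(self, reference, library, geometry, name, sign):
        out = tp.simulate_thick_reflection(reference, library[name], geometry)
        k = int(np.argmax(np.abs(out.amplitude)))
        assert np.sign(out.amplitude[k]) == sign

    def test_phase_follows_index_ordering(self, reference, library, geometry):
        """Main-peak sign equals the reference's iff n_sample < n_window.

        Evaluated at 0.3 THz, where the pulse carries most of its energy.
        """
        for name in ("silicone", "latex", "plasticine", "playdoh", "water", "skin"):
            mat = library[name]
            out = tp.simulate_thick_reflection(reference, mat, geometry)
            k = int(np.argmax(np.abs(out.amplitude)))
            same_sign = np.sign(out.amplitude[k]) == 1  # reference peak is positive
            assert same_sign == (mat.n_at(0.3) < 2.10), name


class TestThinOverlay:
    def test_rejects_bad_thickness_and_orders(self, reference, library, geometry):
        with pytest.raises(ValueError):
            tp.simulate_thin_overlay(reference, library["silicone"], 0.0,
                                     library["air"], geometry)
        with pytest.raises(ValueError):
            tp.simulate_thin_overlay(reference, library["silicone"], 0.5,
                                     library["air"], geometry, orders=0)

    def test_opaque_limit_matches_thick_model(self, reference, library, geometry):
        """Strong absorption or thickness kills the internal echoes."""
        thick = tp.simulate_thick_reflection(reference, library["water"], geometry)
        overlay = tp.simulate_thin_overlay(reference, library["water"], 5.0,
                                           library["air"], geometry, orders=None)
        assert np.allclose(overlay.amplitude, thick.amplitude, atol=1e-6)

    def test_second_echo_sign_follows_backing(self, reference, library, geometry):
        """Air behind the overlay gives a positive echo, a finger a negative one."""
        for backing, sign in (("air", +1), ("skin", -1)):
            out = tp.simulate_thin_overlay(reference, library["silicone"], 0.5,
                                           library[backing], geometry)
            sel = out.t > 13.0  # beyond the main pulse
            k = np.flatnonzero(sel)[int(np.argmax(np.abs(out.amplitude[sel])))]
            assert np.sign(out.amplitude[k]) == sign, backing

    def test_echo_delay_matches_time_of_flight(self, reference, library, geometry):
        """tau = 2 n d cos(theta_s)/c, the ray delay corrected for the
        oblique wavefront (the relation the depth formula inverts)."""
        d_mm, n = 0.5, library["silicone"].n_at(1.0)
        theta_s = math.radians(tp.snell_angle(geometry.theta1_deg, 2.10, n))
        tau_expected = 2.0 * n * d_mm * 1000.0 * math.cos(theta_s) / 299.792458
        out = tp.simulate_thin_overlay(reference, library["silicone"], d_mm,
                                       library["air"], geometry)
        rf = tp.response_function(out, reference)
        echoes = tp.find_echoes(rf, 2, min_separation_ps=1.5)
        tau = abs(echoes[0][0] - echoes[1][0])
        assert tau == pytest.approx(tau_expected, abs=0.05)

    def test_full_series_matches_transfer_matrix_oracle(self, reference, library,
                                                        geometry):
        """orders=None must agree with the independent characteristic-matrix
        computation to 1e-6 relative amplitude."""
        d_um = 500.0
        out = tp.simulate_thin_overlay(reference, library["silicone"], d_um / 1000,
                                       library["skin"], geometry, orders=None)
        nu = np.fft.rfftfreq(reference.amplitude.size, reference.dt)
        sel = (nu >= 0.1) & (nu <= 2.0)
        ratio = (np.fft.rfft(out.amplitude) / np.fft.rfft(reference.amplitude))[sel]
        N_q = complex_index_at(geometry.window, nu[sel])
        N_s = complex_index_at(library["silicone"], nu[sel])
        N_b = complex_index_at(library["skin"], nu[sel])
        r = tmm_reflection_p(N_q, [(N_s, d_um)], N_b, geometry.theta1_deg, nu[sel])
        r_air = tmm_reflection_p(N_q, [], np.ones_like(nu[sel], complex),
                                 geometry.theta1_deg, nu[sel])
        oracle = np.conj(r / r_air)  # package spectra use the DFT sign convention
        assert np.max(np.abs(ratio - oracle)) <= 1e-6 * np.max(np.abs(oracle))

    def test_finite_orders_converge_to_full_series(self, reference, library, geometry):
        full = tp.simulate_thin_overlay(reference, library["silicone"], 0.5,
                                        library["air"], geometry, orders=None)
        few = tp.simulate_thin_overlay(reference, library["silicone"], 0.5,
                                       library["air"], geometry, orders=12)
        assert np.allclose(full.amplitude, few.amplitude, atol=1e-9)


class TestLayerStack:
    def test_single_layer_matches_overlay_series(self, library, geometry):
        stack = LayerStack(layers=(Layer(library["latex"], 0.5),),
                           backing=library["skin"])
        nu = np.linspace(0.1, 2.0, 64)
        r_stack = tp.stack_reflection(stack, geometry, nu)
        N = complex_index_at(library["latex"], nu)
        oracle = tmm_reflection_p(complex_index_at(geometry.window, nu),
                                  [(N, 500.0)],
                                  complex_index_at(library["skin"], nu),
                                  geometry.theta1_deg, nu)
        assert np.allclose(r_stack, oracle, atol=1e-9)

    def test_json_round_trip(self, library):
        stack = LayerStack(layers=(Layer(library["latex"], 0.5),
                                   Layer(library["silicone"], 1.25)),
                           backing=library["air"])
        back = LayerStack.from_json(stack.to_json(), library)
        assert [l.material.name for l in back.layers] == ["latex", "silicone"]
        assert back.layers[1].thickness_mm == 1.25
        assert back.backing.name == "air"


class TestSimulateFinger:
    def test_internal_echo_depth_recovers_sc_thickness(self, reference, library,
                                                       geometry):
        """A 0.2 mm stratum corneum trails the main pulse by roughly 2.5 ps,
        and inverting the delay with the mean skin index n ~ 2 recovers the
        configured depth to ~15% (the inversion uses the rough band-mean
        index, exactly as the printed estimate does)."""
        params = tp.SkinParams(0.2, library["skin"], library["epidermis"], 1.0)
        out = tp.simulate_finger(reference, params, geometry)
        rf = tp.response_function(out, reference)
        echoes = tp.find_echoes(rf, 2, min_separation_ps=1.2)
        tau = abs(echoes[0][0] - echoes[1][0])
        assert 2.2 <= tau <= 3.0
        depth = tp.estimate_interface_depth(tau, 2.0, geometry.theta1_deg)
        assert depth == pytest.approx(200.0, rel=0.15)

    def test_negative_main_phase(self, reference, library, geometry):
        params = tp.SkinParams(0.35, library["skin"], library["epidermis"], 1.0)
        out = tp.simulate_finger(reference, params, geometry)
        k = int(np.argmax(np.abs(out.amplitude)))
        assert out.amplitude[k] < 0

    def test_zero_contrast_kills_the_echo(self, reference, library, geometry):
        """Without an index step under the stratum corneum, the two-layer
        model degenerates to the bare thick reflection (no internal echo)."""
        sc = library["skin"]
        almost = OpticalMaterial("epi0", "skin", sc.nu, sc.n + 1e-9, sc.alpha)
        out = tp.simulate_finger(reference, tp.SkinParams(0.3, sc, almost, 1.0),
                                 geometry)
        thick = tp.simulate_thick_reflection(reference, sc, geometry)
        assert np.allclose(out.amplitude, thick.amplitude, atol=1e-8)

    def test_pressure_scales_amplitude(self, reference, library, geometry):
        soft = tp.simulate_finger(reference, tp.SkinParams(
            0.3, library["skin"], library["epidermis"], 1.0), geometry)
        hard = tp.simulate_finger(reference, tp.SkinParams(
            0.3, library["skin"], library["epidermis"], 0.6), geometry)
        assert np.allclose(hard.amplitude, 0.6 * soft.amplitude)

    def test_invariants_enforced(self, library):
        with pytest.raises(ValueError):
            tp.SkinParams(0.01, library["skin"], library["epidermis"], 1.0)
        with pytest.raises(ValueError):
            tp.SkinParams(0.3, library["epidermis"], library["skin"], 1.0)
        with pytest.raises(ValueError):
            tp.SkinParams(0.3, library["skin"], library["epidermis"], 1.5)


def test_geometry_derived_angle(geometry):
    assert round(geometry.theta1_deg) == 20
    with pytest.raises(ValueError):
        tp.Geometry(theta0_deg=95.0)
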