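"""Equivalent circuit, impedance spectra, regime taxonomy and the
Nyquist link between spectra and eigenvalues."""

import cmath
import math

import numpy as np
import pytest

from fhncircuit import (
    ModelParams,
    SpectrumClass,
    admittance_at,
    bifurcation_summary,
    classify_spectrum,
    classify_spectrum_detail,
    ec_elements,
    impedance_at,
    impedance_zeros,
    jacobian,
    preset,
    spectrum,
    stability_report,
)

from conftest import random_params


class TestECElements:
    def test_model_e_elements_at_origin(self):
        ec = ec_elements(0.0, preset("E"))
        assert ec.C_m == pytest.approx(0.02)
        assert ec.G_b == pytest.approx(-2.0)
        assert ec.R_b == pytest.approx(-0.5)
        assert ec.R_a == pytest.approx(0.75)
        assert ec.L == pytest.approx(0.625)
        assert ec.R_dc == pytest.approx(-1.5)

    def test_channel_branch_opens_at_reference_voltage(self):
        for name in ("A", "D", "E"):
            p = preset(name)
            ec = ec_elements(p.u_1, p)
            assert ec.G_b == 0.0
            assert ec.R_dc == pytest.approx(ec.R_a)

    def test_dc_resistance_diverges_at_saddle_node(self):
        p = preset("E")
        u_sn = math.sqrt(1.0 / 3.0)
        assert abs(1.0 / ec_elements(u_sn, p).R_dc) < 1e-12

    def test_negative_channel_resistance_inside_ndr_window(self):
        p = preset("C")
        for u in (0.0, 0.5, 0.999):
            assert ec_elements(u, p).G_b < 0
        for u in (1.001, 1.5):
            assert ec_elements(u, p).G_b > 0


class TestImpedanceValues:
    def test_dc_limit_is_signed_dc_resistance(self):
        for name in ("A", "C", "E"):
            p = preset(name)
            for u in (0.0, 0.6, 1.2):
                z = impedance_at(u, p, 0.0)
                assert z.imag == 0.0
                assert z.real == pytest.approx(ec_elements(u, p).R_dc, rel=1e-14)

    def test_capacitive_asymptote(self):
        z = impedance_at(0.0, preset("E"), 1e6)
        assert abs(z) == pytest.approx(5.0e-5, rel=1e-2)

    def test_low_frequency_approach(self):
        """Re Z -> R_dc and Im Z -> 0 from the regime-appropriate side."""
        p = preset("C")
        w = 1e-9 / p.tau_k
        z = impedance_at(0.9, p, w)
        assert z.real == pytest.approx(ec_elements(0.9, p).R_dc, rel=1e-6)
        assert abs(z.imag) < 1e-6 * abs(z.real)
        assert z.imag > 0  # inductive regime: crosses into the fourth quadrant

        zA = impedance_at(0.0, preset("A"), 1e-9 / preset("A").tau_k)
        assert zA.imag < 0  # capacitive arc leaves downward

    def test_bias_symmetry(self, rng):
        """Z depends on the bias only through u^2."""
        for p in random_params(rng, 20):
            u = float(rng.uniform(0, 2))
            w = np.logspace(-2, 5, 40)
            np.testing.assert_allclose(
                impedance_at(u, p, w), impedance_at(-u, p, w), rtol=1e-14
            )


class TestSpectrum:
    def test_head_entry_is_dc_resistance(self):
        for name in ("A", "B", "C", "D", "E", "F"):
            p = preset(name)
            for u in (0.0, 0.9, 1.1):
                spec = spectrum(u, p)
                assert spec.omegas[0] == 0.0
                assert np.all(np.diff(spec.omegas) > 0)
                assert spec.Z[0].imag == 0.0
                assert spec.Z[0].real == pytest.approx(
                    ec_elements(u, p).R_dc, rel=1e-14
                )

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            spectrum(0.0, preset("A"), omega_min=10.0, omega_max=1.0)
        with pytest.raises(ValueError):
            spectrum(0.0, preset("A"), omega_min=-1.0, omega_max=1.0)


class TestRegimeClassification:
    @pytest.mark.parametrize(
        "name,u,expected",
        [
            ("A", 0.0, SpectrumClass.RC_ARC),
            ("B", 0.0, SpectrumClass.BENT_ARC),
            ("C", 0.0, SpectrumClass.HIDDEN_NDR),
            ("C", 0.5, SpectrumClass.HIDDEN_NDR),
            ("C", 0.9, SpectrumClass.INDUCTIVE_LOOP),
            ("D", 1.1, SpectrumClass.INDUCTIVE_LOOP),
            ("E", 0.0, SpectrumClass.NEGATIVE_RDC),
            ("F", 0.0, SpectrumClass.NEGATIVE_RDC),
        ],
    )
    def test_preset_regime_taxonomy(self, name, u, expected):
        assert classify_spectrum(u, preset(name)) is expected

    def test_hidden_ndr_crossing_direction_matches_instability(self):
        """The spectrum enters Re Z < 0 through the fourth quadrant of the
        -Im plot exactly when the bias is an unstable focus (tr J > 0)."""
        p = preset("C")
        u_H = bifurcation_summary(p).hopf_voltage
        for u in (0.3, 0.6, u_H - 0.01):
            d = classify_spectrum_detail(u, p)
            assert d.regime is SpectrumClass.HIDDEN_NDR
            assert d.re_crossing_omega is not None
            assert impedance_at(u, p, d.re_crossing_omega * 0.999).imag > 0
        for u in (u_H + 0.01, 0.95):
            d = classify_spectrum_detail(u, p)
            assert d.regime is SpectrumClass.INDUCTIVE_LOOP
            assert impedance_at(u, p, d.re_crossing_omega * 0.999).imag < 0

    def test_loop_condition_on_stable_branch(self):
        """On the stable positive-R_dc branch (b = 1, bias outside the NDR
        window) an inductive loop appears iff eps < r/b, over a 20x20 grid."""
        eps_grid = np.logspace(-2, 1.3, 20)
        r_grid = np.logspace(-1, 0.6, 20)
        u = 1.05
        for eps in eps_grid:
            for r in r_grid:
                if abs(eps - r) < 0.05 * min(eps, r):
                    continue  # skip the boundary itself
                p = ModelParams.from_ratios(b=1.0, epsilon=float(eps), r=float(r))
                label = classify_spectrum(u, p)
                assert label is not SpectrumClass.NEGATIVE_RDC
                assert label is not SpectrumClass.HIDDEN_NDR
                assert (label is SpectrumClass.INDUCTIVE_LOOP) == (eps < r)

    def test_bend_ratio_reported(self):
        d = classify_spectrum_detail(0.0, preset("B"))
        assert d.bend_ratio == pytest.approx((1.2 / 1.0) / 1.8, rel=1e-12)


class TestNyquistLink:
    def test_admittance_zeros_equal_jacobian_eigenvalues(self, rng):
        """The natural frequencies extracted from the circuit equal the
        state-space eigenvalues, over 1000 random draws."""
        for p in random_params(rng, 1000):
            u = float(rng.uniform(-2, 2))
            got = impedance_zeros(u, p)
            want = sorted(
                (complex(z) for z in np.linalg.eigvals(jacobian(u, p))),
                key=lambda z: (z.real, z.imag),
            )
            for g, w in zip(got, want):
                assert abs(g - w) <= 1e-9 * max(abs(g), abs(w), 1e-30)

    def test_purely_imaginary_pair_at_hopf(self):
        p = preset("C")
        u_H = bifurcation_summary(p).hopf_voltage
        z1, z2 = impedance_zeros(u_H, p)
        det = stability_report(u_H, p).det_norm / p.tau_m ** 2
        assert abs(z1.real) < 1e-9 * abs(z1)
        assert abs(z1.imag) == pytest.approx(math.sqrt(det), rel=1e-9)
        # the impedance itself has a pole there: the admittance vanishes
        assert abs(admittance_at(u_H, p, math.sqrt(det))) < 1e-12

    def test_saddle_gives_real_roots_of_opposite_sign(self):
        z1, z2 = impedance_zeros(0.0, preset("E"))
        assert z1.imag == z2.imag == 0
        assert z1.real < 0 < z2.real

    def test_admittance_minimum_vanishes_exactly_at_hopf(self):
        """min_w |Y(iw)| drops to zero only at the Hopf bias; off-Hopf
        biases keep it bounded away from zero."""
        p = preset("C")
        u_H = bifurcation_summary(p).hopf_voltage

        def min_abs_y(u):
            det = stability_report(u, p).det_norm / p.tau_m ** 2
            w0 = math.sqrt(abs(det))
            w = np.linspace(0.5 * w0, 1.5 * w0, 2001)
            return float(np.min(np.abs(admittance_at(u, p, w))))

        assert min_abs_y(u_H) < 1e-8
        for du in (1.1e-3, 0.01, -1.1e-3, -0.01):
            assert min_abs_y(u_H + du) > 1e-6
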