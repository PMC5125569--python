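import math
from itertools import product

import numpy as np
import pytest

from dendrifield import transfer
from dendrifield.params import (
    MORPHOLOGY_SWEEP,
    BiophysicalParams,
    PointModelParams,
    derive_cable_params,
)

F_GRID = np.logspace(-1, 4, 200)
OMEGA = 2 * np.pi * F_GRID


def morphologies():
    for L, Dd, Ds in product(*(MORPHOLOGY_SWEEP[k] for k in ("L", "D_d", "D_s"))):
        yield derive_cable_params(BiophysicalParams(D_s=Ds, D_d=Dd, L=L))


def ep_point(cable):
    return PointModelParams.for_ep(cable, alpha=transfer.alpha_factor(cable))


class TestWavenumber:
    def test_dc_value_is_inverse_length_constant(self, cable):
        z0 = complex(transfer.z_of_omega(0.0, cable))
        assert z0.imag == 0.0
        assert z0.real == pytest.approx(1.0 / cable.lambda_c, rel=1e-12)

    def test_high_precision_oracle_at_100hz(self, cable):
        # frozen 20-digit evaluation of the two radicals (sympy, exact rationals)
        z = complex(transfer.z_of_omega(2 * np.pi * 100.0, cable))
        assert z.real == pytest.approx(4077.5207438663255542, rel=1e-12)
        assert z.imag == pytest.approx(3852.3319082013049165, rel=1e-12)

    def test_hermitian_symmetry_and_branch(self, cable):
        z_pos = transfer.z_of_omega(OMEGA, cable)
        z_neg = transfer.z_of_omega(-OMEGA, cable)
        np.testing.assert_allclose(z_neg, np.conj(z_pos), rtol=1e-14)
        assert np.all(z_pos.real >= 0) and np.all(z_pos.imag >= 0)


class TestDenominatorAndImpedances:
    def test_dc_closed_form_lif(self, cable):
        x0 = complex(transfer.x_denominator(0.0, cable))
        closed = cable.G_s + math.sqrt(cable.g_m * cable.g_i) * math.tanh(
            cable.L / cable.lambda_c
        )
        assert x0.imag == 0.0
        assert x0.real == pytest.approx(closed, rel=1e-12)
        # frozen high-precision value
        assert x0.real == pytest.approx(8.5084381464925894e-10, rel=1e-12)

    def test_zero_length_cable_reduces_to_point_membrane(self, cable):
        from dataclasses import replace

        tiny = replace(cable, L=1e-12)
        w = 2 * np.pi * 50.0
        x = complex(transfer.x_denominator(w, tiny))
        assert x == pytest.approx(tiny.C_s * 1j * w + tiny.G_s, rel=1e-6)

    def test_eif_dc_positive_and_slightly_reduced(self, cable, eif):
        lin = transfer.MembraneLinearization.from_params(eif, cable.G_s)
        x_eif = complex(transfer.x_denominator(0.0, cable, eif, lin)).real
        x_lif = complex(transfer.x_denominator(0.0, cable)).real
        assert 0 < x_eif < x_lif

    def test_somatic_impedance_monotone_decreasing(self, cable):
        gain = np.abs(transfer.somatic_impedance(OMEGA, cable))
        assert np.all(np.diff(gain) <= 1e-18)

    def test_distal_transfer_vanishes_at_high_frequency(self, cable):
        z = transfer.z_of_omega(2 * np.pi * 1e4, cable)
        gain = abs(complex(transfer.distal_transfer(2 * np.pi * 1e4, cable)))
        dc = abs(complex(transfer.distal_transfer(0.0, cable)))
        assert gain < 1e-3 * dc

    def test_hermitian_symmetry_of_all_transfer_functions(self, cable, eif):
        lin = transfer.MembraneLinearization.from_params(eif, cable.G_s)
        point = ep_point(cable)
        for fn in (
            lambda w: transfer.x_denominator(w, cable, eif, lin),
            lambda w: transfer.somatic_impedance(w, cable),
            lambda w: transfer.distal_transfer(w, cable),
            lambda w: transfer.filter_somatic(w, cable, point, eif, lin),
            lambda w: transfer.filter_distal(w, cable, point, eif, lin),
            lambda w: transfer.field_response_A(w, 1.0, cable),
            lambda w: transfer.equivalent_current_B(w, 1.0, cable, point),
        ):
            np.testing.assert_allclose(fn(-OMEGA), np.conj(fn(OMEGA)), rtol=1e-12)


class TestLinearization:
    def test_lif_limit_is_trivial(self, lif, cable):
        lin = transfer.MembraneLinearization.from_params(lif, cable.G_s)
        assert lin.leak_factor == 1.0 and lin.offset_current == 0.0

    def test_continuity_to_lif_at_tiny_slope(self, cable, eif):
        """All EIF-branch quantities at Delta_T=1e-6 mV match the LIF branch to 6 sig figs."""
        from dataclasses import replace

        near_lif = replace(eif, Delta_T=1e-9, V_s=eif.V_T)  # 1e-6 mV in SI volts
        lin = transfer.MembraneLinearization.from_params(near_lif, cable.G_s)
        point = ep_point(cable)
        w = 2 * np.pi * np.array([0.0, 7.0, 300.0])
        for eif_val, lif_val in (
            (transfer.x_denominator(w, cable, near_lif, lin), transfer.x_denominator(w, cable)),
            (
                transfer.filter_somatic(w, cable, point, near_lif, lin),
                transfer.filter_somatic(w, cable, point),
            ),
            (
                transfer.equivalent_current_B(w, 1.0, cable, point, near_lif, lin),
                transfer.equivalent_current_B(w, 1.0, cable, point),
            ),
        ):
            np.testing.assert_allclose(eif_val, lif_val, rtol=1e-6)


class TestFilters:
    def test_zero_length_cable_gives_identity_filters(self, cable):
        from dataclasses import replace

        tiny = replace(cable, L=1e-12)
        point = PointModelParams(C=tiny.C_s, G=tiny.G_s)
        np.testing.assert_allclose(
            transfer.filter_somatic(OMEGA, tiny, point), 1.0, rtol=1e-6
        )
        np.testing.assert_allclose(
            transfer.filter_distal(OMEGA, tiny, point), 1.0, rtol=1e-6
        )

    def test_somatic_dc_closed_form(self, cable):
        point = PointModelParams(C=cable.C_s, G=cable.G_s)
        val = complex(transfer.filter_somatic(0.0, cable, point))
        closed = cable.G_s / (
            cable.G_s
            + math.sqrt(cable.g_m * cable.g_i) * math.tanh(cable.L / cable.lambda_c)
        )
        assert val.imag == 0.0
        assert val.real == pytest.approx(closed, rel=1e-12)
        assert val.real < 1.0

    def test_distal_equals_somatic_times_sech(self, cable):
        point = ep_point(cable)
        z = transfer.z_of_omega(OMEGA, cable)
        np.testing.assert_allclose(
            transfer.filter_distal(OMEGA, cable, point),
            transfer.filter_somatic(OMEGA, cable, point) * transfer.sech_zL(z, cable.L),
            rtol=1e-12,
        )

    def test_highpass_lowpass_shapes_all_morphologies(self):
        """|L_s| non-decreasing (-> 1 asymptotically), |L_d| non-increasing (-> 0)."""
        for cab in morphologies():
            point = ep_point(cab)
            ls = np.abs(transfer.filter_somatic(OMEGA, cab, point))
            ld = np.abs(transfer.filter_distal(OMEGA, cab, point))
            assert np.all(np.diff(ls) >= -1e-12)
            assert np.all(np.diff(ld) <= 1e-12)
            # |L_s| -> 1 like f^(-1/2); check far beyond the physiological band
            assert abs(complex(transfer.filter_somatic(2 * np.pi * 1e10, cab, point))) == (
                pytest.approx(1.0, abs=5e-3)
            )
            assert ld[-1] < 0.05


class TestAlpha:
    def test_range_and_zero_length_limit(self):
        from dataclasses import replace

        for cab in morphologies():
            a = transfer.alpha_factor(cab)
            assert 0 < a <= 1
            assert transfer.alpha_factor(replace(cab, L=1e-15)) == pytest.approx(1.0)

    def test_equals_gs_over_x0_in_lif_limit(self, cable):
        assert transfer.alpha_factor(cable) == pytest.approx(
            cable.G_s / complex(transfer.x_denominator(0.0, cable)).real, rel=1e-12
        )

    def test_long_cable_limit(self, cable):
        from dataclasses import replace

        long = replace(cable, L=1.0)
        assert transfer.alpha_factor(long) == pytest.approx(
            cable.G_s / (cable.G_s + cable.g_i / cable.lambda_c), rel=1e-9
        )

    def test_dc_exponential_current_steady_state_matches(self, cable):
        """Fixed points of BS (quasi-static) and eP driven by the exponential current agree.

        Oracle: scalar root finds on each model's DC balance with the full
        exponential nonlinearity, no linearization.
        """
        from scipy.optimize import brentq

        alpha = transfer.alpha_factor(cable)
        x0 = complex(transfer.x_denominator(0.0, cable)).real
        G_s, dT, vT = cable.G_s, 1.5e-3, 10e-3
        i0 = 6e-12  # subcritical drive

        v_bs = brentq(lambda v: x0 * v - G_s * dT * math.exp((v - vT) / dT) - i0, 0, vT)
        # eP receives the DC-filtered drive alpha*i0 and the alpha-scaled exponential
        v_ep = brentq(
            lambda v: G_s * v - alpha * G_s * dT * math.exp((v - vT) / dT) - alpha * i0,
            0,
            vT,
        )
        assert v_ep == pytest.approx(v_bs, rel=1e-10)


class TestFieldResponse:
    def test_zero_length_cable_not_polarized(self, cable):
        from dataclasses import replace

        tiny = replace(cable, L=1e-15)
        assert abs(complex(transfer.field_response_A(2 * np.pi * 10, 1.0, tiny))) < 1e-18

    def test_low_frequency_sensitivity_near_0p3_mm(self, cable):
        sens_mm = abs(complex(transfer.field_response_A(2 * np.pi * 0.5, 1.0, cable))) * 1e3
        assert sens_mm == pytest.approx(0.30, abs=0.05)

    def test_sensitivity_decreasing_B_increasing_all_morphologies(self, cable):
        """|A|/E1 falls with frequency everywhere; |B| rises strictly at the
        default morphology and, across the sweep, rises apart from a shallow
        (< 4% relative) shoulder near a few hundred Hz in the short-thin-cable
        large-soma corner, where the sensitivity briefly falls faster than the
        membrane admittance grows."""
        for cab in morphologies():
            point = ep_point(cab)
            A = np.abs(transfer.field_response_A(OMEGA, 1.0, cab))
            B = np.abs(transfer.equivalent_current_B(OMEGA, 1.0, cab, point))
            assert np.all(np.diff(A) <= 1e-18)
            drawdown = np.max((np.maximum.accumulate(B) - B) / np.maximum.accumulate(B))
            assert drawdown < 0.04
            assert B[-1] > B[0]
        B0 = np.abs(transfer.equivalent_current_B(OMEGA, 1.0, cable, ep_point(cable)))
        assert np.all(np.diff(B0) > 0)

    def test_b_is_a_times_point_admittance(self, cable, eif):
        lin = transfer.MembraneLinearization.from_params(eif, cable.G_s)
        point = ep_point(cable)
        w = 2 * np.pi * 1e3
        A = complex(transfer.field_response_A(w, 1.0, cable, eif, lin))
        B = complex(transfer.equivalent_current_B(w, 1.0, cable, point, eif, lin))
        leak = 1.0 - point.alpha * math.exp((eif.V_0 - eif.V_T) / eif.Delta_T)
        assert B == pytest.approx(A * (point.C * 1j * w + point.G * leak), rel=1e-12)

    def test_field_linearity_in_amplitude(self, cable):
        w = 2 * np.pi * 25.0
        a1 = complex(transfer.field_response_A(w, 1.0, cable))
        a10 = complex(transfer.field_response_A(w, 10.0, cable))
        assert a10 == pytest.approx(10 * a1, rel=1e-12)
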