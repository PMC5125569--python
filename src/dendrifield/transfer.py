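"""Closed-form frequency-domain transfer functions of the ball-and-stick neuron.

Everything here follows from solving the passive cable equation with a lumped
(possibly linearized-EIF) soma at x=0 and a sealed end with synaptic flux at
x=L, under the temporal Fourier convention that multiplies the e^{+i omega t}
component of a real signal by the transfer value. With that convention a
passive membrane produces a phase *lag* (negative argument) and every transfer
function is Hermitian: H(-omega) = conj(H(omega)).

Provided quantities, all as functions of angular frequency omega [rad/s]:

* ``z_of_omega``      — complex cable wavenumber z(omega) [1/m]
* ``x_denominator``   — shared denominator X(omega) [S]
* ``somatic_impedance`` / ``distal_transfer`` — somatic voltage per unit
  somatic / distal input current [Ohm]
* ``filter_somatic`` / ``filter_distal``      — the dimensionless input
  filters of the extended point (eP) model
* ``alpha_factor``    — exponential-term scaling of the eP EIF model
* ``field_response_A``— somatic voltage phasor per uniform field [V]
* ``equivalent_current_B`` — field-equivalent input current phasor [A]

The soma may carry an exponential spike-initiation current; its linearization
around a baseline voltage V_0 enters through ``MembraneLinearization``. In the
LIF limit (Delta_T == 0) the exponential term is omitted and all expressions
are exact for subthreshold drive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import DerivedCableParams, PointModelParams, SpikeMechanismParams

__all__ = [
    "MembraneLinearization",
    "z_of_omega",
    "tanh_zL",
    "sech_zL",
    "x_denominator",
    "somatic_impedance",
    "distal_transfer",
    "filter_somatic",
    "filter_distal",
    "alpha_factor",
    "field_response_A",
    "equivalent_current_B",
    "frequency_table",
]


@dataclass(frozen=True)
class MembraneLinearization:
    """Linearization of the somatic exponential current around baseline V_0.

    ``leak_factor`` multiplies the somatic leak conductance:
    1 - exp((V_0 - V_T)/Delta_T); ``offset_current`` is the accompanying
    steady current G_s * exp((V_0 - V_T)/Delta_T) * (Delta_T - V_0) [A].
    Both reduce to the trivial values (1, 0) in the LIF limit.
    """

    leak_factor: float
    offset_current: float

    @classmethod
    def from_params(
        cls, spike: SpikeMechanismParams, G_s: float
    ) -> "MembraneLinearization":
        if spike.is_lif:
            return cls(leak_factor=1.0, offset_current=0.0)
        e = math.exp((spike.V_0 - spike.V_T) / spike.Delta_T)
        return cls(
            leak_factor=1.0 - e,
            offset_current=G_s * e * (spike.Delta_T - spike.V_0),
        )


def z_of_omega(omega, cable: DerivedCableParams):
    """Complex cable wavenumber z(omega) [1/m].

    Computed from the explicit two-radical form

        z = sqrt((g_m + R)/(2 g_i)) + sgn(omega) * i * sqrt((-g_m + R)/(2 g_i)),
        R = sqrt(g_m^2 + omega^2 c_m^2),

    rather than a principal complex sqrt, which pins the sign convention:
    Re z >= 0, sign(Im z) == sign(omega), and z(-omega) = conj(z(omega)).
    """
    omega = np.asarray(omega, dtype=float)
    radical = np.sqrt(cable.g_m**2 + omega**2 * cable.c_m**2)
    re = np.sqrt((cable.g_m + radical) / (2.0 * cable.g_i))
    im = np.sqrt(np.maximum(radical - cable.g_m, 0.0) / (2.0 * cable.g_i))
    return re + 1j * np.sign(omega) * im


def tanh_zL(z, L: float):
    """tanh(z L) for complex z with Re(z) >= 0, safe against overflow.

    For |Re(zL)| beyond ~350, cosh/sinh overflow double precision; tanh -> 1
    there (Re z >= 0), so the value is clamped via the scaled identity
    tanh(w) = (1 - e^{-2w}) / (1 + e^{-2w}).
    """
    w = np.asarray(z * L)
    e = np.exp(-2.0 * w)  # |e| <= 1 since Re w >= 0
    return (1.0 - e) / (1.0 + e)


def sech_zL(z, L: float):
    """sech(z L) via scaled exponentials: 2 e^{-w} / (1 + e^{-2w}), Re w >= 0."""
    w = np.asarray(z * L)
    e = np.exp(-w)
    return 2.0 * e / (1.0 + e * e)


def x_denominator(
    omega,
    cable: DerivedCableParams,
    spike: SpikeMechanismParams | None = None,
    lin: MembraneLinearization | None = None,
):
    """Shared denominator X(omega) [S] of every somatic response component.

        X(omega) = C_s i omega + G_s * leak_factor + z(omega) g_i tanh(z(omega) L)

    where ``leak_factor`` is 1 in the LIF limit and
    1 - exp((V_0 - V_T)/Delta_T) for the linearized EIF soma.
    """
    if lin is None:
        lin = (
            MembraneLinearization(1.0, 0.0)
            if spike is None
            else MembraneLinearization.from_params(spike, cable.G_s)
        )
    omega = np.asarray(omega, dtype=float)
    z = z_of_omega(omega, cable)
    return (
        cable.C_s * 1j * omega
        + cable.G_s * lin.leak_factor
        + z * cable.g_i * tanh_zL(z, cable.L)
    )


def somatic_impedance(omega, cable, spike=None, lin=None):
    """Somatic voltage response per unit somatic input current, 1/X(omega) [Ohm]."""
    return 1.0 / x_denominator(omega, cable, spike, lin)


def distal_transfer(omega, cable, spike=None, lin=None):
    """Somatic voltage per unit distal input current, sech(zL)/X(omega) [Ohm]."""
    z = z_of_omega(omega, cable)
    return sech_zL(z, cable.L) / x_denominator(omega, cable, spike, lin)


def _point_admittance(omega, point: PointModelParams, spike=None):
    """C i omega + G * (1 - alpha e^{(V_0-V_T)/Delta_T}) of the point membrane [S]."""
    omega = np.asarray(omega, dtype=float)
    if spike is None or spike.is_lif:
        leak = 1.0
    else:
        leak = 1.0 - point.alpha * math.exp((spike.V_0 - spike.V_T) / spike.Delta_T)
    return point.C * 1j * omega + point.G * leak


def filter_somatic(omega, cable, point: PointModelParams, spike=None, lin=None):
    """Dimensionless somatic input filter of the eP model.

    Ratio of point-membrane admittance to X(omega); with C = C_s and G = G_s
    this is a high-pass filter whose gain tends to 1 at high frequency: fast
    somatic input charges the somatic capacitance before leaking into the
    cable, so the dendrite only attenuates the slow components.
    """
    return _point_admittance(omega, point, spike) / x_denominator(omega, cable, spike, lin)


def filter_distal(omega, cable, point: PointModelParams, spike=None, lin=None):
    """Dimensionless distal input filter: filter_somatic * sech(z(omega) L).

    Low-pass — distal input is attenuated along the cable increasingly with
    frequency, so its gain decays to 0.
    """
    z = z_of_omega(omega, cable)
    return filter_somatic(omega, cable, point, spike, lin) * sech_zL(z, cable.L)


def alpha_factor(cable: DerivedCableParams) -> float:
    """Scaling of the eP exponential term, alpha = G_s / (G_s + tanh(L/lambda) g_i/lambda).

    With lambda = sqrt(g_i/g_m) this equals G_s/X(0) in the LIF limit; it
    guarantees that the spike-initiation current drives the same steady-state
    somatic depolarization in the BS and eP models. 0 < alpha <= 1, with
    alpha -> 1 as L -> 0.
    """
    lam = cable.lambda_c
    return cable.G_s / (cable.G_s + math.tanh(cable.L / lam) * cable.g_i / lam)


def field_response_A(phi, E1: float, cable, spike=None, lin=None):
    """Somatic voltage phasor A(phi) [V] in response to the field E1 sin(phi t).

        A(phi) = E1 g_i [sech(z(phi) L) - 1] / X(phi)

    The subthreshold somatic response is |A| sin(phi t + arg A). A vanishes
    for L = 0: a point neuron is not polarized by a uniform field. The
    sensitivity |A|/E1 has units of length (polarization length).
    """
    z = z_of_omega(phi, cable)
    return (
        E1 * cable.g_i * (sech_zL(z, cable.L) - 1.0)
        / x_denominator(phi, cable, spike, lin)
    )


def equivalent_current_B(phi, E1: float, cable, point: PointModelParams, spike=None, lin=None):
    """Field-equivalent input current phasor B(phi) [A] for the point model.

    B(phi) = A(phi) * (C i phi + G (1 - alpha e^{(V_0-V_T)/Delta_T})): the
    current that, injected into the point membrane, reproduces the somatic
    field response. Its magnitude *increases* with frequency (the membrane
    admittance grows faster than the sensitivity falls) up to ~10 kHz.
    """
    return field_response_A(phi, E1, cable, spike, lin) * _point_admittance(
        phi, point, spike
    )


def frequency_table(f_hz, values) -> "np.recarray":
    """Columnar table (f, Re, Im, gain, phase) for export/regression tests."""
    f_hz = np.asarray(f_hz, dtype=float)
    values = np.asarray(values, dtype=complex)
    out = np.recarray(f_hz.shape, dtype=[
        ("f", float), ("re", float), ("im", float), ("gain", float), ("phase", float),
    ])
    out.f, out.re, out.im = f_hz, values.real, values.imag
    out.gain, out.phase = np.abs(values), np.angle(values)
    return out
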