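"""Point neuron simulators: the extended point (eP) model and the plain P model.

The eP model is a single-compartment integrate-and-fire neuron

    C dV/dt + G V - alpha G Delta_T e^{(V - V_T)/Delta_T}
        = [L_s * I_s](t) + [L_d * I_d](t) + I_E(t)

whose input currents are first passed through the analytically derived
dendritic filters (somatic high-pass L_s, distal low-pass L_d) and augmented
with the field-equivalent current I_E(t) = |B(phi)| sin(phi t + arg B(phi)).
With C = C_s, G = G_s and alpha from the cable geometry, its subthreshold
somatic voltage equals that of the ball-and-stick model exactly (LIF case) or
to linearization accuracy (EIF case). On reaching V_s the voltage is reset to
the elevated value V_r' = (V_r + V_T)/2 and clamped for T_ref.

The P model is the same membrane without the extension (identity filters,
alpha = 1); its two parameters are calibrated per input condition: G_P
matches the DC somatic impedance of the BS model at the input site, and C_P
maximizes the spike coincidence factor Gamma against a BS reference train.

Filters are applied spectrally: FFT of the trace, multiplication by the
filter sampled on the transform's frequency grid, inverse FFT. The trace is
treated as periodic, so it is pre-padded with one membrane time constant of
mirrored samples on each side (then trimmed) to suppress wrap-around
transients; Hermitian symmetry of the filter is verified by checking that the
imaginary residue of the output is at rounding level before discarding it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import BLOWUP, point_step_loop
from .analysis import coincidence_factor
from .params import (
    BiophysicalParams,
    DerivedCableParams,
    PointModelParams,
    SpikeMechanismParams,
    derive_cable_params,
)
from .stimuli import FieldParams
from .traces import CurrentTrace, SpikeTrain, VoltageTrace
from . import transfer

__all__ = [
    "FilteredInput",
    "FieldEquivalentCurrent",
    "PointResult",
    "apply_filter",
    "build_field_current",
    "simulate_point",
    "simulate_ep",
    "fit_p_model",
    "PModelFit",
]

_MV, _PA = 1e-3, 1e-12


@dataclass(frozen=True)
class FilteredInput:
    """A current trace after dendritic filtering, tagged with its provenance."""

    trace: CurrentTrace
    which: str  # "somatic" or "distal"
    params_digest: str


@dataclass(frozen=True)
class FieldEquivalentCurrent:
    """Sinusoidal field-equivalent current: amplitude [pA], phase [rad], f_field [Hz]."""

    amplitude: float
    phase: float
    f_field: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")

    def sample(self, duration: float, dt: float) -> CurrentTrace:
        """Evaluate |B| sin(phi t + arg B) [pA] on the grid t = 0, dt, ... [ms]."""
        n = int(round(duration / dt))
        t_s = dt * 1e-3 * np.arange(n)
        phi = 2.0 * np.pi * self.f_field
        return CurrentTrace(dt=dt, values=self.amplitude * np.sin(phi * t_s + self.phase))


@dataclass(frozen=True)
class PointResult:
    v: VoltageTrace
    spikes: SpikeTrain


def _as_cable(params) -> DerivedCableParams:
    if isinstance(params, BiophysicalParams):
        return derive_cable_params(params)
    return params


def apply_filter(
    I: CurrentTrace,
    which: str,
    params: BiophysicalParams | DerivedCableParams,
    point: PointModelParams | None = None,
    spike: SpikeMechanismParams | None = None,
) -> FilteredInput:
    """Convolve a current trace with the somatic or distal dendritic filter.

    ``which`` selects ``"somatic"`` (high-pass L_s) or ``"distal"`` (low-pass
    L_d). ``point`` defaults to the eP choice C = C_s, G = G_s with alpha from
    the cable geometry. A constant input I0 maps to the constant L(0) * I0.
    """
    if I.values.size < 2:
        raise ValueError("trace must contain at least 2 samples")
    cable = _as_cable(params)
    if point is None:
        point = PointModelParams.for_ep(cable, alpha=transfer.alpha_factor(cable))
    if which == "somatic":
        filt = transfer.filter_somatic
    elif which == "distal":
        filt = transfer.filter_distal
    else:
        raise ValueError(f"which must be 'somatic' or 'distal', got {which!r}")
    lin = None if spike is None else transfer.MembraneLinearization.from_params(spike, cable.G_s)

    pad = int(round(cable.tau_m / (I.dt * 1e-3)))
    pad = min(pad, I.values.size - 1)
    x = np.pad(I.values, pad, mode="reflect") if pad else I.values.copy()
    n = x.size
    freqs = np.fft.fftfreq(n, d=I.dt * 1e-3)
    H = np.asarray(filt(2.0 * np.pi * freqs, cable, point, spike, lin), dtype=complex)
    if n % 2 == 0:
        H[n // 2] = H[n // 2].real  # Nyquist bin must be real for a real signal
    y = np.fft.ifft(np.fft.fft(x) * H)
    scale = max(np.max(np.abs(x)), 1e-300)
    resid = np.max(np.abs(y.imag)) / scale
    if resid > 1e-10:
        raise AssertionError(
            f"filter output has imaginary residue {resid:.2e}; Hermitian symmetry violated"
        )
    out = y.real[pad : pad + I.values.size] if pad else y.real
    digest = f"{which}:L={cable.L:.6g},Ds_C={point.C:.6g},alpha={point.alpha:.6g}"
    return FilteredInput(
        trace=CurrentTrace(dt=I.dt, values=out, t0=I.t0), which=which, params_digest=digest
    )


def build_field_current(
    field: FieldParams,
    params: BiophysicalParams | DerivedCableParams,
    spike: SpikeMechanismParams | None = None,
    point: PointModelParams | None = None,
) -> FieldEquivalentCurrent:
    """Field-equivalent current for the point model, from the closed form B(phi).

    For the EIF membrane (``spike`` with Delta_T > 0) the linearized leak
    factor enters both B's numerator admittance and the denominator.
    """
    cable = _as_cable(params)
    if point is None:
        point = PointModelParams.for_ep(cable, alpha=transfer.alpha_factor(cable))
    lin = None if spike is None else transfer.MembraneLinearization.from_params(spike, cable.G_s)
    B = complex(
        transfer.equivalent_current_B(field.phi, field.E1, cable, point, spike, lin)
    )
    return FieldEquivalentCurrent(
        amplitude=abs(B) / _PA, phase=float(np.angle(B)), f_field=field.f_field
    )


def simulate_point(
    point: PointModelParams,
    spike: SpikeMechanismParams,
    total_input: CurrentTrace,
    *,
    v_init: float = 0.0,
) -> PointResult:
    """Forward-Euler integration of the point membrane driven by ``total_input``.

    For the eP model ``total_input`` is the sum of the filtered somatic and
    distal inputs and the field-equivalent current; for the P model it is the
    raw input. Reset goes to the elevated V_r'.
    """
    dt = total_input.dt
    n_steps = total_input.values.size - 1
    if n_steps < 1:
        raise ValueError("input trace must contain at least 2 samples")
    dt_s = dt * 1e-3
    v_out = np.empty(n_steps + 1)
    max_spikes = n_steps // max(int(round(spike.T_ref / dt_s)), 1) + 2
    spike_steps = np.empty(max_spikes, dtype=np.int64)
    n_spikes, status, step = point_step_loop(
        v_init * _MV, total_input.values * _PA, dt_s,
        point.C, point.G, point.alpha,
        spike.Delta_T, spike.V_T, spike.V_r_prime, spike.V_s, spike.T_ref,
        v_out, spike_steps,
    )
    if status == BLOWUP:
        raise RuntimeError(
            f"point-model voltage exceeded the guard bound at step {step} "
            f"(t = {step * dt:.3f} ms)"
        )
    return PointResult(
        v=VoltageTrace(dt=dt, values=v_out / _MV),
        spikes=SpikeTrain(times=spike_steps[:n_spikes] * dt, duration=(n_steps + 1) * dt),
    )


def simulate_ep(
    params: BiophysicalParams | DerivedCableParams,
    spike: SpikeMechanismParams,
    I_s: CurrentTrace | None = None,
    I_d: CurrentTrace | None = None,
    field: FieldParams | None = None,
    *,
    dt: float | None = None,
    duration: float | None = None,
    v_init: float = 0.0,
) -> PointResult:
    """Convenience driver for the eP model: filter inputs, add I_E, integrate.

    The same raw input realizations passed to :func:`dendrifield.bs.simulate_bs`
    may be passed here to compare the two models spike for spike.
    """
    cable = _as_cable(params)
    point = PointModelParams.for_ep(cable, alpha=transfer.alpha_factor(cable))
    ref = I_s if I_s is not None else I_d
    if ref is None:
        if dt is None or duration is None:
            raise ValueError("specify dt and duration when no input trace is given")
        n = int(round(duration / dt))
        total = np.zeros(n)
    else:
        dt = ref.dt
        duration = ref.duration
        total = np.zeros(ref.values.size)
    if I_s is not None:
        total = total + apply_filter(I_s, "somatic", cable, point, spike).trace.values
    if I_d is not None:
        total = total + apply_filter(I_d, "distal", cable, point, spike).trace.values
    if field is not None and field.E1 != 0.0:
        ie = build_field_current(field, cable, spike, point)
        total = total + ie.sample(duration, dt).values
    return simulate_point(point, spike, CurrentTrace(dt=dt, values=total), v_init=v_init)


@dataclass(frozen=True)
class PModelFit:
    """Calibrated P-model parameters and the Gamma achieved at the optimum."""

    point: PointModelParams
    gamma: float
    site: str
    c_grid: np.ndarray
    gamma_grid: np.ndarray


def _gamma_for_cp(c_p, g_p, spike, raw_input, bs_train, delta):
    res = simulate_point(PointModelParams(C=c_p, G=g_p), spike, raw_input)
    return coincidence_factor(bs_train, res.spikes, delta=delta).gamma


def fit_p_model(
    bs_train: SpikeTrain,
    raw_input: CurrentTrace,
    site: str,
    params: BiophysicalParams | DerivedCableParams,
    spike: SpikeMechanismParams,
    *,
    delta: float = 3.0,
    n_scan: int = 17,
    c_range: tuple[float, float] = (0.2, 5.0),
    refine_tol: float = 0.01,
) -> PModelFit:
    """Calibrate the plain P model against a BS reference spike train.

    G_P is fixed analytically so that the steady-state somatic voltage
    matches: the reciprocal of the BS DC impedance at the input site
    (somatic: X(0); distal: X(0)/sech(L/lambda), both in the LIF form). C_P is
    then chosen to maximize the coincidence factor Gamma between the BS train
    and the P train driven by the *same* raw input realization: a log-spaced
    scan of ``n_scan`` points over ``c_range`` (in units of C_s) followed by
    golden-section refinement of the bracketing interval to relative
    tolerance ``refine_tol``.
    """
    if bs_train.n == 0:
        raise ValueError("cannot calibrate against an empty reference spike train")
    cable = _as_cable(params)
    x0 = float(np.real(transfer.x_denominator(0.0, cable)))
    if site == "somatic":
        g_p = x0
    elif site == "distal":
        g_p = x0 / float(np.real(transfer.sech_zL(transfer.z_of_omega(0.0, cable), cable.L)))
    else:
        raise ValueError(f"site must be 'somatic' or 'distal', got {site!r}")

    c_grid = cable.C_s * np.logspace(np.log10(c_range[0]), np.log10(c_range[1]), n_scan)
    gammas = np.array([
        _gamma_for_cp(c, g_p, spike, raw_input, bs_train, delta) for c in c_grid
    ])
    best = int(np.nanargmax(gammas))
    lo = c_grid[max(best - 1, 0)]
    hi = c_grid[min(best + 1, n_scan - 1)]

    # golden-section ascent on the bracket (Gamma is noisy-flat near the top;
    # stop on relative bracket width)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c1 = b - invphi * (b - a)
    c2 = a + invphi * (b - a)
    f1 = _gamma_for_cp(c1, g_p, spike, raw_input, bs_train, delta)
    f2 = _gamma_for_cp(c2, g_p, spike, raw_input, bs_train, delta)
    while (b - a) / b > refine_tol:
        if f1 >= f2:
            b, c2, f2 = c2, c1, f1
            c1 = b - invphi * (b - a)
            f1 = _gamma_for_cp(c1, g_p, spike, raw_input, bs_train, delta)
        else:
            a, c1, f1 = c1, c2, f2
            c2 = a + invphi * (b - a)
            f2 = _gamma_for_cp(c2, g_p, spike, raw_input, bs_train, delta)
    candidates = [(gammas[best], c_grid[best]), (f1, c1), (f2, c2)]
    gamma_best, c_best = max(candidates, key=lambda t: t[0])
    return PModelFit(
        point=PointModelParams(C=c_best, G=g_p),
        gamma=float(gamma_best),
        site=site,
        c_grid=c_grid,
        gamma_grid=gammas,
    )
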