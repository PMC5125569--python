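"""Biophysical parameters of the ball-and-stick (BS) neuron and derived quantities.

The BS model is a lumped somatic compartment attached to a finite passive
dendritic cable. All parameters here are held in SI units (F, S, m, V, s);
interfaces that deal in neuroscience units (mV, pA, ms, um) convert at the
boundary. Default values correspond to a cortical pyramidal neuron with a
10 um soma and a 700 um long, 1.2 um thick apical main dendrite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "BiophysicalParams",
    "DerivedCableParams",
    "SpikeMechanismParams",
    "PointModelParams",
    "derive_cable_params",
    "lif_limit",
    "MORPHOLOGY_SWEEP",
]

#: Morphology sweep used throughout: cable length, cable diameter, soma diameter (m).
MORPHOLOGY_SWEEP = {
    "L": (350e-6, 700e-6, 1050e-6),
    "D_d": (0.6e-6, 1.2e-6, 1.8e-6),
    "D_s": (5e-6, 10e-6, 15e-6),
}


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not value > 0.0:
            raise ValueError(f"parameter {name!r} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class BiophysicalParams:
    """Specific membrane/axial constants plus morphology of the BS neuron.

    Attributes
    ----------
    c : float
        Specific membrane capacitance [F/m^2].
    rho_m : float
        Specific membrane conductance [S/m^2].
    rho_i : float
        Specific internal (axial) conductance [S/m].
    D_s, D_d, L : float
        Soma diameter, dendritic cable diameter, cable length [m].
    """

    c: float = 1e-2
    rho_m: float = 1.0 / 2.8
    rho_i: float = 1.0 / 1.5
    D_s: float = 10e-6
    D_d: float = 1.2e-6
    L: float = 700e-6

    def __post_init__(self) -> None:
        _require_positive(
            c=self.c, rho_m=self.rho_m, rho_i=self.rho_i,
            D_s=self.D_s, D_d=self.D_d, L=self.L,
        )


@dataclass(frozen=True)
class DerivedCableParams:
    """Per-unit-length cable constants and lumped somatic quantities (SI).

    ``lambda_c = sqrt(g_i / g_m)`` is the electrotonic length constant: the
    distance over which a steady-state voltage perturbation decays e-fold
    along an infinite cable.
    """

    c_m: float  # dendritic capacitance per unit length [F/m]
    g_m: float  # dendritic conductance per unit length [S/m]
    g_i: float  # internal (axial) conductance per unit length [S*m]
    C_s: float  # somatic capacitance [F]
    G_s: float  # somatic conductance [S]
    L: float    # cable length [m], carried along for convenience
    lambda_c: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "lambda_c", math.sqrt(self.g_i / self.g_m))

    @property
    def tau_m(self) -> float:
        """Membrane time constant c_m/g_m = C_s/G_s [s] (28 ms at defaults)."""
        return self.c_m / self.g_m


def derive_cable_params(bio: BiophysicalParams) -> DerivedCableParams:
    """Compute the derived cable and somatic quantities from specific constants.

    c_m = c*D_d*pi, g_m = rho_m*D_d*pi, g_i = rho_i*(D_d/2)^2*pi,
    C_s = c*D_s^2*pi, G_s = rho_m*D_s^2*pi.
    """
    return DerivedCableParams(
        c_m=bio.c * bio.D_d * math.pi,
        g_m=bio.rho_m * bio.D_d * math.pi,
        g_i=bio.rho_i * (bio.D_d / 2.0) ** 2 * math.pi,
        C_s=bio.c * bio.D_s**2 * math.pi,
        G_s=bio.rho_m * bio.D_s**2 * math.pi,
        L=bio.L,
    )


@dataclass(frozen=True)
class SpikeMechanismParams:
    """Spike initiation, reset and refractoriness (voltages in V, times in s).

    ``Delta_T`` is the threshold slope factor of the exponential
    (spike-initiating sodium) current; ``Delta_T == 0`` encodes the leaky
    integrate-and-fire (LIF) limit in which the exponential term is omitted
    entirely — it must never be used as a divisor.  ``V_r_prime`` is the
    elevated reset used by the point models, (V_r + V_T)/2, which mimics the
    residual dendritic depolarization of the BS model after a spike.
    ``V_0`` is the baseline voltage about which the exponential term is
    linearized when deriving the point-model extension.
    """

    V_T: float = 10e-3
    Delta_T: float = 1.5e-3
    V_r: float = 0.0
    V_r_prime: float = 5e-3
    V_s: float = 20e-3
    T_ref: float = 1.5e-3
    V_0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.V_r <= self.V_r_prime < self.V_T <= self.V_s):
            raise ValueError(
                "spike voltages must satisfy V_r <= V_r_prime < V_T <= V_s; got "
                f"V_r={self.V_r}, V_r_prime={self.V_r_prime}, V_T={self.V_T}, V_s={self.V_s}"
            )
        if self.Delta_T < 0:
            raise ValueError("Delta_T must be >= 0 (0 encodes the LIF limit)")
        if self.T_ref < 0:
            raise ValueError("T_ref must be >= 0")

    @property
    def is_lif(self) -> bool:
        return self.Delta_T == 0.0


def lif_limit(p: SpikeMechanismParams) -> SpikeMechanismParams:
    """Return a copy of ``p`` in the LIF limit: Delta_T -> 0 and V_s = V_T.

    Idempotent. Downstream code treats Delta_T == 0 as "omit the exponential
    term", so no division by Delta_T ever occurs.
    """
    return replace(p, Delta_T=0.0, V_s=p.V_T)


@dataclass(frozen=True)
class PointModelParams:
    """Membrane parameters of a point (single-compartment) neuron model.

    For the extended point (eP) model the capacitance and conductance are
    chosen equal to the somatic quantities of the BS model; ``alpha`` scales
    the exponential term so that the spike-initiating current produces the
    same steady state in both models (``alpha = 1`` in the L -> 0 limit and
    for the plain P model).
    """

    C: float
    G: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        _require_positive(C=self.C, G=self.G)
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha!r}")

    @classmethod
    def for_ep(cls, cable: DerivedCableParams, alpha: float = 1.0) -> "PointModelParams":
        return cls(C=cable.C_s, G=cable.G_s, alpha=alpha)
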