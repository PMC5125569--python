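"""Synthetic inputs: Ornstein-Uhlenbeck synaptic currents and sinusoidal fields.

The OU process emulates in-vivo-like fluctuating synaptic input current

    dI/dt = (I0 - I)/tau + sigma * sqrt(2/tau) * xi(t)

with stationary mean ``I0``, stationary standard deviation ``sigma`` and
correlation time ``tau`` (default 0.5 ms). Because tau is comparable to the
integration step, traces are generated with the *exact* update

    I[n+1] = I0 + (I[n] - I0) e^{-dt/tau} + sigma sqrt(1 - e^{-2 dt/tau}) eta[n]

(eta standard normal), which is distributionally correct at any dt, rather
than by Euler-Maruyama. The initial value is drawn from the stationary
distribution.

Seed policy: one master seed spawns independent substreams per trial and per
input site via ``numpy.random.SeedSequence``, so a BS and a point simulation
that must see the *same* realization share the trace object itself, while
different trials/sites are statistically independent.

User-facing time series use neuroscience units: time in ms, current in pA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .traces import CurrentTrace

__all__ = ["OUParams", "FieldParams", "CurrentTrace", "ou_trace", "field_trace", "spawn_seeds"]


@dataclass(frozen=True)
class OUParams:
    """Ornstein-Uhlenbeck input parameters: mean/sigma [pA], tau [ms]."""

    mean: float
    sigma: float
    tau: float = 0.5
    seed: int | np.random.SeedSequence = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")


@dataclass(frozen=True)
class FieldParams:
    """Uniform extracellular field E(t) = E1 sin(2 pi f_field t): E1 [V/m], f_field [Hz]."""

    E1: float = 1.0
    f_field: float = 10.0

    @property
    def phi(self) -> float:
        """Angular frequency [rad/s]."""
        return 2.0 * np.pi * self.f_field


def spawn_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Spawn ``n`` independent child seed sequences from one master seed."""
    return np.random.SeedSequence(master_seed).spawn(n)


def ou_trace(p: OUParams, duration: float, dt: float) -> CurrentTrace:
    """Generate an OU current realization of ``duration`` ms sampled at ``dt`` ms.

    The first sample is drawn from the stationary distribution
    N(mean, sigma^2); with sigma = 0 the trace relaxes deterministically to
    (and from I(0)=mean, stays at) the mean. Identical ``p.seed`` gives an
    identical trace.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    if duration < dt:
        raise ValueError("duration must be at least one sample interval")
    n = int(round(duration / dt))
    rng = np.random.default_rng(p.seed)
    decay = np.exp(-dt / p.tau)
    kick = p.sigma * np.sqrt(1.0 - decay**2)
    if p.sigma == 0.0:
        values = np.full(n, p.mean)
    else:
        # The centered recurrence x[k] = decay*x[k-1] + u[k] is an AR(1)
        # filter; u[0] carries the stationary initial draw.
        eta = rng.standard_normal(n)
        u = kick * eta
        u[0] = p.sigma * eta[0]
        x = lfilter([1.0], [1.0, -decay], u)
        values = p.mean + x
    return CurrentTrace(dt=dt, values=values)


def field_trace(p: FieldParams, duration: float, dt: float) -> np.ndarray:
    """Sample E(t) = E1 sin(2 pi f t) [V/m] on the grid t = 0, dt, ... (< duration).

    E(0) = 0 and |E| peaks at E1; f_field = 0 or E1 = 0 give identically zero.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    n = int(round(duration / dt))
    t = dt * np.arange(n)  # ms
    return p.E1 * np.sin(2.0 * np.pi * p.f_field * t * 1e-3)
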