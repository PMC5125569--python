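"""Spike-train analysis: coincidence factor, rates, field-locked modulation.

The coincidence factor Gamma quantifies agreement between a reference and a
comparison spike train at temporal precision Delta (default 3 ms):

    Gamma = (N_coinc - <N_coinc>) / ((N_ref + N_comp)/2) * 1/N,
    <N_coinc> = 2 r Delta N_ref,   r = N_comp / T,   N = 1 - 2 r Delta.

<N_coinc> is the chance level of a homogeneous Poisson train with the
comparison train's rate, and N normalizes the maximum to 1, reached when the
trains match spike for spike within Delta. Gamma ~ 0 indicates pure chance.
The measure is asymmetric in (ref, comp); coincidences are counted by greedy
earliest-first one-to-one matching, which is a maximum matching for the
interval-overlap structure induced by a tolerance window.

The field-locked spike-rate modulation r(t) = r0 + r1 sin(phi t + psi) is
estimated from many trials: each spike is assigned its field phase
phi_s = (phi t_s) mod 2pi (complete field cycles only, after discarding an
initial transient), the phase histogram is converted to rate units, and
r1, psi are obtained by linear least squares with r0 fixed to the histogram
mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .stimuli import FieldParams
from .traces import SpikeTrain

__all__ = [
    "CoincidenceResult",
    "ModulationFit",
    "ResonanceCurve",
    "coincidence_factor",
    "count_coincidences",
    "spike_rate",
    "rate_modulation",
    "resonance_curve",
]


@dataclass(frozen=True)
class CoincidenceResult:
    """Gamma plus its ingredients; ``gamma`` is NaN when the normalization N -> 0."""

    gamma: float
    n_coinc: int
    n_ref: int
    n_comp: int
    delta: float
    norm: float

    @property
    def undefined(self) -> bool:
        return not np.isfinite(self.gamma)


def count_coincidences(ref: np.ndarray, comp: np.ndarray, delta: float) -> int:
    """Greedy earliest-first one-to-one matching within +-delta (times in ms)."""
    count = 0
    j = 0
    n_comp = comp.size
    for t in ref:
        while j < n_comp and comp[j] < t - delta:
            j += 1
        if j < n_comp and comp[j] <= t + delta:
            count += 1
            j += 1
    return count


def coincidence_factor(
    ref: SpikeTrain, comp: SpikeTrain, delta: float = 3.0
) -> CoincidenceResult:
    """Coincidence factor Gamma between two spike trains at precision ``delta`` ms.

    The two trains must cover the same duration. When the comparison rate
    approaches 1/(2 delta) the normalization vanishes and ``gamma`` is
    returned as NaN (flagged, not unbounded).
    """
    if ref.duration <= 0 or abs(ref.duration - comp.duration) > max(ref.duration, comp.duration) * 1e-6:
        raise ValueError("trains must share a positive duration")
    n_ref, n_comp = ref.n, comp.n
    n_coinc = count_coincidences(ref.times, comp.times, delta)
    r = n_comp / ref.duration  # spikes per ms
    expected = 2.0 * r * delta * n_ref
    norm = 1.0 - 2.0 * r * delta
    denom = (n_ref + n_comp) / 2.0
    if denom <= 0 or abs(norm) < 1e-12:
        gamma = float("nan")
    else:
        gamma = (n_coinc - expected) / denom / norm
    return CoincidenceResult(
        gamma=gamma, n_coinc=n_coinc, n_ref=n_ref, n_comp=n_comp, delta=delta, norm=norm
    )


def spike_rate(train: SpikeTrain) -> float:
    """Mean spike rate count/duration [Hz]; an empty train has rate 0."""
    return train.rate


@dataclass(frozen=True)
class ModulationFit:
    """Field-locked spike-rate modulation r(t) = r0 + r1 sin(phi t + psi).

    ``impeded`` flags fits with r1 > r0, where the sinusoidal description of
    the trial-averaged rate breaks down (the rate would go negative).
    """

    r0: float
    r1: float
    psi: float
    f_field: float
    n_trials: int
    n_bins: int
    n_spikes: int
    impeded: bool

    @property
    def phases(self) -> tuple[float, float]:  # pragma: no cover - convenience
        return (self.psi, (self.psi + np.pi) % (2 * np.pi))


def rate_modulation(
    trains: Sequence[SpikeTrain],
    field: FieldParams,
    discard: float = 2000.0,
    n_bins: int = 20,
) -> ModulationFit:
    """Fit the spike-rate modulation at one field frequency from many trials.

    ``discard`` [ms] removes the initial transient of every trial; only
    complete field cycles after the discard window are analyzed. Each spike
    contributes its field phase phi_s with E(t_s) = E1 sin(phi_s); the phase
    histogram (``n_bins`` equal bins) is normalized by the analyzed time per
    bin, giving rates in Hz, and r1 >= 0, psi in [0, 2pi) are fitted by least
    squares with r0 fixed to the histogram mean.
    """
    if field.f_field <= 0:
        raise ValueError("field frequency must be positive")
    period = 1e3 / field.f_field  # ms
    phases: list[np.ndarray] = []
    total_time = 0.0  # analyzed time, ms, summed over trials
    for train in trains:
        n_cyc = int((train.duration - discard) / period)
        if n_cyc < 1:
            raise ValueError(
                "each trial must contain at least one complete field cycle after the discard window"
            )
        t_end = discard + n_cyc * period
        total_time += n_cyc * period
        t = train.times
        sel = (t >= discard) & (t < t_end)
        phases.append((2e-3 * np.pi * field.f_field * t[sel]) % (2.0 * np.pi))
    phi_s = np.concatenate(phases) if phases else np.empty(0)
    if phi_s.size == 0:
        raise ValueError("no spikes in the analysis window; cannot fit modulation")

    counts, edges = np.histogram(phi_s, bins=n_bins, range=(0.0, 2.0 * np.pi))
    bin_time_s = (total_time / n_bins) * 1e-3  # s of analyzed time per bin
    rates = counts / bin_time_s
    r0 = float(np.mean(rates))
    centers = 0.5 * (edges[:-1] + edges[1:])
    design = np.column_stack([np.sin(centers), np.cos(centers)])
    (a, b), *_ = np.linalg.lstsq(design, rates - r0, rcond=None)
    r1 = float(np.hypot(a, b))
    psi = float(np.arctan2(b, a) % (2.0 * np.pi))
    return ModulationFit(
        r0=r0, r1=r1, psi=psi, f_field=field.f_field,
        n_trials=len(trains), n_bins=n_bins, n_spikes=int(phi_s.size),
        impeded=r1 > r0,
    )


@dataclass(frozen=True)
class ResonanceCurve:
    """Modulation fits over a frequency sweep plus the resonance summary.

    ``f_res`` is argmax r1 over the sweep grid (ties broken toward the lower
    frequency) and ``r1_max`` the amplitude there.
    """

    fits: tuple[ModulationFit, ...]
    f_res: float
    r1_max: float

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([f.f_field for f in self.fits])

    @property
    def r1(self) -> np.ndarray:
        return np.array([f.r1 for f in self.fits])


def resonance_curve(fits: Sequence[ModulationFit]) -> ResonanceCurve:
    """Summarize a modulation sweep; frequencies must be strictly increasing."""
    freqs = np.array([f.f_field for f in fits])
    if freqs.size == 0:
        raise ValueError("empty sweep")
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("sweep frequencies must be strictly increasing")
    r1 = np.array([f.r1 for f in fits])
    i = int(np.argmax(r1))  # first max -> lower-frequency tie-break
    return ResonanceCurve(fits=tuple(fits), f_res=float(freqs[i]), r1_max=float(r1[i]))
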