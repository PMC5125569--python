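"""Shared time-series containers (neuroscience units: ms, pA, mV) and text I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["CurrentTrace", "VoltageTrace", "SpikeTrain", "write_columnar", "read_columnar"]


def _validate_series(dt: float, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt!r}")
    if values.ndim != 1 or values.size < 1:
        raise ValueError("values must be a non-empty 1-D array")
    if not np.all(np.isfinite(values)):
        raise ValueError("trace contains non-finite samples")
    return values


@dataclass(frozen=True)
class CurrentTrace:
    """Uniformly sampled current time series: ``values`` [pA] at spacing ``dt`` [ms]."""

    dt: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _validate_series(self.dt, self.values))

    @property
    def times(self) -> np.ndarray:
        """Sample times [ms]."""
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        """Covered duration [ms] (n * dt)."""
        return self.dt * self.values.size


@dataclass(frozen=True)
class VoltageTrace:
    """Uniformly sampled membrane-voltage deviation from rest: ``values`` [mV], ``dt`` [ms]."""

    dt: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _validate_series(self.dt, self.values))

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times [ms] over a recording of ``duration`` ms.

    Spike times are the moments the somatic voltage reaches the spike/cutoff
    voltage from below; consecutive spikes are separated by at least the
    refractory period of the emitting model.
    """

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if times.size and (np.any(np.diff(times) <= 0)):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.times.size)

    @property
    def rate(self) -> float:
        """Mean spike rate [Hz]."""
        return 1e3 * self.times.size / self.duration

    def shifted(self, offset: float) -> "SpikeTrain":
        return SpikeTrain(times=self.times + offset, duration=self.duration)


def write_columnar(path: str | Path, header: dict, columns: dict[str, np.ndarray]) -> None:
    """Write named columns as whitespace-separated text with a ``# key: value`` header."""
    path = Path(path)
    names = list(columns)
    data = np.column_stack([np.asarray(columns[k], dtype=float) for k in names])
    lines = [f"# {k}: {v}" for k, v in header.items()]
    lines.append("# columns: " + " ".join(names))
    np.savetxt(path, data, header="\n".join(lines), comments="")


def read_columnar(path: str | Path) -> tuple[dict, dict[str, np.ndarray]]:
    """Read a file written by :func:`write_columnar`."""
    path = Path(path)
    header: dict = {}
    names: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            if key.strip() == "columns":
                names = value.split()
            else:
                header[key.strip()] = value.strip()
    data = np.loadtxt(path, ndmin=2)
    return header, {name: data[:, i] for i, name in enumerate(names)}
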