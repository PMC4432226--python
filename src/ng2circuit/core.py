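"""Shared primitive types: sampled traces and current-step protocols."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trace", "PulseProtocol"]


@dataclass
class Trace:
    """Uniformly sampled signal.

    dt is in ms; samples are mV for kind='voltage' and pA for
    kind='current'. t0 is the time of the first sample in ms.
    """

    dt: float
    samples: np.ndarray
    kind: str = "voltage"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be 1-D")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.kind not in ("voltage", "current"):
            raise ValueError("kind must be 'voltage' or 'current'")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    def index_at(self, t_ms: float) -> int:
        i = int(round((t_ms - self.t0) / self.dt))
        if not 0 <= i < self.n:
            raise IndexError(f"time {t_ms} ms outside trace")
        return i

    def slice(self, t_start: float, t_stop: float) -> np.ndarray:
        i0 = max(0, int(np.ceil((t_start - self.t0) / self.dt)))
        i1 = min(self.n, int(np.floor((t_stop - self.t0) / self.dt)) + 1)
        if i1 <= i0:
            raise ValueError("empty time window")
        return self.samples[i0:i1]


@dataclass(frozen=True)
class PulseProtocol:
    """Square current step: holding level, amplitude, onset, duration (ms)."""

    holding_mv: float
    step_pa: float
    onset_ms: float
    duration_ms: float

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")

    @property
    def offset_ms(self) -> float:
        return self.onset_ms + self.duration_ms
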