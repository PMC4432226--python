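"""Paired-pulse postsynaptic-current sweeps under a binomial quantal
release model with one or two release sites.

Each sweep holds a current trace with two presynaptic stimulus times 50
ms apart (configurable). The response to pulse k is a biexponential
event whose amplitude is ``B_k * q`` with ``B_k ~ Binomial(n_sites,
p_k)`` and ``q`` the (negative) quantal size; white noise of the given
SD is added to the whole trace. Per-sweep vesicle counts are retained
as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import Trace

__all__ = ["ReleaseModelParams", "PairedSweep", "gen_paired_sweeps", "biexp_template"]


@dataclass(frozen=True)
class ReleaseModelParams:
    n_sites: int = 1
    p1: float = 0.6
    p2: float = 0.35
    quantal_size_pa: float = -7.71
    noise_sd_pa: float = 1.5
    rise_tau_ms: float = 0.5676     # biexponential 10-90% rise ~ 0.91 ms
    decay_tau_ms: float = 12.7
    n_sweeps: int = 100
    interpulse_ms: float = 50.0
    intersweep_s: float = 8.0
    latency_ms: float = 1.5

    def __post_init__(self) -> None:
        if self.n_sites not in (1, 2):
            raise ValueError("n_sites must be 1 or 2")
        if not 0.0 <= self.p2 < self.p1 <= 1.0:
            raise ValueError("require 0 <= p2 < p1 <= 1 (paired-pulse depression)")
        if self.quantal_size_pa >= 0:
            raise ValueError("quantal size must be negative (inward current)")
        if self.noise_sd_pa < 0:
            raise ValueError("noise SD must be >= 0")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.rise_tau_ms <= 0 or self.decay_tau_ms <= self.rise_tau_ms:
            raise ValueError("need 0 < rise_tau < decay_tau")


@dataclass
class PairedSweep:
    """One paired-pulse sweep: current trace plus the two stimulus times."""

    trace: Trace
    stim_times_ms: tuple[float, float]
    index: int = 0

    def __post_init__(self) -> None:
        if len(self.stim_times_ms) != 2 or not self.stim_times_ms[0] < self.stim_times_ms[1]:
            raise ValueError("exactly two ordered stimulus times are required")


def biexp_template(t_ms: np.ndarray, rise_tau: float, decay_tau: float) -> np.ndarray:
    """Unit-peak biexponential (difference of exponentials), 0 for t < 0."""
    t = np.asarray(t_ms, dtype=float)
    y = np.where(t >= 0, np.exp(-t / decay_tau) - np.exp(-t / rise_tau), 0.0)
    t_pk = np.log(decay_tau / rise_tau) * rise_tau * decay_tau / (decay_tau - rise_tau)
    peak = np.exp(-t_pk / decay_tau) - np.exp(-t_pk / rise_tau)
    return y / peak


def gen_paired_sweeps(
    params: ReleaseModelParams,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    dt: float = 0.05,
    first_stim_ms: float = 50.0,
    total_ms: float = 250.0,
) -> tuple[list[PairedSweep], dict]:
    """Simulate sweeps and return them with ground truth.

    Ground truth carries the per-sweep vesicle counts ``b1``/``b2`` and
    the exact per-pulse amplitudes ``b_k * q``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = int(round(total_ms / dt)) + 1
    tgrid = dt * np.arange(n)
    stims = (first_stim_ms, first_stim_ms + params.interpulse_ms)
    b1 = rng.binomial(params.n_sites, params.p1, size=params.n_sweeps)
    b2 = rng.binomial(params.n_sites, params.p2, size=params.n_sweeps)
    sweeps: list[PairedSweep] = []
    for i in range(params.n_sweeps):
        y = np.zeros(n)
        for b, stim in zip((b1[i], b2[i]), stims):
            if b:
                y += b * params.quantal_size_pa * biexp_template(
                    tgrid - stim - params.latency_ms,
                    params.rise_tau_ms, params.decay_tau_ms)
        if params.noise_sd_pa > 0:
            y += rng.normal(0.0, params.noise_sd_pa, size=n)
        sweeps.append(PairedSweep(
            trace=Trace(dt=dt, samples=y, kind="current"),
            stim_times_ms=stims, index=i))
    truth = dict(
        b1=b1, b2=b2,
        amp1_pa=b1 * params.quantal_size_pa,
        amp2_pa=b2 * params.quantal_size_pa,
        params=params,
    )
    return sweeps, truth
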