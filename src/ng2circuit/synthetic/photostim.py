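"""Photostimulation trials: Poisson spontaneous background plus, for
connected pairs, one evoked event per trial at a right-skewed latency
bounded at 100 ms (truncated log-normal stand-in; the reference data
give only a histogram).
"""

from __future__ import annotations

import numpy as np

from ..core import Trace
from ..mapping import PhotostimTrial
from .release import biexp_template

__all__ = ["gen_photostim_trials", "render_average_trace", "truncated_lognormal_latency"]

EVOKED_WINDOW_MS = 100.0


def truncated_lognormal_latency(
    rng: np.random.Generator,
    median_ms: float = 30.0,
    sigma: float = 0.6,
    upper_ms: float = EVOKED_WINDOW_MS,
) -> float:
    """One latency draw from a log-normal truncated to (0, upper_ms]."""
    for _ in range(1000):
        x = float(rng.lognormal(np.log(median_ms), sigma))
        if x <= upper_ms:
            return x
    return upper_ms  # pragma: no cover - pathological parameters only


def gen_photostim_trials(
    connected: bool,
    spontaneous_rate_hz: float,
    n_trials: int,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    latency_law=None,
    failure_rate: float = 0.0,
    window_ms: tuple[float, float] = (-2000.0, 2000.0),
    evoked_amplitude_pa: float = -10.0,
    spont_amplitude_pa: float = -10.0,
    spot_position=(0.0, 0.0, 0.0),
    pulse_ms: float = 3.0,
) -> list[PhotostimTrial]:
    """Simulate rasters of event times (ms, relative to the stimulus)."""
    if n_trials < 0:
        raise ValueError("n_trials must be >= 0")
    if spontaneous_rate_hz < 0:
        raise ValueError("spontaneous rate must be >= 0")
    if not 0.0 <= failure_rate <= 1.0:
        raise ValueError("failure rate must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    if latency_law is None:
        latency_law = truncated_lognormal_latency
    lo, hi = window_ms
    span_s = (hi - lo) / 1000.0
    trials: list[PhotostimTrial] = []
    for i in range(n_trials):
        n_bg = rng.poisson(spontaneous_rate_hz * span_s)
        times = list(rng.uniform(lo, hi, size=n_bg))
        amps = list(rng.normal(spont_amplitude_pa, 1.0, size=n_bg))
        if connected and rng.random() >= failure_rate:
            times.append(latency_law(rng))
            amps.append(float(rng.normal(evoked_amplitude_pa, 1.0)))
        order = np.argsort(times)
        trials.append(PhotostimTrial(
            spot_position_um=np.asarray(spot_position, dtype=float),
            pulse_ms=pulse_ms,
            event_times_ms=np.asarray(times)[order],
            event_amplitudes_pa=np.asarray(amps)[order],
            trial_index=i,
        ))
    return trials


def render_average_trace(
    trials: list[PhotostimTrial],
    *,
    dt: float = 0.5,
    window_ms: tuple[float, float] = (-200.0, 200.0),
    rise_tau_ms: float = 1.0,
    decay_tau_ms: float = 12.7,
    noise_sd_pa: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Trace:
    """Average current trace across trials, events rendered as biexponentials."""
    if not trials:
        raise ValueError("no trials to average")
    lo, hi = window_ms
    n = int(round((hi - lo) / dt)) + 1
    tgrid = lo + dt * np.arange(n)
    acc = np.zeros(n)
    for trial in trials:
        y = np.zeros(n)
        for t_ev, a_ev in zip(trial.event_times_ms, trial.event_amplitudes_pa):
            if t_ev < lo - 5 * decay_tau_ms or t_ev > hi:
                continue
            y += a_ev * biexp_template(tgrid - t_ev, rise_tau_ms, decay_tau_ms)
        if noise_sd_pa > 0:
            if rng is None:
                rng = np.random.default_rng()
            y += rng.normal(0.0, noise_sd_pa, size=n)
        acc += y
    return Trace(dt=dt, samples=acc / len(trials), kind="current", t0=lo)
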