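"""Synthetic current-clamp traces for two interneuron firing phenotypes.

Action potentials are template-based: each spike is a Gaussian
depolarizing lobe plus an asymmetric (fast-rise / slow-fall) Gaussian
after-hyperpolarization lobe riding on a plateau. Every waveform feature
the extraction stage measures is an explicit function of the template
parameters, so the generator can solve per spike for lobe amplitudes
that make the extracted threshold-to-peak amplitude and trough depth
match the requested values to numerical precision (the retained ground
truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from ..core import PulseProtocol, Trace

__all__ = [
    "EphysClassParams",
    "CellDraw",
    "RecordingSet",
    "FSI_PARAMS",
    "NFSI_PARAMS",
    "draw_cell",
    "gen_interneuron_trace",
    "gen_rc_trace",
    "gen_interneuron_recording",
    "gen_cohort",
]

FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM = factor * sigma

# Threshold rule shared with the extraction stage: the spike threshold is
# the first point on the rising face where dV/dt exceeds twice the
# pre-spike baseline derivative level (median |dV/dt|, floored).
THRESHOLD_SEARCH_MS = 5.0
THRESHOLD_BASELINE_MS = 5.0
THRESHOLD_DERIV_FLOOR = 1.0  # mV/ms


@dataclass(frozen=True)
class EphysClassParams:
    """Population means and dispersions for one firing phenotype.

    Dispersions are standard deviations of the per-cell draws. AHP width
    and peak-to-trough latency are fixed template constants per class.
    """

    label: str
    ap_amplitude_mv: float = 70.0
    ap_amplitude_sd: float = 2.0
    ap_duration_ms: float = 1.4
    ap_duration_sd: float = 0.1
    ahp_mv: float = -15.0
    ahp_sd: float = 0.6
    duration_increase_pct: float = 7.0
    duration_increase_sd: float = 0.8
    amplitude_reduction_pct: float = 0.0
    amplitude_reduction_sd: float = 1.0
    early_accommodation_pct: float = 14.0
    early_accommodation_sd: float = 3.6
    input_resistance_mohm: float = 208.0
    input_resistance_sd: float = 18.0
    firing_rate_hz: float = 28.0
    firing_rate_sd: float = 2.7
    ahp_width_ms: float = 25.0
    peak_to_ahp_ms: float = 7.0

    def __post_init__(self) -> None:
        if self.label not in ("FSI", "NFSI"):
            raise ValueError("label must be 'FSI' or 'NFSI'")
        for name in (
            "ap_amplitude_sd", "ap_duration_sd", "ahp_sd", "duration_increase_sd",
            "amplitude_reduction_sd", "early_accommodation_sd",
            "input_resistance_sd", "firing_rate_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


FSI_PARAMS = EphysClassParams(
    label="FSI",
    ap_amplitude_mv=70.73, ap_amplitude_sd=2.33,
    ap_duration_ms=1.37, ap_duration_sd=0.10,
    ahp_mv=-15.89, ahp_sd=0.61,
    duration_increase_pct=6.79, duration_increase_sd=0.75,
    amplitude_reduction_pct=-0.24, amplitude_reduction_sd=0.94,
    early_accommodation_pct=14.14, early_accommodation_sd=3.61,
    input_resistance_mohm=208.22, input_resistance_sd=17.97,
    firing_rate_hz=28.32, firing_rate_sd=2.73,
    ahp_width_ms=25.57, peak_to_ahp_ms=7.18,
)

NFSI_PARAMS = EphysClassParams(
    label="NFSI",
    ap_amplitude_mv=70.61, ap_amplitude_sd=1.09,
    ap_duration_ms=2.41, ap_duration_sd=0.10,
    ahp_mv=-8.43, ahp_sd=0.40,
    duration_increase_pct=55.06, duration_increase_sd=5.92,
    amplitude_reduction_pct=7.59, amplitude_reduction_sd=1.14,
    early_accommodation_pct=39.33, early_accommodation_sd=1.85,
    input_resistance_mohm=399.96, input_resistance_sd=19.75,
    firing_rate_hz=24.18, firing_rate_sd=0.93,
    ahp_width_ms=21.53, peak_to_ahp_ms=13.85,
)


@dataclass
class CellDraw:
    """Concrete per-cell parameter values actually used by the generator."""

    label: str
    a1_mv: float
    a2_mv: float
    d1_ms: float
    d2_ms: float
    ahp_mv: float
    early_accommodation_pct: float
    input_resistance_mohm: float
    firing_rate_hz: float
    ahp_width_ms: float
    peak_to_ahp_ms: float

    @property
    def amplitude_reduction_pct(self) -> float:
        return 100.0 * (self.a1_mv - self.a2_mv) / self.a1_mv

    @property
    def duration_increase_pct(self) -> float:
        return 100.0 * (self.d2_ms - self.d1_ms) / self.d1_ms


def draw_cell(params: EphysClassParams, rng: np.random.Generator) -> CellDraw:
    """Draw one cell from the class distribution, clipped to sane ranges."""
    a1 = float(np.clip(rng.normal(params.ap_amplitude_mv, params.ap_amplitude_sd), 30.0, 120.0))
    d1 = float(np.clip(rng.normal(params.ap_duration_ms, params.ap_duration_sd), 0.5, 3.2))
    red = rng.normal(params.amplitude_reduction_pct, params.amplitude_reduction_sd)
    inc = rng.normal(params.duration_increase_pct, params.duration_increase_sd)
    a2 = float(np.clip(a1 * (1.0 - red / 100.0), 25.0, 125.0))
    d2 = float(np.clip(d1 * (1.0 + inc / 100.0), 0.5, 4.0))
    return CellDraw(
        label=params.label,
        a1_mv=a1, a2_mv=a2, d1_ms=d1, d2_ms=d2,
        ahp_mv=float(np.clip(rng.normal(params.ahp_mv, params.ahp_sd), -40.0, -1.0)),
        early_accommodation_pct=float(
            np.clip(rng.normal(params.early_accommodation_pct, params.early_accommodation_sd), -50.0, 90.0)
        ),
        input_resistance_mohm=float(
            np.clip(rng.normal(params.input_resistance_mohm, params.input_resistance_sd), 20.0, 2000.0)
        ),
        firing_rate_hz=float(np.clip(rng.normal(params.firing_rate_hz, params.firing_rate_sd), 5.0, 80.0)),
        ahp_width_ms=params.ahp_width_ms,
        peak_to_ahp_ms=params.peak_to_ahp_ms,
    )


def zero_dispersion(params: EphysClassParams) -> EphysClassParams:
    """Copy of ``params`` with all dispersions set to zero."""
    return replace(
        params,
        ap_amplitude_sd=0.0, ap_duration_sd=0.0, ahp_sd=0.0,
        duration_increase_sd=0.0, amplitude_reduction_sd=0.0,
        early_accommodation_sd=0.0, input_resistance_sd=0.0, firing_rate_sd=0.0,
    )


# ---------------------------------------------------------------------------
# analytic template pieces

class _Gauss:
    def __init__(self, tc: float, amp: float, sigma: float):
        self.tc, self.amp, self.sigma = tc, amp, sigma

    def __call__(self, t):
        x = (np.asarray(t, dtype=float) - self.tc) / self.sigma
        return self.amp * np.exp(-0.5 * x * x)

    def deriv(self, t):
        t = np.asarray(t, dtype=float)
        x = (t - self.tc) / self.sigma
        return -self.amp * x / self.sigma * np.exp(-0.5 * x * x)

    @property
    def extent(self) -> tuple[float, float]:
        return self.tc - 7 * self.sigma, self.tc + 7 * self.sigma


class _AhpLobe:
    """Negative lobe with fast rise and slower fall (piecewise sigma)."""

    def __init__(self, tc: float, depth: float, sigma_rise: float, sigma_fall: float):
        self.tc, self.depth = tc, depth
        self.sigma_rise, self.sigma_fall = sigma_rise, sigma_fall

    def _sig(self, t):
        return np.where(np.asarray(t) < self.tc, self.sigma_rise, self.sigma_fall)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        x = (t - self.tc) / self._sig(t)
        return -self.depth * np.exp(-0.5 * x * x)

    def deriv(self, t):
        t = np.asarray(t, dtype=float)
        s = self._sig(t)
        x = (t - self.tc) / s
        return self.depth * x / s * np.exp(-0.5 * x * x)

    @property
    def extent(self) -> tuple[float, float]:
        return self.tc - 7 * self.sigma_rise, self.tc + 7 * self.sigma_fall


def _step_response(t, rest: float, plateau: float, protocol: PulseProtocol, tau: float):
    """Membrane charging toward the plateau during the step, back after."""
    t = np.asarray(t, dtype=float)
    v = np.full(t.shape, rest)
    on, off = protocol.onset_ms, protocol.offset_ms
    during = (t >= on) & (t < off)
    v[during] = rest + (plateau - rest) * (1.0 - np.exp(-(t[during] - on) / tau))
    v_off = rest + (plateau - rest) * (1.0 - np.exp(-protocol.duration_ms / tau))
    after = t >= off
    v[after] = rest + (v_off - rest) * np.exp(-(t[after] - off) / tau)
    return v


def _step_response_deriv(t, rest: float, plateau: float, protocol: PulseProtocol, tau: float):
    t = np.asarray(t, dtype=float)
    d = np.zeros(t.shape)
    on, off = protocol.onset_ms, protocol.offset_ms
    during = (t >= on) & (t < off)
    d[during] = (plateau - rest) / tau * np.exp(-(t[during] - on) / tau)
    v_off = rest + (plateau - rest) * (1.0 - np.exp(-protocol.duration_ms / tau))
    after = t >= off
    d[after] = -(v_off - rest) / tau * np.exp(-(t[after] - off) / tau)
    return d


def _spike_times(draw: CellDraw, protocol: PulseProtocol, first_delay: float = 15.0,
                 n_spikes: int | None = None) -> tuple[np.ndarray, dict]:
    """Spike peak times implementing the accommodation scheme.

    The first inter-spike interval is shortened by the early-accommodation
    factor relative to the steady interval used for all later spikes, so
    F_init > F_200 = F_final and the early accommodation percentage of the
    extracted train equals the drawn value; F_total = n / duration.
    """
    T = protocol.duration_ms
    ea = draw.early_accommodation_pct / 100.0
    if n_spikes is None:
        n = int(round(draw.firing_rate_hz * T / 1000.0))
        n = max(3, n)
    else:
        n = n_spikes
    if n == 2:
        isi_ss = min(55.0, (T - first_delay - 5.0))
        isi1 = (1.0 - ea) * isi_ss
        times = protocol.onset_ms + first_delay + np.array([0.0, isi1])
        f_init = 1000.0 / isi1
        truth = dict(n_spikes=2, f_init=f_init, f_200=None, f_final=f_init,
                     f_total=2000.0 / T, early_accommodation=None)
        return times, truth
    # steady interval chosen so the last spike lands just inside the pulse
    isi_ss = (T - first_delay - 5.0) / ((1.0 - ea) + (n - 2))
    isi1 = (1.0 - ea) * isi_ss
    offsets = np.concatenate([[0.0], [isi1], isi1 + isi_ss * np.arange(1, n - 1)])
    times = protocol.onset_ms + first_delay + offsets
    f_ss = 1000.0 / isi_ss
    f_init = 1000.0 / isi1
    truth = dict(
        n_spikes=n,
        f_init=f_init, f_200=f_ss, f_final=f_ss,
        f_total=n * 1000.0 / T,
        early_accommodation=100.0 * (f_init - f_ss) / f_init,
        late_accommodation=0.0,
    )
    return times, truth


def _solve_spike_lobes(
    t_peak: float,
    a_target: float,
    sigma: float,
    ahp_target: float,
    lat: float,
    ahp_width: float,
    bg: Callable,
    bg_deriv: Callable,
) -> tuple[_Gauss, _AhpLobe, float]:
    """Solve lobe amplitudes so the extracted spike features are exact.

    Returns the two lobes plus the analytic threshold voltage. The
    threshold is where the total dV/dt first exceeds twice the baseline
    derivative level on the rising face; amplitude is threshold-to-peak
    and the AHP trough sits ``ahp_target`` (negative) below threshold.
    """
    sr = max(lat / 2.5, 0.8)
    sf = max(ahp_width / FWHM_FACTOR * 2.0 - sr, 0.5 * sr)  # FWHM ~ factor*(sr+sf)/2
    amp = a_target
    depth = max(1e-3, -ahp_target)
    v_thr = None
    for _ in range(4):
        lobe = _AhpLobe(t_peak + lat, depth, sr, sf)

        def total_bg(t):
            return bg(t) + lobe(t)

        def total_bg_deriv(t):
            return bg_deriv(t) + lobe.deriv(t)

        tb = np.linspace(t_peak - THRESHOLD_SEARCH_MS - THRESHOLD_BASELINE_MS,
                         t_peak - THRESHOLD_SEARCH_MS, 101)
        level = max(THRESHOLD_DERIV_FLOOR, float(np.median(np.abs(total_bg_deriv(tb)))))
        gauss = _Gauss(t_peak, amp, sigma)

        def f(t):
            return total_bg_deriv(t) + gauss.deriv(t) - 2.0 * level

        lo, hi = t_peak - THRESHOLD_SEARCH_MS, t_peak - sigma
        if f(lo) >= 0:  # derivative already high at window edge: widen once
            lo = t_peak - 1.6 * THRESHOLD_SEARCH_MS
        t_star = brentq(f, lo, hi, xtol=1e-10)
        v_thr = float(total_bg(t_star) + gauss(t_star))
        v_peak = float(total_bg(t_peak) + amp)
        amp += a_target - (v_peak - v_thr)
        t_tr = t_peak + lat
        v_trough = float(bg(t_tr) + gauss(t_tr) - depth)
        depth += (v_trough - v_thr) - ahp_target
        depth = max(1e-3, depth)
    return _Gauss(t_peak, amp, sigma), _AhpLobe(t_peak + lat, depth, sr, sf), v_thr


def gen_interneuron_trace(
    params: EphysClassParams | CellDraw,
    protocol: PulseProtocol,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    dt: float = 0.05,
    rest_mv: float = -70.0,
    plateau_mv: float = -36.0,
    tau_membrane_ms: float = 2.0,
    pre_ms: float = 100.0,
    post_ms: float = 100.0,
    noise_sd_mv: float = 0.0,
    n_spikes: int | None = None,
) -> tuple[Trace, dict]:
    """Generate a spiking voltage trace and its exact ground truth.

    ``params`` may be class-level parameters (a cell is drawn) or an
    already drawn :class:`CellDraw`. The ground truth dict carries the
    per-spike threshold, amplitude, duration, AHP and the firing-rate
    quantities the template embodies.
    """
    if dt > 0.05:
        raise ValueError("sampling interval must be <= 0.05 ms")
    if protocol.step_pa <= 0:
        raise ValueError("protocol must have a depolarizing step")
    if rng is None:
        rng = np.random.default_rng(seed)
    draw = params if isinstance(params, CellDraw) else draw_cell(params, rng)

    times, rate_truth = _spike_times(draw, protocol, n_spikes=n_spikes)
    n_total = int(round((protocol.offset_ms + post_ms + pre_ms) / dt)) + 1
    t0 = protocol.onset_ms - pre_ms
    tgrid = t0 + dt * np.arange(n_total)

    def bg_base(t):
        return _step_response(t, rest_mv, plateau_mv, protocol, tau_membrane_ms)

    def bg_base_deriv(t):
        return _step_response_deriv(t, rest_mv, plateau_mv, protocol, tau_membrane_ms)

    lobes: list = []
    spikes_truth = []
    for i, tp in enumerate(times):
        a = draw.a1_mv if i == 0 else draw.a2_mv
        d = draw.d1_ms if i == 0 else draw.d2_ms
        sigma = d / FWHM_FACTOR
        prev = list(lobes)

        def bg(t, prev=prev):
            v = bg_base(t)
            for lb in prev:
                v = v + lb(t)
            return v

        def bg_deriv(t, prev=prev):
            v = bg_base_deriv(t)
            for lb in prev:
                v = v + lb.deriv(t)
            return v

        gauss, ahp_lobe, v_thr = _solve_spike_lobes(
            tp, a, sigma, draw.ahp_mv, draw.peak_to_ahp_ms, draw.ahp_width_ms,
            bg, bg_deriv,
        )
        lobes.extend([gauss, ahp_lobe])
        spikes_truth.append(dict(
            peak_time_ms=float(tp), threshold_mv=v_thr,
            amplitude_mv=a, duration_ms=d,
            ahp_mv=draw.ahp_mv, peak_to_ahp_ms=draw.peak_to_ahp_ms,
        ))

    v = bg_base(tgrid)
    for lb in lobes:
        lo, hi = lb.extent
        i0 = max(0, int((lo - t0) / dt))
        i1 = min(n_total, int((hi - t0) / dt) + 1)
        v[i0:i1] += lb(tgrid[i0:i1])
    if noise_sd_mv > 0:
        v = v + rng.normal(0.0, noise_sd_mv, size=v.shape)

    truth = dict(
        label=draw.label,
        spike_times_ms=np.array(times),
        spikes=spikes_truth,
        a1_mv=draw.a1_mv, a2_mv=draw.a2_mv,
        d1_ms=draw.d1_ms, d2_ms=draw.d2_ms,
        amplitude_reduction_pct=draw.amplitude_reduction_pct,
        duration_increase_pct=draw.duration_increase_pct,
        ahp_mv=draw.ahp_mv,
        input_resistance_mohm=draw.input_resistance_mohm,
        **rate_truth,
    )
    return Trace(dt=dt, samples=v, kind="voltage", t0=t0), truth


def gen_rc_trace(
    r_mohm: float,
    protocol: PulseProtocol,
    *,
    c_pf: float = 100.0,
    dt: float = 0.05,
    pre_ms: float = 100.0,
    post_ms: float = 100.0,
    noise_sd_mv: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Trace:
    """Passive RC response to a current step (used for input resistance)."""
    if r_mohm <= 0:
        raise ValueError("resistance must be positive")
    tau = r_mohm * c_pf / 1000.0  # ms
    dv = r_mohm * protocol.step_pa / 1000.0  # mV
    t0 = protocol.onset_ms - pre_ms
    n = int(round((protocol.offset_ms + post_ms + pre_ms) / dt)) + 1
    t = t0 + dt * np.arange(n)
    v = np.full(n, protocol.holding_mv)
    during = (t >= protocol.onset_ms) & (t < protocol.offset_ms)
    v[during] += dv * (1.0 - np.exp(-(t[during] - protocol.onset_ms) / tau))
    v_off = dv * (1.0 - np.exp(-protocol.duration_ms / tau))
    after = t >= protocol.offset_ms
    v[after] += v_off * np.exp(-(t[after] - protocol.offset_ms) / tau)
    if noise_sd_mv > 0:
        if rng is None:
            rng = np.random.default_rng()
        v = v + rng.normal(0.0, noise_sd_mv, size=n)
    return Trace(dt=dt, samples=v, kind="voltage", t0=t0)


LONG_PROTOCOL = PulseProtocol(holding_mv=-70.0, step_pa=200.0, onset_ms=100.0, duration_ms=1000.0)
SHORT_PROTOCOL = PulseProtocol(holding_mv=-70.0, step_pa=200.0, onset_ms=50.0, duration_ms=80.0)
HYPER_PROTOCOL = PulseProtocol(holding_mv=-60.0, step_pa=-200.0, onset_ms=100.0, duration_ms=800.0)


@dataclass
class RecordingSet:
    """The three traces the feature-extraction stage consumes."""

    long: tuple[Trace, PulseProtocol]
    short: tuple[Trace, PulseProtocol]
    hyper: tuple[Trace, PulseProtocol]


def gen_interneuron_recording(
    params: EphysClassParams | CellDraw,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    dt: float = 0.05,
    noise_sd_mv: float = 0.0,
) -> tuple[RecordingSet, dict]:
    """Long suprathreshold, short 2-spike and hyperpolarizing traces for one cell."""
    if rng is None:
        rng = np.random.default_rng(seed)
    draw = params if isinstance(params, CellDraw) else draw_cell(params, rng)
    long_tr, truth = gen_interneuron_trace(
        draw, LONG_PROTOCOL, rng=rng, dt=dt, noise_sd_mv=noise_sd_mv)
    short_tr, short_truth = gen_interneuron_trace(
        draw, SHORT_PROTOCOL, rng=rng, dt=dt, noise_sd_mv=noise_sd_mv, n_spikes=2)
    hyper_tr = gen_rc_trace(
        draw.input_resistance_mohm, HYPER_PROTOCOL, dt=dt,
        noise_sd_mv=noise_sd_mv, rng=rng)
    truth["short_spikes"] = short_truth["spikes"]
    truth["short_spike_times_ms"] = short_truth["spike_times_ms"]
    rec = RecordingSet(
        long=(long_tr, LONG_PROTOCOL),
        short=(short_tr, SHORT_PROTOCOL),
        hyper=(hyper_tr, HYPER_PROTOCOL),
    )
    return rec, truth


def gen_cohort(
    n_per_class: int,
    seed: int,
    *,
    fsi: EphysClassParams = FSI_PARAMS,
    nfsi: EphysClassParams = NFSI_PARAMS,
    dt: float = 0.05,
    noise_sd_mv: float = 0.0,
) -> list[tuple[RecordingSet, dict]]:
    """Seeded cohort of labelled recordings, FSI cells first."""
    if n_per_class < 0:
        raise ValueError("n_per_class must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for params in (fsi, nfsi):
        for _ in range(n_per_class):
            out.append(gen_interneuron_recording(params, rng=rng, dt=dt, noise_sd_mv=noise_sd_mv))
    return out
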