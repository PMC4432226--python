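"""Extraction of spike-train and waveform parameters from current-clamp
traces, and rule-based classification of interneurons as fast-spiking
(FSI) or non-fast-spiking (NFSI).

The feature set has exactly 19 entries: four firing frequencies, two
accommodation percentages, threshold, two spike amplitudes and their
percentage reduction, two spike durations and their percentage increase,
AHP depth/width/latency, the two extreme AP slopes, and the input
resistance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .core import PulseProtocol, Trace
from .synthetic.ephys import FWHM_FACTOR, RecordingSet

__all__ = [
    "FeatureError",
    "SpikeFeatureSet",
    "FiringRates",
    "ClassificationRule",
    "DEFAULT_RULE",
    "detect_spikes",
    "firing_frequencies",
    "accommodation",
    "spike_threshold",
    "spike_amplitude",
    "spike_duration",
    "ahp_metrics",
    "ap_slopes",
    "input_resistance",
    "extract_feature_set",
    "classify_interneuron",
]


class FeatureError(ValueError):
    """A feature could not be computed from the given trace."""


FEATURE_NAMES = (
    "f_total", "f_init", "f_200", "f_final",
    "early_accommodation", "late_accommodation",
    "threshold", "a1", "a2", "amplitude_reduction",
    "d1", "d2", "duration_increase",
    "ahp", "ahp_width", "peak_to_ahp",
    "depol_slope", "hyperpol_slope", "r_in",
)


@dataclass
class SpikeFeatureSet:
    """The 19 extracted parameters for one interneuron.

    Fields that could not be measured are ``nan`` and listed in
    ``missing``.
    """

    f_total: float = math.nan          # Hz
    f_init: float = math.nan           # Hz
    f_200: float = math.nan            # Hz
    f_final: float = math.nan          # Hz
    early_accommodation: float = math.nan  # %
    late_accommodation: float = math.nan   # %
    threshold: float = math.nan        # mV
    a1: float = math.nan               # mV
    a2: float = math.nan               # mV
    amplitude_reduction: float = math.nan  # %
    d1: float = math.nan               # ms
    d2: float = math.nan               # ms
    duration_increase: float = math.nan    # %
    ahp: float = math.nan              # mV (negative)
    ahp_width: float = math.nan        # ms
    peak_to_ahp: float = math.nan      # ms
    depol_slope: float = math.nan      # mV/ms
    hyperpol_slope: float = math.nan   # mV/ms
    r_in: float = math.nan             # MOhm
    missing: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


# ---------------------------------------------------------------------------
# spike detection and firing statistics

def detect_spikes(
    trace: Trace,
    protocol: PulseProtocol,
    *,
    min_height_mv: float = -20.0,
    min_prominence_mv: float = 20.0,
) -> np.ndarray:
    """Peak times (ms) of suprathreshold action potentials in the step window."""
    if trace.kind != "voltage":
        raise FeatureError("spike detection requires a voltage trace")
    if trace.n == 0:
        raise FeatureError("empty trace")
    t = trace.times
    mask = (t >= protocol.onset_ms) & (t <= protocol.offset_ms)
    if not mask.any():
        raise FeatureError("protocol step does not overlap the trace")
    v = trace.samples[mask]
    # distance of a few samples only: spikes closer than 1 ms stay separate
    idx, _ = find_peaks(v, height=min_height_mv, prominence=min_prominence_mv,
                        distance=max(1, int(round(0.2 / trace.dt))))
    return t[mask][idx]


@dataclass
class FiringRates:
    f_total: float
    f_init: float | None
    f_200: float | None
    f_final: float | None
    flags: list


def firing_frequencies(spike_times: np.ndarray, protocol: PulseProtocol) -> FiringRates:
    """F_total plus the three instantaneous rates (Hz).

    F_total is spike count over pulse duration. F_init and F_final come
    from the first and last inter-spike intervals; F_200 from the
    interval containing t = 200 ms after pulse onset. With fewer than
    two spikes the instantaneous rates are flagged, not silently zeroed.
    """
    st = np.sort(np.asarray(spike_times, dtype=float))
    f_total = st.size / (protocol.duration_ms / 1000.0)
    flags: list = []
    if st.size < 2:
        flags.append("insufficient_spikes")
        return FiringRates(f_total, None, None, None, flags)
    isis = np.diff(st)
    f_init = 1000.0 / isis[0]
    f_final = 1000.0 / isis[-1]
    t200 = protocol.onset_ms + 200.0
    bracket = np.nonzero((st[:-1] <= t200) & (st[1:] > t200))[0]
    if bracket.size:
        f_200 = 1000.0 / isis[bracket[0]]
    else:
        f_200 = None
        flags.append("no_isi_at_200ms")
    return FiringRates(f_total, f_init, f_200, f_final, flags)


def accommodation(f_init: float, f_200: float, f_final: float) -> tuple[float, float]:
    """Early and late accommodation in percent of the initial rate."""
    if f_init is None or f_init <= 0:
        raise FeatureError("F_init must be positive")
    early = 100.0 * (f_init - f_200) / f_init
    late = 100.0 * (f_200 - f_final) / f_init
    return early, late


# ---------------------------------------------------------------------------
# waveform features

def _derivative(trace: Trace) -> np.ndarray:
    return np.gradient(trace.samples, trace.dt)


def _threshold_point(
    trace: Trace,
    spike_time: float,
    *,
    search_ms: float = 5.0,
    baseline_ms: float = 5.0,
    deriv_floor: float = 1.0,
    factor: float = 2.0,
) -> tuple[float, int]:
    """(threshold voltage, sample index) by the derivative-doubling rule.

    The reference level is the median |dV/dt| over ``baseline_ms``
    preceding the search window, floored at ``deriv_floor`` mV/ms to
    avoid near-zero division on quiescent baselines.
    """
    i_peak = trace.index_at(spike_time)
    dv = _derivative(trace)
    i_search = max(0, i_peak - int(round(search_ms / trace.dt)))
    i_base0 = max(0, i_search - int(round(baseline_ms / trace.dt)))
    if i_base0 == i_search:
        level = deriv_floor
    else:
        level = max(deriv_floor, float(np.median(np.abs(dv[i_base0:i_search]))))
    seg = dv[i_search:i_peak + 1]
    above = np.nonzero(seg >= factor * level)[0]
    if above.size == 0:
        raise FeatureError("no derivative-doubling point found before the peak")
    i_thr = i_search + int(above[0])
    return float(trace.samples[i_thr]), i_thr


def spike_threshold(trace: Trace, spike_time: float, **kwargs) -> float:
    """Spike threshold (mV): where dV/dt first doubles its baseline level."""
    return _threshold_point(trace, spike_time, **kwargs)[0]


def spike_amplitude(trace: Trace, spike_time: float, threshold: float) -> float:
    """Threshold-to-peak amplitude (mV)."""
    return float(trace.samples[trace.index_at(spike_time)] - threshold)


def _above_threshold_segment(trace: Trace, spike_time: float, threshold: float,
                             max_half_ms: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    i_peak = trace.index_at(spike_time)
    v = trace.samples
    half = int(round(max_half_ms / trace.dt))
    i0 = i_peak
    while i0 > max(0, i_peak - half) and v[i0 - 1] > threshold:
        i0 -= 1
    i1 = i_peak
    while i1 < min(v.size - 1, i_peak + half) and v[i1 + 1] > threshold:
        i1 += 1
    t = trace.t0 + trace.dt * np.arange(i0, i1 + 1)
    return t, v[i0:i1 + 1]


def spike_duration(trace: Trace, spike_time: float, threshold: float) -> float:
    """FWHM (ms) of a Gaussian fitted to the above-threshold spike face."""
    t, v = _above_threshold_segment(trace, spike_time, threshold)
    if v.size < 5:
        raise FeatureError("above-threshold segment too short for a Gaussian fit")
    a0 = float(v.max() - threshold)
    t00 = float(t[np.argmax(v)])
    s0 = max(trace.dt, (t[-1] - t[0]) / 4.0)

    def model(x, a, t0, s, c):
        return a * np.exp(-0.5 * ((x - t0) / s) ** 2) + c

    try:
        popt, _ = curve_fit(
            model, t, v, p0=(a0, t00, s0, threshold),
            bounds=([0.1 * a0, t[0], trace.dt / 2, threshold - 0.5 * a0],
                    [3.0 * a0, t[-1], (t[-1] - t[0]), threshold + 0.5 * a0]),
            maxfev=5000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise FeatureError(f"Gaussian fit did not converge: {exc}") from exc
    return float(FWHM_FACTOR * popt[2])


def ahp_metrics(
    trace: Trace,
    spike_time: float,
    threshold: float,
    *,
    next_spike_time: float | None = None,
    max_window_ms: float = 40.0,
) -> tuple[float, float | None, float]:
    """(AHP depth mV, AHP width ms or None, peak-to-trough latency ms).

    The trough is searched between the peak and either the next spike's
    rising face or ``max_window_ms``. A trough above threshold means no
    measurable AHP and raises :class:`FeatureError`.
    """
    i_peak = trace.index_at(spike_time)
    t_end = spike_time + max_window_ms
    if next_spike_time is not None:
        t_end = min(t_end, next_spike_time - 3.0)
    i_end = min(trace.n - 1, int(round((t_end - trace.t0) / trace.dt)))
    if i_end <= i_peak + 1:
        raise FeatureError("no room after the peak to search for an AHP")
    seg = trace.samples[i_peak:i_end + 1]
    i_tr = int(np.argmin(seg))
    v_tr = float(seg[i_tr])
    if v_tr >= threshold:
        raise FeatureError("no post-spike trough below threshold (missing AHP)")
    ahp = v_tr - threshold
    latency = i_tr * trace.dt
    half = threshold + ahp / 2.0
    below = seg <= half
    width = None
    idx = np.nonzero(below)[0]
    if idx.size:
        i_lo, i_hi = idx[0], idx[-1]
        if i_lo > 0 and i_hi < seg.size - 1:
            width = (i_hi - i_lo) * trace.dt
    return ahp, width, latency


def ap_slopes(trace: Trace, spike_time: float, *, window_ms: float = 5.0) -> tuple[float, float]:
    """(max, min) of dV/dt over a window around the spike peak (mV/ms)."""
    i_peak = trace.index_at(spike_time)
    half = int(round(window_ms / trace.dt))
    i0, i1 = max(0, i_peak - half), min(trace.n, i_peak + half)
    dv = np.gradient(trace.samples[i0:i1], trace.dt)
    if dv.size < 3 or np.ptp(trace.samples[i0:i1]) < 1.0:
        raise FeatureError("no spike waveform in slope window")
    return float(dv.max()), float(dv.min())


def input_resistance(trace: Trace, protocol: PulseProtocol, *, tail_fraction: float = 0.2) -> float:
    """Steady-state input resistance (MOhm) from a hyperpolarizing step."""
    if protocol.step_pa == 0:
        raise FeatureError("zero current step")
    base = trace.slice(protocol.onset_ms - 50.0, protocol.onset_ms - 1.0).mean()
    t1 = protocol.offset_ms - tail_fraction * protocol.duration_ms
    steady = trace.slice(t1, protocol.offset_ms - trace.dt).mean()
    dv = steady - base  # mV
    return float(dv / protocol.step_pa * 1000.0)  # mV/pA -> MOhm


# ---------------------------------------------------------------------------
# composite extraction and classification

def extract_feature_set(rec: RecordingSet) -> SpikeFeatureSet:
    """All 19 parameters from a long-pulse, short-pulse and hyperpolarizing trace.

    Waveform features use the first two APs of the short suprathreshold
    pulse; firing statistics use the long pulse.
    """
    fs = SpikeFeatureSet()

    long_tr, long_proto = rec.long
    st = detect_spikes(long_tr, long_proto)
    rates = firing_frequencies(st, long_proto)
    fs.f_total = rates.f_total
    if rates.f_init is None or rates.f_200 is None or rates.f_final is None:
        fs.missing += ["f_init", "f_200", "f_final", "early_accommodation", "late_accommodation"]
    else:
        fs.f_init, fs.f_200, fs.f_final = rates.f_init, rates.f_200, rates.f_final
        fs.early_accommodation, fs.late_accommodation = accommodation(
            rates.f_init, rates.f_200, rates.f_final)

    short_tr, short_proto = rec.short
    sp = detect_spikes(short_tr, short_proto)
    if sp.size < 2:
        fs.missing += ["threshold", "a1", "a2", "amplitude_reduction", "d1", "d2",
                       "duration_increase", "ahp", "ahp_width", "peak_to_ahp",
                       "depol_slope", "hyperpol_slope"]
    else:
        t1, t2 = float(sp[0]), float(sp[1])
        thr1 = spike_threshold(short_tr, t1)
        thr2 = spike_threshold(short_tr, t2)
        fs.threshold = thr1
        fs.a1 = spike_amplitude(short_tr, t1, thr1)
        fs.a2 = spike_amplitude(short_tr, t2, thr2)
        fs.amplitude_reduction = 100.0 * (fs.a1 - fs.a2) / fs.a1
        fs.d1 = spike_duration(short_tr, t1, thr1)
        fs.d2 = spike_duration(short_tr, t2, thr2)
        fs.duration_increase = 100.0 * (fs.d2 - fs.d1) / fs.d1
        try:
            ahp, width, lat = ahp_metrics(short_tr, t1, thr1, next_spike_time=t2)
            fs.ahp = ahp
            fs.ahp_width = width if width is not None else math.nan
            if width is None:
                fs.missing.append("ahp_width")
            fs.peak_to_ahp = lat
        except FeatureError:
            fs.missing += ["ahp", "ahp_width", "peak_to_ahp"]
        fs.depol_slope, fs.hyperpol_slope = ap_slopes(short_tr, t1)

    hyper_tr, hyper_proto = rec.hyper
    fs.r_in = input_resistance(hyper_tr, hyper_proto)
    return fs


@dataclass(frozen=True)
class ClassificationRule:
    """Midpoint thresholds on the three discriminative features.

    A feature votes FSI when it is on the FSI side of its threshold;
    majority of three votes decides. The call is ambiguous when any
    feature lies within ``margin`` (in feature units) of its threshold,
    or when required features are missing.
    """

    ahp_threshold_mv: float = -12.16
    duration_increase_threshold_pct: float = 30.925
    amplitude_reduction_threshold_pct: float = 3.675
    margin: float = 0.0


DEFAULT_RULE = ClassificationRule()


def classify_interneuron(fs: SpikeFeatureSet, rule: ClassificationRule = DEFAULT_RULE) -> str:
    """'FSI', 'NFSI' or 'ambiguous' from the three-feature majority rule."""
    feats = (fs.ahp, fs.duration_increase, fs.amplitude_reduction)
    if any(f is None or math.isnan(f) for f in feats):
        return "ambiguous"
    thresholds = (
        rule.ahp_threshold_mv,
        rule.duration_increase_threshold_pct,
        rule.amplitude_reduction_threshold_pct,
    )
    if any(abs(f - thr) <= rule.margin for f, thr in zip(feats, thresholds)):
        return "ambiguous"
    votes = sum((
        fs.ahp <= rule.ahp_threshold_mv,
        fs.duration_increase <= rule.duration_increase_threshold_pct,
        fs.amplitude_reduction <= rule.amplitude_reduction_threshold_pct,
    ))
    return "FSI" if votes >= 2 else "NFSI"
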