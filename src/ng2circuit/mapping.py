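"""Photostimulation connectivity mapping.

Turns per-trial event rasters into connection calls (evoked-occurrence
enrichment within 100 ms of the stimulus AND a detectable averaged
response), applies spot-displacement / pulse-duration controls, and
assembles distance-resolved connectivity maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import uniform_filter1d

from .core import Trace

__all__ = [
    "PhotostimTrial",
    "ConnectivityMap",
    "EvokedOccurrence",
    "build_raster",
    "evoked_occurrence",
    "averaged_response_detected",
    "call_connection",
    "selectivity_controls",
    "assemble_map",
    "distance_profile",
]

DEFAULT_WINDOW_MS = 100.0
PULSE_RANGE_MS = (3.0, 8.0)


@dataclass
class PhotostimTrial:
    """One photostimulation trial: spot, pulse, and relative event times."""

    spot_position_um: np.ndarray
    pulse_ms: float
    event_times_ms: np.ndarray
    event_amplitudes_pa: np.ndarray | None = None
    trial_index: int = 0
    displaced_spot: bool = False
    altered_pulse: bool = False

    def __post_init__(self) -> None:
        self.spot_position_um = np.asarray(self.spot_position_um, dtype=float)
        self.event_times_ms = np.asarray(self.event_times_ms, dtype=float)
        if not PULSE_RANGE_MS[0] <= self.pulse_ms <= PULSE_RANGE_MS[1]:
            raise ValueError(
                f"pulse duration {self.pulse_ms} ms outside {PULSE_RANGE_MS}")


@dataclass
class ConnectivityMap:
    """Recorded cell plus the statuses of every tested interneuron around it."""

    recorded_position: np.ndarray
    recorded_kind: str
    positions: np.ndarray
    statuses: list

    def __post_init__(self) -> None:
        self.recorded_position = np.asarray(self.recorded_position, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if self.recorded_kind not in ("NG2", "pyramidal"):
            raise ValueError("recorded kind must be 'NG2' or 'pyramidal'")
        if len(self.statuses) != len(self.positions):
            raise ValueError("one status per interneuron required")
        bad = set(self.statuses) - {"connected", "unconnected", "ambiguous"}
        if bad:
            raise ValueError(f"unknown statuses: {bad}")

    @property
    def distances_um(self) -> np.ndarray:
        return np.linalg.norm(self.positions - self.recorded_position, axis=1)

    @property
    def ambiguous_fraction(self) -> float:
        s = np.asarray(self.statuses)
        return float((s == "ambiguous").mean()) if s.size else 0.0

    def split_distances(self) -> tuple[np.ndarray, np.ndarray]:
        """(connected, unconnected) distance samples; ambiguous excluded."""
        s = np.asarray(self.statuses)
        d = self.distances_um
        return d[s == "connected"], d[s == "unconnected"]


def build_raster(trials: Sequence[PhotostimTrial]) -> list[np.ndarray]:
    """Sorted event-time arrays, one per trial."""
    return [np.sort(np.asarray(t.event_times_ms, dtype=float)) for t in trials]


@dataclass(frozen=True)
class EvokedOccurrence:
    p_evoked: float
    baseline_rate_hz: float
    expected_p: float
    p_value: float
    n_trials: int


def evoked_occurrence(
    raster: Sequence[np.ndarray],
    *,
    window_ms: float = DEFAULT_WINDOW_MS,
    baseline_ms: tuple[float, float] = (-2000.0, 2000.0),
) -> EvokedOccurrence:
    """Fraction of trials with >=1 event within the post-stimulus window,
    with a one-sided exact binomial test against the Poisson background
    expectation estimated from events outside the window."""
    n = len(raster)
    if n == 0:
        raise ValueError("no trials")
    lo, hi = baseline_ms
    k = 0
    n_outside = 0
    for ev in raster:
        ev = np.asarray(ev, dtype=float)
        in_win = (ev > 0) & (ev <= window_ms)
        k += bool(in_win.any())
        n_outside += int(((ev >= lo) & (ev <= hi) & ~in_win).sum())
    outside_s = (hi - lo - window_ms) / 1000.0
    rate = n_outside / (n * outside_s) if outside_s > 0 else 0.0
    p0 = 1.0 - np.exp(-rate * window_ms / 1000.0)
    if p0 <= 0.0:
        p_value = 0.0 if k > 0 else 1.0
    else:
        p_value = float(sps.binomtest(k, n, p0, alternative="greater").pvalue)
    return EvokedOccurrence(
        p_evoked=k / n, baseline_rate_hz=rate, expected_p=p0,
        p_value=p_value, n_trials=n)


def averaged_response_detected(
    avg_trace: Trace,
    *,
    window_ms: float = DEFAULT_WINDOW_MS,
    baseline_ms: tuple[float, float] = (-1000.0, 0.0),
    factor: float = 2.0,
) -> bool:
    """True iff the averaged post-stimulus peak exceeds ``factor`` x the SD
    of the averaged-trace baseline."""
    base = avg_trace.slice(max(baseline_ms[0], avg_trace.t0), baseline_ms[1])
    sd = float(base.std())
    smooth = Trace(dt=avg_trace.dt, kind=avg_trace.kind, t0=avg_trace.t0,
                   samples=uniform_filter1d(
                       avg_trace.samples, size=max(1, int(round(3.0 / avg_trace.dt)))))
    resp = smooth.slice(0.0, window_ms)
    peak = float(np.max(np.abs(resp - base.mean())))
    if sd == 0.0:
        return peak > 0.0
    return peak > factor * sd


def call_connection(
    occurrence: EvokedOccurrence,
    avg_detected: bool,
    *,
    alpha: float = 0.05,
) -> str:
    """'connected' iff both criteria hold, 'unconnected' iff both fail,
    'ambiguous' otherwise."""
    enriched = occurrence.p_value < alpha
    if enriched and avg_detected:
        return "connected"
    if not enriched and not avg_detected:
        return "unconnected"
    return "ambiguous"


def selectivity_controls(
    target_significant: bool,
    displaced_significant: bool | None = None,
    longer_pulse_significant: bool | None = None,
) -> str:
    """Interpret spot-displacement and pulse-duration controls.

    A response that persists with a displaced spot is a false positive; a
    response appearing only with a longer pulse marks a previously false
    negative connection, now considered genuine.
    """
    if target_significant:
        if displaced_significant is None:
            return "ambiguous"
        return "false_positive" if displaced_significant else "genuine"
    if longer_pulse_significant is None:
        return "ambiguous"
    return "false_negative" if longer_pulse_significant else "unconnected"


def assemble_map(
    calls: Sequence[str],
    positions: np.ndarray,
    recorded_position: np.ndarray | Sequence[float] = (0.0, 0.0, 0.0),
    recorded_kind: str = "NG2",
) -> ConnectivityMap:
    """Bundle per-interneuron calls into a map (ambiguous kept but flagged)."""
    return ConnectivityMap(
        recorded_position=np.asarray(recorded_position, dtype=float),
        recorded_kind=recorded_kind,
        positions=np.asarray(positions, dtype=float),
        statuses=list(calls),
    )


def distance_profile(
    maps: Sequence[ConnectivityMap],
    bin_width_um: float = 10.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-bin connection probability plus the connected-vs-unconnected
    distance comparison (two-sample KS).

    Ambiguous interneurons are excluded from all denominators. Returns
    ``(profile, summary)`` where summary holds the pooled distance
    samples, the KS statistic/p-value (or a notice when there are no
    connected cells), and the max connected distance.
    """
    if not maps:
        raise ValueError("no maps")
    conn = np.concatenate([m.split_distances()[0] for m in maps])
    unconn = np.concatenate([m.split_distances()[1] for m in maps])
    all_d = np.concatenate([conn, unconn])
    all_c = np.concatenate([np.ones(conn.size, bool), np.zeros(unconn.size, bool)])
    if all_d.size == 0:
        raise ValueError("maps contain no unambiguous interneurons")
    n_bins = int(np.ceil(all_d.max() / bin_width_um)) or 1
    edges = bin_width_um * np.arange(n_bins + 1)
    idx = np.minimum(np.digitize(all_d, edges) - 1, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        n = int(sel.sum())
        k = int(all_c[sel].sum())
        rows.append(dict(
            bin_lo_um=edges[b], bin_hi_um=edges[b + 1],
            n=n, k=k, p=(k / n if n else np.nan)))
    profile = pd.DataFrame(rows)
    summary: dict = dict(
        connected_distances=conn, unconnected_distances=unconn,
        max_connected_um=(float(conn.max()) if conn.size else None),
    )
    if conn.size == 0 or unconn.size == 0:
        summary["ks_notice"] = "distance-distribution test skipped: a group is empty"
    else:
        ks = sps.ks_2samp(conn, unconn)
        summary["ks_statistic"] = float(ks.statistic)
        summary["ks_p_value"] = float(ks.pvalue)
    return profile, summary
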