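"""Developmental time course of connectivity (postnatal days 8-13).

Per-day connection probabilities peak at day 10; per-cell Na+ current
density and spontaneous synaptic frequency are drawn from a bivariate
normal whose correlation is day-specific (nonzero only at the peak day
by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimecourseParams", "gen_timecourse"]

DAYS = (8, 9, 10, 11, 12, 13)


def _default_probabilities() -> dict:
    return {8: 0.28, 9: 0.33, 10: 0.44, 11: 0.35, 12: 0.22, 13: 0.12}


def _default_frequencies() -> dict:
    return {8: 0.12, 9: 0.18, 10: 0.24, 11: 0.20, 12: 0.16, 13: 0.12}


def _default_correlations() -> dict:
    return {d: (0.7 if d == 10 else 0.0) for d in DAYS}


@dataclass(frozen=True)
class TimecourseParams:
    connection_probability: dict = field(default_factory=_default_probabilities)
    spont_frequency_hz: dict = field(default_factory=_default_frequencies)
    na_density_mean_pa_pf: float = 23.0
    na_density_sd: float = 8.0
    frequency_sd_hz: float = 0.06
    correlation: dict = field(default_factory=_default_correlations)

    def __post_init__(self) -> None:
        peak_day = max(self.connection_probability, key=self.connection_probability.get)
        if peak_day != 10:
            raise ValueError("connection probability must peak at day 10")
        for p in self.connection_probability.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        for r in self.correlation.values():
            if not -1.0 <= r <= 1.0:
                raise ValueError("correlations must be in [-1, 1]")


def gen_timecourse(
    params: TimecourseParams,
    n_cells_per_day: int,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-cell records: day, connected flag, Na+ density, spontaneous frequency."""
    if n_cells_per_day < 1:
        raise ValueError("n_cells_per_day must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for day in sorted(params.connection_probability):
        p = params.connection_probability[day]
        rho = float(params.correlation.get(day, 0.0))
        mu = np.array([params.na_density_mean_pa_pf, params.spont_frequency_hz[day]])
        cov = np.array([
            [params.na_density_sd ** 2, rho * params.na_density_sd * params.frequency_sd_hz],
            [rho * params.na_density_sd * params.frequency_sd_hz, params.frequency_sd_hz ** 2],
        ])
        draws = rng.multivariate_normal(mu, cov, size=n_cells_per_day)
        connected = rng.random(n_cells_per_day) < p
        for i in range(n_cells_per_day):
            rows.append(dict(
                day=day,
                connected=bool(connected[i]),
                na_density_pa_pf=float(max(0.0, draws[i, 0])),
                spont_frequency_hz=float(max(0.0, draws[i, 1])),
            ))
    return pd.DataFrame(rows)
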