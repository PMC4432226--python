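"""Inferential statistics for connectivity data.

Wilson score intervals for binomial connection probabilities, the
interval-overlap decision rule, Pearson chi-square on 2x2 tables,
reconstruction of integer contingency tables from rounded published
summaries, per-group probability tables and Pearson correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "WilsonInterval",
    "ContingencyTable2x2",
    "round_half_up",
    "wilson_interval",
    "interval_overlap_test",
    "pearson_chi2",
    "reconstruct_contingency",
    "probability_by_group",
    "pearson_correlation",
    "mann_whitney",
    "kruskal_wallis",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (half-up), as printed tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class WilsonInterval:
    """Two-sided Wilson score interval for a binomial proportion."""

    k: int
    n: int
    level: float
    p_hat: float
    lower: float
    upper: float

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        return round_half_up(self.lower, ndigits), round_half_up(self.upper, ndigits)

    def overlaps(self, other: "WilsonInterval") -> bool:
        # closed-interval convention: touching endpoints count as overlap
        return self.lower <= other.upper and other.lower <= self.upper


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of connected/unconnected pairs in two groups.

    Rows are groups (A, B); columns are (connected, unconnected).
    """

    connected_a: int
    unconnected_a: int
    connected_b: int
    unconnected_b: int

    def __post_init__(self) -> None:
        for v in (self.connected_a, self.unconnected_a, self.connected_b, self.unconnected_b):
            if v < 0:
                raise ValueError("contingency counts must be non-negative")

    @property
    def n_a(self) -> int:
        return self.connected_a + self.unconnected_a

    @property
    def n_b(self) -> int:
        return self.connected_b + self.unconnected_b

    def as_array(self) -> np.ndarray:
        return np.array(
            [[self.connected_a, self.unconnected_a], [self.connected_b, self.unconnected_b]],
            dtype=float,
        )


def wilson_interval(k: int, n: int, level: float = 0.90) -> WilsonInterval:
    """Two-sided Wilson score interval for ``k`` successes out of ``n``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("k must satisfy 0 <= k <= n")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    z = float(sps.norm.ppf(0.5 + level / 2.0))
    p = k / n
    z2 = z * z
    denom = 1.0 + z2 / n
    centre = (p + z2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z2 / (4 * n * n)) / denom
    return WilsonInterval(
        k=int(k), n=int(n), level=level, p_hat=p,
        lower=max(0.0, centre - half), upper=min(1.0, centre + half),
    )


def interval_overlap_test(
    ci_a: WilsonInterval, ci_b: WilsonInterval
) -> tuple[bool, float]:
    """Decide whether two proportions differ by interval disjointness.

    Returns ``(different, alpha_bound)`` where ``alpha_bound`` is the
    nominal bound ``(1 - level)**2`` on the chance of disjoint intervals
    under equal underlying probabilities.
    """
    if ci_a.level != ci_b.level:
        raise ValueError("intervals must share a confidence level")
    alpha_bound = (1.0 - ci_a.level) ** 2
    return (not ci_a.overlaps(ci_b)), alpha_bound


def pearson_chi2(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Returns ``(statistic, df, p_value)`` with df = 1.
    """
    if isinstance(table, ContingencyTable2x2):
        obs = table.as_array()
    else:
        obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("chi-square requires positive margins")
    expected = row @ col / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat, df=1))
    return stat, 1, p


def reconstruct_contingency(
    p_a: float,
    p_b: float,
    total_pairs: int,
    total_connected: int,
    *,
    ci_a_rounded: tuple[float, float] | None = None,
    ci_b_rounded: tuple[float, float] | None = None,
    chi2_rounded: float | None = None,
    level: float = 0.90,
    ndigits: int = 2,
) -> ContingencyTable2x2:
    """Recover the integer 2x2 table behind rounded published summaries.

    Enumerates all splits ``k_a + k_b = total_connected`` over group sizes
    ``n_a + n_b = total_pairs`` whose proportions round (half-up, ``ndigits``)
    to ``p_a`` and ``p_b``; surviving candidates are disambiguated by the
    rounding of at least one corroborating statistic (Wilson CI bounds
    and/or the chi-square value). Raises if no or several candidates remain.
    """
    if total_connected > total_pairs:
        raise ValueError("total_connected cannot exceed total_pairs")
    if ci_a_rounded is None and ci_b_rounded is None and chi2_rounded is None:
        raise ValueError("at least one corroborating statistic is required")

    candidates: list[ContingencyTable2x2] = []
    for n_a in range(1, total_pairs):
        n_b = total_pairs - n_a
        k_lo = max(0, total_connected - n_b)
        k_hi = min(total_connected, n_a)
        for k_a in range(k_lo, k_hi + 1):
            k_b = total_connected - k_a
            if round_half_up(k_a / n_a, ndigits) != round_half_up(p_a, ndigits):
                continue
            if round_half_up(k_b / n_b, ndigits) != round_half_up(p_b, ndigits):
                continue
            cand = ContingencyTable2x2(k_a, n_a - k_a, k_b, n_b - k_b)
            if _corroborates(cand, ci_a_rounded, ci_b_rounded, chi2_rounded, level, ndigits):
                candidates.append(cand)

    if not candidates:
        raise ValueError("no integer table is consistent with the printed summaries")
    if len(candidates) > 1:
        raise ValueError(
            f"reconstruction is not unique: {len(candidates)} candidate tables survive"
        )
    return candidates[0]


def _corroborates(
    table: ContingencyTable2x2,
    ci_a_rounded: tuple[float, float] | None,
    ci_b_rounded: tuple[float, float] | None,
    chi2_rounded: float | None,
    level: float,
    ndigits: int,
) -> bool:
    if ci_a_rounded is not None:
        ci = wilson_interval(table.connected_a, table.n_a, level)
        if ci.rounded(ndigits) != tuple(round_half_up(v, ndigits) for v in ci_a_rounded):
            return False
    if ci_b_rounded is not None:
        ci = wilson_interval(table.connected_b, table.n_b, level)
        if ci.rounded(ndigits) != tuple(round_half_up(v, ndigits) for v in ci_b_rounded):
            return False
    if chi2_rounded is not None:
        stat, _, _ = pearson_chi2(table)
        if round_half_up(stat, ndigits) != round_half_up(chi2_rounded, ndigits):
            return False
    return True


def probability_by_group(
    records: pd.DataFrame,
    *,
    group_col: str = "group",
    day_col: str | None = "day",
    connected_col: str = "connected",
    level: float = 0.90,
) -> pd.DataFrame:
    """Per-(group, day) connection probabilities with Wilson intervals.

    ``records`` holds one row per tested pair. Empty cells are simply
    absent from the output. Returns columns k, n, p, lower, upper.
    """
    if records.empty:
        raise ValueError("no records provided")
    keys = [group_col] if day_col is None or day_col not in records else [group_col, day_col]
    rows = []
    for key, sub in records.groupby(keys, sort=True):
        k = int(np.asarray(sub[connected_col], dtype=bool).sum())
        n = len(sub)
        ci = wilson_interval(k, n, level)
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        row.update(k=k, n=n, p=k / n, lower=ci.lower, upper=ci.upper)
        rows.append(row)
    return pd.DataFrame(rows)


def pearson_correlation(x: Iterable[float], y: Iterable[float]) -> tuple[float, float]:
    """Pearson r and its two-sided p-value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("inputs must not be constant")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


# Thin generic wrappers; provided for completeness, not tuned further.

def mann_whitney(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    res = sps.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis(*groups) -> tuple[float, float]:
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)
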