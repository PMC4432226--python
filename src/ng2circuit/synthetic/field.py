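"""Distance-dependent connectivity fields around a recorded cell.

Interneuron somata are placed uniformly in a disc around the recorded
cell. For glial (NG2) targets the connection probability is ``p_near``
up to 50 um, decays linearly to zero at 70 um and is exactly zero
beyond; for pyramidal targets it is constant within the field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..mapping import ConnectivityMap

__all__ = ["FieldParams", "connection_probability", "gen_connectivity_field"]

NG2_PLATEAU_UM = 50.0
NG2_CUTOFF_UM = 70.0


@dataclass(frozen=True)
class FieldParams:
    radius_um: float = 100.0
    n_interneurons: int = 30
    target_kind: str = "NG2"
    p_near: float = 0.5

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("field radius must be positive")
        if self.n_interneurons < 0:
            raise ValueError("interneuron count must be >= 0")
        if self.target_kind not in ("NG2", "pyramidal"):
            raise ValueError("target kind must be 'NG2' or 'pyramidal'")
        if not 0.0 <= self.p_near <= 1.0:
            raise ValueError("p_near must be in [0, 1]")


def connection_probability(distance_um: np.ndarray, params: FieldParams) -> np.ndarray:
    """The distance rule: plateau/linear-decay for NG2, constant for pyramidal."""
    d = np.asarray(distance_um, dtype=float)
    if params.target_kind == "pyramidal":
        return np.where(d <= params.radius_um, params.p_near, 0.0)
    p = np.where(
        d <= NG2_PLATEAU_UM,
        params.p_near,
        params.p_near * (NG2_CUTOFF_UM - d) / (NG2_CUTOFF_UM - NG2_PLATEAU_UM),
    )
    return np.clip(np.where(d > NG2_CUTOFF_UM, 0.0, p), 0.0, 1.0)


def gen_connectivity_field(
    params: FieldParams,
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> ConnectivityMap:
    """Ground-truth map: uniform positions, flags drawn from the distance rule."""
    if rng is None:
        rng = np.random.default_rng(seed)
    n = params.n_interneurons
    # uniform in a disc around the recorded cell (z = 0)
    r = params.radius_um * np.sqrt(rng.random(n))
    phi = 2 * np.pi * rng.random(n)
    positions = np.column_stack([r * np.cos(phi), r * np.sin(phi), np.zeros(n)])
    p = connection_probability(r, params)
    connected = rng.random(n) < p
    statuses = np.where(connected, "connected", "unconnected")
    return ConnectivityMap(
        recorded_position=np.zeros(3),
        recorded_kind=params.target_kind,
        positions=positions,
        statuses=list(statuses),
    )
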