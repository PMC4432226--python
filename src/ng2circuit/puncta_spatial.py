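"""Spatial statistics for 3D synaptic puncta around a reconstructed cell:
fluorescence-profile colocalization, soma/branch assignment with
geodesic distances, distance distributions, and puncta densities in
eccentric spherical shells clipped to the imaging stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PunctaCloud",
    "CellMorphology",
    "profile_overlap",
    "classify_contacts",
    "assign_compartment",
    "distance_distributions",
    "shell_volume",
    "clipped_ball_volume",
    "shell_density_profile",
]

OVERLAP_CONTACT_THRESHOLD = 0.23


@dataclass
class PunctaCloud:
    """Labelled 3D points inside an imaging stack.

    ``labels`` maps channel name (e.g. 'vgat', 'pv', 'g2') to a boolean
    array over points. ``stack_bounds`` is (x extent, y extent,
    z thickness) in um with the origin at a stack corner.
    """

    points: np.ndarray
    labels: dict
    stack_bounds: tuple[float, float, float]
    profiles: list | None = None  # optional per-punctum 1D fluorescence profiles

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        for name, arr in self.labels.items():
            arr = np.asarray(arr, dtype=bool)
            if arr.size != len(self.points):
                raise ValueError(f"label '{name}' length mismatch")
            self.labels[name] = arr
        b = np.asarray(self.stack_bounds, dtype=float)
        if (b <= 0).any():
            raise ValueError("stack bounds must be positive")
        if len(self.points) and ((self.points < -1e-9).any() or (self.points > b + 1e-9).any()):
            raise ValueError("points must lie within the stack bounds")

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass
class CellMorphology:
    """Soma (center + radius) and branches as 3D polylines rooted at the soma."""

    soma_center: np.ndarray
    soma_radius: float
    branches: list

    def __post_init__(self) -> None:
        self.soma_center = np.asarray(self.soma_center, dtype=float)
        if self.soma_radius <= 0:
            raise ValueError("soma radius must be positive")
        self.branches = [np.asarray(b, dtype=float).reshape(-1, 3) for b in self.branches]
        for b in self.branches:
            start_gap = abs(np.linalg.norm(b[0] - self.soma_center) - self.soma_radius)
            if start_gap > 1.0:
                raise ValueError("branches must start on the soma surface")


def profile_overlap(profile_a, profile_b) -> float:
    """Fraction of profile A's area shared with profile B.

    Profiles are (x, y) pairs on a common axis. The denominator is the
    punctum's own (first) profile area, so the measure is asymmetric
    unless the areas are equal; contact is declared above 0.23.
    """
    xa, ya = (np.asarray(v, dtype=float) for v in profile_a)
    xb, yb = (np.asarray(v, dtype=float) for v in profile_b)
    if xa.shape != ya.shape or xb.shape != yb.shape:
        raise ValueError("profiles must be (x, y) arrays of equal shape")
    if not np.array_equal(xa, xb):
        raise ValueError("profiles must share a common axis")
    if (ya < 0).any() or (yb < 0).any():
        raise ValueError("profiles must be non-negative")
    area_a = np.trapezoid(ya, xa)
    if area_a <= 0:
        raise ValueError("punctum profile has zero area")
    shared = np.trapezoid(np.minimum(ya, yb), xa)
    return float(shared / area_a)


def _point_to_polyline(p: np.ndarray, poly: np.ndarray) -> tuple[float, float]:
    """(perpendicular distance, arc length from polyline start to foot)."""
    best = (np.inf, 0.0)
    arc = 0.0
    for a, b in zip(poly[:-1], poly[1:]):
        ab = b - a
        seg_len = float(np.linalg.norm(ab))
        if seg_len == 0:
            continue
        t = float(np.clip(np.dot(p - a, ab) / seg_len**2, 0.0, 1.0))
        foot = a + t * ab
        d = float(np.linalg.norm(p - foot))
        if d < best[0]:
            best = (d, arc + t * seg_len)
        arc += seg_len
    return best


def assign_compartment(
    punctum: np.ndarray,
    morphology: CellMorphology,
    *,
    mode: str = "geodesic",
    contact_tolerance_um: float = 1.0,
) -> tuple[str | None, float, bool]:
    """(compartment, distance from soma in um, contact flag).

    Somatic puncta get distance 0. Branch puncta get the geodesic arc
    length along the nearest branch from the soma surface (or straight
    Euclidean distance from the soma center with ``mode='euclidean'``).
    Puncta farther than the tolerance from any branch are non-contacts.
    """
    p = np.asarray(punctum, dtype=float)
    r_c = float(np.linalg.norm(p - morphology.soma_center))
    if r_c <= morphology.soma_radius:
        return "soma", 0.0, True
    best_d, best_arc = np.inf, 0.0
    for poly in morphology.branches:
        d, arc = _point_to_polyline(p, poly)
        if d < best_d:
            best_d, best_arc = d, arc
    if best_d > contact_tolerance_um:
        return None, np.nan, False
    dist = best_arc if mode == "geodesic" else r_c - morphology.soma_radius
    return "branch", float(dist), True


def classify_contacts(
    cloud: PunctaCloud,
    morphology: CellMorphology,
    *,
    pv_channel: str = "pv",
    contact_tolerance_um: float = 1.0,
    cell_profile=None,
) -> pd.DataFrame:
    """Per-punctum contact category and subcellular assignment.

    Contact is decided by the fluorescence-profile overlap rule when the
    cloud carries profiles (and a cell profile is given), else by the
    geometric branch/soma tolerance. Categories are 'pv_contact',
    'non_pv_contact' and 'non_contact'.
    """
    pv = cloud.labels.get(pv_channel, np.zeros(cloud.n, dtype=bool))
    rows = []
    for i in range(cloud.n):
        comp, dist, contact = assign_compartment(
            cloud.points[i], morphology, contact_tolerance_um=contact_tolerance_um)
        if cloud.profiles is not None and cell_profile is not None:
            contact = contact and (
                profile_overlap(cloud.profiles[i], cell_profile) > OVERLAP_CONTACT_THRESHOLD)
        if not contact:
            cat = "non_contact"
        else:
            cat = "pv_contact" if pv[i] else "non_pv_contact"
        rows.append(dict(category=cat, compartment=comp, distance_um=dist, pv=bool(pv[i])))
    return pd.DataFrame(rows)


def distance_distributions(pv_plus_um, pv_minus_um) -> dict:
    """Cumulative curves, branch means and a two-sample KS comparison.

    Inputs are branch distances (somatic puncta, distance 0, are
    expected to have been excluded by the caller for the means).
    """
    a = np.sort(np.asarray(pv_plus_um, dtype=float))
    b = np.sort(np.asarray(pv_minus_um, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ks = sps.ks_2samp(a, b)
    return dict(
        pv_plus_sorted=a, pv_minus_sorted=b,
        pv_plus_cum=np.arange(1, a.size + 1) / a.size,
        pv_minus_cum=np.arange(1, b.size + 1) / b.size,
        mean_pv_plus=float(a.mean()), mean_pv_minus=float(b.mean()),
        ks_statistic=float(ks.statistic), ks_p_value=float(ks.pvalue),
    )


def _cap_volume(r: float, h: float) -> float:
    h = min(max(h, 0.0), 2.0 * r)
    return np.pi * h * h * (3.0 * r - h) / 3.0


def clipped_ball_volume(r: float, z_center: float, z_thickness: float) -> float:
    """Volume of a ball clipped by the two z planes of the stack."""
    full = 4.0 / 3.0 * np.pi * r**3
    cap_below = _cap_volume(r, r - z_center)            # below z = 0
    cap_above = _cap_volume(r, r - (z_thickness - z_center))  # above z = thickness
    return full - cap_below - cap_above


def shell_volume(
    r_inner: float,
    r_outer: float,
    stack_bounds: tuple[float, float, float],
    center,
) -> float:
    """Volume (um^3) of a spherical shell clipped by the stack's z planes.

    x,y bounds are not clipped analytically; callers stop growing shells
    at the x,y boundary instead. The center must lie inside the stack.
    """
    if not 0 <= r_inner < r_outer:
        raise ValueError("require 0 <= r_inner < r_outer")
    c = np.asarray(center, dtype=float)
    b = np.asarray(stack_bounds, dtype=float)
    if (c < 0).any() or (c > b).any():
        raise ValueError("center must lie inside the stack bounds")
    z_c, z_t = float(c[2]), float(b[2])
    outer = clipped_ball_volume(r_outer, z_c, z_t)
    inner = clipped_ball_volume(r_inner, z_c, z_t) if r_inner > 0 else 0.0
    return outer - inner


def shell_density_profile(
    cloud: PunctaCloud,
    *,
    center=None,
    step_um: float = 5.0,
    vgat_channel: str = "vgat",
    pv_channel: str = "pv",
) -> pd.DataFrame:
    """Per-shell puncta densities (puncta/um^3) for all-VGAT and VGAT/PV
    subsets, in concentric shells grown until the x,y stack boundary."""
    if step_um <= 0:
        raise ValueError("step must be positive")
    b = np.asarray(cloud.stack_bounds, dtype=float)
    c = np.asarray(center, dtype=float) if center is not None else b / 2.0
    max_r = min(c[0], b[0] - c[0], c[1], b[1] - c[1])
    n_shells = int(np.floor(max_r / step_um))
    if n_shells < 1:
        raise ValueError("stack too small for a single shell at this step")
    vgat = cloud.labels.get(vgat_channel, np.ones(cloud.n, dtype=bool))
    pv = cloud.labels.get(pv_channel, np.zeros(cloud.n, dtype=bool))
    d = (np.linalg.norm(cloud.points - c, axis=1) if cloud.n
         else np.empty(0))
    rows = []
    for s in range(n_shells):
        r0, r1 = s * step_um, (s + 1) * step_um
        vol = shell_volume(r0, r1, tuple(b), c)
        in_shell = (d >= r0) & (d < r1) if cloud.n else np.empty(0, dtype=bool)
        n_all = int((in_shell & vgat).sum()) if cloud.n else 0
        n_pv = int((in_shell & vgat & pv).sum()) if cloud.n else 0
        rows.append(dict(
            r_inner_um=r0, r_outer_um=r1, volume_um3=vol,
            n_vgat=n_all, n_vgat_pv=n_pv,
            density_vgat=n_all / vol, density_vgat_pv=n_pv / vol,
        ))
    return pd.DataFrame(rows)
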