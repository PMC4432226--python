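"""Synthetic 3D puncta clouds around a reconstructed cell.

PV+ puncta are placed at geodesic distances from the soma drawn from an
exponential law with a proximal scale, PV- puncta with a distal scale;
points sit on radial branch polylines with small jitter and are clipped
to the imaging stack. A fraction of puncta lands on the soma itself.
"""

from __future__ import annotations

import numpy as np

from ..puncta_spatial import CellMorphology, PunctaCloud

__all__ = ["gen_puncta_cloud", "default_morphology"]


def default_morphology(
    center: np.ndarray | tuple = (62.5, 62.5, 9.6),
    soma_radius: float = 5.0,
    n_branches: int = 6,
    branch_length: float = 50.0,
) -> CellMorphology:
    """Radial star of straight branches in the xy plane, rooted on the soma."""
    center = np.asarray(center, dtype=float)
    branches = []
    for k in range(n_branches):
        phi = 2 * np.pi * k / n_branches
        u = np.array([np.cos(phi), np.sin(phi), 0.0])
        start = center + soma_radius * u
        end = start + branch_length * u
        branches.append(np.vstack([start, end]))
    return CellMorphology(soma_center=center, soma_radius=soma_radius, branches=branches)


def gen_puncta_cloud(
    n_pv: int,
    n_nonpv: int,
    proximal_scale: float = 12.8,
    distal_scale: float = 22.5,
    stack_bounds: tuple[float, float, float] = (125.0, 125.0, 19.2),
    seed: int | None = None,
    *,
    rng: np.random.Generator | None = None,
    morphology: CellMorphology | None = None,
    soma_fraction_pv: float = 0.3,
    soma_fraction_nonpv: float = 0.1,
    jitter_um: float = 0.5,
) -> tuple[PunctaCloud, CellMorphology, dict]:
    """Puncta cloud + morphology + ground truth (true geodesic distances)."""
    if n_pv < 0 or n_nonpv < 0:
        raise ValueError("puncta counts must be >= 0")
    if proximal_scale <= 0 or distal_scale <= 0:
        raise ValueError("distance scales must be positive")
    if any(b <= 0 for b in stack_bounds):
        raise ValueError("stack bounds must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    if morphology is None:
        morphology = default_morphology(
            center=(stack_bounds[0] / 2, stack_bounds[1] / 2, stack_bounds[2] / 2))

    points, pv_flags, true_dist, on_soma = [], [], [], []
    for n_points, scale, soma_frac, is_pv in (
        (n_pv, proximal_scale, soma_fraction_pv, True),
        (n_nonpv, distal_scale, soma_fraction_nonpv, False),
    ):
        for _ in range(n_points):
            if rng.random() < soma_frac:
                # on the soma surface
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                p = morphology.soma_center + morphology.soma_radius * u
                d = 0.0
                soma_flag = True
            else:
                branch = morphology.branches[rng.integers(len(morphology.branches))]
                length = float(np.linalg.norm(branch[-1] - branch[0]))
                d = float(rng.exponential(scale))
                while d > length:
                    d = float(rng.exponential(scale))
                u = (branch[-1] - branch[0]) / length
                p = branch[0] + d * u + rng.normal(0.0, jitter_um / 3.0, size=3)
                soma_flag = False
            p = np.clip(p, 0.0, np.asarray(stack_bounds))
            points.append(p)
            pv_flags.append(is_pv)
            true_dist.append(d)
            on_soma.append(soma_flag)

    points = np.asarray(points, dtype=float).reshape(-1, 3)
    labels = {
        "vgat": np.ones(len(points), dtype=bool),
        "pv": np.asarray(pv_flags, dtype=bool),
    }
    cloud = PunctaCloud(points=points, labels=labels, stack_bounds=tuple(stack_bounds))
    truth = dict(
        geodesic_distance_um=np.asarray(true_dist),
        on_soma=np.asarray(on_soma, dtype=bool),
        proximal_scale=proximal_scale,
        distal_scale=distal_scale,
    )
    return cloud, morphology, truth
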