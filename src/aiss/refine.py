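"""Final-stage rigid-body refinement, duplicate-aware selection and reporting.

Refinement minimizes the bias-free screening energy over the six pose
degrees of freedom with a derivative-free simplex; intramolecular relaxation
is delegated to an external optimizer through the workflow adapter.
Selection returns either the few lowest, mutually distinct poses (single
mode, default 15) or every significantly attractive pose (ensemble mode).
Reported interaction energies are always bias-free.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .energy import interaction_energy
from .molio import (
    Molecule,
    Pose,
    euler_rotation_matrices,
    normalize_angles,
    write_multi_xyz,
)

logger = logging.getLogger(__name__)


@dataclass
class ComplexResult:
    """One final complex: merged geometry, its pose and energy bookkeeping."""

    geometry: Molecule  # merged A + posed B, A atoms first
    pose: Pose
    screening_energy: float  # bias-free screening score before refinement
    final_energy: float  # bias-free energy after refinement
    e_int: float  # E(AB) - E(A) - E(B)
    rank: int


def local_optimize_rigid(
    pose: Pose,
    energy_fn: Callable[[np.ndarray], float],
    maxfev: int = 2000,
    tol: float = 1e-6,
    b_has_fixed_atoms: bool = False,
) -> Pose:
    """Derivative-free local minimization over the 6 pose DOF.

    ``energy_fn`` maps a 6-vector (x, y, z, alpha, beta, gamma) to a scalar
    energy.  The returned pose never scores above the input pose (the
    initial point is part of the simplex).  Fragment A never moves, so fixed
    atoms on A are honored trivially; fixed atoms on B make rigid pose
    optimization ill-defined and are skipped with a warning.
    """
    x0 = np.concatenate([pose.translation, pose.angles])
    e0 = float(energy_fn(x0))
    if not math.isfinite(e0):
        raise ValueError("non-finite energy at the starting pose")
    if b_has_fixed_atoms:
        logger.warning(
            "mobile fragment carries fixed atoms; skipping rigid pose optimization"
        )
        return Pose(pose.translation, pose.angles, e0)
    res = minimize(
        energy_fn,
        x0,
        method="Nelder-Mead",
        options={"maxfev": maxfev, "fatol": tol, "xatol": 1e-4},
    )
    if res.fun <= e0:
        return Pose(res.x[:3], normalize_angles(res.x[3:]), float(res.fun))
    return Pose(pose.translation, pose.angles, e0)


def _rotation_geodesic(ang_i: np.ndarray, ang_j: np.ndarray) -> float:
    """Geodesic angle between two orientations given as Euler triples."""
    ri, rj = euler_rotation_matrices(np.vstack([ang_i, ang_j]))
    cos = (np.trace(ri @ rj.T) - 1.0) / 2.0
    return float(math.acos(max(-1.0, min(1.0, cos))))


def _is_distinct(
    pose: Pose, selected: Sequence[Pose], trans_rms: float, angle_dist: float
) -> bool:
    for other in selected:
        rms = float(np.sqrt(((pose.translation - other.translation) ** 2).mean()))
        if rms > trans_rms:
            continue
        if _rotation_geodesic(pose.angles, other.angles) > angle_dist:
            continue
        return False  # both below threshold -> duplicate
    return True


def select_final(
    poses: Sequence[Pose],
    mode: str = "single",
    n_single: int = 15,
    ensemble_window: float = 10.0,
    trans_rms: float = 0.5,
    angle_dist: float = 0.2,
) -> list[Pose]:
    """Pick the poses to refine.

    Single mode returns the ``n_single`` lowest, mutually distinct poses;
    ensemble mode returns all distinct poses that are attractive (score < 0)
    and within ``ensemble_window`` kcal/mol of the best score.  Two poses are
    duplicates when both their translation RMS and their orientation
    geodesic distance fall below the thresholds.
    """
    if mode not in ("single", "ensemble"):
        raise ValueError("mode must be 'single' or 'ensemble'")
    poses = sorted(poses, key=lambda p: p.score)
    if not poses:
        logger.warning("select_final received no poses")
        return []
    selected: list[Pose] = []
    best = poses[0].score
    for pose in poses:
        if mode == "single" and len(selected) >= n_single:
            break
        if mode == "ensemble" and (
            pose.score >= 0.0 or pose.score > best + ensemble_window
        ):
            break
        if _is_distinct(pose, selected, trans_rms, angle_dist):
            selected.append(pose.copy())
    return selected


def report(
    results: Sequence[ComplexResult],
    e_a: float = 0.0,
    e_b: float = 0.0,
    out_dir: str | Path | None = None,
    prefix: str = "aiss",
) -> pd.DataFrame:
    """Tabulate ranked results; optionally write the XYZ ensemble and CSV.

    ``e_a``/``e_b`` are the monomer energies used for E_int bookkeeping
    (zero for the built-in backend, whose monomer energy vanishes by
    construction).
    """
    rows = []
    for r in sorted(results, key=lambda r: r.final_energy):
        rows.append(
            {
                "rank": r.rank,
                "screening_energy": r.screening_energy,
                "final_energy": r.final_energy,
                "e_int": interaction_energy(r.final_energy, e_a, e_b),
                "x": r.pose.translation[0],
                "y": r.pose.translation[1],
                "z": r.pose.translation[2],
                "alpha": r.pose.angles[0],
                "beta": r.pose.angles[1],
                "gamma": r.pose.angles[2],
            }
        )
    df = pd.DataFrame(rows)
    if out_dir is not None and len(results) > 0:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ordered = sorted(results, key=lambda r: r.final_energy)
        comments = [
            f"rank={r.rank} E_int={r.e_int:.8f} kcal/mol" for r in ordered
        ]
        write_multi_xyz(
            [r.geometry for r in ordered], out_dir / f"{prefix}_ensemble.xyz", comments
        )
        df.to_csv(out_dir / f"{prefix}_summary.csv", index=False)
    return df
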