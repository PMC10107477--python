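"""Brute-force grid reference for validating the stochastic search.

Enumerates rigid placements of the mobile fragment on a dense Cartesian
translation grid (and, for polyatomic mobile fragments, an Euler-angle
grid), then polishes the best grid point with the same derivative-free local
optimizer the pipeline uses.  This is exhaustive — and therefore only usable
at desk scale — but independent of the pose generators and the genetic
optimization, which makes it the validation oracle for them.
"""

from __future__ import annotations

import math

import numpy as np

from .energy import PreparedFragment, pose_energies
from .molio import Pose
from .refine import local_optimize_rigid


def brute_force_minimum(
    a: PreparedFragment,
    b: PreparedFragment,
    spacing: float = 0.25,
    angle_step_deg: float = 15.0,
    margin: float = 3.0,
    polish: bool = True,
) -> Pose:
    """Global-minimum pose by exhaustive enumeration plus local polish.

    The translation grid covers A's bounding box expanded by the extent of B
    plus ``margin`` on every side.  Monatomic mobile fragments skip the
    rotational grid entirely (their energy is orientation-independent).
    """
    extent_b = float(np.linalg.norm(b.coords - b.cma, axis=1).max())
    lo = a.coords.min(axis=0) - (extent_b + margin) - a.cma
    hi = a.coords.max(axis=0) + (extent_b + margin) - a.cma
    axes = [np.arange(lo[d], hi[d] + 0.5 * spacing, spacing) for d in range(3)]
    trans = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    if len(b.coords) == 1:
        angle_grid = np.zeros((1, 3))
    else:
        step = math.radians(angle_step_deg)
        alphas = np.arange(0.0, 2.0 * math.pi - 1e-9, step)
        betas = np.arange(0.0, math.pi + 1e-9, step)
        gammas = np.arange(0.0, 2.0 * math.pi - 1e-9, step)
        angle_grid = np.stack(
            np.meshgrid(alphas, betas, gammas, indexing="ij"), axis=-1
        ).reshape(-1, 3)

    best_e = math.inf
    best_t = trans[0]
    best_a = angle_grid[0]
    chunk = max(1, int(4_000_000 / max(1, len(a.coords) * len(b.coords))))
    for ang in angle_grid:
        angs = np.broadcast_to(ang, (len(trans), 3))
        for s in range(0, len(trans), chunk):
            e = pose_energies(a, b, trans[s : s + chunk], angs[s : s + chunk])
            i = int(np.argmin(e))
            if e[i] < best_e:
                best_e = float(e[i])
                best_t = trans[s + i]
                best_a = ang
    pose = Pose(best_t, best_a, best_e)
    if polish:
        def scalar(x: np.ndarray) -> float:
            return float(pose_energies(a, b, x[None, :3], x[None, 3:])[0])

        pose = local_optimize_rigid(pose, scalar)
    return pose
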