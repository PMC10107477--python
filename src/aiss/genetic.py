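"""Two-step genetic optimization of rigid-body poses.

Each pose is a 6-vector (CMA displacement x, y, z and Euler angles alpha,
beta, gamma).  One generation consists of (1) a crossover of pose pairs,
where each child component c is the blend f_c * parent_i + (1 - f_c) *
parent_j with fresh uniform random factors f_1..f_6, followed by rank
truncation of the combined parent+child pool, and (2) a random mutation of a
fraction (default 50 %) of the population in position and angle.  The
screening energy of every newly generated pose is used for ranking, and the
cycle is repeated a fixed number of generations (default ten).

Angles are blended along the shorter arc of the circle so that the f = 0 and
f = 1 endpoints reproduce the parents exactly without wrap discontinuities.
The incumbent best pose is reinserted if mutation loses it, so the
best-energy trace is non-increasing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .molio import Pose, normalize_angles

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * math.pi

# energy_fn maps batches: (k, 3) translations, (k, 3) angles -> (k,) scores
EnergyFn = Callable[[np.ndarray, np.ndarray], np.ndarray]


@dataclass
class Population:
    """A scored population of rigid-body poses (array-of-structs layout)."""

    translations: np.ndarray  # (N, 3)
    angles: np.ndarray  # (N, 3)
    scores: np.ndarray  # (N,)
    generation: int = 0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, dtype=float).reshape(-1, 3)
        self.angles = normalize_angles(
            np.asarray(self.angles, dtype=float).reshape(-1, 3)
        )
        self.scores = np.asarray(self.scores, dtype=float).reshape(-1)
        if not (len(self.translations) == len(self.angles) == len(self.scores)):
            raise ValueError("population arrays must have equal length")

    def __len__(self) -> int:
        return len(self.scores)

    @classmethod
    def from_poses(
        cls, poses: Sequence[Pose], generation: int = 0, rng_seed: int | None = None
    ) -> "Population":
        return cls(
            translations=np.array([p.translation for p in poses]),
            angles=np.array([p.angles for p in poses]),
            scores=np.array([p.score for p in poses]),
            generation=generation,
            rng_seed=rng_seed,
        )

    @property
    def poses(self) -> list[Pose]:
        return [
            Pose(t.copy(), a.copy(), float(s))
            for t, a, s in zip(self.translations, self.angles, self.scores)
        ]

    def sorted(self) -> "Population":
        order = np.argsort(self.scores, kind="stable")
        return Population(
            self.translations[order],
            self.angles[order],
            self.scores[order],
            self.generation,
            self.rng_seed,
        )

    def best(self) -> Pose:
        i = int(np.argmin(self.scores))
        return Pose(self.translations[i].copy(), self.angles[i].copy(), float(self.scores[i]))


def _blend_angles(ai: np.ndarray, aj: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Blend angles along the shorter arc; f=1 -> ai, f=0 -> aj (mod 2*pi)."""
    delta = np.mod(ai - aj + math.pi, TWO_PI) - math.pi
    return normalize_angles(aj + f * delta)


def crossover(pose_i: Pose, pose_j: Pose, f: Sequence[float]) -> Pose:
    """Blend two parent poses with factors f_1..f_6 in [0, 1].

    Translation components use the linear blend f*i + (1-f)*j; angles are
    blended along the shorter arc.  The child is returned unscored.
    """
    f = np.asarray(f, dtype=float).reshape(6)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("crossover factors must lie in [0, 1]")
    trans = f[:3] * pose_i.translation + (1.0 - f[:3]) * pose_j.translation
    ang = _blend_angles(pose_i.angles, pose_j.angles, f[3:])
    return Pose(trans, ang)


def crossover_population(
    pop: Population,
    rng: np.random.Generator,
    energy_fn: EnergyFn,
    max_pairs: int | None = None,
) -> Population:
    """Generate children from every ordered parent pair and rank-truncate.

    Children of all ordered pairs (i, j), i != j, are built with fresh
    uniform random factors per pair; the combined parent+child pool is scored
    and truncated back to the population size by ascending screening energy
    (stable sort, so the best parent always survives).  ``max_pairs`` caps
    the number of pairs by random subsampling for expensive backends.
    """
    n = len(pop)
    if n < 2:
        return pop
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    mask = ii != jj
    ii, jj = ii[mask], jj[mask]
    if max_pairs is not None and len(ii) > max_pairs:
        keep = rng.choice(len(ii), size=max_pairs, replace=False)
        keep.sort()
        ii, jj = ii[keep], jj[keep]
    f = rng.random((len(ii), 6))
    child_t = f[:, :3] * pop.translations[ii] + (1.0 - f[:, :3]) * pop.translations[jj]
    child_a = _blend_angles(pop.angles[ii], pop.angles[jj], f[:, 3:])
    child_s = energy_fn(child_t, child_a)
    pool_t = np.vstack([pop.translations, child_t])
    pool_a = np.vstack([pop.angles, child_a])
    pool_s = np.concatenate([pop.scores, child_s])
    order = np.argsort(pool_s, kind="stable")[:n]
    return Population(
        pool_t[order], pool_a[order], pool_s[order], pop.generation + 1, pop.rng_seed
    )


def mutate(
    pop: Population,
    rng: np.random.Generator,
    energy_fn: EnergyFn,
    fraction: float = 0.5,
    sigma_t: float = 1.0,
    sigma_a: float = 0.3,
) -> Population:
    """Gaussian-perturb a random subset of poses in position and angle.

    Exactly ``round(fraction * N)`` distinct poses, chosen uniformly at
    random, receive N(0, sigma_t^2) translation noise and N(0, sigma_a^2)
    angle noise (re-normalized to [0, 2*pi)); mutated poses are re-scored.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("mutation fraction must lie in [0, 1]")
    n = len(pop)
    k = int(round(fraction * n))
    trans = pop.translations.copy()
    ang = pop.angles.copy()
    scores = pop.scores.copy()
    if k > 0:
        idx = np.sort(rng.choice(n, size=k, replace=False))
        trans[idx] = trans[idx] + rng.normal(0.0, sigma_t, size=(k, 3))
        ang[idx] = normalize_angles(ang[idx] + rng.normal(0.0, sigma_a, size=(k, 3)))
        scores[idx] = energy_fn(trans[idx], ang[idx])
    return Population(trans, ang, scores, pop.generation, pop.rng_seed)


def ga_optimize(
    initial: Population,
    energy_fn: EnergyFn,
    generations: int = 10,
    rng: np.random.Generator | int | None = None,
    mutation_fraction: float = 0.5,
    sigma_t: float = 1.0,
    sigma_a: float = 0.3,
    max_pairs: int | None = None,
    trace: list | None = None,
) -> Population:
    """Run the two-step genetic optimization and return the sorted population.

    The incumbent best pose is retained across generations: if a mutation
    step loses it, it replaces the worst pose (elitism), so the best score
    never increases.  ``trace``, if given, collects
    (generation, best, mean) tuples for convergence inspection.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if isinstance(rng, (int, np.integer)) or rng is None:
        seed = initial.rng_seed if rng is None else int(rng)
        rng = np.random.default_rng(seed)
    pop = initial
    if not np.all(np.isfinite(pop.scores)):
        pop = Population(
            pop.translations,
            pop.angles,
            energy_fn(pop.translations, pop.angles),
            pop.generation,
            pop.rng_seed,
        )
    best = pop.best()
    if trace is not None:
        trace.append((pop.generation, float(best.score), float(pop.scores.mean())))
    for _ in range(generations):
        pop = crossover_population(pop, rng, energy_fn, max_pairs=max_pairs)
        pop = mutate(
            pop, rng, energy_fn,
            fraction=mutation_fraction, sigma_t=sigma_t, sigma_a=sigma_a,
        )
        if pop.scores.min() > best.score:  # elitist reinsertion
            worst = int(np.argmax(pop.scores))
            pop.translations[worst] = best.translation
            pop.angles[worst] = best.angles
            pop.scores[worst] = best.score
        cur = pop.best()
        if cur.score < best.score:
            best = cur
        if trace is not None:
            trace.append((pop.generation, float(best.score), float(pop.scores.mean())))
        logger.debug(
            "GA generation %d: best %.6f mean %.6f",
            pop.generation, best.score, float(pop.scores.mean()),
        )
    return pop.sorted()
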