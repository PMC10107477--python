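"""Intermolecular scoring backends and screening bias potentials.

The built-in backend scores a rigid pose with a classical pairwise model:
12-6 Lennard-Jones (Lorentz-Berthelot mixing) plus vacuum Coulomb
(332.0637 kcal A mol^-1 e^-2).  Only intermolecular atom pairs contribute;
monomer energies are zero by construction, so the interaction energy of a
complex equals its pair energy.  Distances are clamped at ``R_CAP`` and
coincident atoms receive a finite penalty so that no score is ever
non-finite — genetic optimization must be able to rank any generated pose.

Bias potentials implement user-directed screening: an attractive Gaussian
well pulls the mobile fragment's center of mass toward a chosen site, a
repulsive quadratic wall pushes its atoms back toward a chosen region.
Bias terms enter screening scores only; reported energies are bias-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from . import params
from .molio import Molecule, Pose, center_of_mass, posed_coords

COULOMB_KCAL = 332.0637  # kcal mol^-1 A e^-2
R_CAP = 0.5  # A; pair distances are clamped here (clash cap)
COINCIDENT_R = 1e-6  # A
COINCIDENT_PENALTY = 1.0e4  # kcal mol^-1 per (near-)coincident pair


@dataclass(frozen=True)
class AtomParams:
    """Per-atom parameters of the built-in classical model."""

    lj_epsilon: float  # kcal mol^-1
    lj_sigma: float  # A
    vdw_radius: float  # A
    partial_charge: float = 0.0  # e

    def __post_init__(self) -> None:
        if self.lj_epsilon < 0:
            raise ValueError("lj_epsilon must be >= 0")
        if self.lj_sigma <= 0 or self.vdw_radius <= 0:
            raise ValueError("lj_sigma and vdw_radius must be > 0")


@dataclass
class PreparedFragment:
    """A molecule with per-atom parameter arrays attached (prepared once)."""

    mol: Molecule
    epsilon: np.ndarray
    sigma: np.ndarray
    vdw: np.ndarray
    charges: np.ndarray

    @property
    def coords(self) -> np.ndarray:
        return self.mol.coords

    @property
    def cma(self) -> np.ndarray:
        return center_of_mass(self.mol)

    def with_coords(self, coords: np.ndarray) -> "PreparedFragment":
        return PreparedFragment(
            self.mol.with_coords(coords), self.epsilon, self.sigma, self.vdw, self.charges
        )


def assign_params(
    mol: Molecule, overrides: dict[str, AtomParams] | None = None
) -> list[AtomParams]:
    """Element-keyed parameter assignment.

    Partial charges come from the molecule if present, otherwise the total
    charge is smeared uniformly over all atoms.  ``overrides`` maps element
    symbols to replacement parameters (used heavily by the toy fixtures).
    """
    n = len(mol)
    if mol.partial_charges is not None:
        charges = np.asarray(mol.partial_charges, dtype=float)
    else:
        charges = np.full(n, mol.total_charge / n)
    out = []
    for sym, q in zip(mol.elements, charges):
        if overrides and sym in overrides:
            base = overrides[sym]
            out.append(
                AtomParams(base.lj_epsilon, base.lj_sigma, base.vdw_radius, float(q))
            )
        else:
            sigma, eps = params.lj_parameters(sym)
            out.append(AtomParams(eps, sigma, params.vdw_radius(sym), float(q)))
    return out


class EnergyBackend(Protocol):
    """Contract of an intermolecular scoring backend.

    ``prepare`` is called once per fragment; ``evaluate`` scores fragment A
    against an already-posed copy of fragment B.  Evaluation must be
    deterministic and tend to zero as the fragments separate.
    """

    def prepare(self, mol: Molecule) -> PreparedFragment: ...

    def evaluate(self, a: PreparedFragment, b_posed: PreparedFragment) -> float: ...


class BuiltinBackend:
    """Classical LJ + Coulomb backend (see module docstring)."""

    def __init__(self, overrides: dict[str, AtomParams] | None = None) -> None:
        self.overrides = overrides or {}

    def prepare(self, mol: Molecule) -> PreparedFragment:
        ap = assign_params(mol, self.overrides)
        return PreparedFragment(
            mol=mol,
            epsilon=np.array([p.lj_epsilon for p in ap]),
            sigma=np.array([p.lj_sigma for p in ap]),
            vdw=np.array([p.vdw_radius for p in ap]),
            charges=np.array([p.partial_charge for p in ap]),
        )

    def evaluate(self, a: PreparedFragment, b_posed: PreparedFragment) -> float:
        return pair_energy(a, b_posed)

    def evaluate_poses(
        self, a: PreparedFragment, b: PreparedFragment,
        translations: np.ndarray, angles: np.ndarray,
    ) -> np.ndarray:
        return pose_energies(a, b, translations, angles)


def _pairwise_terms(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Raw and clamped intermolecular distance matrices (nA, nB)."""
    diff = coords_a[:, None, :] - coords_b[None, :, :]
    r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    return r, np.maximum(r, R_CAP)


def _energy_from_distances(
    r: np.ndarray, r_eff: np.ndarray, a: PreparedFragment, b: PreparedFragment
) -> float:
    eps = np.sqrt(a.epsilon[:, None] * b.epsilon[None, :])  # Berthelot
    sig = 0.5 * (a.sigma[:, None] + b.sigma[None, :])  # Lorentz
    sr6 = (sig / r_eff) ** 6
    e_lj = 4.0 * eps * (sr6 * sr6 - sr6)
    e_coul = COULOMB_KCAL * a.charges[:, None] * b.charges[None, :] / r_eff
    penalty = COINCIDENT_PENALTY * np.count_nonzero(r < COINCIDENT_R)
    return float(e_lj.sum() + e_coul.sum() + penalty)


def pair_energy(a: PreparedFragment, b_posed: PreparedFragment) -> float:
    """Intermolecular energy (kcal/mol) between two parameterized fragments."""
    r, r_eff = _pairwise_terms(a.coords, b_posed.coords)
    return _energy_from_distances(r, r_eff, a, b_posed)


def pose_energies(
    a: PreparedFragment,
    b: PreparedFragment,
    translations: np.ndarray,
    angles: np.ndarray,
) -> np.ndarray:
    """Vectorized screening energies for a batch of poses of fragment B."""
    translations = np.atleast_2d(np.asarray(translations, dtype=float))
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    coords = posed_coords(b.coords, b.cma, a.cma, translations, angles)  # (k, nB, 3)
    diff = a.coords[None, :, None, :] - coords[:, None, :, :]  # (k, nA, nB, 3)
    r = np.sqrt(np.einsum("kijx,kijx->kij", diff, diff))
    r_eff = np.maximum(r, R_CAP)
    eps = np.sqrt(a.epsilon[:, None] * b.epsilon[None, :])[None]
    sig = (0.5 * (a.sigma[:, None] + b.sigma[None, :]))[None]
    sr6 = (sig / r_eff) ** 6
    e_lj = 4.0 * eps * (sr6 * sr6 - sr6)
    e_coul = COULOMB_KCAL * (a.charges[:, None] * b.charges[None, :])[None] / r_eff
    penalty = COINCIDENT_PENALTY * np.count_nonzero(r < COINCIDENT_R, axis=(1, 2))
    return e_lj.sum(axis=(1, 2)) + e_coul.sum(axis=(1, 2)) + penalty


_KR_SIGMA, _KR_EPSILON = params.lj_parameters("Kr")


def electrostatic_potential(a: PreparedFragment, point: Sequence[float]) -> float:
    """Coulomb potential of fragment A at a point, in e/A (no 332.0637 factor)."""
    d = np.linalg.norm(a.coords - np.asarray(point, dtype=float), axis=1)
    d = np.maximum(d, R_CAP)
    return float((a.charges / d).sum())


def probe_energy(a: PreparedFragment, point: Sequence[float], q_probe: float) -> float:
    """Energy of a Kr-parameterized probe pseudo-atom at ``point``.

    The probe carries charge ``q_probe`` (the workflow uses 0 and +/-0.1 e).
    """
    point = np.asarray(point, dtype=float).reshape(3)
    d = np.linalg.norm(a.coords - point, axis=1)
    d_eff = np.maximum(d, R_CAP)
    eps = np.sqrt(a.epsilon * _KR_EPSILON)
    sig = 0.5 * (a.sigma + _KR_SIGMA)
    sr6 = (sig / d_eff) ** 6
    e = 4.0 * eps * (sr6 * sr6 - sr6)
    e_coul = COULOMB_KCAL * q_probe * a.charges / d_eff
    penalty = COINCIDENT_PENALTY * np.count_nonzero(d < COINCIDENT_R)
    return float(e.sum() + e_coul.sum() + penalty)


def probe_energies_grid(
    a: PreparedFragment, points: np.ndarray, charges: Sequence[float]
) -> np.ndarray:
    """(n_points, n_charges) probe energies, vectorized over a whole grid."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    diff = points[:, None, :] - a.coords[None, :, :]
    d = np.sqrt(np.einsum("pik,pik->pi", diff, diff))
    d_eff = np.maximum(d, R_CAP)
    eps = np.sqrt(a.epsilon * _KR_EPSILON)[None]
    sig = (0.5 * (a.sigma + _KR_SIGMA))[None]
    sr6 = (sig / d_eff) ** 6
    e_lj = (4.0 * eps * (sr6 * sr6 - sr6)).sum(axis=1)
    esp = (a.charges[None] / d_eff).sum(axis=1)
    penalty = COINCIDENT_PENALTY * np.count_nonzero(d < COINCIDENT_R, axis=1)
    qs = np.asarray(charges, dtype=float)
    return (e_lj + penalty)[:, None] + COULOMB_KCAL * esp[:, None] * qs[None, :]


@dataclass
class BiasSpec:
    """User-directed screening bias.

    ``mode='attractive'``: Gaussian well -strength * exp(-d^2 / range^2)
    where d is the distance of the mobile fragment's CMA to the site.
    ``mode='repulsive'``: quadratic wall
    strength * sum_i max(0, d_i - region_radius)^2 / range^2 over the mobile
    fragment's atoms, pushing them back inside the region.

    The site is either a set of atom indices on the host fragment (its
    centroid is the site point) or an explicit Cartesian point.
    """

    mode: str  # {"attractive", "repulsive"}
    strength: float  # kcal mol^-1
    range: float  # A
    atom_indices: tuple[int, ...] | None = None
    point: tuple[float, float, float] | None = None
    region_radius: float = 3.0  # A, repulsive mode

    def __post_init__(self) -> None:
        if self.mode not in ("attractive", "repulsive"):
            raise ValueError("bias mode must be 'attractive' or 'repulsive'")
        if self.strength <= 0 or self.range <= 0:
            raise ValueError("bias strength and range must be > 0")
        if (self.atom_indices is None) == (self.point is None):
            raise ValueError("exactly one of atom_indices or point must be given")
        if self.mode == "repulsive" and self.region_radius <= 0:
            raise ValueError("region_radius must be > 0")

    def site_point(self, a: Molecule) -> np.ndarray:
        if self.point is not None:
            return np.asarray(self.point, dtype=float).reshape(3)
        idx = np.asarray(self.atom_indices, dtype=int)
        return a.coords[idx].mean(axis=0)


def bias_energy(b_posed: Molecule, bias: BiasSpec, a: Molecule) -> float:
    """Screening-only bias term for one posed copy of the mobile fragment."""
    site = bias.site_point(a)
    if bias.mode == "attractive":
        d = float(np.linalg.norm(center_of_mass(b_posed) - site))
        return -bias.strength * float(np.exp(-(d * d) / (bias.range**2)))
    d = np.linalg.norm(b_posed.coords - site, axis=1)
    over = np.maximum(0.0, d - bias.region_radius)
    return bias.strength * float((over * over).sum()) / (bias.range**2)


def bias_energies_batch(
    b: PreparedFragment,
    bias: BiasSpec,
    a: PreparedFragment,
    translations: np.ndarray,
    angles: np.ndarray,
) -> np.ndarray:
    """Vectorized bias terms for a batch of poses."""
    site = bias.site_point(a.mol)
    translations = np.atleast_2d(np.asarray(translations, dtype=float))
    if bias.mode == "attractive":
        cma_b = a.cma + translations  # rotation about B's own CMA keeps it fixed
        d2 = ((cma_b - site) ** 2).sum(axis=1)
        return -bias.strength * np.exp(-d2 / bias.range**2)
    coords = posed_coords(b.coords, b.cma, a.cma, translations, np.atleast_2d(angles))
    d = np.linalg.norm(coords - site, axis=2)
    over = np.maximum(0.0, d - bias.region_radius)
    return bias.strength * (over * over).sum(axis=1) / bias.range**2


def interaction_energy(e_ab: float, e_a: float, e_b: float) -> float:
    """E_int = E(AB) - E(A) - E(B)."""
    for v in (e_ab, e_a, e_b):
        if not np.isfinite(v):
            raise ValueError("interaction_energy requires finite energies")
    return e_ab - e_a - e_b
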