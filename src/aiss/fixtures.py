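"""Deterministic toy-system generators for tests and examples.

Every system the test suite needs is generated programmatically: single
Lennard-Jones atoms, seeded LJ clusters, planar six-membered rings, hollow
spherical cage hosts, point ions and random blobs.  Pseudo-atoms reuse real
element symbols; their LJ parameters are controlled exactly through the
parameter-override hook of the built-in backend (``overrides_for``), so the
closed-form optima below are exact for the model being tested.

By construction the probe/vdW radius of an overridden LJ species is chosen
so that van-der-Waals contact (0.9 x sum of radii) coincides with the LJ
minimum distance 2^(1/6) sigma — contact-placed poses then start at the
analytic optimum of the toy model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .energy import AtomParams, COULOMB_KCAL, R_CAP
from .molio import Molecule
from .search import fibonacci_sphere

TWO_POW_SIXTH = 2.0 ** (1.0 / 6.0)

KINDS = ("lj_atom", "lj_cluster", "planar_ring", "cage_host", "point_ion", "random_blob")


@dataclass
class FixtureSpec:
    """Declarative description of a toy system."""

    kind: str
    seed: int = 0
    element: str = "Kr"
    sigma: float = 3.4  # A, LJ override
    epsilon: float = 0.24  # kcal/mol, LJ override
    n_atoms: int = 5  # lj_cluster / random_blob
    min_spacing: float = 3.8  # A, lj_cluster / random_blob
    ring_radius: float = 1.39  # A, planar_ring
    shell_radius: float = 6.0  # A, cage_host
    shell_atoms: int = 60  # cage_host
    charge: float = 1.0  # e, point_ion
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")
        if self.sigma <= 0 or self.epsilon < 0:
            raise ValueError("sigma must be > 0 and epsilon >= 0")
        if self.n_atoms < 1 or self.shell_atoms < 4:
            raise ValueError("invalid atom counts")


def _contact_radius(sigma: float, contact_scale: float = 0.9) -> float:
    """vdW radius such that contact_scale * 2r equals the LJ minimum."""
    return TWO_POW_SIXTH * sigma / (2.0 * contact_scale)


def overrides_for(spec: FixtureSpec) -> dict[str, AtomParams]:
    """Parameter overrides that give the fixture its exact sigma/epsilon."""
    return {
        spec.element: AtomParams(
            lj_epsilon=spec.epsilon,
            lj_sigma=spec.sigma,
            vdw_radius=_contact_radius(spec.sigma),
        )
    }


def make_fixture(spec: FixtureSpec) -> Molecule:
    """Build the molecule a :class:`FixtureSpec` describes (seed-deterministic)."""
    center = np.asarray(spec.center, dtype=float)
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "lj_atom":
        return Molecule([spec.element], center[None, :])
    if spec.kind == "point_ion":
        return Molecule(
            ["Na"], center[None, :],
            total_charge=int(round(spec.charge)),
            partial_charges=np.array([spec.charge]),
        )
    if spec.kind == "planar_ring":
        ang = 2.0 * math.pi * np.arange(6) / 6.0
        coords = np.column_stack(
            [spec.ring_radius * np.cos(ang), spec.ring_radius * np.sin(ang), np.zeros(6)]
        )
        return Molecule(["C"] * 6, coords + center)
    if spec.kind == "cage_host":
        coords = spec.shell_radius * fibonacci_sphere(spec.shell_atoms)
        return Molecule([spec.element] * spec.shell_atoms, coords + center)
    # seeded clusters with a minimum-spacing rejection loop
    coords = [np.zeros(3)]
    box = spec.min_spacing * max(1.5, spec.n_atoms ** (1.0 / 3.0))
    while len(coords) < spec.n_atoms:
        cand = rng.uniform(-box, box, size=3)
        if all(np.linalg.norm(cand - c) >= spec.min_spacing for c in coords):
            coords.append(cand)
    coords = np.array(coords) - np.mean(coords, axis=0)
    element = spec.element if spec.kind == "lj_cluster" else "C"
    return Molecule([element] * spec.n_atoms, coords + center)


def analytic_optimum(kind: str, **params) -> tuple[float, float]:
    """Closed-form (distance, energy) optimum of a two-body toy system.

    ``lj_dimer``: Lorentz-Berthelot mixed 12-6 minimum at 2^(1/6) sigma_mix
    with depth -eps_mix.  ``coulomb_pair`` (epsilon = 0): monotone Coulomb
    attraction, reported at the backend's clash-cap boundary.
    """
    if kind == "lj_dimer":
        sigma_a = params["sigma_a"]
        eps_a = params["eps_a"]
        sigma_b = params.get("sigma_b", sigma_a)
        eps_b = params.get("eps_b", eps_a)
        sigma_mix = 0.5 * (sigma_a + sigma_b)
        eps_mix = math.sqrt(eps_a * eps_b)
        return TWO_POW_SIXTH * sigma_mix, -eps_mix
    if kind == "coulomb_pair":
        q1, q2 = params["q1"], params["q2"]
        if q1 * q2 >= 0:
            raise ValueError("coulomb_pair optimum requires opposite charges")
        return R_CAP, COULOMB_KCAL * q1 * q2 / R_CAP
    raise ValueError(f"unsupported analytic optimum kind {kind!r}")
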