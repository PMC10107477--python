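"""Molecule data model, XYZ/PDB I/O and rigid-body geometry primitives.

Coordinates are Cartesian Angstrom throughout.  A :class:`Pose` places a
rigid mobile fragment B relative to a host fragment A through the
displacement of B's center of mass (CMA) from A's CMA plus three Euler
angles.  The Euler convention used everywhere in this package is intrinsic
z-y'-z'' (alpha, beta, gamma):

    R(alpha, beta, gamma) = Rz(alpha) @ Ry(beta) @ Rz(gamma)

which coincides with scipy's ``Rotation.from_euler("ZYZ", ...)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import params

TWO_PI = 2.0 * math.pi


class FormatError(ValueError):
    """Malformed structure file."""


@dataclass
class Molecule:
    """A rigid molecular fragment.

    Parameters
    ----------
    elements
        Element symbols, one per atom (Z <= 86; D/T accepted for hydrogen
        isotopes).
    coords
        (N, 3) Cartesian coordinates in Angstrom.
    total_charge
        Total charge in units of e.
    n_unpaired
        Number of unpaired electrons.
    partial_charges
        Optional per-atom charges; must sum to ``total_charge``.
    atomic_masses
        Optional per-atom masses in amu; defaults to standard atomic weights.
    fixed_mask
        Optional per-atom boolean flags marking atoms that must not move
        during refinement.
    """

    elements: list[str]
    coords: np.ndarray
    total_charge: int = 0
    n_unpaired: int = 0
    partial_charges: np.ndarray | None = None
    atomic_masses: np.ndarray | None = None
    fixed_mask: np.ndarray | None = None
    comment: str = ""

    def __post_init__(self) -> None:
        self.elements = [str(e) for e in self.elements]
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = len(self.elements)
        if n < 1:
            raise ValueError("a molecule must contain at least one atom")
        if self.coords.shape != (n, 3):
            raise ValueError(
                f"coordinate shape {self.coords.shape} does not match {n} elements"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for sym in self.elements:
            z = params.atomic_number(sym)
            if z > params.MAX_Z:
                raise ValueError(
                    f"element {sym!r} (Z={z}) beyond supported range (Z <= {params.MAX_Z})"
                )
        if self.atomic_masses is None:
            self.atomic_masses = np.array(
                [params.atomic_mass(s) for s in self.elements]
            )
        else:
            self.atomic_masses = np.asarray(self.atomic_masses, dtype=float)
            if self.atomic_masses.shape != (n,):
                raise ValueError("atomic_masses length mismatch")
        if np.any(self.atomic_masses <= 0):
            raise ValueError("atomic masses must be strictly positive")
        if self.partial_charges is not None:
            self.partial_charges = np.asarray(self.partial_charges, dtype=float)
            if self.partial_charges.shape != (n,):
                raise ValueError("partial_charges length mismatch")
            if abs(float(self.partial_charges.sum()) - self.total_charge) > 1e-6:
                raise ValueError(
                    "partial charges must sum to the total charge within 1e-6 e"
                )
        if self.fixed_mask is not None:
            self.fixed_mask = np.asarray(self.fixed_mask, dtype=bool)
            if self.fixed_mask.shape != (n,):
                raise ValueError("fixed_mask length mismatch")

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def with_coords(self, coords: np.ndarray) -> "Molecule":
        return replace(self, coords=np.asarray(coords, dtype=float))

    def translated(self, shift: Sequence[float]) -> "Molecule":
        return self.with_coords(self.coords + np.asarray(shift, dtype=float))

    def vdw_radii(self) -> np.ndarray:
        return np.array([params.vdw_radius(s) for s in self.elements])


@dataclass
class Pose:
    """6-DOF rigid placement of a mobile fragment relative to a host.

    ``translation`` is the CMA displacement of the mobile fragment from the
    host's CMA (Angstrom); ``angles`` are intrinsic z-y'-z'' Euler angles,
    stored normalized to [0, 2*pi).  ``score`` is the screening energy
    (kcal/mol for the built-in backend); ``nan`` means not yet evaluated.
    """

    translation: np.ndarray
    angles: np.ndarray
    score: float = math.nan

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.angles = normalize_angles(np.asarray(self.angles, dtype=float).reshape(3))

    @property
    def evaluated(self) -> bool:
        return math.isfinite(self.score)

    def copy(self) -> "Pose":
        return Pose(self.translation.copy(), self.angles.copy(), self.score)


def normalize_angles(angles: np.ndarray) -> np.ndarray:
    """Wrap angles into [0, 2*pi)."""
    out = np.mod(angles, TWO_PI)
    # mod can return 2*pi for tiny negative inputs due to rounding
    out[out >= TWO_PI] = 0.0
    return out


def center_of_mass(mol: Molecule) -> np.ndarray:
    m = mol.atomic_masses
    return (m[:, None] * mol.coords).sum(axis=0) / m.sum()


def euler_rotation_matrix(angles: Sequence[float]) -> np.ndarray:
    """Rotation matrix for intrinsic z-y'-z'' Euler angles (alpha, beta, gamma)."""
    a, b, g = (float(x) for x in np.asarray(angles, dtype=float).reshape(3))
    ca, sa = math.cos(a), math.sin(a)
    cb, sb = math.cos(b), math.sin(b)
    cg, sg = math.cos(g), math.sin(g)
    return np.array(
        [
            [ca * cb * cg - sa * sg, -ca * cb * sg - sa * cg, ca * sb],
            [sa * cb * cg + ca * sg, -sa * cb * sg + ca * cg, sa * sb],
            [-sb * cg, sb * sg, cb],
        ]
    )


def euler_rotation_matrices(angles: np.ndarray) -> np.ndarray:
    """Vectorized form: (k, 3) angle triples -> (k, 3, 3) rotation matrices."""
    angles = np.asarray(angles, dtype=float).reshape(-1, 3)
    a, b, g = angles[:, 0], angles[:, 1], angles[:, 2]
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    r = np.empty((len(angles), 3, 3))
    r[:, 0, 0] = ca * cb * cg - sa * sg
    r[:, 0, 1] = -ca * cb * sg - sa * cg
    r[:, 0, 2] = ca * sb
    r[:, 1, 0] = sa * cb * cg + ca * sg
    r[:, 1, 1] = -sa * cb * sg + ca * cg
    r[:, 1, 2] = sa * sb
    r[:, 2, 0] = -sb * cg
    r[:, 2, 1] = sb * sg
    r[:, 2, 2] = cb
    return r


def euler_angles_from_matrix(matrix: np.ndarray) -> np.ndarray:
    """Inverse of :func:`euler_rotation_matrix`, normalized to [0, 2*pi)."""
    import warnings

    from scipy.spatial.transform import Rotation

    with warnings.catch_warnings():
        # at beta = 0 the z-y'-z'' chart is degenerate; any representative works
        warnings.simplefilter("ignore", UserWarning)
        ang = Rotation.from_matrix(np.asarray(matrix, dtype=float)).as_euler("ZYZ")
    return normalize_angles(ang)


def apply_pose(frag_b: Molecule, pose: Pose, cma_a: Sequence[float]) -> Molecule:
    """Rigidly place fragment B: rotate about its own CMA, then translate so
    CMA(B) = cma_a + pose.translation."""
    cma_a = np.asarray(cma_a, dtype=float).reshape(3)
    cma_b = center_of_mass(frag_b)
    rot = euler_rotation_matrix(pose.angles)
    coords = (frag_b.coords - cma_b) @ rot.T + cma_a + pose.translation
    return frag_b.with_coords(coords)


def posed_coords(
    coords_b: np.ndarray,
    cma_b: np.ndarray,
    cma_a: np.ndarray,
    translations: np.ndarray,
    angles: np.ndarray,
) -> np.ndarray:
    """Batch pose application: (k,3) translations/angles -> (k, nB, 3) coords."""
    rots = euler_rotation_matrices(angles)
    local = coords_b - cma_b  # (nB, 3)
    rotated = np.einsum("kij,nj->kni", rots, local)
    return rotated + (cma_a + np.atleast_2d(translations))[:, None, :]


# ---------------------------------------------------------------------------
# file I/O


def _parse_comment_metadata(comment: str) -> tuple[int, int]:
    charge, uhf = 0, 0
    for tok in comment.split():
        low = tok.lower()
        if low.startswith("charge="):
            charge = int(round(float(tok.split("=", 1)[1])))
        elif low.startswith("uhf="):
            uhf = int(round(float(tok.split("=", 1)[1])))
    return charge, uhf


def read_xyz(path: str | Path) -> Molecule:
    """Read a standard XYZ file (first frame).

    The comment line may carry ``charge=<int>`` and ``uhf=<int>`` tokens,
    which populate total charge and number of unpaired electrons.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError(f"{path}: line 1: malformed atom-count line {lines[0]!r}")
    if n < 1:
        raise FormatError(f"{path}: line 1: atom count must be >= 1")
    comment = lines[1] if len(lines) > 1 else ""
    elements: list[str] = []
    coords = np.empty((n, 3))
    for i in range(n):
        lineno = i + 3
        if i + 2 >= len(lines) or not lines[i + 2].strip():
            raise FormatError(
                f"{path}: line {max(len(lines), 1)}: expected {n} atom records, "
                "file ends early"
            )
        parts = lines[i + 2].split()
        if len(parts) < 4:
            raise FormatError(f"{path}: line {lineno}: expected 'element x y z'")
        sym = parts[0].capitalize() if len(parts[0]) <= 2 else parts[0]
        try:
            params.atomic_number(sym)
        except params.ParameterizationError:
            raise FormatError(
                f"{path}: line {lineno}: unknown element symbol {parts[0]!r}"
            )
        try:
            coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
        except ValueError:
            raise FormatError(f"{path}: line {lineno}: could not parse coordinates")
        elements.append(sym)
    charge, uhf = _parse_comment_metadata(comment)
    return Molecule(
        elements=elements,
        coords=coords,
        total_charge=charge,
        n_unpaired=uhf,
        comment=comment,
    )


def write_xyz(mol: Molecule, path: str | Path, comment: str | None = None) -> Path:
    """Write a molecule as standard XYZ (10 printed decimals)."""
    path = Path(path)
    path.write_text(format_xyz(mol, comment))
    return path


def format_xyz(mol: Molecule, comment: str | None = None) -> str:
    if comment is None:
        comment = f"charge={mol.total_charge} uhf={mol.n_unpaired}"
    lines = [str(mol.n_atoms), comment]
    for sym, (x, y, z) in zip(mol.elements, mol.coords):
        lines.append(f"{sym:<3s} {x:20.10f} {y:20.10f} {z:20.10f}")
    return "\n".join(lines) + "\n"


def write_multi_xyz(
    mols: Sequence[Molecule], path: str | Path, comments: Sequence[str] | None = None
) -> Path:
    """Concatenate structures into a multi-frame XYZ ensemble file."""
    path = Path(path)
    blocks = []
    for i, mol in enumerate(mols):
        comment = comments[i] if comments is not None else None
        blocks.append(format_xyz(mol, comment))
    path.write_text("".join(blocks))
    return path


def read_pdb(path: str | Path) -> Molecule:
    """Read ATOM/HETATM records from a PDB file (coordinates and elements only)."""
    import gemmi

    st = gemmi.read_structure(str(path))
    elements: list[str] = []
    coords: list[list[float]] = []
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    elements.append(atom.element.name)
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # first model only
    if not elements:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    return Molecule(elements=elements, coords=np.array(coords))


def merge(a: Molecule, b: Molecule) -> Molecule:
    """Concatenate two fragments (A first) into one molecule."""
    pc = None
    if a.partial_charges is not None or b.partial_charges is not None:
        pa = a.partial_charges if a.partial_charges is not None else np.zeros(len(a))
        pb = b.partial_charges if b.partial_charges is not None else np.zeros(len(b))
        pc = np.concatenate([pa, pb])
    fm = None
    if a.fixed_mask is not None or b.fixed_mask is not None:
        fa = a.fixed_mask if a.fixed_mask is not None else np.zeros(len(a), bool)
        fb = b.fixed_mask if b.fixed_mask is not None else np.zeros(len(b), bool)
        fm = np.concatenate([fa, fb])
    return Molecule(
        elements=a.elements + b.elements,
        coords=np.vstack([a.coords, b.coords]),
        total_charge=a.total_charge + b.total_charge,
        n_unpaired=a.n_unpaired + b.n_unpaired,
        partial_charges=pc,
        atomic_masses=np.concatenate([a.atomic_masses, b.atomic_masses]),
        fixed_mask=fm,
    )
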