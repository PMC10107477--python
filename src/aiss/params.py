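"""Element data for the built-in classical scoring backend.

Masses and van der Waals / covalent radii come from rdkit's periodic table.
Lennard-Jones well parameters are a bundled UFF-style table of
(r_min / Angstrom, well depth / kcal mol^-1) for common elements; any other
element up to radon (Z <= 86) falls back to a radius-derived sigma with a
generic 0.1 kcal/mol depth.  The backend is a classical stand-in and makes
no claim of numerical agreement with tight-binding interaction force fields.
"""

from __future__ import annotations

from functools import lru_cache

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

_PT = Chem.GetPeriodicTable()

MAX_Z = 86  # elements up to radon

# isotopes rdkit's symbol lookup does not know
_ISOTOPE_MASS = {"D": 2.014, "T": 3.016}

TWO_POW_SIXTH = 2.0 ** (1.0 / 6.0)

# UFF-style nonbonded parameters: symbol -> (x = pair r_min, D = well depth)
UFF_LJ: dict[str, tuple[float, float]] = {
    "H": (2.886, 0.044),
    "He": (2.362, 0.056),
    "B": (4.083, 0.180),
    "C": (3.851, 0.105),
    "N": (3.660, 0.069),
    "O": (3.500, 0.060),
    "F": (3.364, 0.050),
    "Ne": (3.243, 0.042),
    "Na": (2.983, 0.030),
    "Mg": (3.021, 0.111),
    "Al": (4.499, 0.505),
    "Si": (4.295, 0.402),
    "P": (4.147, 0.305),
    "S": (4.035, 0.274),
    "Cl": (3.947, 0.227),
    "Ar": (3.868, 0.185),
    "K": (3.812, 0.035),
    "Ca": (3.399, 0.238),
    "Fe": (2.912, 0.013),
    "Cu": (3.495, 0.005),
    "Zn": (2.763, 0.124),
    "Br": (4.189, 0.251),
    "Kr": (4.141, 0.220),
    "Pd": (2.899, 0.048),
    "Ag": (3.148, 0.036),
    "I": (4.009, 0.339),
    "Xe": (4.404, 0.332),
    "Pt": (2.754, 0.080),
    "Au": (3.293, 0.039),
    "Hg": (2.705, 0.385),
    "Pb": (4.297, 0.663),
    "Rn": (4.765, 0.248),
}


class ParameterizationError(KeyError):
    """Raised when an element cannot be parameterized."""


@lru_cache(maxsize=None)
def atomic_number(symbol: str) -> int:
    base = "H" if symbol in _ISOTOPE_MASS else symbol
    try:
        z = _PT.GetAtomicNumber(base)
    except Exception as exc:  # rdkit raises a boost RuntimeError
        raise ParameterizationError(f"unknown element symbol {symbol!r}") from exc
    if z < 1:
        raise ParameterizationError(f"unknown element symbol {symbol!r}")
    return z


def atomic_mass(symbol: str) -> float:
    if symbol in _ISOTOPE_MASS:
        return _ISOTOPE_MASS[symbol]
    atomic_number(symbol)
    return float(_PT.GetAtomicWeight(symbol))


def vdw_radius(symbol: str) -> float:
    base = "H" if symbol in _ISOTOPE_MASS else symbol
    atomic_number(base)
    return float(_PT.GetRvdw(base))


def covalent_radius(symbol: str) -> float:
    base = "H" if symbol in _ISOTOPE_MASS else symbol
    atomic_number(base)
    return float(_PT.GetRcovalent(base))


def lj_parameters(symbol: str) -> tuple[float, float]:
    """(sigma / Angstrom, epsilon / kcal mol^-1) for one element.

    sigma is the zero-crossing distance of the like-pair 12-6 potential,
    i.e. r_min / 2^(1/6).
    """
    base = "H" if symbol in _ISOTOPE_MASS else symbol
    z = atomic_number(base)
    if z > MAX_Z:
        raise ParameterizationError(
            f"element {symbol!r} (Z={z}) beyond supported range (Z <= {MAX_Z})"
        )
    if base in UFF_LJ:
        x, d = UFF_LJ[base]
        return x / TWO_POW_SIXTH, d
    # fallback: LJ minimum at vdW contact distance, generic shallow well
    return 2.0 * vdw_radius(base) / TWO_POW_SIXTH, 0.1
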