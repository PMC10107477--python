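"""Interaction-site pre-screening and the three deterministic pose generators.

The pre-screen probes a shell grid around the host fragment A with a neutral
and artificially +/-0.1 e charged Kr pseudo-atom, ranking candidate
interaction sites by their best probe energy.  Three generators then build
rigid poses of the mobile fragment B:

* pocket search — buried grid points (high fraction of occluded ray
  directions) are clustered and B is placed at each cluster center;
* stacking search — planar ring moieties are detected on both fragments and
  B's ring is stacked face-to-face over A's ring at scanned offsets, twists
  and parallel displacements;
* angular grid search — B slides to van-der-Waals contact along
  quasi-uniform directions around A, plus direct placements at the best
  probe sites.

All generators are deterministic given their configuration; randomness
enters the workflow only in the genetic optimization stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from . import params
from .energy import PreparedFragment, probe_energies_grid
from .molio import (
    Molecule,
    Pose,
    center_of_mass,
    euler_angles_from_matrix,
    euler_rotation_matrices,
)

logger = logging.getLogger(__name__)

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass
class ProbeSite:
    """One ranked probe position from the pre-screen."""

    point: np.ndarray  # (3,) A
    best_charge: float  # e, the probe charge giving the lowest energy
    energy: float  # kcal mol^-1
    burial: float  # fraction of ray directions occluded by fragment A


@dataclass
class PlanarMoiety:
    """A planar ring system (>= 5 atoms, RMS out-of-plane < 0.1 A)."""

    atom_indices: tuple[int, ...]
    centroid: np.ndarray
    normal: np.ndarray


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors (deterministic Fibonacci lattice)."""
    if n < 1:
        return np.zeros((0, 3))
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = GOLDEN_ANGLE * i
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _rotation_to(v: np.ndarray) -> np.ndarray:
    """Proper rotation taking the z axis onto unit vector v."""
    ez = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(ez, v))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(ez, v)
    axis /= np.linalg.norm(axis)
    angle = math.acos(max(-1.0, min(1.0, c)))
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + math.sin(angle) * k + (1.0 - math.cos(angle)) * (k @ k)


_ICOSA_VERTICES = None


def _icosahedron_vertices() -> np.ndarray:
    global _ICOSA_VERTICES
    if _ICOSA_VERTICES is None:
        phi = (1.0 + math.sqrt(5.0)) / 2.0
        v = []
        for a in (1.0, -1.0):
            for b in (phi, -phi):
                v += [(0.0, a, b), (a, b, 0.0), (b, 0.0, a)]
        v = np.array(v)
        _ICOSA_VERTICES = v / np.linalg.norm(v, axis=1, keepdims=True)
    return _ICOSA_VERTICES


def orientation_set(n: int = 12) -> np.ndarray:
    """(n, 3) Euler-angle triples of a fixed quasi-uniform rotation list.

    For n <= 12 the rotations map the z axis onto the icosahedron vertices;
    larger sets fall back to a Fibonacci direction lattice with a
    golden-angle twist about each direction.
    """
    if n < 1:
        return np.zeros((0, 3))
    dirs = _icosahedron_vertices()[:n] if n <= 12 else fibonacci_sphere(n)
    angles = np.empty((len(dirs), 3))
    for i, v in enumerate(dirs):
        rot = _rotation_to(v)
        if n > 12:  # extra in-place twist for variety in large sets
            c, s = math.cos(GOLDEN_ANGLE * i), math.sin(GOLDEN_ANGLE * i)
            twist = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
            rot = rot @ twist
        angles[i] = euler_angles_from_matrix(rot)
    return angles


# ---------------------------------------------------------------------------
# probe grid and pre-screen


def build_probe_grid(
    a: PreparedFragment, spacing: float = 0.5, margin: float = 3.0
) -> np.ndarray:
    """Shell grid of candidate probe points around fragment A.

    A regular Cartesian grid over A's bounding box expanded by ``margin``
    is filtered to points outside every atom's van-der-Waals sphere but
    within ``margin`` of at least one such sphere surface.
    """
    if spacing <= 0 or margin <= 0:
        raise ValueError("spacing and margin must be > 0")
    lo = a.coords.min(axis=0) - margin
    hi = a.coords.max(axis=0) + margin
    axes = [np.arange(lo[d], hi[d] + 0.5 * spacing, spacing) for d in range(3)]
    # degenerate spacing: always keep at least the box corners
    axes = [ax if len(ax) > 1 else np.array([lo[d], hi[d]]) for d, ax in enumerate(axes)]
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    keep = np.zeros(len(pts), dtype=bool)
    chunk = 65536
    for s in range(0, len(pts), chunk):
        block = pts[s : s + chunk]
        diff = block[:, None, :] - a.coords[None, :, :]
        d = np.sqrt(np.einsum("pik,pik->pi", diff, diff))
        gap = d - a.vdw[None, :]
        keep[s : s + chunk] = np.all(gap > 0.0, axis=1) & (gap.min(axis=1) < margin)
    return pts[keep]


def burial_fractions(
    points: np.ndarray,
    a: PreparedFragment,
    n_rays: int = 64,
    cutoff: float = 8.0,
) -> np.ndarray:
    """Fraction of ray directions from each point that hit fragment A.

    A ray hits if it intersects any atom's vdW sphere within ``cutoff`` A.
    Convex exteriors score well below 1; cavity interiors approach 1.
    """
    points = np.atleast_2d(points)
    if len(points) == 0:
        return np.zeros(0)
    dirs = fibonacci_sphere(n_rays)  # (r, 3)
    out = np.empty(len(points))
    chunk = max(1, int(2_000_000 / max(1, len(a.coords) * n_rays)))
    for s in range(0, len(points), chunk):
        block = points[s : s + chunk]
        vec = a.coords[None, :, :] - block[:, None, :]  # (p, n, 3)
        d2 = np.einsum("pnk,pnk->pn", vec, vec)
        proj = np.einsum("pnk,rk->pnr", vec, dirs)  # (p, n, r)
        perp2 = d2[:, :, None] - proj**2
        hit = (
            (proj > 0.0)
            & (proj <= cutoff)
            & (perp2 < (a.vdw**2)[None, :, None])
        )
        out[s : s + chunk] = hit.any(axis=1).mean(axis=1)
    return out


def probe_prescreen(
    a: PreparedFragment,
    grid: np.ndarray,
    charges: Sequence[float] = (0.0, 0.1, -0.1),
    n_rays: int = 64,
    burial_cutoff: float = 8.0,
) -> list[ProbeSite]:
    """Rank grid points by their best Kr-probe energy over the probe charges."""
    grid = np.atleast_2d(grid) if len(grid) else np.zeros((0, 3))
    if len(grid) == 0:
        logger.warning("probe pre-screen received an empty grid")
        return []
    energies = probe_energies_grid(a, grid, charges)  # (p, q)
    best_q = np.argmin(energies, axis=1)
    best_e = energies[np.arange(len(grid)), best_q]
    burial = burial_fractions(grid, a, n_rays=n_rays, cutoff=burial_cutoff)
    order = np.argsort(best_e, kind="stable")
    qs = np.asarray(charges, dtype=float)
    return [
        ProbeSite(
            point=grid[i].copy(),
            best_charge=float(qs[best_q[i]]),
            energy=float(best_e[i]),
            burial=float(burial[i]),
        )
        for i in order
    ]


def probe_sites_to_xyz(sites: Sequence[ProbeSite]) -> Molecule:
    """Export ranked probe sites as Kr pseudo-atoms for visual inspection."""
    if not sites:
        raise ValueError("no probe sites to export")
    return Molecule(
        elements=["Kr"] * len(sites),
        coords=np.array([s.point for s in sites]),
    )


# ---------------------------------------------------------------------------
# clash filtering and contact sliding


def clash_free_mask(
    a: PreparedFragment,
    b: PreparedFragment,
    translations: np.ndarray,
    angles: np.ndarray,
    clash_scale: float = 0.7,
) -> np.ndarray:
    """True for poses whose closest intermolecular contact stays above
    ``clash_scale`` times the sum of vdW radii."""
    from .molio import posed_coords

    translations = np.atleast_2d(translations)
    angles = np.atleast_2d(angles)
    coords = posed_coords(b.coords, b.cma, a.cma, translations, angles)
    diff = a.coords[None, :, None, :] - coords[:, None, :, :]
    r = np.sqrt(np.einsum("kijx,kijx->kij", diff, diff))
    limit = clash_scale * (a.vdw[:, None] + b.vdw[None, :])
    return np.all(r > limit[None], axis=(1, 2))


def contact_distance(
    a: PreparedFragment,
    b_local: np.ndarray,
    b_vdw: np.ndarray,
    direction: np.ndarray,
    contact_scale: float = 0.9,
) -> float | None:
    """Largest CMA distance along ``direction`` at which an oriented copy of
    B first touches A (any pair at ``contact_scale`` x sum of vdW radii).

    ``b_local`` holds B's atom offsets from its CMA, already rotated.
    Returns None if B never touches A along this direction.
    """
    # pair (i, j) touches when |(a_i - cma_a - b_j) - d u| = c_ij
    w = (a.coords - a.cma)[:, None, :] - b_local[None, :, :]  # (nA, nB, 3)
    c = contact_scale * (a.vdw[:, None] + b_vdw[None, :])
    wu = np.einsum("ijk,k->ij", w, direction)
    disc = wu**2 - np.einsum("ijk,ijk->ij", w, w) + c**2
    ok = disc >= 0.0
    if not ok.any():
        return None
    roots = wu[ok] + np.sqrt(disc[ok])
    return float(roots.max())


# ---------------------------------------------------------------------------
# generators

ScoreFn = Callable[[np.ndarray, np.ndarray], np.ndarray]


def _scored_poses(
    translations: np.ndarray, angles: np.ndarray, score_fn: ScoreFn
) -> list[Pose]:
    if len(translations) == 0:
        return []
    scores = score_fn(translations, angles)
    return [
        Pose(t, a, float(s)) for t, a, s in zip(translations, angles, scores)
    ]


def pocket_search(
    a: PreparedFragment,
    b: PreparedFragment,
    score_fn: ScoreFn,
    grid: np.ndarray | None = None,
    burial: np.ndarray | None = None,
    burial_threshold: float = 0.6,
    cluster_distance: float = 2.0,
    n_orientations: int = 12,
    clash_scale: float = 0.7,
    grid_spacing: float = 0.5,
    grid_margin: float = 3.0,
    n_rays: int = 64,
    burial_cutoff: float = 8.0,
) -> list[Pose]:
    """Place B at the centers of buried (concave) regions of A.

    Grid points whose burial fraction exceeds the threshold are clustered by
    single linkage; each cluster center is tried with a fixed orientation
    set, keeping clash-free poses.  Convex hosts yield an empty list.
    """
    if grid is None:
        grid = build_probe_grid(a, grid_spacing, grid_margin)
    if len(grid) == 0:
        return []
    if burial is None:
        burial = burial_fractions(grid, a, n_rays=n_rays, cutoff=burial_cutoff)
    pts = grid[burial > burial_threshold]
    if len(pts) == 0:
        return []
    # single-linkage clustering = connected components of the contact graph
    tree = cKDTree(pts)
    pairs = tree.query_pairs(cluster_distance, output_type="ndarray")
    adj = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(len(pts), len(pts))
    )
    n_comp, labels = connected_components(adj, directed=False)
    centers = np.array([pts[labels == c].mean(axis=0) for c in range(n_comp)])
    orientations = orientation_set(n_orientations)
    trans = np.repeat(centers - a.cma, len(orientations), axis=0)
    angs = np.tile(orientations, (len(centers), 1))
    ok = clash_free_mask(a, b, trans, angs, clash_scale)
    return _scored_poses(trans[ok], angs[ok], score_fn)


def _bond_graph(mol: Molecule, scale: float = 1.2) -> nx.Graph:
    rcov = np.array([params.covalent_radius(s) for s in mol.elements])
    tree = cKDTree(mol.coords)
    g = nx.Graph()
    g.add_nodes_from(range(len(mol)))
    maxr = 2.0 * scale * rcov.max() if len(mol) else 0.0
    for i, j in tree.query_pairs(maxr):
        d = float(np.linalg.norm(mol.coords[i] - mol.coords[j]))
        if d < scale * (rcov[i] + rcov[j]):
            g.add_edge(i, j)
    return g


def _plane_fit(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    centroid = coords.mean(axis=0)
    _, svals, vt = np.linalg.svd(coords - centroid)
    normal = vt[-1]
    rms = float(np.sqrt((((coords - centroid) @ normal) ** 2).mean()))
    return centroid, normal, rms


def detect_planar_moieties(
    mol: Molecule,
    ring_sizes: tuple[int, int] = (5, 7),
    planarity_rms: float = 0.1,
    merge_angle_deg: float = 15.0,
) -> list[PlanarMoiety]:
    """Find planar ring systems on a covalent-distance bond graph.

    Rings of 5-7 atoms from the cycle basis are kept if their RMS
    out-of-plane deviation is below ``planarity_rms``; fused coplanar rings
    (sharing atoms, normals within ``merge_angle_deg``) merge into one
    moiety.
    """
    g = _bond_graph(mol)
    rings: list[set[int]] = []
    normals: list[np.ndarray] = []
    for cyc in nx.cycle_basis(g):
        if not ring_sizes[0] <= len(cyc) <= ring_sizes[1]:
            continue
        coords = mol.coords[list(cyc)]
        _, normal, rms = _plane_fit(coords)
        if rms < planarity_rms:
            rings.append(set(cyc))
            normals.append(normal)
    # merge fused coplanar rings
    cos_tol = math.cos(math.radians(merge_angle_deg))
    merged = True
    while merged:
        merged = False
        for i in range(len(rings)):
            for j in range(i + 1, len(rings)):
                if rings[i] & rings[j] and abs(float(np.dot(normals[i], normals[j]))) > cos_tol:
                    union = rings[i] | rings[j]
                    coords = mol.coords[sorted(union)]
                    _, normal, rms = _plane_fit(coords)
                    if rms < planarity_rms:
                        rings[i] = union
                        normals[i] = normal
                        del rings[j], normals[j]
                        merged = True
                        break
            if merged:
                break
    out = []
    for ring in rings:
        idx = tuple(sorted(ring))
        if len(idx) < 5:
            continue
        centroid, normal, _ = _plane_fit(mol.coords[list(idx)])
        out.append(PlanarMoiety(idx, centroid, normal))
    return out


def stack_search(
    a: PreparedFragment,
    b: PreparedFragment,
    score_fn: ScoreFn,
    offsets: np.ndarray | None = None,
    n_twists: int = 6,
    twist_span_deg: float = 60.0,
    displacements: float = 1.5,
    clash_scale: float = 0.7,
) -> list[Pose]:
    """Stack planar moieties of B face-to-face over planar moieties of A.

    For every A-ring x B-ring pair, poses are emitted along both normals of
    the A ring at scanned centroid offsets (default 3.0-4.5 A in 0.25 A
    steps) and twist angles about the stacking axis, plus parallel-displaced
    variants.  Fragments without planar moieties give an empty list.
    """
    moieties_a = detect_planar_moieties(a.mol)
    moieties_b = detect_planar_moieties(b.mol)
    if not moieties_a or not moieties_b:
        return []
    if offsets is None:
        offsets = np.arange(3.0, 4.5 + 1e-9, 0.25)
    twists = np.radians(np.arange(n_twists) * twist_span_deg / max(1, n_twists))
    cma_b = b.cma
    trans_list: list[np.ndarray] = []
    ang_list: list[np.ndarray] = []
    for ma in moieties_a:
        # in-plane axes of the A ring for parallel displacement
        u = np.cross(ma.normal, [1.0, 0.0, 0.0])
        if np.linalg.norm(u) < 1e-6:
            u = np.cross(ma.normal, [0.0, 1.0, 0.0])
        u /= np.linalg.norm(u)
        v = np.cross(ma.normal, u)
        lateral = [
            np.zeros(3),
            displacements * u, -displacements * u,
            displacements * v, -displacements * v,
        ]
        for mb in moieties_b:
            for sign in (1.0, -1.0):
                axis = sign * ma.normal
                # orient B's ring normal antiparallel to the stacking axis
                base = _rotation_to(-axis) @ _rotation_to(mb.normal).T
                for tw in twists:
                    c, s = math.cos(tw), math.sin(tw)
                    k = np.array(
                        [[0, -axis[2], axis[1]],
                         [axis[2], 0, -axis[0]],
                         [-axis[1], axis[0], 0]]
                    )
                    rot = (np.eye(3) + s * k + (1 - c) * (k @ k)) @ base
                    ang = euler_angles_from_matrix(rot)
                    for off in offsets:
                        for lat in lateral:
                            target = ma.centroid + off * axis + lat
                            cma_new = target - rot @ (mb.centroid - cma_b)
                            trans_list.append(cma_new - a.cma)
                            ang_list.append(ang)
    trans = np.array(trans_list)
    angs = np.array(ang_list)
    ok = clash_free_mask(a, b, trans, angs, clash_scale)
    return _scored_poses(trans[ok], angs[ok], score_fn)


def angular_grid_search(
    a: PreparedFragment,
    b: PreparedFragment,
    score_fn: ScoreFn,
    sites: Sequence[ProbeSite] = (),
    n_directions: int = 32,
    n_orientations: int = 12,
    top_k_sites: int = 10,
    contact_scale: float = 0.9,
    slide_step: float = 0.1,
    clash_scale: float = 0.7,
) -> list[Pose]:
    """General placements of B on an angular grid around A.

    B slides inward along each of ``n_directions`` quasi-uniform directions
    until first vdW contact (backed off by one slide step); additionally B's
    CMA is placed at the ``top_k_sites`` best probe sites.  Each placement is
    sampled at a fixed orientation set and scored; clash-free poses are
    returned.
    """
    if n_directions <= 0 and (top_k_sites <= 0 or not sites):
        return []
    orientations = orientation_set(n_orientations)
    if len(orientations) == 0:
        return []
    dirs = fibonacci_sphere(n_directions)
    rots = euler_rotation_matrices(orientations)
    b_local0 = b.coords - b.cma
    trans_list: list[np.ndarray] = []
    ang_list: list[np.ndarray] = []
    for rot, ang in zip(rots, orientations):
        b_local = b_local0 @ rot.T
        for u in dirs:
            d = contact_distance(a, b_local, b.vdw, u, contact_scale)
            if d is None:
                continue
            trans_list.append((d + slide_step) * u)
            ang_list.append(ang)
    for site in list(sites)[: max(0, top_k_sites)]:
        for ang in orientations:
            trans_list.append(site.point - a.cma)
            ang_list.append(ang)
    if not trans_list:
        return []
    trans = np.array(trans_list)
    angs = np.array(ang_list)
    ok = clash_free_mask(a, b, trans, angs, clash_scale)
    return _scored_poses(trans[ok], angs[ok], score_fn)
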