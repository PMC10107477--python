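"""End-to-end orchestration of the interaction-site screening pipeline.

A run proceeds: backend preparation (once per fragment) -> probe-grid
pre-screen -> pocket search (its poses are refined directly) -> stacking +
angular searches -> the best poses are combined into a genetic optimization
-> duplicate-aware selection -> rigid local refinement -> ranked report.
Bias potentials, if configured, enter generator scores, GA ranking and
selection only; every reported energy is recomputed bias-free.

An aggregate can be grown iteratively by feeding a result geometry back in
as the new host fragment (``iterative_add``).  External single-point /
optimizer programs plug in through a plain-XYZ subprocess adapter.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .energy import (
    AtomParams,
    BiasSpec,
    BuiltinBackend,
    PreparedFragment,
    bias_energies_batch,
    pair_energy,
    pose_energies,
)
from .genetic import Population, ga_optimize
from .molio import Molecule, Pose, apply_pose, merge
from .refine import ComplexResult, local_optimize_rigid, select_final
from .search import (
    angular_grid_search,
    build_probe_grid,
    burial_fractions,
    pocket_search,
    probe_prescreen,
    stack_search,
)

logger = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    """All tunable knobs of the pipeline with their workflow defaults."""

    mode: str = "single"  # {"single", "ensemble"}
    population_size: int = 100
    generations: int = 10
    mutation_fraction: float = 0.5
    sigma_t: float = 1.0  # A, mutation translation width
    sigma_a: float = 0.3  # rad, mutation angle width
    n_final: int = 15
    ensemble_window: float = 10.0  # kcal/mol above the best score
    probe_charges: tuple[float, ...] = (0.0, 0.1, -0.1)
    grid_spacing: float = 0.5  # A
    grid_margin: float = 3.0  # A
    n_directions: int = 32
    n_orientations: int = 12
    top_k_sites: int = 10
    use_pocket: bool = True
    use_stack: bool = True
    use_angular: bool = True
    pocket_burial_threshold: float = 0.6
    pocket_cluster_distance: float = 2.0  # A
    n_burial_rays: int = 64
    burial_ray_cutoff: float = 8.0  # A
    stack_offset_min: float = 3.0  # A
    stack_offset_max: float = 4.5  # A
    stack_offset_step: float = 0.25  # A
    stack_twists: int = 6
    stack_twist_span_deg: float = 60.0
    stack_displacement: float = 1.5  # A
    slide_step: float = 0.1  # A
    contact_scale: float = 0.9  # x sum of vdW radii
    clash_scale: float = 0.7  # x sum of vdW radii
    distinct_trans_rms: float = 0.5  # A
    distinct_angle: float = 0.2  # rad
    opt_maxfev: int = 2000
    opt_tol: float = 1e-6
    max_pairs: int | None = None  # cap on GA crossover pairs
    bias: BiasSpec | None = None
    rng_seed: int = 0
    backend: str = "builtin"  # {"builtin", "external"}
    param_overrides: dict[str, AtomParams] = field(default_factory=dict)
    external: "ExternalBackendConfig | None" = None

    def __post_init__(self) -> None:
        if self.mode not in ("single", "ensemble"):
            raise ValueError("mode must be 'single' or 'ensemble'")
        for name in ("population_size", "generations", "n_final"):
            if getattr(self, name) < 0 or (
                name == "population_size" and self.population_size < 1
            ):
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.mutation_fraction <= 1.0:
            raise ValueError("mutation_fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.bias is not None:
            d["bias"] = dataclasses.asdict(self.bias)
        d["param_overrides"] = {
            k: dataclasses.asdict(v) for k, v in self.param_overrides.items()
        }
        if self.external is not None:
            d["external"] = dataclasses.asdict(self.external)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SearchConfig":
        d = dict(d)
        if d.get("bias"):
            b = dict(d["bias"])
            if b.get("atom_indices") is not None:
                b["atom_indices"] = tuple(b["atom_indices"])
            if b.get("point") is not None:
                b["point"] = tuple(b["point"])
            d["bias"] = BiasSpec(**b)
        if d.get("param_overrides"):
            d["param_overrides"] = {
                k: AtomParams(**v) for k, v in d["param_overrides"].items()
            }
        if d.get("external"):
            d["external"] = ExternalBackendConfig(**d["external"])
        if d.get("probe_charges") is not None:
            d["probe_charges"] = tuple(d["probe_charges"])
        return cls(**d)


def load_config(path: str | Path) -> SearchConfig:
    """Read a flat-key YAML config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SearchConfig.from_dict(data)


def _screening_fn(
    a: PreparedFragment, b: PreparedFragment, bias: BiasSpec | None
):
    """Batch score function: screening energy plus (optional) bias term."""

    def fn(translations: np.ndarray, angles: np.ndarray) -> np.ndarray:
        e = pose_energies(a, b, translations, angles)
        if bias is not None:
            e = e + bias_energies_batch(b, bias, a, translations, angles)
        return e

    return fn


def _scalar_energy_fn(a: PreparedFragment, b: PreparedFragment):
    """Bias-free scalar energy over a 6-vector, for the local optimizer."""

    def fn(x: np.ndarray) -> float:
        return float(pose_energies(a, b, x[None, :3], x[None, 3:])[0])

    return fn


def _refine_pose(
    pose: Pose, a: PreparedFragment, b: PreparedFragment, cfg: SearchConfig
) -> Pose:
    scalar = _scalar_energy_fn(a, b)
    b_fixed = b.mol.fixed_mask is not None and bool(b.mol.fixed_mask.any())
    return local_optimize_rigid(
        pose, scalar, maxfev=cfg.opt_maxfev, tol=cfg.opt_tol,
        b_has_fixed_atoms=b_fixed,
    )


def _result_from_pose(
    pose: Pose,
    screening_energy: float,
    a: PreparedFragment,
    b: PreparedFragment,
) -> ComplexResult:
    geom_b = apply_pose(b.mol, pose, a.cma)
    geometry = merge(a.mol, geom_b)
    final = pair_energy(a, b.with_coords(geom_b.coords))
    return ComplexResult(
        geometry=geometry,
        pose=pose,
        screening_energy=screening_energy,
        final_energy=final,
        e_int=final,  # built-in backend: monomer energies vanish
        rank=0,
    )


def run_aiss(
    a: Molecule, b: Molecule, cfg: SearchConfig | None = None
) -> list[ComplexResult]:
    """Run the full screening pipeline for host A and mobile fragment B.

    Returns ranked complexes (ascending final energy).  Raises if the input
    fragments overlap as given (any A-B distance below 0.5 A).
    """
    cfg = cfg or SearchConfig()
    diff = a.coords[:, None, :] - b.coords[None, :, :]
    if float(np.sqrt((diff**2).sum(axis=2)).min()) < 0.5:
        raise ValueError(
            "input fragments overlap; provide spatially separated geometries"
        )
    if len(a) < len(b):
        logger.warning(
            "fragment A is smaller than fragment B; screening is more "
            "efficient when the larger fragment is given first"
        )
    backend = BuiltinBackend(cfg.param_overrides)
    pa = backend.prepare(a)  # done once per fragment
    pb = backend.prepare(b)
    screen = _screening_fn(pa, pb, cfg.bias)

    grid = build_probe_grid(pa, cfg.grid_spacing, cfg.grid_margin)
    burial = burial_fractions(
        grid, pa, n_rays=cfg.n_burial_rays, cutoff=cfg.burial_ray_cutoff
    )
    sites = probe_prescreen(
        pa, grid, cfg.probe_charges,
        n_rays=cfg.n_burial_rays, burial_cutoff=cfg.burial_ray_cutoff,
    )
    # reuse the grid burial for the sites (same points, same rays)
    logger.info("pre-screen: %d grid points", len(grid))

    results: list[ComplexResult] = []
    if cfg.use_pocket:
        pocket_poses = pocket_search(
            pa, pb, screen, grid=grid, burial=burial,
            burial_threshold=cfg.pocket_burial_threshold,
            cluster_distance=cfg.pocket_cluster_distance,
            n_orientations=cfg.n_orientations,
            clash_scale=cfg.clash_scale,
        )
        logger.info("pocket search: %d poses", len(pocket_poses))
        # pocket poses are refined directly, bypassing the GA
        for pose in [] if not pocket_poses else select_final(
            pocket_poses, "single", cfg.n_final,
            trans_rms=cfg.distinct_trans_rms, angle_dist=cfg.distinct_angle,
        ):
            refined = _refine_pose(pose, pa, pb, cfg)
            results.append(_result_from_pose(refined, pose.score, pa, pb))

    pool: list[Pose] = []
    if cfg.use_stack:
        offsets = np.arange(
            cfg.stack_offset_min, cfg.stack_offset_max + 1e-9, cfg.stack_offset_step
        )
        stack_poses = stack_search(
            pa, pb, screen, offsets=offsets,
            n_twists=cfg.stack_twists, twist_span_deg=cfg.stack_twist_span_deg,
            displacements=cfg.stack_displacement, clash_scale=cfg.clash_scale,
        )
        logger.info("stack search: %d poses", len(stack_poses))
        pool.extend(stack_poses)
    if cfg.use_angular:
        angular_poses = angular_grid_search(
            pa, pb, screen, sites=sites,
            n_directions=cfg.n_directions, n_orientations=cfg.n_orientations,
            top_k_sites=cfg.top_k_sites, contact_scale=cfg.contact_scale,
            slide_step=cfg.slide_step, clash_scale=cfg.clash_scale,
        )
        logger.info("angular search: %d poses", len(angular_poses))
        pool.extend(angular_poses)

    if pool:
        pool.sort(key=lambda p: p.score)
        initial = Population.from_poses(
            pool[: cfg.population_size], rng_seed=cfg.rng_seed
        )
        trace: list = []
        final_pop = ga_optimize(
            initial, screen,
            generations=cfg.generations,
            rng=np.random.default_rng(cfg.rng_seed),
            mutation_fraction=cfg.mutation_fraction,
            sigma_t=cfg.sigma_t, sigma_a=cfg.sigma_a,
            max_pairs=cfg.max_pairs, trace=trace,
        )
        logger.info(
            "GA: best %.6f after %d generations", final_pop.scores[0], cfg.generations
        )
        selected = select_final(
            final_pop.poses, cfg.mode, cfg.n_final,
            ensemble_window=cfg.ensemble_window,
            trans_rms=cfg.distinct_trans_rms, angle_dist=cfg.distinct_angle,
        )
        for pose in selected:
            refined = _refine_pose(pose, pa, pb, cfg)
            results.append(_result_from_pose(refined, pose.score, pa, pb))
    elif not results:
        logger.warning("no generator produced any pose; returning empty result")
        return []

    # external refinement / re-scoring hook
    if cfg.backend == "external" and cfg.external is not None:
        results = _apply_external(results, cfg)

    results.sort(key=lambda r: r.final_energy)
    for i, r in enumerate(results):
        r.rank = i + 1
    return results


def iterative_add(
    core: Molecule, c: Molecule, cfg: SearchConfig | None = None
) -> list[ComplexResult]:
    """Add fragment C to a previously generated aggregate (the rigid host)."""
    return run_aiss(core, c, cfg)


# ---------------------------------------------------------------------------
# external program adapter


class AdapterError(RuntimeError):
    """External program invocation or parsing failed."""


@dataclass
class ExternalBackendConfig:
    """How to call an external single-point / optimizer program.

    The adapter writes ``input.xyz`` (with charge/uhf metadata on the
    comment line), invokes ``command + [input.xyz] + args``, parses the
    energy from stdout with ``energy_regex`` and, for optimizations, reads
    the relaxed geometry from ``opt_geometry_file``.  The defaults match an
    xtb-style program.
    """

    command: tuple[str, ...] = ("xtb",)
    singlepoint_args: tuple[str, ...] = ()
    optimize_args: tuple[str, ...] = ("--opt",)
    energy_regex: str = r"TOTAL ENERGY\s+(-?\d+\.\d+)"
    energy_scale: float = 1.0  # multiply parsed energy into kcal/mol
    opt_geometry_file: str = "xtbopt.xyz"
    timeout: float = 600.0


def external_adapter(
    geometry: Molecule,
    task: str,
    ext: ExternalBackendConfig,
) -> tuple[float, Molecule]:
    """Run the configured external program on one geometry.

    ``task`` is ``"singlepoint"`` or ``"optimize"``.  Returns the parsed
    energy (scaled by ``energy_scale``) and the (possibly relaxed) geometry.
    Raises :class:`AdapterError` on a missing executable, a nonzero exit, an
    unparseable energy or an atom-count change.
    """
    from .molio import read_xyz, write_xyz

    if task not in ("singlepoint", "optimize"):
        raise ValueError("task must be 'singlepoint' or 'optimize'")
    args = ext.singlepoint_args if task == "singlepoint" else ext.optimize_args
    with tempfile.TemporaryDirectory(prefix="aiss_ext_") as tmp:
        tmpdir = Path(tmp)
        inp = tmpdir / "input.xyz"
        write_xyz(geometry, inp)
        cmd = [*ext.command, str(inp), *args]
        try:
            proc = subprocess.run(
                cmd, cwd=tmpdir, capture_output=True, text=True, timeout=ext.timeout
            )
        except FileNotFoundError as exc:
            raise AdapterError(f"external program not found: {ext.command[0]}") from exc
        except subprocess.TimeoutExpired as exc:
            raise AdapterError(f"external program timed out: {cmd}") from exc
        if proc.returncode != 0:
            raise AdapterError(
                f"external program exited with {proc.returncode}: {proc.stderr[-2000:]}"
            )
        m = re.search(ext.energy_regex, proc.stdout)
        if m is None:
            raise AdapterError(
                f"could not parse energy with regex {ext.energy_regex!r}; "
                f"stderr: {proc.stderr[-500:]}"
            )
        energy = float(m.group(1)) * ext.energy_scale
        out_geom = geometry
        if task == "optimize":
            opt_path = tmpdir / ext.opt_geometry_file
            if not opt_path.exists():
                raise AdapterError(f"optimized geometry file {opt_path.name} missing")
            out_geom = read_xyz(opt_path)
            if len(out_geom) != len(geometry):
                raise AdapterError(
                    "external optimizer changed the atom count "
                    f"({len(geometry)} -> {len(out_geom)})"
                )
        return energy, out_geom


def _apply_external(
    results: list[ComplexResult], cfg: SearchConfig
) -> list[ComplexResult]:
    """Re-score (and optionally relax) final complexes externally.

    Any adapter failure falls back to the built-in energies with a warning;
    the pipeline never hard-fails because of an external program.
    """
    out = []
    for r in results:
        try:
            e_ab, geom = external_adapter(r.geometry, "optimize", cfg.external)
            r = ComplexResult(
                geometry=geom, pose=r.pose,
                screening_energy=r.screening_energy,
                final_energy=e_ab, e_int=e_ab, rank=r.rank,
            )
        except AdapterError as exc:
            logger.warning("external backend failed (%s); keeping built-in energy", exc)
        out.append(r)
    return out


def write_run_manifest(
    path: str | Path, cfg: SearchConfig, n_results: int
) -> Path:
    """JSON manifest recording config, seed and package version."""
    path = Path(path)
    payload = {
        "package": "aiss",
        "version": _pkg_version,
        "seed": cfg.rng_seed,
        "n_results": n_results,
        "config": cfg.to_dict(),
    }
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
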