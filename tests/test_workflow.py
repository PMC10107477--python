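"""End-to-end pipeline, iterative aggregation, config and external adapter."""

import os
import stat

import numpy as np
import pytest

from aiss import (
    AtomParams,
    BiasSpec,
    FixtureSpec,
    Molecule,
    SearchConfig,
    analytic_optimum,
    iterative_add,
    make_fixture,
    overrides_for,
    run_aiss,
)
from aiss.energy import BuiltinBackend, pose_energies
from aiss.refine import report
from aiss.search import angular_grid_search, build_probe_grid, probe_prescreen
from aiss.workflow import (
    AdapterError,
    ExternalBackendConfig,
    external_adapter,
    load_config,
    write_run_manifest,
)

from conftest import LJ_EPSILON, LJ_SIGMA


class TestRunAiss:
    def test_lj_dimer_recovers_analytic_optimum(self, lj_dimer, lj_overrides):
        r_star, e_star = analytic_optimum("lj_dimer", sigma_a=LJ_SIGMA, eps_a=LJ_EPSILON)
        cfg = SearchConfig(param_overrides=lj_overrides, rng_seed=1)
        res = run_aiss(*lj_dimer, cfg)
        best = res[0]
        sep = np.linalg.norm(best.geometry.coords[1] - best.geometry.coords[0])
        assert best.e_int == pytest.approx(e_star, rel=0.01)
        assert sep == pytest.approx(r_star, rel=0.01)
        assert [r.rank for r in res] == list(range(1, len(res) + 1))

    def test_overlapping_inputs_rejected(self, lj_overrides):
        a = make_fixture(FixtureSpec("lj_atom"))
        b = make_fixture(FixtureSpec("lj_atom", center=(0.2, 0.0, 0.0)))
        with pytest.raises(ValueError, match="overlap"):
            run_aiss(a, b, SearchConfig(param_overrides=lj_overrides))

    def test_warns_when_host_smaller(self, caplog, lj_overrides):
        a = make_fixture(FixtureSpec("lj_atom"))
        b = make_fixture(FixtureSpec("lj_cluster", n_atoms=3, center=(14.0, 0, 0)))
        with caplog.at_level("WARNING"):
            run_aiss(a, b, SearchConfig(param_overrides=lj_overrides, rng_seed=0))
        assert "larger fragment" in caplog.text

    def test_pipeline_dominates_generators(self, lj_overrides):
        """Final best energy never exceeds the best pre-GA generator score."""
        rng = np.random.default_rng(5)
        a = Molecule(["C"] * 4, rng.uniform(-2, 2, (4, 3)))
        b = make_fixture(FixtureSpec("lj_atom", center=(12.0, 0, 0)))
        cfg = SearchConfig(param_overrides=lj_overrides, rng_seed=2)
        backend = BuiltinBackend(lj_overrides)
        pa, pb = backend.prepare(a), backend.prepare(b)
        fn = lambda t, ang: pose_energies(pa, pb, t, ang)
        sites = probe_prescreen(pa, build_probe_grid(pa, 0.5, 3.0))
        pre_ga = min(p.score for p in angular_grid_search(pa, pb, fn, sites=sites))
        res = run_aiss(a, b, cfg)
        assert res[0].final_energy <= pre_ga + 1e-12

    def test_ensemble_mode_returns_attractive_set(self, lj_dimer, lj_overrides):
        cfg = SearchConfig(
            mode="ensemble", param_overrides=lj_overrides, rng_seed=1
        )
        res = run_aiss(*lj_dimer, cfg)
        assert res
        assert all(r.screening_energy < 0 for r in res)

    def test_end_to_end_seed_determinism(self, tmp_path, lj_dimer, lj_overrides):
        files = []
        for run in ("x", "y"):
            cfg = SearchConfig(param_overrides=lj_overrides, rng_seed=7)
            res = run_aiss(*lj_dimer, cfg)
            out = tmp_path / run
            report(res, out_dir=out, prefix="d")
            files.append(out)
        assert (files[0] / "d_ensemble.xyz").read_bytes() == (
            files[1] / "d_ensemble.xyz"
        ).read_bytes()
        assert (files[0] / "d_summary.csv").read_bytes() == (
            files[1] / "d_summary.csv"
        ).read_bytes()


class TestIterativeAdd:
    def test_lj_trimer_additivity_bound(self, lj_overrides):
        spec = FixtureSpec("lj_atom", sigma=LJ_SIGMA, epsilon=LJ_EPSILON)
        cfg = SearchConfig(param_overrides=lj_overrides, rng_seed=1)
        a = make_fixture(spec)
        b = make_fixture(FixtureSpec("lj_atom", center=(9.0, 0, 0)))
        dimer = run_aiss(a, b, cfg)[0]
        c = make_fixture(FixtureSpec("lj_atom", center=(20.0, 0, 0)))
        trimer = iterative_add(dimer.geometry, c, cfg)[0]
        # pairwise-additive model: the equilateral trimer binds at least
        # twice the dimer well depth
        assert trimer.final_energy + dimer.final_energy <= 2.0 * dimer.final_energy

    def test_null_fragment_adds_nothing(self, lj_dimer, lj_overrides):
        overrides = dict(lj_overrides)
        overrides["He"] = AtomParams(0.0, LJ_SIGMA, 1.9)
        cfg = SearchConfig(param_overrides=overrides, rng_seed=3)
        a, b = lj_dimer
        dimer = run_aiss(a, b, cfg)[0]
        ghost = Molecule(["He"], np.array([[30.0, 0.0, 0.0]]))
        res = iterative_add(dimer.geometry, ghost, cfg)
        assert abs(res[0].e_int) < 1e-6

    def test_fixed_core_bitwise_unchanged(self, lj_dimer, lj_overrides):
        cfg = SearchConfig(param_overrides=lj_overrides, rng_seed=1)
        a, b = lj_dimer
        core = run_aiss(a, b, cfg)[0].geometry
        core.fixed_mask = np.ones(len(core), dtype=bool)
        c = make_fixture(FixtureSpec("lj_atom", center=(25.0, 0, 0)))
        res = iterative_add(core, c, cfg)
        for r in res:
            assert np.array_equal(r.geometry.coords[: len(core)], core.coords)


class TestBiasWorkflow:
    @pytest.fixture
    def two_site_system(self):
        # strong site (deep well) at the origin, weak site 10 A away
        a = Molecule(["Kr", "Xe"], np.array([[0.0, 0, 0], [10.0, 0, 0]]))
        b = Molecule(["Ar"], np.array([[20.0, 0.0, 0.0]]))
        overrides = {
            "Kr": AtomParams(1.0, 3.4, 1.9),
            "Xe": AtomParams(0.3, 3.4, 1.9),
            "Ar": AtomParams(1.0, 3.4, 1.9),
        }
        return a, b, overrides

    def test_undirected_run_prefers_strong_site(self, two_site_system):
        a, b, overrides = two_site_system
        res = run_aiss(a, b, SearchConfig(param_overrides=overrides, rng_seed=3))
        guest = res[0].geometry.coords[-1]
        assert np.linalg.norm(guest) < np.linalg.norm(guest - [10.0, 0, 0])

    def test_attractive_bias_redirects_to_weak_site(self, two_site_system):
        a, b, overrides = two_site_system
        bias = BiasSpec("attractive", strength=20.0, range=5.0, point=(10.0, 0.0, 0.0))
        cfg = SearchConfig(param_overrides=overrides, rng_seed=3, bias=bias)
        res = run_aiss(a, b, cfg)
        guest = res[0].geometry.coords[-1]
        assert np.linalg.norm(guest - [10.0, 0, 0]) < bias.range

    def test_reported_energies_are_bias_free(self, two_site_system):
        """Recomputing the reported energies without any bias must agree bitwise."""
        from aiss.energy import pair_energy

        a, b, overrides = two_site_system
        bias = BiasSpec("attractive", strength=20.0, range=5.0, point=(10.0, 0.0, 0.0))
        cfg = SearchConfig(param_overrides=overrides, rng_seed=3, bias=bias)
        res = run_aiss(a, b, cfg)
        backend = BuiltinBackend(overrides)
        pa = backend.prepare(a)
        for r in res:
            posed = backend.prepare(b).with_coords(r.geometry.coords[len(a):])
            assert pair_energy(pa, posed) == r.final_energy == r.e_int


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        import yaml

        cfg = SearchConfig(
            mode="ensemble", generations=4, rng_seed=9,
            bias=BiasSpec("repulsive", 2.0, 1.5, atom_indices=(0, 2), region_radius=4.0),
            param_overrides={"Kr": AtomParams(0.5, 3.0, 1.8)},
        )
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(cfg.to_dict()))
        loaded = load_config(path)
        assert loaded.mode == "ensemble" and loaded.generations == 4
        assert loaded.bias.atom_indices == (0, 2)
        assert loaded.param_overrides["Kr"].lj_sigma == 3.0

    @pytest.mark.parametrize(
        "kw", [dict(mode="triple"), dict(mutation_fraction=1.5),
               dict(population_size=0)]
    )
    def test_invalid_config(self, kw):
        with pytest.raises(ValueError):
            SearchConfig(**kw)

    def test_manifest_records_seed(self, tmp_path):
        import json

        cfg = SearchConfig(rng_seed=13)
        p = write_run_manifest(tmp_path / "m.json", cfg, 5)
        data = json.loads(p.read_text())
        assert data["seed"] == 13 and data["n_results"] == 5


def _make_stub(path, body):
    path.write_text("#!/usr/bin/env python\n" + body)
    path.chmod(path.stat().st_mode | stat.S_IEXEC)
    return path


class TestExternalAdapter:
    @pytest.fixture
    def geometry(self, lj_dimer):
        return lj_dimer[0]

    def test_unconfigured_runs_builtin(self, lj_dimer, lj_overrides):
        cfg = SearchConfig(param_overrides=lj_overrides, rng_seed=1, backend="external")
        res = run_aiss(*lj_dimer, cfg)  # external config absent -> built-in path
        assert res and np.isfinite(res[0].final_energy)

    def test_energy_propagated_from_stub(self, tmp_path, geometry):
        stub = _make_stub(tmp_path / "stub.py", "print('TOTAL ENERGY -12.345')\n")
        ext = ExternalBackendConfig(command=("python", str(stub)),
                                    singlepoint_args=())
        e, geom = external_adapter(geometry, "singlepoint", ext)
        assert e == pytest.approx(-12.345)
        assert len(geom) == len(geometry)

    def test_optimize_reads_shifted_geometry(self, tmp_path, geometry):
        body = (
            "import sys\n"
            "lines = open(sys.argv[1]).read().splitlines()\n"
            "out = [lines[0], lines[1]]\n"
            "for l in lines[2:]:\n"
            "    p = l.split()\n"
            "    out.append(f'{p[0]} {float(p[1]) + 1.0} {p[2]} {p[3]}')\n"
            "open('xtbopt.xyz', 'w').write('\\n'.join(out) + '\\n')\n"
            "print('TOTAL ENERGY -3.5')\n"
        )
        stub = _make_stub(tmp_path / "opt.py", body)
        ext = ExternalBackendConfig(command=("python", str(stub)), optimize_args=())
        e, geom = external_adapter(geometry, "optimize", ext)
        assert e == pytest.approx(-3.5)
        assert np.allclose(geom.coords[:, 0], geometry.coords[:, 0] + 1.0)

    def test_atom_count_change_rejected(self, tmp_path, geometry):
        body = (
            "open('xtbopt.xyz', 'w').write('2\\n\\nC 0 0 0\\nC 1 0 0\\n')\n"
            "print('TOTAL ENERGY -1.0')\n"
        )
        stub = _make_stub(tmp_path / "bad.py", body)
        ext = ExternalBackendConfig(command=("python", str(stub)), optimize_args=())
        with pytest.raises(AdapterError, match="atom count"):
            external_adapter(geometry, "optimize", ext)

    def test_missing_executable(self, geometry):
        ext = ExternalBackendConfig(command=("definitely-not-a-program",))
        with pytest.raises(AdapterError, match="not found"):
            external_adapter(geometry, "singlepoint", ext)

    def test_unparseable_energy(self, tmp_path, geometry):
        stub = _make_stub(tmp_path / "silent.py", "print('no energy here')\n")
        ext = ExternalBackendConfig(command=("python", str(stub)))
        with pytest.raises(AdapterError, match="parse"):
            external_adapter(geometry, "singlepoint", ext)

    def test_workflow_falls_back_on_adapter_failure(self, lj_dimer, lj_overrides, caplog):
        cfg = SearchConfig(
            param_overrides=lj_overrides, rng_seed=1, backend="external",
            external=ExternalBackendConfig(command=("definitely-not-a-program",)),
        )
        with caplog.at_level("WARNING"):
            res = run_aiss(*lj_dimer, cfg)
        assert res and np.isfinite(res[0].final_energy)
        assert "external backend failed" in caplog.text
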