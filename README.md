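# aiss — automated interaction-site screening for rigid molecular fragments

`aiss` generates low-energy non-covalent dimer, oligomer and aggregate
geometries from two rigid molecular fragments. It is aimed at computational
chemists who need physically reasonable starting structures for host–guest
complexes, π-stacked assemblies, ion placements or growing aggregates —
without restricting themselves to biomolecular docking tools — and who will
typically re-optimize the resulting geometries with a quantum-chemistry or
force-field program afterwards.

## Method

Given a host fragment A and a mobile fragment B, a placement of B is a pose

- **t** = (x, y, z): displacement of B's center of mass (CMA) from A's CMA,
- (α, β, γ): intrinsic z-y′-z″ Euler angles of B,

scored by an intermolecular screening energy. The pipeline runs:

1. **Backend preparation** — per-atom parameters are assigned once per
   fragment. The built-in backend is a classical pairwise model
   E = Σᵢⱼ 4εᵢⱼ[(σᵢⱼ/rᵢⱼ)¹² − (σᵢⱼ/rᵢⱼ)⁶] + 332.0637 qᵢqⱼ/rᵢⱼ
   over intermolecular pairs only (Lorentz–Berthelot mixing, kcal/mol, Å);
   external programs can be plugged in through a subprocess adapter.
2. **Probe pre-screen** — a shell grid around A is probed with a neutral and
   ±0.1 e charged Kr pseudo-atom; grid points are ranked by their best probe
   energy to locate candidate interaction sites.
3. **Pose generators** — a pocket search (clusters of buried grid points), a
   π-stacking search (planar ring moieties stacked face-to-face over scanned
   offsets, twists and parallel displacements) and an angular grid search
   (B slid to van-der-Waals contact along quasi-uniform directions, plus the
   best probe sites), all deterministic.
4. **Genetic optimization** — the best 100 poses of the stack and angular
   searches enter a two-step genetic algorithm. Each generation blends every
   parent pair component-wise, childᶜ = fᶜ·parentᵢᶜ + (1−fᶜ)·parentⱼᶜ with
   fresh uniform random f₁…f₆, rank-truncates the pool, then randomly mutates
   50 % of the population in position and angle; ten generations by default,
   with elitism.
5. **Selection and refinement** — either the 15 lowest mutually distinct
   poses (single mode) or all significantly attractive ones (ensemble mode)
   are locally optimized over the six rigid DOF and ranked by the
   interaction energy E_int = E(AB) − E(A) − E(B).

Directed screening adds a user-defined attractive or repulsive bias
potential to the *screening* scores only — the reported energies and final
ranking are always bias-free. Aggregates are grown by feeding a result
geometry back in as the new host.

## Worked example

```python
import numpy as np
from aiss import FixtureSpec, SearchConfig, analytic_optimum, \
    make_fixture, overrides_for, run_aiss

spec = FixtureSpec("lj_atom", sigma=3.4, epsilon=0.24)
a = make_fixture(spec)
b = make_fixture(FixtureSpec("lj_atom", sigma=3.4, epsilon=0.24,
                             center=(9.0, 0.0, 0.0)))
cfg = SearchConfig(param_overrides=overrides_for(spec), rng_seed=1)
best = run_aiss(a, b, cfg)[0]
sep = np.linalg.norm(best.geometry.coords[1] - best.geometry.coords[0])
print(f"E_int = {best.e_int:.6f} kcal/mol at r = {sep:.4f} A")
print("analytic optimum:", analytic_optimum("lj_dimer", sigma_a=3.4, eps_a=0.24))
```

prints

```
E_int = -0.240000 kcal/mol at r = 3.8164 A
analytic optimum: (3.816370964382858, -0.24)
```

i.e. the pipeline recovers the closed-form optimum of the toy dimer
(well depth −ε = −0.24 kcal/mol at r = 2^(1/6)·σ) exactly. The same run is
available from the shell:

```sh
aiss dock a.xyz b.xyz --seed 1 --out run1
```

which writes a ranked multi-structure XYZ ensemble, a CSV summary and a JSON
run manifest. For two stacked six-membered carbon rings it reports
`best E_int = -3.065017 kcal/mol` with an inter-centroid distance of 3.63 Å.
`aiss ensemble` returns all significantly attractive structures and
`aiss add` grows an existing aggregate by one fragment; `--directed
point:x,y,z` / `--directed atoms:i,j,...` with `--bias-mode` steer the
search toward a chosen site.

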