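# Methods

## Scope and model

`aiss` solves a rigid-body global-optimization problem: find the lowest
intermolecular-energy placements of a mobile fragment B around a host
fragment A. Both fragments are rigid throughout the search; intramolecular
relaxation is out of scope and is delegated to an external optimizer through
the subprocess adapter. A placement (pose) has six degrees of freedom — the
CMA displacement of B from A's CMA and three Euler angles — and the search
never moves fragment A, so fixed-atom constraints on the host hold by
construction.

### Euler convention

All modules share the intrinsic z-y′-z″ convention,
R(α, β, γ) = Rz(α)·Ry(β)·Rz(γ), identical to scipy's
`Rotation.from_euler("ZYZ", ...)`, which is used as an independent
cross-check in the tests and for matrix→angle extraction. Angles are stored
normalized to [0, 2π). B rotates about its own CMA before translation, so a
pose's translation is exactly the CMA displacement.

### Built-in screening energy

The built-in backend is a classical pairwise model over *intermolecular*
pairs only: 12-6 Lennard-Jones with Lorentz–Berthelot mixing plus vacuum
Coulomb with the conversion 332.0637 kcal·Å·mol⁻¹·e⁻². Monomer energies are
zero by construction, so E_int of a complex equals its pair energy. Per-atom
parameters come from a bundled table of UFF-style (r_min, well-depth) values
for common elements; any other element up to radon falls back to a sigma
derived from its van-der-Waals radius (LJ minimum at vdW contact) with a
generic 0.1 kcal/mol depth. Masses and vdW/covalent radii come from rdkit's
periodic table (D/T masses special-cased). Partial charges are taken from
the input when given, otherwise the total charge is smeared uniformly over
all atoms — the simplest defensible default, overridable per atom. This
backend is a documented stand-in with the same call contract as an external
intermolecular force field; it makes no claim of numerical agreement with
any tight-binding parameterization.

Numerical safety: pair distances are clamped at r_cap = 0.5 Å and pairs
closer than 10⁻⁶ Å add a finite 10⁴ kcal/mol penalty, so no score is ever
NaN or infinite — the genetic algorithm must be able to rank any pose it
generates. A consequence is that a pure opposite-charge Coulomb pair has its
"optimum" at the clash-cap boundary, which the fixtures module reports as
such.

## Pipeline stages and their parameters

**Probe pre-screen.** A Cartesian grid (default spacing 0.5 Å) over A's
bounding box expanded by a margin (default 3 Å) is filtered to the shell
outside every vdW sphere but within the margin of at least one sphere
surface. Each point is probed with a Kr-parameterized pseudo-atom at charges
0 and ±0.1 e; the best of the three energies ranks the point. Burial — the
fraction of 64 Fibonacci-lattice ray directions that hit a vdW sphere of A
within 8 Å — is computed per point and drives the pocket search.

**Pocket search.** Grid points with burial > 0.6 are clustered by single
linkage at 2 Å (connected components of the contact graph); each cluster
center is tried with a fixed 12-orientation set (rotations onto the
icosahedron vertices), and clash-free poses are kept. Pocket detection has
no canonical definition in this setting; ray-sampled burial was chosen for
being parameter-light and exactly testable on a hollow-cage fixture whose
interior burial is 1 by construction. Pocket poses are refined directly and
bypass the genetic stage, which exists to mix the surface-oriented stack and
angular poses.

**Stacking search.** Rings of 5–7 atoms are found as the cycle basis of a
bond graph (bond = distance < 1.2× sum of covalent radii), kept if their RMS
out-of-plane deviation is < 0.1 Å, and fused coplanar rings (normals within
15°) merge into one planar moiety. For every A-moiety × B-moiety pair, B is
stacked face-to-face along ±normal at offsets 3.0–4.5 Å in 0.25 Å steps,
six twist angles spanning 60° (the periodicity of a six-ring), and
parallel-displaced variants at ±1.5 Å along two in-plane axes.

**Angular grid search.** B is placed at vdW contact along 32 Fibonacci
directions around A's CMA and directly at the 10 best probe sites, each at
the 12-orientation set. Contact (any pair at 0.9× sum of vdW radii) is
found analytically per direction and orientation — the largest root of the
per-pair touching quadratic — which is equivalent to the 0.1 Å slide-step
definition within one step at a fraction of the cost; the pose backs off by
one slide step from touch.

**Genetic optimization.** The best 100 stack+angular poses (fewer if the
generators produced fewer) seed the population. Each generation: children
are built for every ordered parent pair (i ≠ j) with fresh uniform random
factors f₁…f₆, blending translations linearly and angles along the shorter
arc of the circle (this preserves the f = 0/1 endpoint identities exactly
while avoiding the 0/2π wrap discontinuity); the parent+child pool is
stably sorted by score and truncated to the population size; then exactly
round(0.5·N) poses, chosen uniformly, receive Gaussian noise (σ_t = 1.0 Å,
σ_a = 0.3 rad — scales comparable to one grid spacing and one twist step)
and are re-scored. If mutation loses the incumbent best, it replaces the
worst pose, making the best-score trace exactly non-increasing. Ten
generations by default. The i = j children are omitted as identical to
their parents, and (j, i) duplicates of (i, j) are kept because their blend
factors are freshly drawn; a `max_pairs` cap subsamples pairs for expensive
backends (all pairs are evaluated by default).

**Selection and refinement.** Single mode keeps the 15 lowest mutually
distinct poses; ensemble mode keeps every distinct pose that is attractive
(score < 0) and within 10 kcal/mol of the best — "significantly attractive"
has no canonical threshold, and the window is config-exposed. Two poses are
duplicates when their translation RMS ≤ 0.5 Å *and* their orientation
geodesic distance ≤ 0.2 rad; the filter is idempotent. Selected poses are
minimized over the six DOF with Nelder–Mead (energy tolerance 10⁻⁶, 2000
evaluation cap); the initial point belongs to the starting simplex, so
refinement never increases the energy. If B carries fixed atoms, rigid pose
optimization is ill-defined and is skipped with a warning.

**Bias potentials (directed screening).** Attractive:
−S·exp(−d²/ρ²), d = |CMA(B) − site|; repulsive:
S·Σ_B max(0, dᵢ − R₀)²/ρ² over B's atoms outside a region of radius R₀.
Only "distance-dependent" is prescribed for these terms; a bounded Gaussian
well was chosen because an unbounded attraction can drag the fragments into
unphysically short contact, and a quadratic outside-region wall is smooth at
the region boundary. Bias terms enter generator scores, GA ranking and
selection — nothing else. Reported screening energies, final energies,
E_int and the final ranking are recomputed bias-free, and a test asserts
bitwise equality of reported energies with and without a bias for identical
geometries. A directed run changes *which* poses survive screening, exactly
as a site-directed user intends, not how they are reported.

## Synthetic systems and what the tests show

The fixtures module generates every test system: single LJ atoms and seeded
clusters, exactly planar six-membered rings (radius 1.39 Å), a hollow
60-atom shell of radius 6 Å (cage host), point ions and random blobs.
Pseudo-atoms reuse real element symbols with their LJ parameters controlled
exactly through the backend's override hook, and the override also sets the
vdW radius so that the contact criterion (0.9× sum of radii) lands at the
LJ minimum distance 2^(1/6)σ — contact-placed poses then start at the
analytic optimum of the model, which makes the generator contracts exactly
assertable.

These toys validate the *search machinery*: closed-form optimum recovery,
agreement with an exhaustive 0.25 Å translation-grid + polish oracle on
small random clusters (the oracle fixtures use a monatomic mobile fragment
so the translation grid is exhaustive at desk scale), cage burial, stacking
geometry, bias isolation and determinism. They do not validate chemistry:
the classical backend has no polarization, charge penetration, many-body
terms or solvation, and passing tests say nothing about agreement with
tight-binding or DFT energetics on real molecules. The acceptance script
runs the dimer-recovery sweep at 60 seeds and the oracle comparison at 20
fixtures — problem sizes chosen to keep a full reproduction under a few
minutes on one core; the test suite runs the recovery sweep at 100 seeds.

## Design choices on genuinely open points

- **Crossover→truncate→mutate order** (mutation acting on the already
  truncated population) with elitist reinsertion: the simplest order that
  satisfies rank-based selection and a monotone best-energy trace.
- **Selection scheme**: plain rank truncation with stable (energy, insertion
  order) tie-breaking for determinism; no niching or adaptive schedules.
- **Pocket poses bypass the GA** and are optimized directly; the GA pool is
  seeded from the stack and angular searches only.
- **Probe radius/σ of the Kr probe** come from the same parameter table as
  any Kr atom; probe charges ±0.1 e are small enough to rank electrostatic
  preference without distorting the dispersion minimum.
- **Grid filter** keeps points outside every vdW sphere and within the
  margin of the nearest sphere surface (min-gap reading of the shell
  condition), which reduces to the obvious shell for a single atom.

## Known limitations

- Rigid fragments end to end; conformational response to binding is not
  modeled inside the package.
- The classical backend's absolute energies are not comparable to
  quantum-chemical interaction energies; it orders poses of the same system.
- Pocket detection by ray burial can miss shallow grooves (burial ≤ 0.6)
  and merges adjacent sub-pockets closer than the cluster distance.
- The exhaustive oracle is only affordable for monatomic mobile fragments;
  polyatomic B is validated against generator coverage and descent
  properties instead.
- Charge smearing for missing partial charges is uniform; strongly polar
  fragments should supply explicit per-atom charges.
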