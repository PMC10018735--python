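# Methods

## Coupling matrix and convergence diagnostic

For K distance constraints on N sites, the gradient matrix `B` (K×3N)
holds in row i the unit vector of constraint i, with `−û` in the block
of its first site and `+û` in the block of its second.  With the
diagonal inverse-mass matrix `M⁻¹`, the Gram matrix `G = B M⁻¹ Bᵀ` has
diagonal `1/m_a + 1/m_b`; the scaling `S = diag(G)^(−1/2)` (units
amu^1/2) normalizes it, and the coupling matrix is `A = I − S G S`:
symmetric, dimensionless, zero on the diagonal, with off-diagonal
entries equal to the cosine of the angle between two constraints
sharing a site times `S_ii S_jj / m_shared`.  `λ_max` is the largest
absolute eigenvalue, computed by dense symmetric eigendecomposition —
K stays in the tens-to-hundreds for single molecules, so sparse
iterative solvers would add nothing.

Everything is evaluated on a single snapshot.  That is adequate
whenever the constrained sites barely fluctuate (rigid ring scaffolds);
for floppier molecules a caller can average `λ_max` over frames, but
the per-frame contract is the primitive.

`λ_max` is invariant under rigid motion of the configuration, uniform
scaling of all masses, and uniform scaling of all coordinates; these
invariances are enforced as tests.

### Expansion-order estimate

Under typical bond distortions `λ_max ≈ 0.4` and order 4 suffices, so
order p is deemed sufficient when `λᵖ ≤ 0.4⁴`, i.e.

```
p = floor(4·ln 0.4 / ln λ),  clamped to ≥ 1.
```

The floor reproduces every (λ, order) pair we can check from rounded
spectral radii (0.50→5, 0.80→16, 0.73→11, 0.71→10).  The
proportionality constant of the underlying error relation is unknown
and irrelevant: only the relative rule is used.  Gromacs internally
doubles the requested order for constraints in 3-cycles; that doubling
is *reported* (via the triangle count) but never folded into the
estimate, so the printed order is the raw rule-of-thumb value.

### Projection modes

`lincs_project` implements one projection step with the K×K inverse
either solved exactly (the oracle) or replaced by `S (Σₚ Aᵖ) S`.  The
truncated mode with `λ_max ≥ 1` is not an error — divergence is a
reportable property — but the result carries a warning flag.  The
truncation error obeys the geometric remainder bound
`‖Σ₀ᵖ Aᵏ − (I−A)⁻¹‖ ≤ λ^(p+1)/(1−λ)`, which the tests verify on every
fixture.

## Equimomental engine

The pseudo inertia tensor `X̃ = Σ mᵢ (rᵢ,1)(rᵢ,1)ᵀ` jointly encodes
M (entry 4,4), M·R (block 1:3,4) and the second-moment matrix (upper
3×3), from which the conventional inertia tensor is
`X = tr(C)·I − C`.  In the principal frame (CoM at the origin, C
diagonal) `X̃` is diagonal and factors as `X̃ = D̃ (Σ ṽᵢṽᵢᵀ) D̃` with
`D̃ = X̃^(1/2)` and `Σ ṽᵢṽᵢᵀ = I` on the range of `D̃`.  Any `U ∈ SO(4)`
applied to the ṽ leaves `X̃` unchanged; the transformed masses are the
squared fourth homogeneous components, bounded by `0 ≤ mᵢ′ ≤ M` and
summing to M.

Numerical choices:

* **Principal-axis convention.**  Eigenvectors sorted by descending
  eigenvalue; each axis's first component of magnitude > 1e−12 made
  positive; determinant forced to +1 by flipping the third axis.  This
  makes the frame — and everything downstream — deterministic.
* **Degenerate bodies.**  Diagonal entries of `X̃` below 1e−12 of the
  maximum are treated as exact zeros; `D̃⁺` replaces `D̃⁻¹`.  Rotations
  must then act only on the range (generated via the range projector),
  so planar scaffolds remain planar; a rotation that would mix the
  null space is rejected rather than silently breaking the moments.
* **Random rotations.**  `U = exp(W)` with the six independent entries
  of the skew-symmetric generator drawn i.i.d. `N(0, s²)` — the
  simplest parameterization giving uniform-direction small steps and
  exactly orthogonal output.  The step scale s defaults to 0.05 rad;
  nothing fixes this scale physically, it only trades acceptance rate
  against exploration speed and is exposed as a parameter.
* **Mass floor.**  A transformed point with mass below `1e−6·M`
  (configurable) is rejected: its position `x̃₁:₃/x̃₄` degenerates as
  the fourth component vanishes.

## Scaffold optimization

Step 1 *decouples* the masses of all sites in edge-sharing constraint
triangles (auto-detected as 3-cycles of the constraint graph that share
a constraint; an explicit target set is accepted too): one new massive
noninteracting carrier per target, co-located and inheriting the mass,
while the original bead becomes a massless virtual site.  Constraints
are re-addressed to the carriers.  The kinetic degree-of-freedom count
`3N − 3N_virtual − K` is invariant under this step by construction.

Steps 2–3 minimize `λ_max` by a strictly greedy Monte Carlo walk: a
proposal is the equimomental transform of the *original* scaffold under
a cumulative 4D rotation (so the moments are preserved to roundoff over
the whole run, with no drift from re-decomposition); it is rejected
when any pair of scaffold beads falls below the minimum distance
(default 0.27 nm, applied to massive sites only — massless sites are
reconstructed geometrically and cannot destabilize integration the same
way) or any mass hits the floor, and accepted exactly when `λ_max`
strictly decreases.  There is no Metropolis temperature: only
lowering moves are taken, so the trace is strictly decreasing by
construction.  Stopping is `max_iters` (default 100 000) or an optional
`target_lambda`.  Only sites participating in constraints enter the
scaffold; flexibly bonded sites (the sterol tail bead) stay untouched.

Step 4 regenerates each constraint's length as its distance in the
optimized scaffold and refits every massless site in the scaffold's
frame.

The minimum-distance floor is what ultimately bounds the achievable
`λ_max`: beyond some point, further lowering requires beads closer than
the floor, and such proposals are rejected.

## Virtual-site reconstruction

Every massless site uses the single out-of-plane three-parent form
`r = r₁ + a·r₁₂ + b·r₁₃ + c·(r₁₂×r₁₃)` (Gromacs `virtual_sites3`
funct 4), including effectively coplanar targets (c ≈ 0) — one uniform
code path and one emitted directive type.  The coefficients solve a
3×3 linear system exactly at the reference snapshot, so reconstruction
reproduces the target to machine precision there and is equivariant
under rigid motions of the scaffold.  The parent triple is the
best-conditioned 3-combination of scaffold sites (largest cross-product
norm, ties broken by ascending index); conditioning depends only on the
parents, so one triple serves all reconstructed sites.  Parents with
cross-product norm below 1e−9 nm² are rejected as collinear.
Coefficients are fitted in the single reference configuration used for
optimization, consistent with the rigid-scaffold assumption.

## Topology model and file dialects

Internal units are nm, amu and radians; files use the Gromacs
conventions (1-based indices, degrees for angle equilibria, Å for PDB
coordinates), converted at the I/O boundary.  The itp dialect covers
`[atoms]`, `[constraints]`, `[bonds]`, `[angles]`, `[dihedrals]`,
`[virtual_sites3]` (funct 1 and 4), `[exclusions]` and
`[moleculetype]`; unknown directives are skipped with a logged warning
so real force-field files load, while preprocessor directives and
`[virtual_sitesn]` are rejected explicitly (an n-body construction
cannot be represented in the three-parent form used throughout).
Constraints to massless sites are rejected: the constraint algebra
needs finite inverse masses on both endpoints.  Bond graphs sometimes
*draw* constraints between massive and virtual sites to indicate
reconstructed rigid geometry; that is a drawing convention, not a
solvable constraint, and such files must encode those edges as
virtual-site constructions instead.

## Synthetic fixtures: what they emulate, what they do not

All test inputs are generated programmatically:

* **Coupled equilateral triangles** (4 equal-mass sites, 5 constraints)
  — the analytically clean hinge, `λ_max = 1/2` exactly.
* **United-atom alkanes** — trans zig-zag chains, bond length 0.153 nm,
  angle 109.47°, CH₃ = 15.035 / CH₂ = 14.027 amu.  Angle constraints
  are encoded the way the solver sees them: as 1–3 distance constraints
  of length `2L·sin(θ/2)`.  The printed one-decimal diagnostics (0.8
  for butane, 1.2 for pentane) are insensitive to the exact united-atom
  masses, which is itself a test.
* **Planar trapezoids** — four-bead rings constrained on the sides plus
  one diagonal, the pattern of small planar aromatics; flipping to the
  shorter diagonal lowers `λ_max` on the default skewed geometry.
* **Cholesterol-like hinge** — 8 sites: four near-coplanar ring beads
  in two skewed coupled triangles with unequal masses
  (72/36/36/159 amu), a flexibly bonded tail bead, and three
  out-of-plane virtual sites; one flexible bond, angle and dihedral.
  The registry constants are synthetic, chosen once so `λ_max ≈ 0.95` —
  the regime of real coarse-grained cholesterol — with every
  constrained edge above the 0.27 nm floor.  They are *not* parameters
  of any published force field, so tests against this fixture establish
  the machinery (spectral analysis, decoupling bookkeeping,
  equimomental optimization, exact reconstruction), not the specific
  published numbers of any real cholesterol model; reproducing those
  requires loading the published topology files as external inputs.

What the fixtures deliberately omit: thermal fluctuations (everything
is single-snapshot), solvent and nonbonded context, and multi-molecule
topologies.  Passing tests therefore demonstrate the correctness of the
constraint algebra and the optimizer's invariants, not the dynamical
consequences in a simulated membrane.

## Problem sizes and determinism

The test suite and the acceptance script run the optimizer at
2 000–20 000 proposals with fixed seeds; on the synthetic hinge the
spectral radius typically drops from ≈0.95 to below 0.3 within a few
thousand proposals, comfortably past the ≤0.85 level the tests assert.
Identical configuration (including the seed) gives bit-identical
results; all randomness flows through one `numpy` generator.

## Known limitations

* Only the single-step projection is modeled; the iterative
  rotation-correction loop of production LINCS and its parallel
  decomposition are out of scope, as are SHAKE/RATTLE comparisons.
* The optimizer keeps the number of scaffold points fixed; reduction to
  the minimal four points of a general rigid body, or pinning chosen
  positions/masses during the walk, is not implemented.
* The greedy walk finds a good, not provably optimal, `λ_max`; with a
  different seed the final scaffold differs even when the final
  spectral radius is similar.
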