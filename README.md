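# lincsopt

Diagnostics and optimization for bond-constraint topologies in molecular
dynamics: compute the LINCS constraint-coupling matrix of a molecule,
read off whether the solver's series expansion will converge, and — when
it will not — rearrange the constrained masses *equimomentally* so that
it does, without touching the molecule's interactions.

## The problem

MD engines replace stiff bonds by holonomic distance constraints and
enforce them after every unconstrained step with the LINCS projection

```
r' = r_unc − M⁻¹ Bᵀ (B M⁻¹ Bᵀ)⁻¹ (B·r_unc − d)
```

where `M` is the diagonal mass matrix, `B` the K×3N gradient matrix of
the K constraint equations and `d` their prescribed lengths.  The K×K
inverse is rewritten as `S (I − A)⁻¹ S` and expanded as the geometric
series `Σₚ Aᵖ`, truncated at the requested order (`lincs_order`).  The
coupling matrix `A` is symmetric with zero diagonal; its entries are
cosines of the angles between constraints sharing an atom, times a
dimensionless mass factor.  The expansion converges iff the spectral
radius `λ_max = max |eig(A)| < 1`, and slowly when `λ_max` is close
to 1 — the signature of coupled constraint triangles with unequal
masses, as in coarse-grained sterol ring systems.  Under-converged
constraints leak kinetic energy and produce artificial temperature
gradients between molecule types.

Rigid-body dynamics depends on a mass distribution only through its
total mass `M`, center of mass `R` and inertia tensor `X`.  Arrangements
sharing all three are *equimomental*, and the whole family is generated
by 4D rotations of the square-root factors of the 4×4 pseudo inertia
tensor `X̃ = Σᵢ mᵢ (rᵢ,1)(rᵢ,1)ᵀ`, which also re-weights the masses as
the squared fourth homogeneous component.  `lincsopt` exploits this:
it decouples the masses of the coupled-triangle beads onto
noninteracting carrier sites, walks greedily through equimomental
configurations (small random SO(4) steps, accepting exactly the moves
that lower `λ_max`, rejecting beads closer than 2.7 Å), and finally
reconstructs every massless interaction site in the frame of the
optimized scaffold — so the force field is retained exactly while the
constraint algebra becomes well-conditioned.

## Worked example

```
$ python examples/optimize_hinge.py
original:  8 sites, lambda_max=0.9542, order=78, DoF correction=2.4
optimized: 12 sites, lambda_max=0.2793, order=2, DoF correction=3.6
accepted 40 of 10000 proposals; kinetic DoF unchanged at 10
interaction sites rebuilt to within 2.2e-16 nm of their original positions
```

The synthetic cholesterol-like hinge (two skewed coupled constraint
triangles, unequal masses) starts at `λ_max ≈ 0.95`, which would demand
an expansion order near 80; after the equimomental optimization the
same molecule — same interactions, same 10 kinetic degrees of freedom —
sits at `λ_max ≈ 0.28`.  The temperature-correction factor changes from
24/10 to 36/10 only because four formerly massive interaction beads are
now massless virtual sites rebuilt from the four new carriers.

The other scripts in `examples/` show the individual capabilities:
spectral diagnostics of classic angle-constrained alkanes
(`diagnose_constraints.py`), moment preservation under random
equimomental transforms (`equimomental_transforms.py`) and the
diagonal-flip experiment on planar four-bead rings
(`diagonal_flip.py`).

## Command line

```
lincsopt diagnose --top mol.itp --coords mol.gro [--json]
lincsopt optimize --top mol.itp --coords mol.gro --seed 1 --out opt.itp
lincsopt fixtures emit --kind hinge --out-dir fixtures/
```

`diagnose` prints K, `λ_max`, the convergence flag, the estimated
expansion order, the number of constraint triangles (for which Gromacs
doubles the requested order) and the degree-of-freedom temperature
correction.  `optimize` writes the optimized topology, matching
coordinates and a JSON run report.

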