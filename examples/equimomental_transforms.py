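"""Equimomental rearrangements of a rigid scaffold.

Decomposes the four-bead sterol ring scaffold through its pseudo inertia
tensor, applies random 4D rotations and shows that total mass, center of
mass and inertia tensor are preserved while positions and masses change.
"""

import numpy as np

from lincsopt import apply_so4, decompose, moment_summary, random_so4
from lincsopt.equimomental import RigidBodySpec
from lincsopt.fixtures import HINGE_REGISTRY

spec = RigidBodySpec(positions=HINGE_REGISTRY["ring_positions"].copy(),
                     masses=HINGE_REGISTRY["ring_masses"].copy())
before = moment_summary(spec)
print("masses before:", np.round(spec.masses, 2))

dec = decompose(spec)
rng = np.random.default_rng(0)
worst = 0.0
for _ in range(200):
    out = apply_so4(dec, random_so4(0.3, rng),
                    mass_floor=1e-9 * spec.total_mass)
    worst = max(worst, before.max_relative_deviation(moment_summary(out)))
print("masses after one draw:", np.round(out.masses, 2))
print(f"total mass after: {out.masses.sum():.6f} "
      f"(before: {spec.total_mass:.6f})")
print(f"max relative deviation of (M, R, X) over 200 draws: {worst:.2e}")
print()
print("The mass distribution moves freely through the equimomental "
      "family, yet every draw leaves the rigid-body moments unchanged "
      "to roundoff — the dynamics of the scaffold cannot tell the "
      "difference.")
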