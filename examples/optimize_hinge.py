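"""Full optimization of the cholesterol-like hinge topology.

Decouples the ring masses onto carrier sites, minimizes the coupling
spectral radius by a greedy Monte Carlo walk over equimomental
configurations, and reconstructs every interaction site around the
optimized scaffold.  The interactions — and hence the force field — are
untouched; only the mass-carrying constraint scaffold changes.
"""

import numpy as np

from lincsopt import (OptimizerConfig, coupling_matrix,
                      dof_correction_factor, make_hinge_cholesterol_like,
                      optimize_topology, required_lincs_order)
from lincsopt.vsites import reconstruct_positions

top, conf = make_hinge_cholesterol_like()
cm = coupling_matrix(top, conf)
print(f"original:  {top.n_sites} sites, lambda_max={cm.lambda_max:.4f}, "
      f"order={required_lincs_order(cm.lambda_max)}, "
      f"DoF correction={dof_correction_factor(top):.1f}")

res = optimize_topology(top, conf, OptimizerConfig(max_iters=10_000,
                                                   rng_seed=1))
opt = res.topology
cm2 = coupling_matrix(opt, res.config)
print(f"optimized: {opt.n_sites} sites, lambda_max={cm2.lambda_max:.4f}, "
      f"order={required_lincs_order(cm2.lambda_max)}, "
      f"DoF correction={dof_correction_factor(opt):.1f}")
print(f"accepted {res.result.accepted} of {res.result.proposed} proposals; "
      f"kinetic DoF unchanged at {opt.kinetic_dof()}")

recon = reconstruct_positions(res.config.coords, opt.vsites)
targets = np.array([conf.coords[v.site] for v in opt.vsites])
err = np.max(np.linalg.norm(recon - targets, axis=1))
print(f"interaction sites rebuilt to within {err:.1e} nm of their "
      f"original positions")
print()
print("A lower lambda_max means the constraint solver converges at a "
      "much lower expansion order, while the reconstruction error shows "
      "the molecule's interaction geometry is fully retained.")
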