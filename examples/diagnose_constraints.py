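"""Spectral diagnostics of classic constrained molecules.

Builds three small fixtures, computes the constraint-coupling matrix of
each and prints its spectral radius lambda_max together with the series
expansion order it implies.  lambda_max < 1 is required for the solver's
geometric series to converge at all, and the closer it sits to 1 the
higher the expansion order needed.
"""

from lincsopt import (coupling_matrix, make_alkane, make_coupled_triangles,
                      required_lincs_order)

cases = [
    ("equilateral coupled triangles", make_coupled_triangles()),
    ("angle-constrained butane", make_alkane(4)),
    ("angle-constrained pentane", make_alkane(5)),
]

for name, (top, conf) in cases:
    cm = coupling_matrix(top, conf)
    order = (str(required_lincs_order(cm.lambda_max))
             if cm.convergent else "n/a (diverges)")
    print(f"{name:32s}  K={cm.K}  lambda_max={cm.lambda_max:.3f}  "
          f"order={order}")

print()
print("Equal masses and equilateral triangles give lambda_max = 1/2 "
      "exactly; the angle-constrained pentane chain exceeds 1, so no "
      "finite expansion order can converge for it.")
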