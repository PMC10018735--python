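"""Virtual-site fitting and reconstruction.

A massless interaction site is expressed in the local frame of three
massive parents as

    r = r1 + a*(r2 - r1) + b*(r3 - r1) + c*(r2 - r1) x (r3 - r1)

(the Gromacs "3out" construction).  For non-collinear parents the three
coefficients solve a 3x3 linear system exactly, so the reconstruction
reproduces the target position to machine precision at the reference
snapshot, and is equivariant under rigid motions of the scaffold.  The
single out-of-plane form is used uniformly, including for coplanar
targets (c ~ 0): one code path, one itp directive.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .equimomental import RigidBodySpec
from .errors import DegenerateGeometryError

__all__ = ["FrameFit", "fit_vsite", "reconstruct_positions", "choose_parents"]

#: Parents whose cross product is shorter than this (nm^2) are treated
#: as collinear: the out-of-plane direction is undefined.
_COLLINEAR_TOL = 1e-9


@dataclass
class FrameFit:
    """Fitted construction coefficients for one virtual site.

    ``coeffs`` are (a, b, c): in-plane a, b dimensionless, out-of-plane c
    in nm^-1.  ``residual`` (nm) is the reconstruction error at the fit
    snapshot; it is zero up to roundoff because the system is solved
    exactly.
    """

    parents: tuple[int, int, int]
    coeffs: tuple[float, float, float]
    residual: float


def _frame_matrix(parent_positions: np.ndarray) -> np.ndarray:
    r12 = parent_positions[1] - parent_positions[0]
    r13 = parent_positions[2] - parent_positions[0]
    cross = np.cross(r12, r13)
    if np.linalg.norm(cross) < _COLLINEAR_TOL:
        raise DegenerateGeometryError("virtual-site parents are collinear")
    return np.column_stack([r12, r13, cross])


def fit_vsite(target: np.ndarray, parent_positions: np.ndarray,
              parents: tuple[int, int, int] = (0, 1, 2)) -> FrameFit:
    """Solve for (a, b, c) placing ``target`` in the parents' frame."""
    target = np.asarray(target, dtype=float)
    parent_positions = np.asarray(parent_positions, dtype=float)
    mat = _frame_matrix(parent_positions)
    coeffs = np.linalg.solve(mat, target - parent_positions[0])
    rebuilt = parent_positions[0] + mat @ coeffs
    residual = float(np.linalg.norm(rebuilt - target))
    return FrameFit(parents=tuple(parents), coeffs=tuple(coeffs),
                    residual=residual)


def reconstruct_positions(scaffold_coords: np.ndarray,
                          fits: list[FrameFit]) -> np.ndarray:
    """Rebuild virtual-site positions from scaffold coordinates.

    ``fits[k].parents`` index into ``scaffold_coords``.  Rigid motions of
    the scaffold produce identically moved virtual sites.
    """
    scaffold_coords = np.asarray(scaffold_coords, dtype=float)
    out = np.empty((len(fits), 3))
    for k, fit in enumerate(fits):
        p = scaffold_coords[list(fit.parents)]
        mat = _frame_matrix(p)
        out[k] = p[0] + mat @ np.asarray(fit.coeffs)
    return out


def choose_parents(scaffold: RigidBodySpec | np.ndarray) -> tuple[int, int, int]:
    """Best-conditioned parent triple among the scaffold sites.

    Scans all 3-combinations and picks the one with the largest
    cross-product norm (the most robust out-of-plane frame); ties break
    by ascending index.  The same triple serves every reconstructed site:
    conditioning depends only on the parents.
    """
    pos = scaffold.positions if isinstance(scaffold, RigidBodySpec) \
        else np.asarray(scaffold, dtype=float)
    n = pos.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 massive scaffold sites")
    best, best_norm = None, _COLLINEAR_TOL
    for triple in combinations(range(n), 3):
        p = pos[list(triple)]
        norm = np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0]))
        if norm > best_norm:
            best, best_norm = triple, norm
    if best is None:
        raise DegenerateGeometryError("all scaffold parent triples are collinear")
    return best
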