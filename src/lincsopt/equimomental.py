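"""Equimomental rigid-body transformations.

Two arrangements of point masses are *equimomental* when they share the
total mass M, center of mass R and inertia tensor X — and hence identical
rigid-body dynamics.  The machinery here parameterizes the family of all
equimomental systems through the 4x4 pseudo inertia tensor

    Xt = sum_i m_i (r_i, 1)(r_i, 1)^T

built from homogeneous coordinates: its (4,4) entry is M, its (1:3,4)
block is M R and its upper 3x3 block is the second-moment matrix from
which X follows.  In the principal frame (CoM at origin, X diagonal) Xt
is diagonal and factors as Xt = Dt (sum_i v_i v_i^T) Dt with
Dt = Xt^(1/2) and unit-completeness sum_i v_i v_i^T = I on the range of
Dt.  Any 4D rotation U applied to the 4-vectors v_i leaves Xt — and so
M, R, X — unchanged, while producing new positions and new masses
m_i' = (x4')^2 (the squared fourth homogeneous component).  The masses
stay bounded, 0 <= m_i' <= M, and sum to M.

Degenerate (planar or linear) bodies have a rank-deficient Dt; the
pseudoinverse restricts the construction to the range, and rotations are
projected onto it so planar scaffolds remain planar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .errors import MassFloorError, ValidationError

__all__ = [
    "RigidBodySpec",
    "MomentSummary",
    "HomogeneousDecomposition",
    "pseudo_inertia_tensor",
    "moment_summary",
    "principal_frame",
    "decompose",
    "random_so4",
    "apply_so4",
]

#: Relative threshold below which a diagonal pseudo-inertia entry is
#: treated as zero (rank deficiency of planar/linear bodies).
_RANK_TOL = 1e-12


@dataclass
class RigidBodySpec:
    """Point masses with positions (nm) and masses (amu)."""

    positions: np.ndarray
    masses: np.ndarray

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError("positions must be (n, 3)")
        if self.masses.shape != (self.positions.shape[0],):
            raise ValidationError("masses must match positions")
        if np.any(self.masses < 0):
            raise ValidationError("masses must be non-negative")
        if not np.any(self.masses > 0):
            raise ValidationError("at least one mass must be positive")

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())


@dataclass
class MomentSummary:
    """Total mass M (amu), center of mass R (nm), inertia tensor X (amu nm^2)."""

    M: float
    R: np.ndarray
    X: np.ndarray

    def max_relative_deviation(self, other: "MomentSummary") -> float:
        """Largest relative difference over M, R components and X entries.

        Scales R by a length derived from X/M and X by its trace so the
        comparison is meaningful near the origin / for diagonal zeros.
        """
        scale_len = np.sqrt(max(np.trace(self.X) / self.M, 1e-30))
        scale_x = max(abs(np.trace(self.X)), 1e-30)
        dm = abs(self.M - other.M) / self.M
        dr = np.max(np.abs(self.R - other.R)) / scale_len
        dx = np.max(np.abs(self.X - other.X)) / scale_x
        return float(max(dm, dr, dx))


@dataclass
class HomogeneousDecomposition:
    """Square-root factorization of the pseudo inertia tensor.

    ``G`` is the SE(3) transform (4x4) from the input frame to the
    principal frame; ``Dt`` the diagonal square root of the principal
    pseudo inertia tensor; ``V`` the per-point 4-vectors (n x 4) with
    ``Dt @ V[i]`` recovering ``sqrt(m_i) * (r_i, 1)`` in the principal
    frame and ``V.T @ V`` the identity on the range of ``Dt``.
    """

    G: np.ndarray
    Dt: np.ndarray
    V: np.ndarray

    @property
    def total_mass(self) -> float:
        return float(self.Dt[3, 3] ** 2)

    def range_projector(self) -> np.ndarray:
        """Orthogonal projector onto the range of Dt."""
        d = np.diag(self.Dt)
        return np.diag((d > 0).astype(float))


def pseudo_inertia_tensor(spec: RigidBodySpec) -> np.ndarray:
    """4x4 pseudo inertia tensor sum_i m_i (r_i,1)(r_i,1)^T."""
    h = np.hstack([spec.positions, np.ones((spec.n_points, 1))])
    return (spec.masses[:, None] * h).T @ h


def moment_summary(spec: RigidBodySpec) -> MomentSummary:
    """M, R and the conventional inertia tensor about the CoM."""
    M = spec.total_mass
    R = spec.masses @ spec.positions / M
    s = spec.positions - R
    C = (spec.masses[:, None] * s).T @ s  # second moments about CoM
    X = np.trace(C) * np.eye(3) - C
    return MomentSummary(M=M, R=R, X=X)


def _principal_rotation(C: np.ndarray) -> np.ndarray:
    """Deterministic principal-axis rotation for a symmetric 3x3 matrix.

    Eigenvectors ordered by descending eigenvalue; each axis's first
    component of magnitude > 1e-12 made positive; determinant fixed to +1
    by flipping the last axis if needed.
    """
    w, v = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    v = v[:, order]
    for j in range(3):
        col = v[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            v[:, j] = -col
    if np.linalg.det(v) < 0:
        v[:, 2] = -v[:, 2]
    return v.T  # rows are principal axes: r' = Rot @ r


def principal_frame(spec: RigidBodySpec) -> tuple[np.ndarray, RigidBodySpec]:
    """Move a body to its principal frame (CoM at origin, X diagonal).

    Returns the SE(3) transform G (4x4 homogeneous matrix) and the
    transformed spec; applying G to the input homogeneous coordinates
    reproduces the output.
    """
    summary = moment_summary(spec)
    s = spec.positions - summary.R
    C = (spec.masses[:, None] * s).T @ s
    rot = _principal_rotation(C)
    G = np.eye(4)
    G[:3, :3] = rot
    G[:3, 3] = -rot @ summary.R
    return G, RigidBodySpec(positions=s @ rot.T, masses=spec.masses.copy())


def decompose(spec: RigidBodySpec) -> HomogeneousDecomposition:
    """Factor the pseudo inertia tensor as Dt (sum v v^T) Dt.

    The body is first moved to its principal frame (recorded in ``G``);
    rank-deficient Dt (planar/linear bodies) is handled through the
    pseudoinverse, so ``V.T @ V`` equals the identity on the range only.
    """
    G, spec_pf = principal_frame(spec)
    Xt = pseudo_inertia_tensor(spec_pf)
    d = np.diag(Xt).copy()
    d[d < _RANK_TOL * d.max()] = 0.0
    Dt = np.diag(np.sqrt(d))
    d_inv = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    h = np.hstack([spec_pf.positions, np.ones((spec.n_points, 1))])
    V = np.sqrt(spec.masses)[:, None] * h * d_inv[None, :]
    return HomogeneousDecomposition(G=G, Dt=Dt, V=V)


def random_so4(step_scale: float, rng: np.random.Generator | int,
               projector: np.ndarray | None = None) -> np.ndarray:
    """Random small 4D rotation U = exp(W), W skew-symmetric Gaussian.

    The six independent generator entries are N(0, step_scale^2); the
    matrix exponential gives an exactly orthogonal U with det +1, tending
    to the identity as step_scale -> 0.  With ``projector`` P, the
    generator is restricted to P W P so the rotation acts only on that
    subspace (identity on its complement) — used for degenerate bodies.
    """
    if step_scale <= 0:
        raise ValueError("step_scale must be positive")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    W = np.zeros((4, 4))
    idx = np.triu_indices(4, k=1)
    vals = rng.normal(0.0, step_scale, size=6)
    W[idx] = vals
    W = W - W.T
    if projector is not None:
        W = projector @ W @ projector
    return expm(W)


def apply_so4(dec: HomogeneousDecomposition, U: np.ndarray,
              mass_floor: float = 0.0) -> RigidBodySpec:
    """Equimomental transform: rotate the 4-vectors and rebuild the body.

    New homogeneous coordinates are ``Dt @ U^T @ v_i``; the new mass is
    the squared fourth component and the new position the first three
    divided by the fourth.  The result is mapped back to the input frame
    through ``G^-1``, so ``U = I`` returns the original body.  M, R and X
    are preserved exactly (up to roundoff).

    For a degenerate (planar/linear) body the rotation must act only on
    the range of Dt — generate it with
    ``random_so4(..., projector=dec.range_projector())`` — otherwise the
    pseudo inertia tensor would not be preserved; a rotation that mixes
    the null space is rejected.

    Raises :class:`MassFloorError` when any transformed mass falls below
    ``mass_floor`` (amu) — the position of a massless point is undefined.
    """
    P = dec.range_projector()
    U_eff = P @ U @ P + (np.eye(4) - P)
    if not np.allclose(U_eff @ U_eff.T, np.eye(4), atol=1e-10):
        raise ValidationError(
            "rotation mixes the null space of a degenerate body; "
            "generate it with projector=dec.range_projector()"
        )
    Vp = dec.V @ U  # row i becomes U^T v_i
    Xp = Vp @ dec.Dt  # homogeneous coords in principal frame, rows
    w4 = Xp[:, 3]
    masses = w4 ** 2
    if np.any(masses < mass_floor):
        raise MassFloorError(
            f"transformed mass {masses.min():.3e} amu below floor {mass_floor:.3e}"
        )
    if np.any(masses <= 0):
        raise MassFloorError("transformed point became exactly massless")
    pos_pf = Xp[:, :3] / w4[:, None]
    # back to the input frame: r = Rot^T (r_pf - t), G = [Rot | t; 0 1]
    rot = dec.G[:3, :3]
    t = dec.G[:3, 3]
    positions = (pos_pf - t) @ rot
    return RigidBodySpec(positions=positions, masses=masses)
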