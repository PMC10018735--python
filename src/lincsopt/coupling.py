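"""LINCS constraint-coupling diagnostics.

The LINCS solver enforces distance constraints after an unconstrained
integration step by projecting positions:

    r_proj = r_unc - M^-1 B^T (B M^-1 B^T)^-1 (B r_unc - d)

where ``M`` is the diagonal mass matrix, ``B`` the K x 3N gradient matrix
of the constraint equations and ``d`` the prescribed lengths.  The
expensive K x K inverse is rewritten as

    (B M^-1 B^T)^-1 = S (I - A)^-1 S,

with ``S`` the inverse square root of the diagonal of ``B M^-1 B^T``, and
``(I - A)^-1`` expanded as the truncated geometric series
``sum_p A^p``.  ``A`` is symmetric with zero diagonal; its off-diagonal
entries are cosines of inter-constraint angles times a dimensionless
mass factor.  The series converges iff the spectral radius
``lambda_max = max |eig(A)| < 1``, and the rate of convergence with the
retained order p is governed by ``lambda_max**p``.  This module builds
these matrices from a single snapshot and derives the diagnostics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import DegenerateGeometryError, NonConvergentError, ValidationError
from .topology import Configuration, Topology

__all__ = [
    "GradientMatrix",
    "CouplingMatrix",
    "ProjectionResult",
    "gradient_matrix",
    "coupling_matrix",
    "lambda_max",
    "required_lincs_order",
    "series_inverse",
    "exact_inverse",
    "lincs_project",
    "detect_coupled_triangles",
    "dof_correction_factor",
]

#: Reference point of the order rule of thumb: under typical bond
#: distortions lambda_max is about 0.4 and order 4 suffices, so order p
#: is deemed sufficient when lambda**p <= 0.4**4.
_RULE_LAMBDA = 0.4
_RULE_ORDER = 4


@dataclass
class GradientMatrix:
    """Constraint gradient matrix B (K x 3N) and inverse masses (amu^-1).

    Row i holds ``-u_i`` in the 3-block of ``site_a`` and ``+u_i`` in the
    block of ``site_b``, with ``u_i`` the unit vector from a to b.
    """

    B: np.ndarray
    M_inv_diag: np.ndarray

    @property
    def n_constraints(self) -> int:
        return self.B.shape[0]

    def gram(self) -> np.ndarray:
        """The K x K matrix B M^-1 B^T."""
        w = np.repeat(self.M_inv_diag, 3)
        return self.B @ (w[:, None] * self.B.T)


@dataclass
class CouplingMatrix:
    """The LINCS coupling matrix A with its scaling S and diagnostics.

    ``A`` is K x K, symmetric, zero-diagonal and dimensionless; ``S`` is
    the positive diagonal (amu^1/2) with
    ``S_ii = 1 / sqrt(1/m_a + 1/m_b)`` for constraint i.  ``convergent``
    is ``lambda_max < 1``.
    """

    A: np.ndarray
    S: np.ndarray
    K: int
    lambda_max: float
    convergent: bool

    def __post_init__(self):
        if self.A.shape != (self.K, self.K):
            raise ValidationError("A must be K x K")


def gradient_matrix(topology: Topology, config: Configuration) -> GradientMatrix:
    """Build B and the inverse-mass diagonal from one snapshot."""
    if config.n_sites != topology.n_sites:
        raise ValidationError("configuration does not match topology")
    n = topology.n_sites
    K = topology.n_constraints
    coords = config.coords
    B = np.zeros((K, 3 * n))
    for i, c in enumerate(topology.constraints):
        vec = coords[c.site_b] - coords[c.site_a]
        norm = np.linalg.norm(vec)
        if norm < 1e-12:
            raise DegenerateGeometryError(
                f"constrained sites {c.site_a} and {c.site_b} coincide"
            )
        u = vec / norm
        B[i, 3 * c.site_a: 3 * c.site_a + 3] = -u
        B[i, 3 * c.site_b: 3 * c.site_b + 3] = u
    masses = topology.masses
    M_inv = np.zeros(n)
    massive = ~np.array([s.is_virtual for s in topology.sites])
    M_inv[massive] = 1.0 / masses[massive]
    return GradientMatrix(B=B, M_inv_diag=M_inv)


def coupling_matrix(topology: Topology, config: Configuration) -> CouplingMatrix:
    """Build A = I - S (B M^-1 B^T) S and its spectral diagnostics."""
    grad = gradient_matrix(topology, config)
    return coupling_from_gradient(grad)


def coupling_from_gradient(grad: GradientMatrix) -> CouplingMatrix:
    """Coupling matrix from a prebuilt gradient matrix."""
    G = grad.gram()
    K = grad.n_constraints
    diag = np.diag(G)
    if np.any(diag <= 0):
        raise ValidationError("constraint with non-positive inverse-mass sum")
    S = 1.0 / np.sqrt(diag)
    A = np.eye(K) - (S[:, None] * G * S[None, :])
    np.fill_diagonal(A, 0.0)  # exact zeros instead of 1e-16 residue
    lam = lambda_max(A)
    return CouplingMatrix(A=A, S=S, K=K, lambda_max=lam, convergent=lam < 1.0)


def lambda_max(A: CouplingMatrix | np.ndarray) -> float:
    """Largest absolute eigenvalue of the coupling matrix."""
    mat = A.A if isinstance(A, CouplingMatrix) else np.asarray(A)
    if mat.size == 0:
        return 0.0
    return float(np.max(np.abs(np.linalg.eigvalsh(mat))))


def required_lincs_order(lam: float) -> int:
    """Rule-of-thumb expansion order for a given spectral radius.

    Order p is sufficient when ``lam**p <= 0.4**4``, i.e.
    ``p = floor(4 ln 0.4 / ln lam)``, clamped to at least 1.  Note that
    Gromacs internally doubles the requested order for constraints in
    triangular arrangements; that doubling is reported separately (see
    :func:`detect_coupled_triangles`) and never folded into this
    estimate.
    """
    if lam >= 1.0:
        raise NonConvergentError(
            f"series does not converge for lambda_max = {lam:.4g} >= 1"
        )
    if lam <= 0.0:
        raise ValueError("lambda_max must be in (0, 1)")
    order = math.floor(_RULE_ORDER * math.log(_RULE_LAMBDA) / math.log(lam))
    return max(order, 1)


def series_inverse(A: np.ndarray, order: int) -> np.ndarray:
    """Truncated geometric series sum_{p=0}^{order} A^p.

    Divergence for spectral radius >= 1 is a property the caller can
    inspect; no exception is raised here.
    """
    A = np.asarray(A, dtype=float)
    K = A.shape[0]
    out = np.eye(K)
    term = np.eye(K)
    for _ in range(order):
        term = term @ A
        out = out + term
    return out


def exact_inverse(A: np.ndarray) -> np.ndarray:
    """Exact (I - A)^-1 by direct solve — the oracle the series approximates."""
    A = np.asarray(A, dtype=float)
    K = A.shape[0]
    return np.linalg.solve(np.eye(K) - A, np.eye(K))


@dataclass
class ProjectionResult:
    """Outcome of a single LINCS projection step."""

    config: Configuration
    mode: str
    series_convergent: bool  # False flags a truncated projection with lambda >= 1


def lincs_project(r_unc: Configuration, topology: Topology, ref: Configuration,
                  mode: str | int = "exact") -> ProjectionResult:
    """One constraint-projection step from reference geometry ``ref``.

    ``mode`` is ``"exact"`` (direct solve of the K x K system) or an
    integer expansion order, in which case the inverse is replaced by
    ``S (sum_p A^p) S``.  A truncated projection with a non-convergent
    coupling matrix is returned with ``series_convergent=False`` and a
    warning rather than an exception.
    """
    if r_unc.n_sites != topology.n_sites:
        raise ValidationError("unconstrained configuration does not match topology")
    grad = gradient_matrix(topology, ref)
    coup = coupling_from_gradient(grad)
    d = np.array([c.length for c in topology.constraints])
    x = r_unc.coords.reshape(-1)
    residual = grad.B @ x - d
    convergent = True
    if mode == "exact":
        rhs = np.linalg.solve(grad.gram(), residual)
        label = "exact"
    else:
        order = int(mode)
        if order < 0:
            raise ValueError("expansion order must be non-negative")
        if not coup.convergent:
            convergent = False
            warnings.warn(
                f"truncated LINCS projection with lambda_max = "
                f"{coup.lambda_max:.3f} >= 1: series diverges",
                RuntimeWarning,
                stacklevel=2,
            )
        inv = coup.S[:, None] * series_inverse(coup.A, order) * coup.S[None, :]
        rhs = inv @ residual
        label = f"truncated({order})"
    w = np.repeat(grad.M_inv_diag, 3)
    x_proj = x - w * (grad.B.T @ rhs)
    return ProjectionResult(
        config=Configuration(x_proj.reshape(-1, 3)),
        mode=label,
        series_convergent=convergent,
    )


def detect_coupled_triangles(topology: Topology) -> list[tuple[int, int, int]]:
    """All 3-cycles of the constraint graph, as constraint-index triples.

    Triangular constraint arrangements are the canonical hard case for
    the series expansion (the third constraint away from any constraint
    of a triangle is itself), which is why Gromacs doubles the requested
    order for them.
    """
    g = nx.Graph()
    g.add_nodes_from(range(topology.n_sites))
    edge_index: dict[tuple[int, int], int] = {}
    for i, c in enumerate(topology.constraints):
        a, b = sorted(c.pair)
        g.add_edge(a, b)
        edge_index[(a, b)] = i
    triangles = []
    for clique in nx.enumerate_all_cliques(g):
        if len(clique) == 3:
            a, b, c = sorted(clique)
            triangles.append(tuple(sorted((
                edge_index[(a, b)], edge_index[(a, c)], edge_index[(b, c)]
            ))))
        elif len(clique) > 3:
            break
    return triangles


def dof_correction_factor(topology: Topology) -> float:
    """Temperature correction 3N / (3N - 3 N_virtual - K).

    Kinetic-energy temperatures computed from all 3N coordinates must be
    rescaled because virtual sites carry no kinetic energy and each
    constraint removes one degree of freedom.
    """
    total = 3 * topology.n_sites
    dof = topology.kinetic_dof()
    if dof <= 0:
        raise ValidationError(
            f"no kinetic degrees of freedom left ({dof}) for {topology.name}"
        )
    return total / dof
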