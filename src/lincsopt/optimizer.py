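"""Constraint-scaffold optimization.

Strongly coupled constraint scaffolds (unequal masses, skewed coupled
triangles) push the spectral radius of the LINCS coupling matrix toward
one, making the series expansion converge slowly or not at all.  Because
rigid-body dynamics depends on the mass distribution only through its
total mass, center of mass and inertia tensor, the masses and positions
of the constrained sites can be rearranged freely within the
equimomental family — the interactions are carried by massless virtual
sites reconstructed around the new scaffold.

The procedure:

1. *Decouple* the masses of the sites in coupled constraint triangles
   onto newly introduced, noninteracting carrier sites (co-located,
   inheriting the mass); the original beads become massless virtual
   interaction sites.
2.-3. *Minimize* lambda_max by a greedy Monte Carlo walk over
   equimomental configurations: propose a small random SO(4) rotation,
   rebuild positions and masses, reject proposals that bring any two
   scaffold beads closer than a minimum distance (default 0.27 nm) or
   drive a mass to (near) zero, and accept exactly those that lower
   lambda_max.
4. *Reconstruct* every massless site in the frame of the optimized
   scaffold and regenerate constraint lengths from the new geometry, so
   the original interaction geometry — and hence the parameterization —
   is retained exactly at the reference snapshot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .coupling import detect_coupled_triangles, lambda_max
from .equimomental import (RigidBodySpec, apply_so4, decompose,
                           moment_summary, random_so4)
from .errors import DegenerateGeometryError, MassFloorError, ValidationError
from .topology import Configuration, Constraint, Site, Topology, VSiteDef
from .vsites import choose_parents, fit_vsite

__all__ = [
    "OptimizerConfig",
    "OptimizationResult",
    "PipelineResult",
    "decouple_masses",
    "minimize_lambda_max",
    "regenerate_constraints",
    "optimize_topology",
]

logger = logging.getLogger(__name__)


@dataclass
class OptimizerConfig:
    """Tunable parameters of the greedy equimomental search.

    ``min_distance`` (nm) rejects pathological scaffolds with beads too
    close for stable integration; ``mass_floor`` is the fraction of the
    total mass below which a transformed point counts as massless;
    ``step_scale`` (radians) sets the width of the Gaussian generator of
    the small 4D rotations.
    """

    min_distance: float = 0.27
    max_iters: int = 100_000
    target_lambda: float | None = None
    step_scale: float = 0.05
    rng_seed: int = 0
    mass_floor: float = 1e-6

    def __post_init__(self):
        if self.min_distance <= 0:
            raise ValidationError("min_distance must be positive")
        if self.max_iters < 1:
            raise ValidationError("max_iters must be at least 1")


@dataclass
class OptimizationResult:
    """Outcome of a greedy lambda_max minimization.

    ``lambda_trace`` starts at the initial value and appends one entry
    per accepted move, so it is strictly decreasing and its last entry
    is ``final_lambda``.
    """

    scaffold: RigidBodySpec
    lambda_trace: list[float]
    initial_lambda: float
    final_lambda: float
    accepted: int
    proposed: int
    constraints: list[Constraint] = field(default_factory=list)


def _scaffold_lambda(positions: np.ndarray, masses: np.ndarray,
                     pairs: list[tuple[int, int]]) -> float:
    """lambda_max of the coupling matrix of a bare scaffold."""
    K = len(pairs)
    n = positions.shape[0]
    B = np.zeros((K, 3 * n))
    for i, (a, b) in enumerate(pairs):
        vec = positions[b] - positions[a]
        u = vec / np.linalg.norm(vec)
        B[i, 3 * a: 3 * a + 3] = -u
        B[i, 3 * b: 3 * b + 3] = u
    w = np.repeat(1.0 / masses, 3)
    G = B @ (w[:, None] * B.T)
    S = 1.0 / np.sqrt(np.diag(G))
    A = np.eye(K) - S[:, None] * G * S[None, :]
    np.fill_diagonal(A, 0.0)
    return lambda_max(A)


def _min_pair_distance(positions: np.ndarray) -> float:
    diff = positions[:, None, :] - positions[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    return float(np.min(d[np.triu_indices(positions.shape[0], k=1)]))


# ---------------------------------------------------------------------------
# step 1: mass decoupling
# ---------------------------------------------------------------------------

def _auto_targets(topology: Topology) -> set[int]:
    """Sites of constraint triangles that share an edge with another."""
    triangles = detect_coupled_triangles(topology)
    coupled = set()
    for i, tri in enumerate(triangles):
        for j, other in enumerate(triangles):
            if i != j and set(tri) & set(other):
                coupled.add(tri)
    sites: set[int] = set()
    for tri in coupled:
        for ci in tri:
            sites.update(topology.constraints[ci].pair)
    return sites


def decouple_masses(
    topology: Topology,
    config: Configuration,
    target_sites: set[int] | str = "auto",
) -> tuple[Topology, Configuration]:
    """Move the masses of coupled-triangle sites onto carrier sites.

    One new massive, noninteracting site is created per target,
    co-located with and inheriting the mass of its original; the
    originals become massless virtual sites whose geometry is expressed
    in the carrier frame.  Constraints are re-addressed to the carriers.
    The kinetic degree-of-freedom count is unchanged: the added
    coordinates are exactly offset by the added virtual sites.

    ``target_sites="auto"`` selects all sites of edge-sharing (coupled)
    constraint triangles; an empty auto-detection is a warning no-op.
    """
    if config.n_sites != topology.n_sites:
        raise ValidationError("configuration does not match topology")
    if target_sites == "auto":
        targets = _auto_targets(topology)
        if not targets:
            logger.warning("no coupled constraint triangles found; "
                           "decoupling is a no-op")
            return topology, config
    else:
        targets = set(target_sites)
        virtual = {s.index for s in topology.sites if s.is_virtual}
        bad = targets & virtual
        if bad:
            raise ValidationError(
                f"cannot decouple virtual sites: {sorted(bad)}"
            )
        sub = nx.Graph()
        sub.add_nodes_from(targets)
        for c in topology.constraints:
            if c.site_a in targets and c.site_b in targets:
                sub.add_edge(c.site_a, c.site_b)
        if len(targets) > 1 and not nx.is_connected(sub):
            raise ValidationError(
                "target sites must be mutually connected by constraints"
            )

    ordered = sorted(targets)
    n = topology.n_sites
    carrier_of = {t: n + k for k, t in enumerate(ordered)}
    carrier_coords = config.coords[ordered]

    sites: list[Site] = []
    for s in topology.sites:
        if s.index in targets:
            sites.append(Site(index=s.index, name=s.name, mass=0.0,
                              is_virtual=True))
        else:
            sites.append(s)
    for k, t in enumerate(ordered):
        orig = topology.sites[t]
        sites.append(Site(index=n + k, name=f"CM{k + 1}", mass=orig.mass,
                          is_virtual=False))

    constraints = [
        Constraint(carrier_of.get(c.site_a, c.site_a),
                   carrier_of.get(c.site_b, c.site_b), c.length)
        for c in topology.constraints
    ]

    # express every virtual site — the decoupled originals and any
    # pre-existing ones whose parents lost their mass — in the carrier frame
    parent_triple_local = choose_parents(carrier_coords)
    parent_triple = tuple(carrier_of[ordered[i]] for i in parent_triple_local)
    parent_pos = config.coords[[ordered[i] for i in parent_triple_local]]

    vsites: list[VSiteDef] = []
    for v in topology.vsites:
        if any(p in targets for p in v.parents):
            fit = fit_vsite(config.coords[v.site], parent_pos)
            vsites.append(VSiteDef(site=v.site, parents=parent_triple,
                                   coeffs=fit.coeffs))
        else:
            vsites.append(v)
    for t in ordered:
        fit = fit_vsite(config.coords[t], parent_pos)
        vsites.append(VSiteDef(site=t, parents=parent_triple,
                               coeffs=fit.coeffs))

    new_top = Topology(
        sites=sites,
        constraints=constraints,
        bonds=topology.bonds,
        angles=topology.angles,
        dihedrals=topology.dihedrals,
        vsites=vsites,
        exclusions=topology.exclusions,
        name=topology.name,
    )
    new_conf = Configuration(np.vstack([config.coords, carrier_coords]))
    assert new_top.kinetic_dof() == topology.kinetic_dof()
    return new_top, new_conf


# ---------------------------------------------------------------------------
# steps 2-3: greedy Monte Carlo minimization
# ---------------------------------------------------------------------------

def minimize_lambda_max(
    scaffold: RigidBodySpec,
    constraints: list[Constraint],
    cfg: OptimizerConfig,
) -> OptimizationResult:
    """Greedy equimomental Monte Carlo minimization of lambda_max.

    Constraint endpoints index into the scaffold points.  Every proposal
    is an equimomental transform of the *original* scaffold (through a
    cumulative 4D rotation), so total mass, center of mass and inertia
    tensor are preserved to roundoff over the whole run.  A proposal is
    rejected when any pair of scaffold beads comes closer than
    ``cfg.min_distance`` or any mass falls below ``cfg.mass_floor`` of
    the total mass; otherwise it is accepted exactly when it strictly
    lowers lambda_max (no Metropolis temperature).
    """
    pairs = [(c.site_a, c.site_b) for c in constraints]
    if _min_pair_distance(scaffold.positions) < cfg.min_distance:
        raise DegenerateGeometryError(
            f"initial scaffold violates the minimum distance "
            f"{cfg.min_distance} nm"
        )
    dec = decompose(scaffold)
    projector = dec.range_projector()
    total_mass = scaffold.total_mass
    floor = cfg.mass_floor * total_mass

    rng = np.random.default_rng(cfg.rng_seed)
    current = scaffold
    current_lambda = _scaffold_lambda(scaffold.positions, scaffold.masses, pairs)
    trace = [current_lambda]
    u_cum = np.eye(4)
    accepted = proposed = 0

    for _ in range(cfg.max_iters):
        if cfg.target_lambda is not None and current_lambda <= cfg.target_lambda:
            break
        proposed += 1
        u_new = u_cum @ random_so4(cfg.step_scale, rng, projector=projector)
        try:
            candidate = apply_so4(dec, u_new, mass_floor=floor)
        except MassFloorError:
            continue
        if _min_pair_distance(candidate.positions) < cfg.min_distance:
            continue
        lam = _scaffold_lambda(candidate.positions, candidate.masses, pairs)
        if lam < current_lambda:
            current, current_lambda, u_cum = candidate, lam, u_new
            trace.append(lam)
            accepted += 1

    return OptimizationResult(
        scaffold=current,
        lambda_trace=trace,
        initial_lambda=trace[0],
        final_lambda=trace[-1],
        accepted=accepted,
        proposed=proposed,
        constraints=regenerate_constraints(current, pairs),
    )


def regenerate_constraints(
    scaffold: RigidBodySpec,
    constraint_pairs: list[tuple[int, int]],
    min_distance: float | None = None,
) -> list[Constraint]:
    """Prescribe each pair's length as its distance in the scaffold."""
    out = []
    for a, b in constraint_pairs:
        d = float(np.linalg.norm(scaffold.positions[b] - scaffold.positions[a]))
        if min_distance is not None and d < min_distance:
            raise ValidationError(
                f"regenerated constraint {a}-{b} shorter than the "
                f"{min_distance} nm minimum distance"
            )
        out.append(Constraint(a, b, d))
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    """Optimized topology/configuration plus the minimization record."""

    topology: Topology
    config: Configuration
    result: OptimizationResult


def optimize_topology(
    topology: Topology,
    config: Configuration,
    cfg: OptimizerConfig | None = None,
) -> PipelineResult:
    """Run the full decouple / minimize / reconstruct pipeline.

    Only sites participating in constraints enter the scaffold;
    flexibly bonded sites (e.g. a tail bead) are left untouched.  After
    minimization the constraint lengths are regenerated from the
    optimized geometry and every massless site is re-expressed in the
    frame of the optimized scaffold, so all interaction-site positions
    at the reference snapshot are reproduced exactly.
    """
    cfg = cfg or OptimizerConfig()
    top_d, conf_d = decouple_masses(topology, config, "auto")

    scaffold_idx = sorted({i for c in top_d.constraints for i in c.pair})
    local = {g: k for k, g in enumerate(scaffold_idx)}
    scaffold = RigidBodySpec(
        positions=conf_d.coords[scaffold_idx],
        masses=top_d.masses[scaffold_idx],
    )
    local_constraints = [
        Constraint(local[c.site_a], local[c.site_b], c.length)
        for c in top_d.constraints
    ]
    result = minimize_lambda_max(scaffold, local_constraints, cfg)

    before = moment_summary(scaffold)
    after = moment_summary(result.scaffold)
    dev = before.max_relative_deviation(after)
    if dev > 1e-8:
        logger.warning("equimomental deviation %.2e after optimization", dev)

    coords = conf_d.coords.copy()
    coords[scaffold_idx] = result.scaffold.positions
    masses = top_d.masses.copy()
    masses[scaffold_idx] = result.scaffold.masses

    sites = [
        Site(index=s.index, name=s.name, mass=float(masses[s.index]),
             is_virtual=s.is_virtual)
        for s in top_d.sites
    ]
    constraints = [
        Constraint(scaffold_idx[c.site_a], scaffold_idx[c.site_b], c.length)
        for c in result.constraints
    ]

    # refit every massless site in the optimized scaffold's frame; its
    # target is its (unchanged) position in the reference snapshot
    triple_local = choose_parents(result.scaffold)
    triple = tuple(scaffold_idx[i] for i in triple_local)
    parent_pos = result.scaffold.positions[list(triple_local)]
    vsites = [
        VSiteDef(site=v.site, parents=triple,
                 coeffs=fit_vsite(coords[v.site], parent_pos).coeffs)
        for v in top_d.vsites
    ]

    top_opt = Topology(
        sites=sites,
        constraints=constraints,
        bonds=top_d.bonds,
        angles=top_d.angles,
        dihedrals=top_d.dihedrals,
        vsites=vsites,
        exclusions=top_d.exclusions,
        name=top_d.name,
    )
    return PipelineResult(topology=top_opt, config=Configuration(coords),
                          result=result)
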