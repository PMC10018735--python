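"""Synthetic topologies with known analytic structure.

Each generator returns a ``(Topology, Configuration)`` pair whose
coordinates satisfy the generated constraints exactly, so every
diagnostic has a ground truth: the coupled-triangle hinge (the scaffold
used for rigid sterol rings), united-atom alkane chains with optional
angle constraints, planar constrained trapezoids, and a cholesterol-like
hinge molecule with virtual sites and a flexible tail.  The generators
are deterministic — no hidden randomness.

The cholesterol-like registry constants are synthetic: unequal masses
and skewed, near-coplanar triangles chosen to land the spectral radius
in the >0.9 regime that real coarse-grained cholesterol occupies.  They
are not parameters of any published force field.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import DegenerateGeometryError, ValidationError
from .topology import (Angle, Bond, Configuration, Constraint, Dihedral,
                       Site, Topology, VSiteDef)

__all__ = [
    "make_coupled_triangles",
    "make_alkane",
    "make_trapezoid",
    "flip_diagonal",
    "make_hinge_cholesterol_like",
    "HINGE_REGISTRY",
    "CH3_MASS",
    "CH2_MASS",
]

#: United-atom masses (amu) for alkane chains.
CH3_MASS = 15.035
CH2_MASS = 14.027

#: Synthetic cholesterol-like hinge: four near-coplanar ring sites in two
#: skewed coupled triangles (unequal masses), one flexibly bonded tail
#: bead and three out-of-plane virtual sites.  Chosen once so the
#: coupling spectral radius is ~0.95.
HINGE_REGISTRY: dict = {
    "ring_positions": np.array([
        [0.0000, 0.3360, 0.0000],
        [0.0800, 0.0000, 0.0000],
        [0.4888, 0.1600, 0.0320],
        [0.8320, -0.1920, 0.0000],
    ]),
    "ring_masses": np.array([72.0, 36.0, 36.0, 159.0]),
    "tail_position": np.array([1.1500, -0.4500, 0.0000]),
    "tail_mass": 72.0,
    # (parents into the ring, (a, b, c)) of the three virtual sites
    "vsite_defs": [
        ((0, 1, 2), (0.35, 0.25, 0.60)),
        ((1, 2, 3), (0.45, 0.30, -0.50)),
        ((0, 2, 3), (0.20, 0.55, 0.40)),
    ],
    "bond_force": 1250.0,     # kJ/mol/nm^2
    "angle_force": 25.0,      # kJ/mol/rad^2
    "dihedral_force": 5.0,    # kJ/mol
}

#: The five constrained edges of a two-triangle hinge on sites 0..3
#: sharing edge (1, 2).
_HINGE_EDGES = [(0, 1), (0, 2), (1, 2), (1, 3), (2, 3)]


def _constraints_from_coords(coords: np.ndarray,
                             pairs: list[tuple[int, int]]) -> list[Constraint]:
    return [Constraint(a, b, float(np.linalg.norm(coords[b] - coords[a])))
            for a, b in pairs]


def _simple_sites(masses, prefix: str = "B") -> list[Site]:
    return [Site(index=i, name=f"{prefix}{i + 1}", mass=float(m))
            for i, m in enumerate(masses)]


# ---------------------------------------------------------------------------
# coupled triangles
# ---------------------------------------------------------------------------

def make_coupled_triangles(
    side: float = 0.30,
    masses=(72.0, 72.0, 72.0, 72.0),
    positions: np.ndarray | None = None,
) -> tuple[Topology, Configuration]:
    """Two coplanar triangles sharing one edge: 4 sites, 5 constraints.

    By default the triangles are equilateral with the given ``side``;
    passing explicit ``positions`` (4 x 3) builds the same connectivity
    on arbitrary geometry (e.g. the skewed cholesterol-like registry
    values).  Degenerate (collinear) geometry is rejected.
    """
    if positions is None:
        h = side * math.sqrt(3.0) / 2.0
        positions = np.array([
            [-h, 0.0, 0.0],
            [0.0, side / 2.0, 0.0],
            [0.0, -side / 2.0, 0.0],
            [h, 0.0, 0.0],
        ])
    else:
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (4, 3):
            raise ValidationError("positions must be (4, 3)")
    for tri in ((0, 1, 2), (1, 2, 3)):
        p = positions[list(tri)]
        if np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0])) < 1e-9:
            raise DegenerateGeometryError(f"triangle {tri} is collinear")
    topology = Topology(
        sites=_simple_sites(masses),
        constraints=_constraints_from_coords(positions, _HINGE_EDGES),
    )
    return topology, Configuration(positions)


# ---------------------------------------------------------------------------
# united-atom alkanes
# ---------------------------------------------------------------------------

def make_alkane(
    n_sites: int,
    bond_length: float = 0.153,
    angle: float = math.radians(109.47),
    masses=None,
    constrain_angles: bool = True,
    conformation: str = "trans",
) -> tuple[Topology, Configuration]:
    """United-atom alkane chain with constrained bonds.

    The chain is laid out as the planar trans zig-zag.  With
    ``constrain_angles`` the bond angles are fixed the way a constraint
    solver sees them: as ordinary 1-3 distance constraints of length
    ``2 L sin(theta/2)``; otherwise flexible angle terms are emitted.
    Default masses are CH3 at the ends and CH2 in between.
    """
    if n_sites < 2:
        raise ValidationError("an alkane needs at least 2 sites")
    if conformation != "trans":
        raise ValidationError(f"unsupported conformation: {conformation!r}")
    if masses is None:
        masses = [CH3_MASS] + [CH2_MASS] * (n_sites - 2) + [CH3_MASS]
    coords = np.zeros((n_sites, 3))
    for i in range(n_sites):
        coords[i, 0] = i * bond_length * math.sin(angle / 2.0)
        coords[i, 1] = (i % 2) * bond_length * math.cos(angle / 2.0)
    pairs = [(i, i + 1) for i in range(n_sites - 1)]
    angles = []
    if constrain_angles:
        pairs += [(i, i + 2) for i in range(n_sites - 2)]
    else:
        angles = [Angle(i, i + 1, i + 2, angle, 520.0)
                  for i in range(n_sites - 2)]
    topology = Topology(
        sites=_simple_sites(masses, prefix="C"),
        constraints=_constraints_from_coords(coords, pairs),
        angles=angles,
    )
    return topology, Configuration(coords)


# ---------------------------------------------------------------------------
# constrained trapezoids
# ---------------------------------------------------------------------------

#: Default skewed planar quadrilateral (nm): distinct diagonals so that
#: flipping the constrained diagonal changes the coupling spectrum.
_TRAPEZOID_CORNERS = np.array([
    [0.00, 0.00, 0.0],
    [0.52, 0.00, 0.0],
    [0.36, 0.30, 0.0],
    [0.08, 0.28, 0.0],
])


def make_trapezoid(
    corners: np.ndarray | None = None,
    masses=(54.0, 54.0, 36.0, 36.0),
    diagonal: str = "long",
) -> tuple[Topology, Configuration]:
    """Planar four-site ring constrained on its sides and one diagonal.

    Sites 0-1-2-3 run around the quadrilateral; the four sides are
    constrained, plus either the longer or the shorter diagonal
    (``diagonal="long"``/``"short"``) — 5 constraints in total, the
    pattern used by small planar aromatics.  Non-planar corner input is
    rejected.
    """
    coords = np.asarray(_TRAPEZOID_CORNERS if corners is None else corners,
                        dtype=float)
    if coords.shape != (4, 3):
        raise ValidationError("corners must be (4, 3)")
    normal = np.cross(coords[1] - coords[0], coords[2] - coords[0])
    nn = np.linalg.norm(normal)
    if nn < 1e-9:
        raise DegenerateGeometryError("degenerate (collinear) corners")
    if abs(np.dot(coords[3] - coords[0], normal / nn)) > 1e-9:
        raise ValidationError("corners are not coplanar")
    if diagonal not in ("long", "short"):
        raise ValidationError("diagonal must be 'long' or 'short'")
    d02 = np.linalg.norm(coords[2] - coords[0])
    d13 = np.linalg.norm(coords[3] - coords[1])
    longer = (0, 2) if d02 >= d13 else (1, 3)
    shorter = (1, 3) if longer == (0, 2) else (0, 2)
    pairs = [(0, 1), (1, 2), (2, 3), (0, 3),
             longer if diagonal == "long" else shorter]
    topology = Topology(
        sites=_simple_sites(masses),
        constraints=_constraints_from_coords(coords, pairs),
    )
    return topology, Configuration(coords)


def flip_diagonal(topology: Topology, config: Configuration) -> Topology:
    """Swap which diagonal of a 4-site ring is constrained.

    The diagonal is identified structurally: it is the unique constraint
    whose removal leaves the remaining four forming a single 4-cycle.
    It is replaced by the complementary diagonal at its geometric
    distance in ``config``.  Applying the flip twice restores the
    original connectivity.
    """
    if topology.n_sites != 4 or topology.n_constraints != 5:
        raise ValidationError("flip_diagonal expects 4 sites and 5 constraints")
    degree = np.zeros(4, dtype=int)
    for c in topology.constraints:
        degree[c.site_a] += 1
        degree[c.site_b] += 1
    candidates = []
    for i, c in enumerate(topology.constraints):
        if degree[c.site_a] == 3 and degree[c.site_b] == 3:
            candidates.append(i)
    if len(candidates) != 1:
        raise ValidationError(
            "no unique diagonal: the constraint graph is not "
            "a 4-cycle plus one chord"
        )
    diag_idx = candidates[0]
    diag = topology.constraints[diag_idx]
    other_pair = tuple(sorted(set(range(4)) - set(diag.pair)))
    dist = float(np.linalg.norm(config.coords[other_pair[1]] -
                                config.coords[other_pair[0]]))
    constraints = list(topology.constraints)
    constraints[diag_idx] = Constraint(other_pair[0], other_pair[1], dist)
    return Topology(
        sites=topology.sites,
        constraints=constraints,
        bonds=topology.bonds,
        angles=topology.angles,
        dihedrals=topology.dihedrals,
        vsites=topology.vsites,
        exclusions=topology.exclusions,
        name=topology.name,
    )


# ---------------------------------------------------------------------------
# cholesterol-like hinge molecule
# ---------------------------------------------------------------------------

def make_hinge_cholesterol_like() -> tuple[Topology, Configuration]:
    """Synthetic sterol-like hinge: 8 sites, 5 constraints, 3 virtual sites.

    Sites 0-3 are the massive ring beads forming two skewed coupled
    triangles (shared edge 1-2), site 4 is the flexibly bonded tail bead
    and sites 5-7 are out-of-plane virtual sites on ring parents.  One
    flexible bond, one angle and one dihedral connect the tail.  The
    registry geometry puts the coupling spectral radius near 0.95 — the
    regime of real coarse-grained cholesterol — while all constrained
    edges stay above the 0.27 nm optimizer floor.
    """
    reg = HINGE_REGISTRY
    ring = reg["ring_positions"]
    tail = reg["tail_position"]

    vsite_coords = []
    for (p1, p2, p3), (a, b, c) in reg["vsite_defs"]:
        r12 = ring[p2] - ring[p1]
        r13 = ring[p3] - ring[p1]
        vsite_coords.append(ring[p1] + a * r12 + b * r13 + c * np.cross(r12, r13))
    coords = np.vstack([ring, tail[None, :], np.array(vsite_coords)])

    sites = [Site(i, f"R{i + 1}", float(m)) for i, m in
             enumerate(reg["ring_masses"])]
    sites.append(Site(4, "TAIL", float(reg["tail_mass"])))
    sites += [Site(5 + k, f"V{k + 1}", 0.0, is_virtual=True)
              for k in range(3)]
    vsites = [VSiteDef(site=5 + k, parents=parents, coeffs=coeffs)
              for k, (parents, coeffs) in enumerate(reg["vsite_defs"])]

    bond_len = float(np.linalg.norm(tail - ring[3]))
    v1, v2 = ring[2] - ring[3], tail - ring[3]
    theta = math.acos(float(np.dot(v1, v2) /
                            (np.linalg.norm(v1) * np.linalg.norm(v2))))
    b1 = np.cross(ring[2] - ring[1], ring[3] - ring[2])
    b2 = np.cross(ring[3] - ring[2], tail - ring[3])
    phi = math.atan2(
        float(np.dot(np.cross(b1, b2), (ring[3] - ring[2]) /
                     np.linalg.norm(ring[3] - ring[2]))),
        float(np.dot(b1, b2)),
    )

    topology = Topology(
        sites=sites,
        constraints=_constraints_from_coords(coords, _HINGE_EDGES),
        bonds=[Bond(3, 4, bond_len, reg["bond_force"])],
        angles=[Angle(2, 3, 4, theta, reg["angle_force"])],
        dihedrals=[Dihedral(1, 2, 3, 4, phi, reg["dihedral_force"])],
        vsites=vsites,
        name="CHOLX",
    )
    return topology, Configuration(coords)
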