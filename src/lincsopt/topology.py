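"""Molecular topology and configuration model.

A :class:`Topology` holds the particles of a single molecule together with
its distance constraints, flexible bonded terms and virtual-site
definitions; a :class:`Configuration` holds one Cartesian snapshot.

Conventions
-----------
* Internal units are nm, amu and radians.  PDB coordinates (Å) are
  converted to nm on read; flexible-angle equilibria are stored in
  radians and emitted in degrees, matching the itp dialect.
* Site indices are 0-based internally and 1-based in files.
* Virtual sites are massless interaction sites constructed geometrically
  from three massive parents each step; they carry forces but no kinetic
  energy.  Distance constraints must connect two massive sites, because
  a constraint on a massless endpoint has an infinite inverse mass and
  the constraint algebra is undefined.

The itp dialect covers the directives ``[atoms]``, ``[constraints]``,
``[bonds]``, ``[angles]``, ``[dihedrals]``, ``[virtual_sites3]``,
``[exclusions]`` and ``[moleculetype]``.  Unknown directives are skipped
with a logged warning so that real force-field files remain loadable.
Preprocessor directives (``#include``, ``#define``) are not supported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParseError, ValidationError

__all__ = [
    "Site",
    "Constraint",
    "VSiteDef",
    "Bond",
    "Angle",
    "Dihedral",
    "Topology",
    "Configuration",
    "GeometryReport",
    "read_topology",
    "read_configuration",
    "write_topology",
    "write_gro",
    "validate_geometry",
]

logger = logging.getLogger(__name__)

#: Directives the parser understands.  Anything else is skipped with a
#: warning.  ``virtual_sitesn`` is recognized but rejected explicitly:
#: an n-body construction cannot be represented by the three-parent
#: out-of-plane form used throughout this package.
_KNOWN_SECTIONS = {
    "moleculetype",
    "atoms",
    "constraints",
    "bonds",
    "angles",
    "dihedrals",
    "virtual_sites3",
    "exclusions",
}


@dataclass(frozen=True)
class Site:
    """A particle: index, label, mass (amu) and virtual-site flag."""

    index: int
    name: str
    mass: float
    is_virtual: bool = False

    def __post_init__(self):
        if self.is_virtual and self.mass != 0.0:
            raise ValidationError(
                f"virtual site {self.name} (index {self.index}) must have zero mass"
            )
        if not self.is_virtual and self.mass <= 0.0:
            raise ValidationError(
                f"massive site {self.name} (index {self.index}) must have mass > 0"
            )


@dataclass(frozen=True)
class Constraint:
    """A holonomic distance constraint with prescribed length (nm)."""

    site_a: int
    site_b: int
    length: float

    def __post_init__(self):
        if self.site_a == self.site_b:
            raise ValidationError("constraint endpoints must differ")
        if self.length <= 0.0:
            raise ValidationError("constraint length must be positive")

    @property
    def pair(self) -> tuple[int, int]:
        return (self.site_a, self.site_b)


@dataclass(frozen=True)
class VSiteDef:
    """Out-of-plane construction of a virtual site from three parents.

    The constructed position is::

        r = r1 + a*(r2 - r1) + b*(r3 - r1) + c*(r2 - r1) x (r3 - r1)

    with dimensionless in-plane coefficients ``a``, ``b`` and an
    out-of-plane coefficient ``c`` in nm^-1 (the cross product carries
    nm^2).  This is the Gromacs ``virtual_sites3`` funct-4 convention.
    """

    site: int
    parents: tuple[int, int, int]
    coeffs: tuple[float, float, float]

    def __post_init__(self):
        if len(set(self.parents)) != 3:
            raise ValidationError("virtual-site parents must be pairwise distinct")


@dataclass(frozen=True)
class Bond:
    """A flexible harmonic bond (length in nm, k in kJ/mol/nm^2)."""

    site_a: int
    site_b: int
    length: float
    force_const: float


@dataclass(frozen=True)
class Angle:
    """A flexible harmonic angle (equilibrium in radians, k in kJ/mol/rad^2)."""

    site_a: int
    site_b: int
    site_c: int
    theta: float
    force_const: float


@dataclass(frozen=True)
class Dihedral:
    """A proper dihedral (equilibrium in radians, k in kJ/mol, multiplicity)."""

    site_a: int
    site_b: int
    site_c: int
    site_d: int
    phi: float
    force_const: float
    multiplicity: int = 1


@dataclass
class Topology:
    """A validated single-molecule topology."""

    sites: list[Site]
    constraints: list[Constraint] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    angles: list[Angle] = field(default_factory=list)
    dihedrals: list[Dihedral] = field(default_factory=list)
    vsites: list[VSiteDef] = field(default_factory=list)
    exclusions: list[tuple[int, ...]] = field(default_factory=list)
    name: str = "MOL"

    def __post_init__(self):
        self.validate()

    # -- derived views -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_virtual(self) -> int:
        return sum(s.is_virtual for s in self.sites)

    @property
    def n_constraints(self) -> int:
        return len(self.constraints)

    @property
    def masses(self) -> np.ndarray:
        return np.array([s.mass for s in self.sites])

    def massive_indices(self) -> list[int]:
        return [s.index for s in self.sites if not s.is_virtual]

    def kinetic_dof(self) -> int:
        """Kinetic degrees of freedom: 3N - 3*N_virtual - K."""
        return 3 * self.n_sites - 3 * self.n_virtual - self.n_constraints

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        n = self.n_sites
        for i, s in enumerate(self.sites):
            if s.index != i:
                raise ValidationError(
                    f"site {s.name}: index {s.index} out of order (expected {i})"
                )
        virtual = {s.index for s in self.sites if s.is_virtual}
        for c in self.constraints:
            for end in c.pair:
                if not 0 <= end < n:
                    raise ValidationError(f"constraint index {end} out of range")
                if end in virtual:
                    raise ValidationError(
                        f"constraint {c.site_a}-{c.site_b} references massless "
                        f"site {end}; constraints require massive endpoints"
                    )
        defined = [v.site for v in self.vsites]
        if len(set(defined)) != len(defined):
            raise ValidationError("a virtual site has more than one definition")
        if set(defined) != virtual:
            missing = virtual - set(defined)
            extra = set(defined) - virtual
            parts = []
            if missing:
                parts.append(f"virtual sites without definition: {sorted(missing)}")
            if extra:
                parts.append(f"definitions for non-virtual sites: {sorted(extra)}")
            raise ValidationError("; ".join(parts))
        for v in self.vsites:
            for p in v.parents:
                if not 0 <= p < n:
                    raise ValidationError(f"virtual-site parent {p} out of range")
                if p in virtual:
                    raise ValidationError(
                        f"virtual-site parent {p} must be a massive site"
                    )
        for group in (self.bonds, self.angles, self.dihedrals):
            for term in group:
                for attr in ("site_a", "site_b", "site_c", "site_d"):
                    idx = getattr(term, attr, None)
                    if idx is not None and not 0 <= idx < n:
                        raise ValidationError(f"bonded-term index {idx} out of range")


@dataclass
class Configuration:
    """One Cartesian snapshot: an (N, 3) coordinate array in nm."""

    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coordinates must be an (N, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")

    @property
    def n_sites(self) -> int:
        return self.coords.shape[0]

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "Configuration":
        """Return a rigidly moved copy (rotation applied first)."""
        out = self.coords
        if rotation is not None:
            out = out @ np.asarray(rotation).T
        if translation is not None:
            out = out + np.asarray(translation)
        return Configuration(out.copy())


# ---------------------------------------------------------------------------
# itp reading
# ---------------------------------------------------------------------------

def _tokenize(text: str):
    """Yield (line_number, section, tokens) for content lines."""
    section = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split(";", 1)[0].strip()
        if not line:
            continue
        if line.startswith("#"):
            raise ParseError(
                f"preprocessor directive not supported: {line.split()[0]}", lineno
            )
        if line.startswith("["):
            if not line.endswith("]"):
                raise ParseError("malformed section header", lineno)
            section = line[1:-1].strip().lower()
            if section == "virtual_sitesn":
                raise ParseError(
                    "[virtual_sitesn] is not supported; only three-parent "
                    "virtual sites ([virtual_sites3]) can be represented",
                    lineno,
                )
            if section not in _KNOWN_SECTIONS:
                logger.warning("ignoring unknown directive [%s] (line %d)",
                               section, lineno)
            continue
        yield lineno, section, line.split()


def _floats(tokens, count, lineno, what):
    try:
        return [float(t) for t in tokens[:count]]
    except ValueError as exc:
        raise ParseError(f"non-numeric value in {what}: {exc}", lineno) from None


def _ints(tokens, count, lineno, what):
    try:
        return [int(t) for t in tokens[:count]]
    except ValueError as exc:
        raise ParseError(f"non-integer index in {what}: {exc}", lineno) from None


def read_topology(text: str) -> Topology:
    """Parse an itp-dialect document into a validated :class:`Topology`.

    Raises :class:`ParseError` naming the offending line for malformed
    directives, and :class:`ValidationError` when the parsed structure
    violates a topology invariant (e.g. a constraint on a massless site).
    """
    name = "MOL"
    atoms: list[tuple[str, float]] = []
    constraints: list[tuple[int, int, float]] = []
    bonds: list[Bond] = []
    angles: list[Angle] = []
    dihedrals: list[Dihedral] = []
    vsite_rows: list[tuple[int, tuple[int, int, int], int, tuple[float, ...], int]] = []
    exclusions: list[tuple[int, ...]] = []

    for lineno, section, tok in _tokenize(text):
        if section is None:
            raise ParseError("content before any [section] header", lineno)
        if section == "moleculetype":
            name = tok[0]
        elif section == "atoms":
            # nr type resnr residue atom cgnr charge mass
            if len(tok) < 8:
                raise ParseError("atom record needs 8 fields "
                                 "(nr type resnr residue atom cgnr charge mass)",
                                 lineno)
            (mass,) = _floats(tok[7:8], 1, lineno, "[atoms]")
            atoms.append((tok[4], mass))
        elif section == "constraints":
            if len(tok) < 4:
                raise ParseError("constraint record needs 4 fields "
                                 "(i j funct length)", lineno)
            i, j = _ints(tok, 2, lineno, "[constraints]")
            (length,) = _floats(tok[3:4], 1, lineno, "[constraints]")
            constraints.append((i - 1, j - 1, length))
        elif section == "bonds":
            if len(tok) < 5:
                raise ParseError("bond record needs 5 fields (i j funct b0 k)",
                                 lineno)
            i, j = _ints(tok, 2, lineno, "[bonds]")
            b0, k = _floats(tok[3:5], 2, lineno, "[bonds]")
            bonds.append(Bond(i - 1, j - 1, b0, k))
        elif section == "angles":
            if len(tok) < 6:
                raise ParseError("angle record needs 6 fields "
                                 "(i j k funct theta0 k)", lineno)
            i, j, k = _ints(tok, 3, lineno, "[angles]")
            theta0, kf = _floats(tok[4:6], 2, lineno, "[angles]")
            angles.append(Angle(i - 1, j - 1, k - 1, math.radians(theta0), kf))
        elif section == "dihedrals":
            if len(tok) < 7:
                raise ParseError("dihedral record needs at least 7 fields "
                                 "(i j k l funct phi0 k [mult])", lineno)
            i, j, k, l = _ints(tok, 4, lineno, "[dihedrals]")
            phi0, kf = _floats(tok[5:7], 2, lineno, "[dihedrals]")
            mult = int(tok[7]) if len(tok) > 7 else 1
            dihedrals.append(Dihedral(i - 1, j - 1, k - 1, l - 1,
                                      math.radians(phi0), kf, mult))
        elif section == "virtual_sites3":
            if len(tok) < 5:
                raise ParseError("virtual_sites3 record needs at least 5 fields",
                                 lineno)
            s, p1, p2, p3, funct = _ints(tok, 5, lineno, "[virtual_sites3]")
            if funct == 4:
                if len(tok) < 8:
                    raise ParseError("funct-4 virtual site needs coefficients a b c",
                                     lineno)
                a, b, c = _floats(tok[5:8], 3, lineno, "[virtual_sites3]")
            elif funct == 1:
                # in-plane linear form: r = r1 + a r12 + b r13, c = 0
                if len(tok) < 7:
                    raise ParseError("funct-1 virtual site needs coefficients a b",
                                     lineno)
                a, b = _floats(tok[5:7], 2, lineno, "[virtual_sites3]")
                c = 0.0
            else:
                raise ParseError(f"unsupported virtual_sites3 funct {funct} "
                                 "(only 1 and 4)", lineno)
            vsite_rows.append((s - 1, (p1 - 1, p2 - 1, p3 - 1), funct,
                               (a, b, c), lineno))
        elif section == "exclusions":
            idx = _ints(tok, len(tok), lineno, "[exclusions]")
            exclusions.append(tuple(i - 1 for i in idx))

    if not atoms:
        raise ParseError("document contains no [atoms] section")
    if not constraints and not bonds:
        raise ParseError("document contains neither [constraints] nor [bonds]")

    virtual = {row[0] for row in vsite_rows}
    sites = [
        Site(index=i, name=nm, mass=mass, is_virtual=i in virtual)
        for i, (nm, mass) in enumerate(atoms)
    ]
    vsites = [VSiteDef(site=s, parents=parents, coeffs=coeffs)
              for s, parents, _funct, coeffs, _ln in vsite_rows]
    return Topology(
        sites=sites,
        constraints=[Constraint(i, j, d) for i, j, d in constraints],
        bonds=bonds,
        angles=angles,
        dihedrals=dihedrals,
        vsites=vsites,
        exclusions=exclusions,
        name=name,
    )


# ---------------------------------------------------------------------------
# itp writing
# ---------------------------------------------------------------------------

def write_topology(topology: Topology) -> str:
    """Serialize a :class:`Topology` back to the itp dialect.

    ``read_topology(write_topology(t))`` reproduces ``t`` up to numeric
    formatting (lengths to 5 decimals, virtual-site coefficients to 6).
    """
    t = topology
    out = []
    out.append("[ moleculetype ]")
    out.append("; name  nrexcl")
    out.append(f"{t.name}  1")
    out.append("")
    out.append("[ atoms ]")
    out.append(";  nr type resnr residue atom cgnr charge     mass")
    for s in t.sites:
        out.append(f"{s.index + 1:5d} {'V' if s.is_virtual else 'P1':>4s} "
                   f"{1:5d} {t.name:>7s} {s.name:>5s} {s.index + 1:5d} "
                   f"{0.0:7.3f} {s.mass:9.4f}")
    if t.constraints:
        out.append("")
        out.append("[ constraints ]")
        out.append(";   i    j funct   length")
        for c in t.constraints:
            out.append(f"{c.site_a + 1:5d} {c.site_b + 1:4d} {1:5d} "
                       f"{c.length:.5f}")
    if t.bonds:
        out.append("")
        out.append("[ bonds ]")
        out.append(";   i    j funct       b0        k")
        for b in t.bonds:
            out.append(f"{b.site_a + 1:5d} {b.site_b + 1:4d} {1:5d} "
                       f"{b.length:.5f} {b.force_const:10.2f}")
    if t.angles:
        out.append("")
        out.append("[ angles ]")
        out.append(";   i    j    k funct   theta0        k")
        for a in t.angles:
            out.append(f"{a.site_a + 1:5d} {a.site_b + 1:4d} {a.site_c + 1:4d} "
                       f"{2:5d} {math.degrees(a.theta):8.3f} "
                       f"{a.force_const:10.2f}")
    if t.dihedrals:
        out.append("")
        out.append("[ dihedrals ]")
        out.append(";   i    j    k    l funct     phi0        k mult")
        for d in t.dihedrals:
            out.append(f"{d.site_a + 1:5d} {d.site_b + 1:4d} {d.site_c + 1:4d} "
                       f"{d.site_d + 1:4d} {1:5d} {math.degrees(d.phi):8.3f} "
                       f"{d.force_const:8.2f} {d.multiplicity:4d}")
    if t.vsites:
        out.append("")
        out.append("[ virtual_sites3 ]")
        out.append("; site   p1   p2   p3 funct        a        b        c")
        for v in t.vsites:
            a, b, c = v.coeffs
            out.append(f"{v.site + 1:5d} {v.parents[0] + 1:4d} "
                       f"{v.parents[1] + 1:4d} {v.parents[2] + 1:4d} {4:5d} "
                       f"{a:9.6f} {b:9.6f} {c:9.6f}")
    if t.exclusions:
        out.append("")
        out.append("[ exclusions ]")
        for group in t.exclusions:
            out.append(" ".join(str(i + 1) for i in group))
    out.append("")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# coordinate I/O
# ---------------------------------------------------------------------------

def read_configuration(text: str, topology: Topology) -> Configuration:
    """Read a GRO- or PDB-dialect snapshot matched to ``topology``.

    The format is auto-detected: documents containing ATOM/HETATM records
    are treated as PDB (Å, converted to nm), anything else as GRO (nm).
    Site order must match the topology's atom order.
    """
    if any(line.startswith(("ATOM", "HETATM")) for line in text.splitlines()):
        coords = _read_pdb(text)
    else:
        coords = _read_gro(text)
    if coords.shape[0] != topology.n_sites:
        raise ValidationError(
            f"coordinate count {coords.shape[0]} does not match "
            f"topology site count {topology.n_sites}"
        )
    return Configuration(coords)


def _read_gro(text: str) -> np.ndarray:
    lines = text.splitlines()
    if len(lines) < 3:
        raise ParseError("GRO document needs title, count and box lines")
    try:
        natoms = int(lines[1].strip())
    except ValueError:
        raise ParseError("invalid atom count", 2) from None
    if len(lines) < natoms + 3:
        raise ParseError(f"GRO document truncated: expected {natoms} atom lines")
    coords = np.empty((natoms, 3))
    for i in range(natoms):
        line = lines[2 + i]
        lineno = 3 + i
        try:
            if len(line) >= 44:
                xyz = (line[20:28], line[28:36], line[36:44])
            else:  # free-format fallback
                xyz = line.split()[-3:]
            coords[i] = [float(v) for v in xyz]
        except (ValueError, IndexError):
            raise ParseError("non-numeric coordinate", lineno) from None
    return coords


def _read_pdb(text: str) -> np.ndarray:
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        try:
            rows.append([float(line[30:38]), float(line[38:46]),
                         float(line[46:54])])
        except (ValueError, IndexError):
            raise ParseError("non-numeric coordinate", lineno) from None
    if not rows:
        raise ParseError("PDB document contains no ATOM/HETATM records")
    return np.array(rows) / 10.0  # Å -> nm


def write_gro(topology: Topology, config: Configuration,
              box: float = 5.0) -> str:
    """Serialize a configuration as a GRO document (nm)."""
    if config.n_sites != topology.n_sites:
        raise ValidationError("configuration does not match topology")
    lines = [f"{topology.name} generated by lincsopt", f"{config.n_sites:5d}"]
    for s, (x, y, z) in zip(topology.sites, config.coords):
        lines.append(f"{1:5d}{topology.name:<5.5s}{s.name:>5.5s}{s.index + 1:5d}"
                     f"{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.append(f"{box:10.5f}{box:10.5f}{box:10.5f}")
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# geometry validation
# ---------------------------------------------------------------------------

@dataclass
class GeometryReport:
    """Per-constraint relative deviations |‖r_a−r_b‖ − d| / d."""

    deviations: np.ndarray
    flagged: list[int]
    tol: float

    @property
    def ok(self) -> bool:
        return not self.flagged


def validate_geometry(topology: Topology, config: Configuration,
                      tol: float = 0.01) -> GeometryReport:
    """Check how well a snapshot satisfies the topology's constraints."""
    if config.n_sites != topology.n_sites:
        raise ValidationError("configuration does not match topology")
    devs = np.empty(topology.n_constraints)
    for i, c in enumerate(topology.constraints):
        dist = float(np.linalg.norm(config.coords[c.site_b] -
                                    config.coords[c.site_a]))
        devs[i] = abs(dist - c.length) / c.length
    flagged = [i for i, d in enumerate(devs) if d > tol]
    return GeometryReport(deviations=devs, flagged=flagged, tol=tol)
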