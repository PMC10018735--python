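import math

import numpy as np
import pytest

from lincsopt import (Configuration, NonConvergentError, Topology,
                      coupling_matrix, detect_coupled_triangles,
                      dof_correction_factor, exact_inverse, gradient_matrix,
                      lambda_max, lincs_project, make_alkane,
                      make_coupled_triangles, required_lincs_order,
                      series_inverse)
from lincsopt.errors import DegenerateGeometryError, ValidationError
from lincsopt.topology import Bond, Constraint, Site

from conftest import all_fixture_pairs, rigid_motion


def simple_topology(masses, pairs, coords):
    """Bare constraint topology with lengths taken from the coordinates."""
    sites = [Site(i, f"A{i+1}", m) for i, m in enumerate(masses)]
    cons = [Constraint(a, b, float(np.linalg.norm(coords[b] - coords[a])))
            for a, b in pairs]
    return Topology(sites=sites, constraints=cons), Configuration(coords)


def oracle_coupling(topology, config):
    """Independent entrywise construction of the coupling matrix.

    Off-diagonal entries are the cosine of the angle between the two
    constraint directions at a shared site, times the shared inverse
    mass and the two scale factors; the sign follows the gradient
    orientations at the shared site.
    """
    cons = topology.constraints
    masses = topology.masses
    K = len(cons)
    coords = config.coords
    units, S = [], []
    for c in cons:
        u = coords[c.site_b] - coords[c.site_a]
        units.append(u / np.linalg.norm(u))
        S.append(1.0 / math.sqrt(1.0 / masses[c.site_a] + 1.0 / masses[c.site_b]))
    A = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            shared = set(cons[i].pair) & set(cons[j].pair)
            total = 0.0
            for k in shared:
                gi = units[i] if k == cons[i].site_b else -units[i]
                gj = units[j] if k == cons[j].site_b else -units[j]
                total += float(np.dot(gi, gj)) / masses[k]
            A[i, j] = A[j, i] = -S[i] * S[j] * total
    return A


class TestGradientMatrix:
    def test_single_constraint_along_x(self):
        top, conf = simple_topology([10.0, 10.0], [(0, 1)],
                                    np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        g = gradient_matrix(top, conf)
        np.testing.assert_allclose(g.B[0], [-1, 0, 0, 1, 0, 0], atol=1e-15)

    @pytest.mark.parametrize("name,pair", all_fixture_pairs(),
                             ids=[n for n, _ in all_fixture_pairs()])
    def test_row_norms_are_sqrt_two(self, name, pair):
        g = gradient_matrix(*pair)
        np.testing.assert_allclose(np.linalg.norm(g.B, axis=1),
                                   math.sqrt(2.0), rtol=1e-12)

    def test_equilateral_block_angles_recover_sixty_degrees(self, equilateral):
        top, conf = equilateral
        g = gradient_matrix(top, conf)
        # constraints 0 (0-1) and 2 (1-2) share site 1
        b0 = -g.B[0, 3:6]   # direction of constraint 0 at site 1
        b2 = g.B[2, 3:6]    # direction of constraint 2 away from site 1
        angle = math.degrees(math.acos(abs(float(np.dot(b0, b2)))))
        assert angle == pytest.approx(60.0, abs=1e-9)

    def test_coincident_sites_raise(self):
        top, conf = simple_topology([10.0, 10.0], [(0, 1)],
                                    np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        conf2 = Configuration(np.zeros((2, 3)) + 0.5)
        with pytest.raises(DegenerateGeometryError):
            gradient_matrix(top, conf2)


class TestCouplingMatrix:
    def test_single_constraint_is_scalar_zero(self):
        top, conf = simple_topology([10.0, 10.0], [(0, 1)],
                                    np.array([[0.0, 0, 0], [0.47, 0, 0]]))
        cm = coupling_matrix(top, conf)
        assert cm.K == 1
        assert cm.A[0, 0] == 0.0
        assert cm.lambda_max == 0.0
        assert cm.convergent

    def test_right_angle_decouples(self):
        coords = np.array([[1.0, 0, 0], [0.0, 0, 0], [0.0, 1.0, 0]])
        top, conf = simple_topology([12.0, 12.0, 12.0], [(1, 0), (1, 2)], coords)
        cm = coupling_matrix(top, conf)
        assert cm.A[0, 1] == pytest.approx(0.0, abs=1e-14)

    def test_collinear_trimer_half(self):
        coords = np.array([[0.0, 0, 0], [0.3, 0, 0], [0.6, 0, 0]])
        top, conf = simple_topology([15.0, 15.0, 15.0], [(0, 1), (1, 2)], coords)
        cm = coupling_matrix(top, conf)
        # hand evaluation of I - S (B M^-1 B^T) S for the 2x2 case
        assert cm.A[0, 1] == pytest.approx(0.5, abs=1e-12)
        assert cm.lambda_max == pytest.approx(0.5, abs=1e-12)

    def test_equal_mass_coupled_equilateral_triangles(self, equilateral):
        cm = coupling_matrix(*equilateral)
        assert cm.lambda_max == pytest.approx(0.5, abs=1e-9)

    @pytest.mark.parametrize("name,pair", all_fixture_pairs(),
                             ids=[n for n, _ in all_fixture_pairs()])
    def test_agrees_with_entrywise_oracle(self, name, pair):
        cm = coupling_matrix(*pair)
        np.testing.assert_allclose(cm.A, oracle_coupling(*pair), atol=1e-12)

    def test_diagonal_zero_and_symmetric(self, hinge):
        cm = coupling_matrix(*hinge)
        assert np.all(np.diag(cm.A) == 0.0)
        np.testing.assert_allclose(cm.A, cm.A.T, atol=1e-14)
        assert np.all(cm.S > 0)


class TestLambdaMax:
    def test_zero_matrix(self):
        assert lambda_max(np.zeros((3, 3))) == 0.0

    def test_angle_constrained_butane(self, butane):
        cm = coupling_matrix(*butane)
        assert round(cm.lambda_max, 1) == 0.8

    def test_angle_constrained_pentane_diverges(self, pentane):
        cm = coupling_matrix(*pentane)
        assert round(cm.lambda_max, 1) == 1.2
        assert not cm.convergent

    def test_printed_values_insensitive_to_united_atom_masses(self):
        # one-decimal diagnostics must not hinge on the exact UA masses
        for masses in (None, [14.5] * 4):
            top, conf = make_alkane(4, masses=masses)
            assert round(coupling_matrix(top, conf).lambda_max, 1) == 0.8

    def test_invariant_under_rigid_motion(self, hinge):
        top, conf = hinge
        lam = coupling_matrix(top, conf).lambda_max
        for seed in range(3):
            moved = rigid_motion(conf, seed=seed)
            assert coupling_matrix(top, moved).lambda_max == \
                pytest.approx(lam, rel=1e-10)

    def test_invariant_under_uniform_mass_scaling(self, hinge):
        top, conf = hinge
        lam = coupling_matrix(top, conf).lambda_max
        scaled = Topology(
            sites=[Site(s.index, s.name, s.mass * 7.3, s.is_virtual)
                   if not s.is_virtual else s for s in top.sites],
            constraints=top.constraints, bonds=top.bonds, angles=top.angles,
            dihedrals=top.dihedrals, vsites=top.vsites, name=top.name)
        assert coupling_matrix(scaled, conf).lambda_max == \
            pytest.approx(lam, rel=1e-10)

    def test_invariant_under_uniform_length_scaling(self, hinge):
        top, conf = hinge
        lam = coupling_matrix(top, conf).lambda_max
        scaled_top = Topology(
            sites=top.sites,
            constraints=[Constraint(c.site_a, c.site_b, c.length * 2.5)
                         for c in top.constraints],
            bonds=top.bonds, angles=top.angles, dihedrals=top.dihedrals,
            vsites=top.vsites, name=top.name)
        scaled_conf = Configuration(conf.coords * 2.5)
        assert coupling_matrix(scaled_top, scaled_conf).lambda_max == \
            pytest.approx(lam, rel=1e-10)

    def test_constraint_orientation_flip_preserves_spectrum(self, hinge):
        top, conf = hinge
        lam = coupling_matrix(top, conf).lambda_max
        flipped = [Constraint(c.site_b, c.site_a, c.length) if i == 2 else c
                   for i, c in enumerate(top.constraints)]
        top2 = Topology(sites=top.sites, constraints=flipped, bonds=top.bonds,
                        angles=top.angles, dihedrals=top.dihedrals,
                        vsites=top.vsites, name=top.name)
        cm1, cm2 = coupling_matrix(top, conf), coupling_matrix(top2, conf)
        assert cm2.lambda_max == pytest.approx(lam, rel=1e-12)
        # conjugation by a sign matrix: magnitudes match entrywise
        np.testing.assert_allclose(np.abs(cm1.A), np.abs(cm2.A), atol=1e-12)


class TestRequiredOrder:
    @pytest.mark.parametrize("lam,expected", [
        (0.4, 4), (0.5, 5), (0.8, 16), (0.73, 11), (0.71, 10),
    ])
    def test_rule_of_thumb(self, lam, expected):
        assert required_lincs_order(lam) == expected

    def test_out_of_domain(self):
        with pytest.raises(NonConvergentError):
            required_lincs_order(1.2)
        with pytest.raises(ValueError):
            required_lincs_order(-0.1)

    def test_clamped_to_at_least_one(self):
        assert required_lincs_order(1e-6) == 1


class TestSeriesInverse:
    def test_zero_matrix_gives_identity(self):
        np.testing.assert_array_equal(series_inverse(np.zeros((4, 4)), 7),
                                      np.eye(4))

    def test_order_zero_is_identity(self, hinge):
        A = coupling_matrix(*hinge).A
        np.testing.assert_array_equal(series_inverse(A, 0), np.eye(A.shape[0]))

    @pytest.mark.parametrize("name,pair", all_fixture_pairs(),
                             ids=[n for n, _ in all_fixture_pairs()])
    def test_geometric_remainder_bound(self, name, pair):
        cm = coupling_matrix(*pair)
        if not cm.convergent:
            pytest.skip("bound only holds for a convergent series")
        lam = cm.lambda_max
        exact = exact_inverse(cm.A)
        for order in (2, 4, 8):
            err = np.linalg.norm(series_inverse(cm.A, order) - exact, ord=2)
            bound = lam ** (order + 1) / (1.0 - lam)
            assert err <= bound + 1e-12

    def test_exact_inverse_is_true_inverse(self, equilateral):
        A = coupling_matrix(*equilateral).A
        K = A.shape[0]
        np.testing.assert_allclose((np.eye(K) - A) @ exact_inverse(A),
                                   np.eye(K), atol=1e-12)


class TestLincsProject:
    def test_satisfied_constraints_unchanged(self, hinge):
        top, conf = hinge
        for mode in ("exact", 8):
            res = lincs_project(conf, top, conf, mode=mode)
            np.testing.assert_allclose(res.config.coords, conf.coords,
                                       atol=1e-12)
            assert res.series_convergent

    def test_single_stretched_constraint_symmetric_correction(self):
        coords = np.array([[0.0, 0, 0], [0.47, 0, 0]])
        top, conf = simple_topology([72.0, 72.0], [(0, 1)], coords)
        stretched = Configuration(np.array([[-0.01, 0, 0], [0.48, 0, 0]]))
        res = lincs_project(stretched, top, conf, mode="exact")
        moved = res.config.coords - stretched.coords
        np.testing.assert_allclose(moved[0], -moved[1], atol=1e-12)
        d = np.linalg.norm(res.config.coords[1] - res.config.coords[0])
        assert d == pytest.approx(0.47, abs=1e-9)

    def test_truncated_converges_to_exact_with_order(self, equilateral):
        top, conf = equilateral
        rng = np.random.default_rng(5)
        stretch = conf.coords * (1.0 + 0.01)
        r_unc = Configuration(stretch + rng.normal(scale=1e-4,
                                                   size=conf.coords.shape))
        exact = lincs_project(r_unc, top, conf, mode="exact").config.coords
        errs = []
        for order in range(1, 13):
            approx = lincs_project(r_unc, top, conf, mode=order).config.coords
            errs.append(np.max(np.abs(approx - exact)))
        assert all(b <= a + 1e-15 for a, b in zip(errs, errs[1:]))
        assert errs[-1] < 1e-3 * errs[0]

    def test_exact_projection_reduces_residual(self, equilateral):
        top, conf = equilateral
        rng = np.random.default_rng(9)
        r_unc = Configuration(conf.coords +
                              rng.normal(scale=0.002, size=conf.coords.shape))
        def max_residual(c):
            return max(abs(np.linalg.norm(c.coords[b] - c.coords[a]) - con.length)
                       for con in top.constraints
                       for a, b in [con.pair])
        res = lincs_project(r_unc, top, conf, mode="exact")
        assert max_residual(res.config) < max_residual(r_unc)

    def test_divergent_truncation_flagged(self, pentane):
        top, conf = pentane
        r_unc = Configuration(conf.coords * 1.01)
        with pytest.warns(RuntimeWarning, match="diverges"):
            res = lincs_project(r_unc, top, conf, mode=4)
        assert not res.series_convergent


class TestTriangleDetection:
    def test_chain_has_no_triangles(self):
        top, _ = make_alkane(4, constrain_angles=False)
        assert detect_coupled_triangles(top) == []

    def test_coupled_triangles_share_an_edge(self, equilateral):
        top, _ = equilateral
        tris = detect_coupled_triangles(top)
        assert len(tris) == 2
        shared = set(tris[0]) & set(tris[1])
        assert len(shared) == 1  # the shared-edge constraint

    def test_large_rings_have_no_triangles(self):
        # fused 5- and 6-cycles, all edges constrained, triangle-free
        ring = [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0),
                (4, 5), (5, 6), (6, 7), (7, 8), (8, 0)]
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(9, 3))
        sites = [Site(i, f"C{i+1}", 12.011) for i in range(9)]
        cons = [Constraint(a, b, float(np.linalg.norm(coords[b] - coords[a])))
                for a, b in ring]
        top = Topology(sites=sites, constraints=cons)
        assert detect_coupled_triangles(top) == []


class TestDofCorrection:
    def test_original_hinge_is_24_over_10(self, hinge):
        top, _ = hinge
        assert dof_correction_factor(top) == pytest.approx(2.4)

    def test_no_constraints_no_virtuals_is_unity(self):
        sites = [Site(i, f"A{i+1}", 10.0) for i in range(3)]
        top = Topology(sites=sites, constraints=[],
                       bonds=[Bond(0, 1, 0.3, 100.0)])
        assert dof_correction_factor(top) == 1.0

    def test_overconstrained_raises(self):
        sites = [Site(0, "A1", 10.0), Site(1, "A2", 10.0)]
        cons = [Constraint(0, 1, l) for l in (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)]
        top = Topology(sites=sites, constraints=cons)
        with pytest.raises(ValidationError):
            dof_correction_factor(top)
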