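"""Interface metrics against independent brute-force recomputation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from groovebinder.fixtures import sc_toy_surfaces
from groovebinder.metrics import (
    BinningError, Distogram, DomainError, PaeMatrix, SizeError,
    UndefinedInterfaceError, cms_from_surfaces, contact_molecular_surface,
    contact_probability_loss, cubic_decay_scale, dot_surface, interface_pae,
    radius_of_gyration, rg_guiding_potential, rg_loss_normalized, sasa,
    sc_from_surfaces, shape_complementarity, DotSurface,
)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration([[1.0, 2.0, 3.0]]) == 0.0

    def test_two_atoms_half_distance(self):
        assert radius_of_gyration([[0, 0, 0], [0, 0, 7.0]]) == pytest.approx(3.5)

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=(50, 3)) * 8
        brute = np.sqrt(np.mean(np.linalg.norm(x - x.mean(0), axis=1) ** 2))
        assert abs(radius_of_gyration(x) - brute) < 1e-9

    def test_empty_raises(self):
        with pytest.raises(SizeError):
            radius_of_gyration(np.empty((0, 3)))

    def test_rigid_motion_invariance(self, rng):
        x = rng.normal(size=(30, 3))
        R = Rotation.random(random_state=5).as_matrix()
        assert radius_of_gyration(x @ R.T + 17.0) == pytest.approx(
            radius_of_gyration(x), abs=1e-9)


class TestRgNormalized:
    def test_single_residue_zero(self):
        assert rg_loss_normalized([[0.0, 0.0, 0.0]], 1) == 0.0

    def test_homogeneous_scaling(self, rng):
        x = rng.normal(size=(40, 3))
        assert rg_loss_normalized(2 * x, 40) == pytest.approx(
            2 * rg_loss_normalized(x, 40))

    def test_uniform_ball_near_sqrt_three_fifths(self, rng):
        # Monte-Carlo sample of a uniform ball of the normalizing radius
        n = 100000
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        r = (3 * 100 * 110.0 / (4 * np.pi)) ** (1 / 3)
        pts = u * r * rng.random(n)[:, None] ** (1 / 3)
        assert rg_loss_normalized(pts, 100) == pytest.approx(
            np.sqrt(3 / 5), abs=0.01)


class TestRgGradient:
    def test_finite_difference(self, rng):
        x = rng.normal(size=(20, 3)) * 5
        _, g = rg_guiding_potential(x)
        h = 1e-4
        worst = 0.0
        for i in range(len(x)):
            for j in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, j] += h
                xm[i, j] -= h
                num = (radius_of_gyration(xp) - radius_of_gyration(xm)) / (2 * h)
                worst = max(worst, abs(num - g[i, j]))
        assert worst < 1e-5

    def test_gradient_sums_to_zero(self, rng):
        _, g = rg_guiding_potential(rng.normal(size=(25, 3)))
        np.testing.assert_allclose(g.sum(axis=0), 0.0, atol=1e-12)

    def test_coincident_atoms_zero_gradient(self):
        val, g = rg_guiding_potential(np.ones((5, 3)))
        assert val == 0.0
        np.testing.assert_array_equal(g, 0.0)


class TestCubicDecay:
    @pytest.mark.parametrize("t,expect", [(100, 2.0), (50, 0.25), (0, 0.0)])
    def test_values(self, t, expect):
        assert cubic_decay_scale(t, 100, 2.0) == pytest.approx(expect)

    def test_domain(self):
        with pytest.raises(DomainError):
            cubic_decay_scale(-1, 100, 2.0)
        with pytest.raises(DomainError):
            cubic_decay_scale(101, 100, 2.0)


def _random_distogram(rng, L=8, K=10, binder=(0, 5), target=(5, 8)):
    edges = np.linspace(2.0, 22.0, K + 1)
    probs = rng.random((L, L, K))
    probs /= probs.sum(-1, keepdims=True)
    return Distogram(probs, edges, binder, target)


class TestContactProbability:
    def test_all_mass_below_eight(self):
        probs = np.zeros((4, 4, 5))
        probs[..., 0] = 1.0
        d = Distogram(probs, np.array([2.0, 4, 6, 8, 10, 12]), (0, 2), (2, 4))
        assert contact_probability_loss(d) == pytest.approx(1.0)

    def test_all_mass_above_eight(self):
        probs = np.zeros((4, 4, 5))
        probs[..., -1] = 1.0
        d = Distogram(probs, np.array([2.0, 4, 6, 8, 10, 12]), (0, 2), (2, 4))
        assert contact_probability_loss(d) == pytest.approx(0.0)

    def test_matches_brute_force_summation(self, rng):
        d = _random_distogram(rng)
        frac = np.clip((8.0 - d.edges[:-1]) / np.diff(d.edges), 0.0, 1.0)
        sub = (d.probs[5:8, 0:5] * frac).sum(-1)
        brute = sub.max(axis=1).mean()
        assert contact_probability_loss(d) == pytest.approx(brute, abs=1e-12)

    def test_no_sub_threshold_bin_raises(self):
        probs = np.zeros((2, 2, 2))
        probs[..., 0] = 1.0
        d = Distogram(probs, np.array([9.0, 10.0, 11.0]), (0, 1), (1, 2))
        with pytest.raises(BinningError):
            contact_probability_loss(d)

    def test_relabeling_within_chain_invariant(self, rng):
        d = _random_distogram(rng)
        perm = np.r_[rng.permutation(5), 5 + rng.permutation(3)]
        d2 = Distogram(d.probs[np.ix_(perm, perm)], d.edges, (0, 5), (5, 8))
        assert contact_probability_loss(d2) == pytest.approx(
            contact_probability_loss(d), abs=1e-12)


class TestInterfacePae:
    def test_constant_matrix(self):
        p = PaeMatrix(np.full((6, 6), 4.25), (0, 4), (4, 6))
        assert interface_pae(p) == pytest.approx(4.25)

    def test_block_structured(self):
        v = np.ones((6, 6))
        v[:4, 4:] = 7.0
        v[4:, :4] = 7.0
        assert interface_pae(PaeMatrix(v, (0, 4), (4, 6))) == pytest.approx(7.0)

    def test_matches_brute_force(self, rng):
        v = rng.random((9, 9)) * 30
        p = PaeMatrix(v, (0, 6), (6, 9))
        brute = np.concatenate([v[:6, 6:].ravel(), v[6:, :6].ravel()]).mean()
        assert interface_pae(p) == pytest.approx(brute, abs=1e-12)

    def test_empty_block_raises(self):
        with pytest.raises(SizeError):
            interface_pae(PaeMatrix(np.ones((3, 3)), (0, 3), (3, 3)))


class TestShapeComplementarity:
    def test_complementary_pocket_scores_high(self):
        convex, pocket = sc_toy_surfaces()
        assert sc_from_surfaces(convex, pocket) >= 0.95

    def test_separated_bodies_undefined(self):
        convex, pocket = sc_toy_surfaces()
        far = DotSurface(points=pocket.points + [0, 0, 50.0],
                         normals=pocket.normals, areas=pocket.areas)
        with pytest.raises(UndefinedInterfaceError):
            sc_from_surfaces(convex, far)

    def test_symmetry(self):
        convex, pocket = sc_toy_surfaces()
        assert sc_from_surfaces(convex, pocket) == pytest.approx(
            sc_from_surfaces(pocket, convex), abs=0.02)

    def test_atom_level_rigid_motion_invariance(self, rng):
        # two flat 4x4 atom sheets stacked 3.9 Å apart
        g = np.stack(np.meshgrid(np.arange(4) * 1.8, np.arange(4) * 1.8),
                     -1).reshape(-1, 2)
        a = np.c_[g, np.zeros(len(g))]
        b = np.c_[g, np.full(len(g), 3.9)]
        sc0 = shape_complementarity(a, b)
        R = Rotation.random(random_state=3).as_matrix()
        t = rng.normal(size=3) * 20
        sc1 = shape_complementarity(a @ R.T + t, b @ R.T + t)
        # invariant within surface-sampling tolerance (dot placement is
        # frame-dependent)
        assert sc1 == pytest.approx(sc0, abs=0.02)
        assert -1.0 <= sc0 <= 1.0


class TestContactMolecularSurface:
    def test_separated_is_zero(self):
        convex, pocket = sc_toy_surfaces()
        far = DotSurface(points=pocket.points + [0, 0, 50.0],
                         normals=pocket.normals, areas=pocket.areas)
        assert cms_from_surfaces(convex, far) == 0.0

    def test_linear_in_patch_area(self):
        small = sc_toy_surfaces(cap_fraction=0.2, n_points=6000)
        large = sc_toy_surfaces(cap_fraction=0.4, n_points=6000)
        v_small = cms_from_surfaces(*small)
        v_large = cms_from_surfaces(*large)
        area_ratio = large[0].areas.sum() / small[0].areas.sum()
        assert v_large / v_small == pytest.approx(area_ratio, rel=0.05)

    def test_atom_level_positive_for_contacting_bodies(self):
        a = np.zeros((1, 3))
        b = np.array([[3.6, 0.0, 0.0]])
        assert contact_molecular_surface(a, b) > 0.0


class TestAlgebraicProperties:
    from hypothesis import given, settings, strategies as st

    @given(st.floats(0.01, 100.0), st.floats(0.0, 1.0), st.floats(0.01, 10.0))
    @settings(max_examples=50, derandomize=True)
    def test_cubic_decay_scales_with_weight_and_fraction(self, T, frac, w0):
        t = frac * T
        assert cubic_decay_scale(t, T, w0) == pytest.approx(w0 * frac ** 3)

    @given(st.floats(0.1, 10.0), st.integers(2, 30))
    @settings(max_examples=50, derandomize=True)
    def test_rg_homogeneity_under_scaling(self, scale, n):
        x = np.random.default_rng(n).normal(size=(n, 3))
        assert radius_of_gyration(scale * x) == pytest.approx(
            scale * radius_of_gyration(x), rel=1e-9)


class TestSasa:
    def test_isolated_atom_full_sphere(self):
        area = sasa(np.zeros((1, 3)), radii=1.7)
        assert area[0] == pytest.approx(4 * np.pi * 3.1 ** 2, rel=1e-6)

    def test_buried_atom_loses_area(self):
        line = np.array([[0.0, 0, 0], [3.0, 0, 0], [6.0, 0, 0]])
        areas = sasa(line)
        assert areas[1] < areas[0]
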