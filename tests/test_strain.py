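"""Deformation gradients, Lagrangian strain, and principal strains."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from elastocycle import (
    build_neighborhoods,
    deformation_gradient,
    lagrange_strain,
    make_affine_ensemble,
    principal_strains,
    strain_field,
)
from elastocycle.strain import (
    SingularGeometryError,
    UnderdeterminedNeighborhoodError,
)
from tests.conftest import rotation_matrix


def _cloud(n=12, seed=0):
    rng = np.random.default_rng(seed)
    return rng.normal(scale=3.0, size=(n, 3))


class TestDeformationGradient:
    def test_identity_on_unchanged_coords(self):
        pts = _cloud()
        F = deformation_gradient(pts, pts)
        np.testing.assert_allclose(F, np.eye(3), atol=1e-12)

    def test_uniform_scaling_about_any_origin(self):
        pts = _cloud()
        scaled = 1.1 * (pts - 7.0) + 7.0  # scaling about (7,7,7)
        F = deformation_gradient(pts, scaled)
        np.testing.assert_allclose(F, 1.1 * np.eye(3), atol=1e-10)

    def test_simple_shear_recovered(self):
        shear = np.array([[1.0, 0.2, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        pts = _cloud(10, seed=3)
        F = deformation_gradient(pts, pts @ shear.T)
        np.testing.assert_allclose(F, shear, atol=1e-10)

    def test_matches_generic_least_squares(self):
        # independent oracle: solve the same minimisation with lstsq
        rng = np.random.default_rng(4)
        pts = _cloud(15, seed=4)
        target = pts @ rng.normal(size=(3, 3)).T + rng.normal(size=3)
        F = deformation_gradient(pts, target)
        dX = pts[1:] - pts[0]
        dx = target[1:] - target[0]
        F_lstsq, *_ = np.linalg.lstsq(dX, dx, rcond=None)
        np.testing.assert_allclose(F, F_lstsq.T, atol=1e-9)

    def test_weighted_equals_unweighted_for_equal_weights(self):
        pts = _cloud(9, seed=5)
        deformed = pts @ (np.eye(3) + 0.05 * np.ones((3, 3)))
        F0 = deformation_gradient(pts, deformed)
        F1 = deformation_gradient(pts, deformed, weights=np.full(8, 3.7))
        np.testing.assert_allclose(F0, F1, atol=1e-12)

    def test_collinear_neighbors_rejected(self):
        line = np.outer(np.arange(6, dtype=float), [1.0, 0.0, 0.0])
        with pytest.raises(SingularGeometryError):
            deformation_gradient(line, line * 2.0)

    def test_too_few_neighbors_rejected(self):
        pts = _cloud(4)
        with pytest.raises(UnderdeterminedNeighborhoodError):
            deformation_gradient(pts, pts)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_affine_exactness_property(self, seed):
        """Any invertible affine map is recovered exactly from any generic cloud."""
        rng = np.random.default_rng(seed)
        A = np.eye(3) + 0.5 * rng.normal(size=(3, 3))
        if abs(np.linalg.det(A)) < 1e-3:
            A += np.eye(3)
        pts = rng.normal(scale=4.0, size=(10, 3))
        F = deformation_gradient(pts, pts @ A.T + rng.normal(size=3))
        np.testing.assert_allclose(F, A, atol=1e-9)


class TestLagrangeStrain:
    def test_identity_gives_zero(self):
        np.testing.assert_array_equal(lagrange_strain(np.eye(3)), np.zeros((3, 3)))

    def test_rotation_is_strain_free(self):
        E = lagrange_strain(rotation_matrix((0, 0, 37)))
        assert np.max(np.abs(E)) < 1e-12

    def test_dilation_closed_form(self):
        E = lagrange_strain(1.1 * np.eye(3))
        np.testing.assert_allclose(E, 0.105 * np.eye(3), atol=1e-12)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_any_rotation_is_strain_free(self, seed):
        from scipy.spatial.transform import Rotation

        R = Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
        assert np.max(np.abs(lagrange_strain(R))) < 1e-12


class TestPrincipalStrains:
    def test_isotropic(self):
        eps, axes = principal_strains(0.105 * np.eye(3))
        np.testing.assert_allclose(eps, [0.105, 0.105, 0.105])
        np.testing.assert_allclose(axes @ axes.T, np.eye(3), atol=1e-12)

    def test_shear_block_eigenvalues(self):
        # strain of simple shear gamma=0.2; 2x2 block oracle 0.01 +- sqrt(0.01^2 + 0.1^2)
        E = np.array([[0.0, 0.1, 0.0], [0.1, 0.02, 0.0], [0.0, 0.0, 0.0]])
        eps, _ = principal_strains(E)
        root = np.sqrt(0.01**2 + 0.1**2)
        np.testing.assert_allclose(eps, [0.01 - root, 0.0, 0.01 + root], atol=1e-12)

    def test_diagonal_passthrough_and_ordering(self):
        eps, _ = principal_strains(np.diag([-0.3, 0.1, 0.2]))
        np.testing.assert_allclose(eps, [-0.3, 0.1, 0.2])

    def test_eigenpairs_satisfy_definition(self):
        rng = np.random.default_rng(8)
        E = rng.normal(size=(3, 3))
        E = 0.5 * (E + E.T)
        eps, axes = principal_strains(E)
        for a in range(3):
            np.testing.assert_allclose(E @ axes[:, a], eps[a] * axes[:, a], atol=1e-8)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            principal_strains(np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, 0.0, 0.0]]))


class TestNeighborhoods:
    def test_modes_agree_on_identical_conformations(self):
        fixture = make_affine_ensemble(50, [np.eye(3)], seed=1)
        both = [
            build_neighborhoods(fixture.ensemble, radius=9.0, mode=m)
            for m in ("intersect-all", "per-pair")
        ]
        for nb_a, nb_b in zip(both[0].neighbors, both[1].neighbors):
            np.testing.assert_array_equal(nb_a, nb_b)

    def test_intersect_all_is_subset_of_per_pair(self):
        fixture = make_affine_ensemble(80, [1.08 * np.eye(3)], seed=6)
        strict = build_neighborhoods(fixture.ensemble, radius=9.0, mode="intersect-all")
        loose = build_neighborhoods(
            fixture.ensemble, radius=9.0, mode="per-pair", reference_label="ref"
        )
        # dilation pushes borderline atoms past the radius in the deformed copy
        assert all(
            set(a) <= set(b) for a, b in zip(strict.neighbors, loose.neighbors)
        )
        assert sum(map(len, strict.neighbors)) < sum(map(len, loose.neighbors))

    def test_neighbor_lists_exclude_center(self):
        fixture = make_affine_ensemble(40, [np.eye(3)], seed=2)
        nb = build_neighborhoods(fixture.ensemble, radius=9.0)
        assert all(i not in set(nb.neighbors[i]) for i in range(len(nb)))


class TestStrainField:
    def test_self_comparison_is_zero(self, dilation_fixture, dilation_neighborhoods):
        field = strain_field(
            dilation_fixture.ensemble, "ref", "ref", dilation_neighborhoods
        )
        assert field.mean_eps3 == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_null(self):
        R = rotation_matrix()
        fixture = make_affine_ensemble(100, [(R, np.array([4.0, -2.0, 9.0]))], seed=7)
        nb = build_neighborhoods(fixture.ensemble, radius=9.0)
        field = strain_field(fixture.ensemble, "def0", "ref", nb)
        assert np.max(np.abs(field.principal)) < 1e-9

    def test_uniform_dilation_field(self, dilation_fixture, dilation_neighborhoods):
        field = strain_field(
            dilation_fixture.ensemble, "def0", "ref", dilation_neighborhoods
        )
        np.testing.assert_allclose(field.principal, 0.105, atol=1e-9)
        assert field.mean_eps3 == pytest.approx(0.105, abs=1e-9)
        truth = dilation_fixture.ground_truth["def0"]
        for record in field.records():
            np.testing.assert_allclose(record.E, truth, atol=1e-9)

    def test_affine_recovery_independent_of_neighborhood(self):
        A = rotation_matrix((10, 0, 25)) @ np.diag([1.1, 0.95, 1.02])
        fixture = make_affine_ensemble(80, [A], seed=9)
        truth = fixture.ground_truth["def0"]
        for radius in (7.0, 9.0, 12.0):
            nb = build_neighborhoods(fixture.ensemble, radius=radius)
            field = strain_field(fixture.ensemble, "def0", "ref", nb)
            np.testing.assert_allclose(field.F, np.broadcast_to(A, field.F.shape), atol=1e-9)
            np.testing.assert_allclose(field.E, np.broadcast_to(truth, field.E.shape), atol=1e-9)

    def test_pair_asymmetry_bounded_for_small_deformations(self):
        fixture = make_affine_ensemble(80, [1.03 * np.eye(3)], seed=10)
        nb = build_neighborhoods(fixture.ensemble, radius=9.0)
        forward = strain_field(fixture.ensemble, "def0", "ref", nb).mean_eps3
        backward = strain_field(fixture.ensemble, "ref", "def0", nb).mean_neg_eps1
        assert abs(forward - backward) / forward < 0.10

    def test_unknown_label_rejected(self, dilation_fixture, dilation_neighborhoods):
        with pytest.raises(KeyError):
            strain_field(
                dilation_fixture.ensemble, "nope", "ref", dilation_neighborhoods
            )
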