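import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from sklearn.decomposition import PCA as SKPCA

from ebdims import (build_ed_enm, fit_pca, load_basis, make_pca_ensemble,
                    normal_modes, pc_distance, project, residue_correspondence,
                    save_basis, superposed, transition_coverage)
from ebdims.pca import project_set


@pytest.fixture(scope="module")
def mode_basis(helix10):
    """Two rigid-motion-free orthonormal directions of the small helix."""
    return normal_modes(build_ed_enm(helix10), 2)


@pytest.fixture(scope="module")
def synthetic_ensemble(helix10, mode_basis):
    return make_pca_ensemble(helix10, mode_basis.modes, [2.0, 1.0], 200,
                             seed=42)


class TestFitPCA:
    def test_three_members_give_at_most_two_components(self, hinge_models):
        ens = residue_correspondence(list(hinge_models))
        basis = fit_pca(ens)
        assert basis.n_components <= 2
        assert basis.variance_fractions.sum() == pytest.approx(1.0, abs=1e-8)

    def test_too_few_members_rejected(self, hinge_models):
        ens = residue_correspondence([hinge_models[0], hinge_models[2]])
        with pytest.raises(ValueError):
            fit_pca(ens)

    def test_recovers_construction_directions(self, synthetic_ensemble,
                                              mode_basis):
        """Ensemble built as mean + a₁v₁ + a₂v₂ with sd (2,1) Å."""
        basis = fit_pca(synthetic_ensemble)
        for k in range(2):
            assert abs(basis.components[k] @ mode_basis.modes[k]) > 0.99
            assert basis.eigenvalues[k] == pytest.approx([4.0, 1.0][k],
                                                         rel=0.25)

    def test_components_orthonormal(self, synthetic_ensemble):
        basis = fit_pca(synthetic_ensemble)
        gram = basis.components @ basis.components.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-8)

    def test_matches_dense_covariance_oracle(self, helix10, mode_basis):
        """Brute force: explicit covariance matrix + sklearn eigensolver."""
        ens = make_pca_ensemble(helix10, mode_basis.modes, [1.5, 0.5], 40,
                                seed=7)
        basis = fit_pca(ens)
        ref = ens.reference.coords
        x = np.asarray([superposed(m.coords, ref).ravel()
                        for m in ens.members])
        sk = SKPCA(n_components=2).fit(x)
        for k in range(2):
            assert abs(basis.components[k] @ sk.components_[k]) == \
                pytest.approx(1.0, abs=1e-8)
            assert basis.eigenvalues[k] == pytest.approx(
                sk.explained_variance_[k], rel=1e-8)

    def test_reference_centring_option(self, synthetic_ensemble):
        b_mean = fit_pca(synthetic_ensemble, about="mean")
        b_ref = fit_pca(synthetic_ensemble, about="reference")
        # same dominant direction, slightly different variance split
        assert abs(b_mean.components[0] @ b_ref.components[0]) > 0.95


class TestProject:
    def test_reference_projects_to_origin(self, synthetic_ensemble):
        basis = fit_pca(synthetic_ensemble)
        p = project(basis, basis.reference_coords, 2)
        np.testing.assert_allclose(p, 0.0, atol=1e-8)

    def test_linearity_in_pc_span(self, synthetic_ensemble):
        basis = fit_pca(synthetic_ensemble)
        delta = basis.components[0].reshape(-1, 3) * 2.0
        p1 = project(basis, basis.reference_coords + delta, 2)
        p3 = project(basis, basis.reference_coords + 3 * delta, 2)
        np.testing.assert_allclose(p3, 3 * p1, atol=1e-6)

    def test_full_reconstruction_of_members(self, synthetic_ensemble):
        basis = fit_pca(synthetic_ensemble)
        k = basis.n_components
        for m in synthetic_ensemble.members[:5]:
            aligned = superposed(m.coords, basis.reference_coords)
            p = project(basis, m.coords, k)
            rebuilt = basis.reference_coords.ravel() + p @ basis.components[:k]
            np.testing.assert_allclose(rebuilt, aligned.ravel(), atol=1e-6)

    def test_rigid_motion_invariance(self, synthetic_ensemble):
        basis = fit_pca(synthetic_ensemble)
        m = synthetic_ensemble.members[3]
        p0 = project(basis, m.coords, 2)
        moved = Rotation.from_euler("zx", [50, 10], degrees=True).apply(m.coords) + 4.0
        np.testing.assert_allclose(project(basis, moved, 2), p0, atol=1e-6)

    def test_too_many_components_rejected(self, hinge_models):
        basis = fit_pca(residue_correspondence(list(hinge_models)))
        with pytest.raises(ValueError):
            project(basis, hinge_models[0].coords, 50)


class TestTransitionCoverage:
    def test_delta_along_pc1(self, synthetic_ensemble):
        basis = fit_pca(synthetic_ensemble)
        ref = basis.reference_coords
        start = synthetic_ensemble.reference
        # small amplitude keeps the superposition step in its linear regime
        target = start.with_coords(ref + basis.components[0].reshape(-1, 3) * 0.1)
        assert transition_coverage(basis, start, target, 1) == \
            pytest.approx(1.0, abs=1e-4)

    def test_equal_split_between_two_pcs(self, synthetic_ensemble):
        basis = fit_pca(synthetic_ensemble)
        ref = basis.reference_coords
        start = synthetic_ensemble.reference
        delta = (basis.components[0] + basis.components[1]).reshape(-1, 3)
        target = start.with_coords(ref + 0.1 * delta)
        assert transition_coverage(basis, start, target, 1) == \
            pytest.approx(0.5, abs=1e-4)
        assert transition_coverage(basis, start, target, 2) == \
            pytest.approx(1.0, abs=1e-4)

    def test_matches_brute_force_accumulation(self, hinge_models):
        ens = residue_correspondence(list(hinge_models))
        basis = fit_pca(ens)
        start, _, target = ens.members
        a = superposed(start.coords, basis.reference_coords)
        b = superposed(target.coords, basis.reference_coords)
        delta = (b - a).ravel()
        acc = 0.0
        for k in range(1, basis.n_components + 1):
            acc += float((basis.components[k - 1] @ delta) ** 2)
            expected = acc / float(delta @ delta)
            assert transition_coverage(basis, start, target, k) == \
                pytest.approx(expected, abs=1e-10)

    def test_identical_endpoints_rejected(self, hinge_models):
        basis = fit_pca(residue_correspondence(list(hinge_models)))
        with pytest.raises(ValueError):
            transition_coverage(basis, hinge_models[0], hinge_models[0])


class TestPCDistance:
    def test_pythagorean(self):
        assert pc_distance([0.0, 0.0], [3.0, 4.0]) == pytest.approx(5.0)

    def test_symmetric_and_zero_on_identical(self):
        a, b = np.array([1.0, -2.0]), np.array([0.5, 3.0])
        assert pc_distance(a, a) == 0.0
        assert pc_distance(a, b) == pc_distance(b, a)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pc_distance([1.0, 2.0], [1.0, 2.0, 3.0])


class TestVarianceProperties:
    def test_mc_mode_ensemble_variance_fractions(self, helix10):
        """Equipartition: fractions follow (k_BT/λ_k) ratios within 10%."""
        nm = normal_modes(build_ed_enm(helix10), 3)
        from ebdims import mc_sample_along_modes
        traj = mc_sample_along_modes(nm, 300.0, 500, seed=11)
        models = [helix10.with_coords(f) for f in traj.frames]
        for i, m in enumerate(models):
            m.id = f"s{i}"
        basis = fit_pca(residue_correspondence(models))
        inv = 1.0 / nm.eigenvalues
        expected = inv / inv.sum()
        np.testing.assert_allclose(basis.variance_fractions[:3], expected,
                                   rtol=0.10)

    def test_three_structure_basis_matches_full_ensemble(self, helix10,
                                                         mode_basis):
        """A dominant motion is recoverable from only {start, mid, target}."""
        ens = make_pca_ensemble(helix10, mode_basis.modes, [3.0, 0.8], 100,
                                seed=13)
        full = fit_pca(ens)
        assert full.variance_fractions[0] > 0.7
        ref = helix10.coords
        v1 = mode_basis.modes[0].reshape(-1, 3)
        three = [helix10.with_coords(ref - 3 * v1),
                 helix10.with_coords(ref),
                 helix10.with_coords(ref + 3 * v1)]
        for i, m in enumerate(three):
            m.id = f"t{i}"
        small = fit_pca(residue_correspondence(three))
        assert abs(small.components[0] @ full.components[0]) > 0.9


class TestPersistence:
    def test_round_trip(self, synthetic_ensemble, tmp_path):
        basis = fit_pca(synthetic_ensemble)
        p = tmp_path / "basis.npz"
        save_basis(basis, p)
        back = load_basis(p)
        np.testing.assert_array_equal(back.components, basis.components)
        np.testing.assert_array_equal(back.eigenvalues, basis.eigenvalues)
        m = synthetic_ensemble.members[7]
        np.testing.assert_allclose(project(back, m.coords, 2),
                                   project(basis, m.coords, 2), atol=1e-12)

    def test_projection_set_frame(self, synthetic_ensemble):
        basis = fit_pca(synthetic_ensemble)
        ps = project_set(basis, synthetic_ensemble, k_components=2)
        df = ps.to_frame()
        assert list(df.columns) == ["label", "PC1", "PC2"]
        assert len(df) == len(synthetic_ensemble)
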