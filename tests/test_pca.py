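"""Essential dynamics: spectra, subspace comparison, projections, modevectors."""

import numpy as np
import pytest

from hemodyn.ensemble import Ensemble
from hemodyn.pca import (EssentialSubspace, compare_subspaces,
                         components_for_variance, compute_subspace,
                         modevectors, project_density)
from test_geometry import point_topology


def gaussian_ensemble(rng, n_frames, directions, scales, n_atoms=3):
    """Frames drawn from a zero-mean Gaussian with given principal axes."""
    dim = 3 * n_atoms
    X = np.zeros((n_frames, dim))
    for d, s in zip(directions, scales):
        X += rng.normal(size=(n_frames, 1)) * s * d[None, :]
    coords = X.reshape(n_frames, n_atoms, 3) + 10.0
    return Ensemble(topology=point_topology(n_atoms, names=["CA"] * n_atoms),
                    coords=coords)


def orthonormal_directions(rng, dim, k):
    M = rng.normal(size=(dim, k))
    Q, _ = np.linalg.qr(M)
    return [Q[:, i] for i in range(k)]


def subspace_from_spectrum(eigenvalues, dim=None, rng=None):
    """Synthetic subspace object with a prescribed spectrum."""
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    dim = dim or len(eigenvalues)
    vecs = np.eye(dim)[:, :len(eigenvalues)]
    return EssentialSubspace(
        selection=np.arange(dim // 3 + 1), mean=np.zeros(dim),
        eigenvalues=eigenvalues, eigenvectors=vecs,
        variance_fractions=eigenvalues / eigenvalues.sum(),
    )


class TestComputeSubspace:
    def test_single_varying_coordinate_captures_all_variance(self, rng):
        coords = np.zeros((50, 3, 3))
        coords[:, 0, 0] = rng.normal(size=50)
        ens = Ensemble(topology=point_topology(3, names=["CA"] * 3), coords=coords)
        sub = compute_subspace(ens, selection=np.arange(3), superpose=False)
        assert sub.variance_fractions[0] == pytest.approx(1.0, abs=1e-10)

    def test_rank_deficient_frame_count_warns(self, rng):
        ens = Ensemble(topology=point_topology(3, names=["CA"] * 3),
                       coords=rng.normal(size=(5, 3, 3)))
        with pytest.warns(UserWarning, match="rank-deficient"):
            compute_subspace(ens, selection=np.arange(3), superpose=False)

    def test_eigenvectors_orthonormal_and_trace_conserved(self, rng):
        ens = gaussian_ensemble(rng, 300, orthonormal_directions(rng, 9, 4),
                                [2.0, 1.0, 0.5, 0.25])
        sub = compute_subspace(ens, selection=np.arange(3), superpose=False)
        V = sub.eigenvectors
        np.testing.assert_allclose(V.T @ V, np.eye(V.shape[1]), atol=1e-8)
        X = ens.coords.reshape(300, 9)
        total_var = np.sum(np.var(X, axis=0, ddof=1))
        assert sub.eigenvalues.sum() == pytest.approx(total_var, abs=1e-8)

    def test_eigendecomposition_matches_svd(self, rng):
        ens = gaussian_ensemble(rng, 200, orthonormal_directions(rng, 9, 3),
                                [2.0, 1.0, 0.5])
        sub = compute_subspace(ens, selection=np.arange(3), superpose=False)
        X = ens.coords.reshape(200, 9)
        Xc = X - X.mean(axis=0)
        s = np.linalg.svd(Xc, compute_uv=False)
        lam_svd = s ** 2 / (200 - 1)
        np.testing.assert_allclose(sub.eigenvalues[:len(lam_svd)], lam_svd, atol=1e-8)

    def test_planted_three_mode_spectrum_recovered(self, rng):
        dirs = orthonormal_directions(rng, 9, 3)
        ens = gaussian_ensemble(rng, 5000, dirs, [2.0, 1.0, 0.5])
        sub = compute_subspace(ens, selection=np.arange(3), superpose=False)
        np.testing.assert_allclose(sub.eigenvalues[:3], [4.0, 1.0, 0.25], rtol=0.10)

    def test_too_few_frames_rejected(self, rng):
        ens = Ensemble(topology=point_topology(3), coords=rng.normal(size=(1, 3, 3)))
        with pytest.raises(ValueError):
            compute_subspace(ens, selection=np.arange(3))


class TestVarianceAccounting:
    def test_single_mode_needs_one_component(self):
        sub = subspace_from_spectrum([5.0, 0.0, 0.0])
        assert components_for_variance(sub, 0.95) == 1

    def test_cumulative_boundary_is_inclusive(self):
        sub = subspace_from_spectrum([0.5, 0.3, 0.15, 0.05])
        assert components_for_variance(sub, 0.95) == 3
        assert components_for_variance(sub, 0.96) == 4

    def test_exclusion_recomputes_over_remaining_variance(self):
        sub = subspace_from_spectrum([0.6, 0.2, 0.1, 0.06, 0.04])
        assert components_for_variance(sub, 0.95) == 4
        sub_excl = subspace_from_spectrum([0.6, 0.2, 0.1, 0.06, 0.04])
        sub_excl.excluded = (1,)
        # over retained variance 0.4: cumsum 0.5 / 0.75 / 0.9 / 1.0
        assert components_for_variance(sub_excl, 0.95) == 4
        assert components_for_variance(sub_excl, 0.75) == 2

    def test_invalid_fraction_rejected(self):
        sub = subspace_from_spectrum([1.0])
        with pytest.raises(ValueError):
            components_for_variance(sub, 0.0)


class TestCompareSubspaces:
    def test_self_comparison_is_perfect(self, rng):
        ens = gaussian_ensemble(rng, 400, orthonormal_directions(rng, 9, 5),
                                [3, 2, 1.5, 1, 0.5])
        sub = compute_subspace(ens, selection=np.arange(3), superpose=False)
        report = compare_subspaces(sub, sub, m=3)
        assert report.rmsip == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(report.max_dot_per_a, 1.0, atol=1e-9)
        assert report.subspace_overlap_pct == pytest.approx(100.0, abs=1e-6)
        assert report.hess_overlap == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_axes_give_zero_overlap(self):
        a = subspace_from_spectrum([1.0], dim=6)
        b = subspace_from_spectrum([1.0], dim=6)
        b.eigenvectors = np.zeros((6, 1))
        b.eigenvectors[3, 0] = 1.0
        report = compare_subspaces(a, b, m=1)
        assert report.rmsip == pytest.approx(0.0, abs=1e-12)

    def test_planted_sixty_degree_angle(self):
        a = subspace_from_spectrum([1.0], dim=6)
        b = subspace_from_spectrum([1.0], dim=6)
        v = np.zeros(6)
        v[0], v[1] = np.cos(np.radians(60)), np.sin(np.radians(60))
        b.eigenvectors = v[:, None]
        report = compare_subspaces(a, b, m=1)
        assert report.dot_matrix[0, 0] == pytest.approx(0.5, abs=1e-9)

    def test_rmsip_symmetric_and_rotation_invariant(self, rng):
        dirs = orthonormal_directions(rng, 12, 6)
        a = gaussian_ensemble(rng, 600, dirs[:3], [2, 1.4, 1], n_atoms=4)
        b = gaussian_ensemble(rng, 600, dirs[2:5], [2, 1.4, 1], n_atoms=4)
        sa = compute_subspace(a, selection=np.arange(4), superpose=False)
        sb = compute_subspace(b, selection=np.arange(4), superpose=False)
        r_ab = compare_subspaces(sa, sb, m=3)
        r_ba = compare_subspaces(sb, sa, m=3)
        assert r_ab.rmsip == pytest.approx(r_ba.rmsip, abs=1e-9)
        # rotating one basis within its own span leaves RMSIP unchanged
        theta = 0.7
        Q = np.eye(3)
        Q[:2, :2] = [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        sb.eigenvectors[:, :3] = sb.eigenvectors[:, :3] @ Q
        r_rot = compare_subspaces(sa, sb, m=3)
        assert r_rot.rmsip == pytest.approx(r_ab.rmsip, abs=1e-8)

    def test_same_covariance_converges_to_full_overlap(self, rng):
        dirs = orthonormal_directions(rng, 9, 3)
        a = gaussian_ensemble(rng, 5000, dirs, [2.0, 1.2, 0.7])
        b = gaussian_ensemble(rng, 5000, dirs, [2.0, 1.2, 0.7])
        sa = compute_subspace(a, selection=np.arange(3), superpose=False)
        sb = compute_subspace(b, selection=np.arange(3), superpose=False)
        assert compare_subspaces(sa, sb, m=3).rmsip >= 0.9

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare_subspaces(subspace_from_spectrum([1.0], dim=6),
                              subspace_from_spectrum([1.0], dim=9), m=1)


class TestProjections:
    def test_mean_projects_to_origin_and_density_normalised(self, rng):
        ens = gaussian_ensemble(rng, 400, orthonormal_directions(rng, 9, 3),
                                [2, 1, 0.5])
        sub = compute_subspace(ens, selection=np.arange(3), superpose=False)
        proj, (xg, yg, Z) = project_density(ens, sub, components=(1, 2))
        np.testing.assert_allclose(proj.mean(axis=0), 0.0, atol=1e-10)
        cell = (xg[1] - xg[0]) * (yg[1] - yg[0])
        assert Z.sum() * cell == pytest.approx(1.0, abs=1e-6)

    def test_excluded_component_needs_override(self, rng):
        ens = gaussian_ensemble(rng, 100, orthonormal_directions(rng, 9, 3),
                                [2, 1, 0.5])
        sub = compute_subspace(ens, selection=np.arange(3), exclude=(1,),
                               superpose=False)
        with pytest.raises(ValueError):
            project_density(ens, sub, components=(1, 2))
        project_density(ens, sub, components=(1, 2), allow_excluded=True)

    def test_bimodal_projections_show_two_density_maxima(self, rng):
        # two well-separated conformational clusters along one direction
        d = orthonormal_directions(rng, 9, 2)
        shift = np.where(rng.random(600) < 0.5, -6.0, 6.0)
        X = shift[:, None] * d[0][None, :] + rng.normal(size=(600, 9)) * 0.8
        ens = Ensemble(topology=point_topology(3, names=["CA"] * 3),
                       coords=X.reshape(600, 3, 3))
        sub = compute_subspace(ens, selection=np.arange(3), superpose=False)
        _, (xg, yg, Z) = project_density(ens, sub, components=(1, 2))
        marginal = Z.sum(axis=1)
        peaks = [i for i in range(1, len(marginal) - 1)
                 if marginal[i] > marginal[i - 1] and marginal[i] > marginal[i + 1]
                 and marginal[i] > 0.1 * marginal.max()]
        assert len(peaks) == 2


class TestModevectors:
    def test_zero_scale_gives_zero_field(self):
        sub = subspace_from_spectrum([2.0, 1.0], dim=6)
        field = modevectors(sub, 1, scale=0.0)
        np.testing.assert_allclose(field.vectors, 0.0)

    def test_magnitudes_match_construction(self):
        sub = subspace_from_spectrum([4.0, 1.0], dim=6)
        field = modevectors(sub, 1, scale=1.5)
        v = sub.component_vector(1).reshape(-1, 3)
        np.testing.assert_allclose(
            field.magnitudes, 2 * 1.5 * np.sqrt(4.0) * np.linalg.norm(v, axis=1),
            atol=1e-12)

    def test_zero_eigenvalue_warns(self):
        sub = subspace_from_spectrum([1.0, 0.0], dim=6)
        with pytest.warns(UserWarning):
            field = modevectors(sub, 2, scale=1.0)
        np.testing.assert_allclose(field.vectors, 0.0)

    def test_top_magnitude_residues_recover_planted_loop(self, default_spec):
        # the dominant collective mode of the deoxy-like state is the large
        # planted loop; its residues carry the largest modevector magnitudes
        from conftest import clone_spec
        from hemodyn.synthetic import sample_ensemble
        spec = clone_spec(default_spec, n_frames=300)
        ens = sample_ensemble(spec, "deoxy", 0)
        core = ens.topology.named_selections["core"]
        sub = compute_subspace(ens, core)
        field = modevectors(sub, 1, scale=2.0)
        resids = ens.topology.resids[core]
        loop = spec.loop_ranges[0]
        top_k = resids[np.argsort(field.magnitudes)[::-1][:loop.end - loop.start + 1]]
        expected = set(range(loop.start, loop.end + 1))
        assert set(top_k.tolist()) == expected
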