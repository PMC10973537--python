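"""Sparsification, cosine affinity and the diffusion-map embedding."""

import numpy as np
import pytest

from gradhier.atlas import ValidationError, default_parcellation
from gradhier.connectivity import fisher_z, group_average, pearson_fc
from gradhier.gradients import (
    GradientParams,
    compute_gradients,
    cosine_affinity,
    diffusion_embedding,
    eigenvalue_spectrum,
    sparsify_rows,
)
from gradhier.io import ConnectivityMatrix

from .oracles import brute_force_diffusion_map


def _random_affinity(p, rng, density=0.5):
    a = rng.random((p, p))
    a[rng.random((p, p)) > density] = 0.0
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    a += 1e-3  # keep connected
    np.fill_diagonal(a, 0.0)
    return a


class TestSparsify:
    def test_top_value_survives_at_sparsity_09(self):
        row = np.array([5.0, 4, 3, 2, 1, 0, -1, -2, -3, -4], dtype=float)
        m = np.zeros((11, 11))
        m[0, 1:] = row
        m[1:, 0] = row
        out = sparsify_rows(m, 0.9)
        # ceil(0.1 * 10) = 1 survivor per row; row 0 keeps only the 5
        assert out[0, 1] == 5.0
        assert (out[0, 2:] == 0).all()

    def test_sparsity_zero_is_identity_off_diagonal(self, rng):
        a = rng.standard_normal((8, 8))
        v = (a + a.T) / 2
        out = sparsify_rows(v, 0.0)
        off = ~np.eye(8, dtype=bool)
        np.testing.assert_array_equal(out[off], v[off])

    def test_exact_count_at_p200(self, rng):
        a = rng.standard_normal((200, 200))
        v = (a + a.T) / 2
        out = sparsify_rows(v, 0.9)
        nonzero_per_row = (out != 0).sum(axis=1)
        assert (nonzero_per_row == 20).all()

    def test_ranking_is_by_value_not_magnitude(self):
        m = np.zeros((4, 4))
        m[0] = [0.0, 0.1, -5.0, 0.2]
        out = sparsify_rows(m, 0.5)  # keep ceil(0.5*3) = 2 per row
        assert out[0, 3] == 0.2 and out[0, 1] == 0.1 and out[0, 2] == 0.0

    def test_ties_keep_lower_parcel_index(self):
        m = np.zeros((4, 4))
        m[0] = [0.0, 0.5, 0.5, 0.5]
        out = sparsify_rows(m, 0.6)  # keep ceil(0.4*3) = 2
        assert out[0, 1] == 0.5 and out[0, 2] == 0.5 and out[0, 3] == 0.0

    def test_invalid_sparsity_rejected(self):
        with pytest.raises(ValidationError):
            sparsify_rows(np.zeros((3, 3)), 1.0)


class TestCosineAffinity:
    def test_identical_rows_affinity_one(self):
        s = np.array([[1.0, 2.0, 0.0], [1.0, 2.0, 0.0], [0.0, 1.0, 1.0]])
        a = cosine_affinity(s)
        assert a[0, 1] == pytest.approx(1.0)

    def test_disjoint_support_affinity_zero(self):
        s = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 0.0, 1.0, 2.0]])
        a = cosine_affinity(s)
        assert a[0, 1] == 0.0

    def test_hand_computed_value(self):
        s = np.array([[1.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        a = cosine_affinity(s)
        assert a[0, 1] == pytest.approx(1 / np.sqrt(2), abs=1e-10)

    def test_all_zero_row_names_parcel(self):
        s = np.array([[1.0, 1.0], [0.0, 0.0]])
        with pytest.raises(ValidationError, match="disconnected parcel.*2"):
            cosine_affinity(s)

    def test_negative_similarities_clipped(self):
        s = np.array([[1.0, -1.0], [-1.0, 1.0], [1.0, 1.0]])
        a = cosine_affinity(s)
        assert a.min() == 0.0 and a[0, 1] == 0.0


class TestDiffusionEmbedding:
    def test_two_bridged_cliques_sign_separated(self):
        p = 8
        a = np.zeros((p, p))
        a[:4, :4] = 1.0
        a[4:, 4:] = 1.0
        np.fill_diagonal(a, 0.0)
        a[3, 4] = a[4, 3] = 1e-3  # weak bridge
        gs = diffusion_embedding(a, GradientParams(n_components=2))
        pg = gs.components[:, 0]
        assert (np.sign(pg[:4]) == np.sign(pg[0])).all()
        assert (np.sign(pg[4:]) == -np.sign(pg[0])).all()

    def test_path_graph_principal_component_monotone(self):
        p = 12
        a = np.zeros((p, p))
        for i in range(p - 1):
            a[i, i + 1] = a[i + 1, i] = 1.0
        gs = diffusion_embedding(a, GradientParams(n_components=2))
        pg = gs.components[:, 0]
        diffs = np.diff(pg)
        assert (diffs > 0).all() or (diffs < 0).all()

    def test_scale_invariance(self, rng):
        a = _random_affinity(30, rng)
        g1 = diffusion_embedding(a, GradientParams(n_components=4))
        g2 = diffusion_embedding(3.7 * a, GradientParams(n_components=4))
        np.testing.assert_allclose(g1.components, g2.components, atol=1e-10)
        np.testing.assert_allclose(g1.eigenvalues, g2.eigenvalues, atol=1e-12)

    @pytest.mark.parametrize("p", [10, 25, 50])
    def test_matches_brute_force_oracle(self, p, rng):
        a = _random_affinity(p, rng)
        k = 5
        gs = diffusion_embedding(a, GradientParams(n_components=k))
        oracle_comps, oracle_lam = brute_force_diffusion_map(a, k)
        np.testing.assert_allclose(gs.eigenvalues, oracle_lam, atol=1e-10)
        for c in range(k):
            ours, theirs = gs.components[:, c], oracle_comps[:, c]
            dev = min(np.abs(ours - theirs).max(), np.abs(ours + theirs).max())
            assert dev < 1e-8

    def test_permutation_equivariance(self, rng):
        meta = default_parcellation(40)
        a = _random_affinity(40, rng)
        perm = rng.permutation(40)
        g1 = diffusion_embedding(a, GradientParams(n_components=3))
        g2 = diffusion_embedding(a[np.ix_(perm, perm)], GradientParams(n_components=3))
        for c in range(3):
            ours, permuted = g1.components[perm, c], g2.components[:, c]
            dev = min(np.abs(ours - permuted).max(), np.abs(ours + permuted).max())
            assert dev < 1e-10

    def test_repeated_runs_bit_identical(self, rng):
        meta = default_parcellation(40)
        a = _random_affinity(40, rng)
        g1 = diffusion_embedding(a, GradientParams(n_components=3), metadata=meta)
        g2 = diffusion_embedding(a, GradientParams(n_components=3), metadata=meta)
        np.testing.assert_array_equal(g1.components, g2.components)

    def test_sign_convention_orients_default_above_somatomotor(self, small_cohort):
        from gradhier.pipeline import subject_fisher_matrices

        z = subject_fisher_matrices(small_cohort)
        avg = group_average(z)
        zm = ConnectivityMatrix(avg.values, value_kind="fisher_z")
        params = GradientParams(sparsity=0.5, n_components=3)
        gs = compute_gradients(zm, params, metadata=small_cohort.metadata)
        meta = small_cohort.metadata
        pg = gs.components[:, 0]
        assert pg[meta.parcels_in("Default")].mean() >= pg[meta.parcels_in("Somatomotor")].mean()

    def test_disconnected_graph_advises_lower_sparsity(self):
        a = np.zeros((6, 6))
        a[:3, :3] = 1.0
        a[3:, 3:] = 1.0
        np.fill_diagonal(a, 0.0)
        with pytest.raises(ValidationError, match="sparsity"):
            diffusion_embedding(a, GradientParams(n_components=2))

    def test_eigenvector_orthogonality_under_stationary_measure(self, rng):
        """Right eigenvectors are orthogonal in the D-weighted inner product."""
        a = _random_affinity(25, rng)
        params = GradientParams(n_components=5)
        gs = diffusion_embedding(a, params)
        d = a.sum(axis=1)
        w = a / np.outer(d**0.5, d**0.5)
        dw = w.sum(axis=1)
        gram = gs.components.T @ np.diag(dw) @ gs.components
        off = gram[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 1e-8


class TestSpectrum:
    def test_spectrum_non_increasing(self, rng):
        a = _random_affinity(30, rng)
        gs = diffusion_embedding(a, GradientParams(n_components=13))
        tab = eigenvalue_spectrum(gs, k=13)
        assert (np.diff(tab["eigenvalue"]) <= 0).all()
        assert tab["variance_explained"].sum() <= 1 + 1e-12

    def test_block_structure_separates_leading_eigenvalues(self, rng):
        p = 30
        a = np.full((p, p), 0.02)
        a[:10, :10] += 1.0
        a[10:20, 10:20] += 1.0
        a[20:, 20:] += 1.0
        np.fill_diagonal(a, 0.0)
        gs = diffusion_embedding(a, GradientParams(n_components=6))
        lam = gs.eigenvalues
        # 3 blocks -> 2 non-trivial community eigenvalues separated from bulk
        assert lam[1] - lam[2] > 5 * (lam[2] - lam[5])

    def test_short_gradient_set_returns_all_components(self, rng):
        a = _random_affinity(20, rng)
        gs = diffusion_embedding(a, GradientParams(n_components=4))
        tab = eigenvalue_spectrum(gs, k=13)
        assert len(tab) == 4
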