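import numpy as np
import pytest
from scipy.linalg import eigh, subspace_angles

from cocost import (
    ContrastiveModel,
    background_rayleigh,
    contrast_matrix,
    filtered_scatter,
    fit,
    load_model,
    save_model,
    top_genes,
    transform,
)
from cocost.graphs import build_knn_affinity, laplacian_filter, normalized_laplacian

from conftest import make_dataset


def random_filter(rng, n):
    pts = rng.standard_normal((n, 3))
    Lbar = normalized_laplacian(build_knn_affinity(pts, k=3, t="auto"))
    return laplacian_filter(Lbar, 0.5)


class TestFilteredScatter:
    def test_identity_filter_gives_plain_scatter(self, rng):
        X = rng.standard_normal((5, 8))
        np.testing.assert_allclose(filtered_scatter(X, np.eye(8)), X @ X.T)

    def test_single_nonzero_gene_row(self, rng):
        X = np.zeros((4, 6))
        X[2] = rng.standard_normal(6)
        H = random_filter(rng, 6)
        M = filtered_scatter(X, H)
        mask = np.ones((4, 4), bool)
        mask[2, 2] = False
        assert np.all(M[mask] == 0)
        assert M[2, 2] != 0

    def test_matches_triple_loop_oracle(self, rng):
        X = rng.standard_normal((4, 6))
        H = random_filter(rng, 6).H.toarray()
        expected = np.zeros((4, 4))
        for i in range(6):
            for j in range(6):
                expected += H[i, j] * np.outer(X[:, i], X[:, j])
        np.testing.assert_allclose(filtered_scatter(X, H), expected, atol=1e-10)

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            filtered_scatter(np.ones((3, 5)), np.eye(4))


class TestFit:
    def test_perfect_cancellation(self, rng):
        ds = make_dataset(rng, n=50, d=10)
        model = fit(ds, ds, eta=1.0, mu1=0.4, mu2=0.4, k=5, p=5)
        assert np.abs(model.eigenvalues).max() < 1e-8

    def test_cpca_oracle_engineered_diagonal(self, rng):
        """With identity filters the fit solves eig(Ct - eta*Cb); on
        diagonal scatters the top direction is the axis whose variance is
        enriched in the target."""
        n = 400
        q, _ = np.linalg.qr(rng.standard_normal((n, 2)))
        z = q * np.sqrt(n - 1)  # exactly orthogonal unit-variance-scale columns
        t_expr = z * np.sqrt([10.0, 5.0])
        b_expr = z * np.sqrt([10.0, 1.0])
        target = make_dataset(rng, n=n, d=2, prefix="t")
        background = make_dataset(rng, n=n, d=2, prefix="b")
        target.expr, background.expr = t_expr, b_expr
        model = fit(background, target, eta=1.0, mu1=0.0, mu2=0.0, k=3, p=1)
        top = model.W[:, 0]
        np.testing.assert_allclose(np.abs(top), [0.0, 1.0], atol=1e-8)
        direct = eigh(t_expr.T @ t_expr - b_expr.T @ b_expr)[0][-1]
        assert model.eigenvalues[0] == pytest.approx(direct, abs=1e-8)

    def test_eta_zero_reduces_to_target_pca(self, pair):
        background, target = pair
        model = fit(background, target, eta=0.0, mu1=0.0, mu2=0.0, k=5, p=4)
        _, s, Vt = np.linalg.svd(target.expr, full_matrices=False)
        np.testing.assert_allclose(
            model.eigenvalues, (s**2)[:4], rtol=1e-10, atol=1e-8
        )
        angles = subspace_angles(model.W, Vt[:4].T)
        assert angles.max() < 1e-6
        Z = transform(model, target)
        scores = target.expr @ Vt[:4].T
        np.testing.assert_allclose(np.abs(Z), np.abs(scores), atol=1e-8)

    def test_background_scaling_eta_rescaling_invariance(self, pair):
        """sqrt(c)-scaled background with eta/c leaves the contrast matrix
        unchanged (auto bandwidth makes graph weights scale-free)."""
        background, target = pair
        c = 7.0
        scaled = make_dataset(np.random.default_rng(0), n=background.n_spots, d=background.n_genes, prefix="b")
        scaled.expr = background.expr * np.sqrt(c)
        scaled.coords = background.coords
        M1 = contrast_matrix(background, target, eta=1.0, mu1=0.3, mu2=0.3, k=5)[0]
        M2 = contrast_matrix(scaled, target, eta=1.0 / c, mu1=0.3, mu2=0.3, k=5)[0]
        np.testing.assert_allclose(M1, M2, atol=1e-9)

    def test_spot_permutation_leaves_subspace_unchanged(self, pair):
        background, target = pair
        perm = np.random.default_rng(7).permutation(target.n_spots)
        shuffled = target.subset_spots(perm)
        m1 = fit(background, target, eta=1.0, mu1=0.5, mu2=0.5, k=5, p=3)
        m2 = fit(background, shuffled, eta=1.0, mu1=0.5, mu2=0.5, k=5, p=3)
        assert subspace_angles(m1.W, m2.W).max() < 1e-6

    def test_orthonormality_and_sign_convention(self, pair):
        background, target = pair
        model = fit(background, target, eta=1.0, mu1=0.5, mu2=0.5, k=5, p=4)
        gram = model.W.T @ model.W
        assert np.abs(gram - np.eye(model.p)).max() < 1e-8
        for j in range(model.p):
            col = model.W[:, j]
            assert col[np.argmax(np.abs(col))] > 0

    def test_eigenvalues_sorted_descending(self, pair):
        background, target = pair
        model = fit(background, target, eta=0.5, p=6, include_negative=True)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)

    def test_negative_components_dropped_by_default(self, pair):
        background, target = pair
        full = fit(background, target, eta=2.0, p=10, include_negative=True)
        assert full.eigenvalues.min() < 0  # strong contrast forces negatives
        default = fit(background, target, eta=2.0, p=10)
        assert default.p < 10
        assert default.eigenvalues.min() >= -1e-8

    def test_p_out_of_range_raises(self, pair):
        background, target = pair
        with pytest.raises(ValueError):
            fit(background, target, p=background.n_genes + 1)

    def test_mismatched_namespaces_raise(self, rng):
        a = make_dataset(rng, n=20, d=5)
        b = make_dataset(rng, n=20, d=6)
        with pytest.raises(ValueError, match="namespace"):
            fit(a, b, p=2)


class TestTheorem:
    def test_positive_components_bounded_by_target_energy(self, rng):
        """Positive-eigenvalue directions satisfy w'Bb w <= (1/eta) w'Bt w,
        and their background energy shrinks as eta grows.  The background
        scatter is singular (more genes than background spots) so positive
        eigenvalues persist at any eta."""
        background = make_dataset(rng, n=20, d=30, prefix="b")
        target = make_dataset(rng, n=25, d=30, prefix="t")
        prev_energy = np.inf
        for eta in [1.0, 10.0, 100.0]:
            M, Bb, Bt, *_ = contrast_matrix(
                background, target, eta=eta, mu1=0.5, mu2=0.5, k=5
            )
            vals, vecs = eigh(M)
            pos = vals > 1e-10
            for lam, w in zip(vals[pos], vecs[:, pos].T):
                assert w @ Bb @ w <= (1.0 / eta) * (w @ Bt @ w) + 1e-10
            energy = float(np.max([w @ Bb @ w for w in vecs[:, pos].T]))
            assert energy < prev_energy + 1e-12
            prev_energy = energy

    def test_negative_eigenvalue_identity(self, pair):
        """Remark-style identity: w'Bt w = eta * w'Bb w + lambda holds
        exactly for every eigenpair, in particular the negative ones."""
        background, target = pair
        eta = 5.0
        M, Bb, Bt, *_ = contrast_matrix(background, target, eta=eta, k=5)
        vals, vecs = eigh(M)
        assert vals.min() < 0
        for lam, w in zip(vals, vecs.T):
            resid = (w @ Bt @ w) - eta * (w @ Bb @ w) - lam
            assert abs(resid) < 1e-8
            if lam < 0:
                assert (w @ Bt @ w) >= -1e-10 and (w @ Bb @ w) >= -1e-10


class TestTransform:
    def test_zero_matrix_maps_to_zero(self, pair):
        background, target = pair
        model = fit(background, target, p=3)
        zero = make_dataset(np.random.default_rng(0), n=5, d=target.n_genes)
        zero.expr = np.zeros_like(zero.expr)
        zero.gene_ids = list(target.gene_ids)
        np.testing.assert_array_equal(transform(model, zero), 0.0)

    def test_spot_permutation_equivariance(self, pair):
        background, target = pair
        model = fit(background, target, p=3)
        perm = np.random.default_rng(3).permutation(target.n_spots)
        Z = transform(model, target)
        Zp = transform(model, target.subset_spots(perm))
        np.testing.assert_array_equal(Zp, Z[perm])

    def test_gene_order_irrelevant(self, pair):
        background, target = pair
        model = fit(background, target, p=3)
        perm = np.random.default_rng(5).permutation(target.n_genes)
        shuffled = target.subset_genes([target.gene_ids[j] for j in perm])
        np.testing.assert_allclose(
            transform(model, shuffled), transform(model, target), atol=1e-12
        )

    def test_missing_genes_named_in_error(self, pair):
        background, target = pair
        model = fit(background, target, p=2)
        truncated = target.subset_genes(target.gene_ids[:-1])
        with pytest.raises(KeyError, match=target.gene_ids[-1]):
            transform(model, truncated)


class TestTopGenes:
    def _model(self, W, genes):
        W = np.asarray(W, float)
        return ContrastiveModel(
            W=W,
            eigenvalues=np.zeros(W.shape[1]),
            eta=1.0,
            mu1=0.0,
            mu2=0.0,
            k=1,
            t_b=1.0,
            t_t=1.0,
            gene_ids=genes,
            graph_mode="molecular",
        )

    def test_sorted_by_magnitude_with_signs(self):
        model = self._model([[0.9], [-0.1], [0.05]], ["g1", "g2", "g3"])
        assert top_genes(model, 1, top_k=2) == [
            ("g1", pytest.approx(0.9), "+"),
            ("g2", pytest.approx(0.1), "-"),
        ]

    def test_top_k_larger_than_gene_count_returns_all(self):
        model = self._model([[0.5], [0.3]], ["a", "b"])
        assert len(top_genes(model, 1, top_k=10)) == 2

    def test_equal_magnitudes_lexicographic(self):
        model = self._model([[0.5], [-0.5], [0.5]], ["zz", "aa", "mm"])
        assert [g for g, _, _ in top_genes(model, 1, top_k=3)] == ["aa", "mm", "zz"]

    def test_component_out_of_range(self):
        model = self._model([[1.0]], ["a"])
        with pytest.raises(ValueError):
            top_genes(model, 2)


class TestBackgroundRayleigh:
    def test_identity_scatter_gives_ones(self, pair):
        background, target = pair
        model = fit(background, target, p=3)
        np.testing.assert_allclose(
            background_rayleigh(model, np.eye(model.n_genes)), 1.0, atol=1e-8
        )

    def test_matches_quadratic_form_loop(self, pair, rng):
        background, target = pair
        model = fit(background, target, p=3)
        A = rng.standard_normal((model.n_genes, model.n_genes))
        B = A @ A.T
        expected = [model.W[:, i] @ B @ model.W[:, i] for i in range(model.p)]
        np.testing.assert_allclose(background_rayleigh(model, B), expected, atol=1e-8)

    def test_null_space_vector_gives_zero(self):
        W = np.array([[1.0], [0.0]])
        model = ContrastiveModel(
            W=W, eigenvalues=np.zeros(1), eta=1.0, mu1=0, mu2=0, k=1,
            t_b=1.0, t_t=1.0, gene_ids=["a", "b"], graph_mode="molecular",
        )
        B = np.array([[0.0, 0.0], [0.0, 2.0]])  # W[:,0] in null space
        assert background_rayleigh(model, B)[0] == 0.0


def test_model_serialization_round_trip(tmp_path, pair):
    background, target = pair
    model = fit(background, target, eta=1.5, mu1=0.2, mu2=0.7, k=4, p=3)
    save_model(model, tmp_path / "model")
    loaded = load_model(tmp_path / "model")
    np.testing.assert_array_equal(loaded.W, model.W)
    np.testing.assert_array_equal(loaded.eigenvalues, model.eigenvalues)
    assert loaded.gene_ids == model.gene_ids
    assert (loaded.eta, loaded.mu1, loaded.mu2, loaded.k) == (1.5, 0.2, 0.7, 4)
    assert loaded.graph_mode == model.graph_mode
    np.testing.assert_array_equal(
        transform(loaded, target), transform(model, target)
    )
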