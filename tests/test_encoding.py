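"""PCA/whitening, GMM codebook and Fisher-vector contracts.

The Fisher vector is checked against an independent finite-difference
gradient of the GMM log-likelihood, scaled by the same closed-form Fisher
information factors.
"""

import numpy as np
import pytest
from scipy.special import logsumexp

from hydramotion.config import PipelineConfig
from hydramotion.encoding import (
    GmmCodebook,
    PcaWhitener,
    block_layout,
    encode_window,
    fisher_vector,
    fit_codebook,
    fit_codebooks,
    fit_pca_whiten,
    load_codebooks,
    normalize_fv,
    save_codebooks,
)
from hydramotion.features import DESC_DIMS, DESC_ORDER, PART_ORDER


def gmm_loglik(X, w, mu, var):
    """Independent log-likelihood used by the finite-difference oracle."""
    d = X.shape[1]
    comp = []
    for i in range(len(w)):
        diff = X - mu[i]
        comp.append(np.log(w[i]) - 0.5 * (np.sum(diff**2 / var[i], axis=1)
                                          + np.sum(np.log(var[i]))
                                          + d * np.log(2 * np.pi)))
    return logsumexp(np.array(comp), axis=0).sum()


def fd_fisher_vector(X, w, mu, var, eps=1e-5):
    """Central finite differences of the log-likelihood, Fisher-scaled."""
    K, d = mu.shape
    T = X.shape[0]
    sigma = np.sqrt(var)
    out = []
    for i in range(K):
        for j in range(d):
            m1, m2 = mu.copy(), mu.copy()
            m1[i, j] += eps; m2[i, j] -= eps
            g = (gmm_loglik(X, w, m1, var) - gmm_loglik(X, w, m2, var)) / (2 * eps)
            out.append(sigma[i, j] / (T * np.sqrt(w[i])) * g)
    for i in range(K):
        for j in range(d):
            s1, s2 = sigma.copy(), sigma.copy()
            s1[i, j] += eps; s2[i, j] -= eps
            g = (gmm_loglik(X, w, mu, s1**2) - gmm_loglik(X, w, mu, s2**2)) / (2 * eps)
            out.append(sigma[i, j] / (T * np.sqrt(2 * w[i])) * g)
    return np.array(out)


class TestPcaWhiten:
    def test_hof_keeps_five_components(self, rng):
        X = rng.normal(0, 1, (200, 9))
        tr = fit_pca_whiten({"tentacle": X[:100], "upper": X[100:]})
        assert tr.n_components == 5

    def test_even_dims_halved(self, rng):
        X = rng.normal(0, 1, (100, 8))
        assert fit_pca_whiten({"upper": X}).n_components == 4

    def test_whitened_components_unit_variance(self, rng):
        X = rng.normal(0, 2.5, (500, 8)) @ rng.normal(0, 1, (8, 8))
        tr = fit_pca_whiten({"upper": X})
        W = tr.transform(X, "upper")
        assert np.allclose(W.var(axis=0, ddof=1), 1.0, atol=1e-6)

    def test_eigenvalue_scaling(self):
        tr = PcaWhitener({"upper": np.zeros(2)}, np.eye(2)[:1],
                         np.array([4.0]))
        out = tr.transform(np.array([[2.0, 0.0]]), "upper")
        assert out[0, 0] == pytest.approx(1.0)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_pca_whiten({"upper": rng.normal(0, 1, (3, 9))})


class TestCodebook:
    def test_k1_closed_form(self, rng):
        X = rng.normal(3.0, 2.0, (2000, 2))
        cb = fit_codebook(X, k=1, seed=0)
        assert np.allclose(cb.weights, [1.0])
        assert np.allclose(cb.means[0], X.mean(axis=0), atol=1e-6)
        assert np.allclose(cb.variances[0], X.var(axis=0), atol=1e-5)

    def test_two_separated_gaussians_recovered(self, rng):
        a = rng.normal(-4.0, 0.5, (1500, 2))
        b = rng.normal(+4.0, 0.5, (1500, 2))
        cb = fit_codebook(np.vstack([a, b]), k=2, seed=1)
        means = cb.means[np.argsort(cb.means[:, 0])]
        assert np.allclose(means[0], [-4, -4], atol=0.1)
        assert np.allclose(means[1], [4, 4], atol=0.1)
        assert cb.weights.sum() == pytest.approx(1.0)

    def test_weights_always_normalized(self, rng):
        cb = fit_codebook(rng.normal(0, 1, (500, 3)), k=5, seed=2)
        assert cb.weights.sum() == pytest.approx(1.0)
        assert (cb.weights > 0).all()

    def test_more_components_than_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_codebook(rng.normal(0, 1, (3, 2)), k=5)


class TestFisherVector:
    def test_single_point_at_mean_closed_form(self):
        cb = GmmCodebook(None, np.array([1.0]), np.zeros((1, 3)),
                         np.ones((1, 3)))
        fv = fisher_vector(np.zeros((1, 3)), cb)
        assert np.allclose(fv[:3], 0.0)
        assert np.allclose(fv[3:], -1.0 / np.sqrt(2.0))

    def test_matches_finite_difference_oracle(self, rng):
        """Closed form vs numeric gradient on 20 random small instances."""
        worst = 0.0
        for _ in range(20):
            K, d = 2, int(rng.integers(1, 4))
            T = int(rng.integers(2, 11))
            w = rng.dirichlet(np.full(K, 5.0))
            mu = rng.normal(0, 1, (K, d))
            var = rng.uniform(0.5, 2.0, (K, d))
            X = rng.normal(0, 1.5, (T, d))
            fv = fisher_vector(X, GmmCodebook(None, w, mu, var))
            oracle = fd_fisher_vector(X, w, mu, var)
            worst = max(worst, np.abs(fv - oracle).max())
        assert worst < 1e-5

    def test_expected_score_vanishes_at_large_t(self, rng):
        """Samples from the codebook's own GMM give a near-zero vector."""
        w = np.array([0.3, 0.5, 0.2])
        mu = rng.normal(0, 2, (3, 2))
        var = rng.uniform(0.5, 1.5, (3, 2))
        comp = rng.choice(3, 100_000, p=w)
        X = mu[comp] + rng.normal(0, 1, (100_000, 2)) * np.sqrt(var[comp])
        fv = fisher_vector(X, GmmCodebook(None, w, mu, var))
        assert np.linalg.norm(fv) < 0.05

    def test_dimension_mismatch_rejected(self):
        cb = GmmCodebook(None, np.array([1.0]), np.zeros((1, 3)),
                         np.ones((1, 3)))
        with pytest.raises(ValueError):
            fisher_vector(np.zeros((5, 2)), cb)


class TestNormalization:
    def test_scalar_example(self):
        assert normalize_fv(np.array([-4.0]))[0] == pytest.approx(-1.0)

    def test_unit_norm(self, rng):
        z = rng.normal(0, 3, 50)
        assert np.linalg.norm(normalize_fv(z)) == pytest.approx(1.0, abs=1e-12)

    def test_alpha_one_is_pure_l2(self, rng):
        z = rng.normal(0, 3, 20)
        assert np.allclose(normalize_fv(z, 1.0), z / np.linalg.norm(z))

    def test_zero_vector_stays_zero(self):
        assert np.allclose(normalize_fv(np.zeros(10)), 0.0)

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError):
            normalize_fv(np.ones(3), alpha=0.0)


def _toy_descriptors(rng, n_by_part):
    out = {}
    for part in PART_ORDER:
        n = n_by_part.get(part, 0)
        out[part] = {d: (rng.uniform(0, 1, (n, DESC_DIMS[d])) if n
                         else np.empty((0, DESC_DIMS[d])))
                     for d in DESC_ORDER}
    return out


@pytest.fixture(scope="module")
def toy_codebooks():
    rng = np.random.default_rng(7)
    cfg = PipelineConfig(gmm_k=3, gmm_subset=10_000)
    windows = [_toy_descriptors(rng, {"tentacle": 40, "upper": 60, "lower": 50})
               for _ in range(3)]
    return fit_codebooks(windows, cfg, seed=0), cfg


class TestEncodeWindow:
    def test_expected_length_and_unit_norm(self, toy_codebooks, rng):
        codebooks, cfg = toy_codebooks
        desc = _toy_descriptors(rng, {"tentacle": 20, "upper": 30, "lower": 10})
        fw = encode_window(desc, codebooks, cfg.fv_alpha)
        k = cfg.gmm_k
        assert fw.vector.size == 3 * 2 * k * (5 + 4 + 4 + 4)
        assert np.linalg.norm(fw.vector) == pytest.approx(1.0)

    def test_empty_parts_contribute_zero_blocks(self, toy_codebooks, rng):
        codebooks, cfg = toy_codebooks
        desc = _toy_descriptors(rng, {"tentacle": 25})
        fw = encode_window(desc, codebooks, cfg.fv_alpha)
        layout = block_layout(codebooks)
        for part in ("upper", "lower"):
            for dtype in DESC_ORDER:
                assert np.allclose(fw.vector[layout[f"{part}/{dtype}"]], 0.0)
        assert np.linalg.norm(fw.vector) == pytest.approx(1.0)

    def test_trajectory_order_invariance(self, toy_codebooks, rng):
        codebooks, cfg = toy_codebooks
        desc = _toy_descriptors(rng, {"upper": 30})
        permuted = {p: {d: v[::-1].copy() for d, v in by.items()}
                    for p, by in desc.items()}
        a = encode_window(desc, codebooks, cfg.fv_alpha)
        b = encode_window(permuted, codebooks, cfg.fv_alpha)
        assert np.allclose(a.vector, b.vector)

    def test_duplication_invariance(self, toy_codebooks, rng):
        """Doubling every descriptor leaves the T-normalized FV unchanged."""
        codebooks, cfg = toy_codebooks
        desc = _toy_descriptors(rng, {"upper": 30})
        doubled = {p: {d: np.vstack([v, v]) if v.size else v
                       for d, v in by.items()}
                   for p, by in desc.items()}
        a = encode_window(desc, codebooks, cfg.fv_alpha)
        b = encode_window(doubled, codebooks, cfg.fv_alpha)
        assert np.allclose(a.vector, b.vector, atol=1e-10)

    def test_all_empty_window_is_zero(self, toy_codebooks):
        codebooks, cfg = toy_codebooks
        desc = _toy_descriptors(np.random.default_rng(0), {})
        fw = encode_window(desc, codebooks, cfg.fv_alpha)
        assert np.allclose(fw.vector, 0.0)

    def test_codebook_roundtrip(self, toy_codebooks, rng, tmp_path):
        codebooks, cfg = toy_codebooks
        path = tmp_path / "cb.npz"
        save_codebooks(codebooks, path)
        loaded = load_codebooks(path)
        desc = _toy_descriptors(rng, {"tentacle": 10, "upper": 10, "lower": 10})
        a = encode_window(desc, codebooks, cfg.fv_alpha)
        b = encode_window(desc, loaded, cfg.fv_alpha)
        assert np.allclose(a.vector, b.vector)
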