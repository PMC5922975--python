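"""Fisher-vector encoding over Gaussian-mixture codebooks.

One codebook is learned per descriptor type (HOF, HOG, MBHx, MBHy):
descriptors are centered per body part, projected by a shared PCA to half
their dimension (ceil(D/2): 5 for the 9-bin HOF, 4 for the 8-bin types),
whitened by the PCA eigenvalues (x_i / sqrt(lambda_i)), and fitted with a
K-component diagonal-covariance Gaussian mixture on a seeded random subset.

A window's descriptors X = {x_t} are then encoded by the Fisher vector: the
gradient of the GMM log-likelihood with respect to the mean and variance
parameters, normalized by the closed-form diagonal approximation of the
Fisher information.  With posterior responsibilities
gamma_t(i) = w_i u_i(x_t) / sum_j w_j u_j(x_t):

    G_mu(i,d)    = 1/(T sqrt(w_i))   sum_t gamma_t(i) (x_td - mu_id)/sigma_id
    G_sigma(i,d) = 1/(T sqrt(2 w_i)) sum_t gamma_t(i) [((x_td - mu_id)/sigma_id)^2 - 1]

Weight gradients are omitted (the improved-Fisher-vector convention).  Each
block is power-normalized, f(z) = sign(z) |z|^alpha with alpha = 0.5, then
l2-normalized.  The window representation concatenates the blocks in the
fixed order (tentacle, upper, lower) x (HOF, HOG, MBHx, MBHy) — within each
block all mean gradients (K x d) then all variance gradients (K x d) — and
is l2-normalized once more, so every encoded window has unit norm (or is
all-zero when no trajectory survived anywhere).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .config import PipelineConfig
from .features import DESC_DIMS, DESC_ORDER, PART_ORDER

RESPONSIBILITY_FLOOR = 1e-10


@dataclass
class PcaWhitener:
    """Per-part centering + shared PCA to ceil(D/2) + eigenvalue whitening."""

    part_means: dict[str, np.ndarray]
    components: np.ndarray      # (n_out, D)
    eigenvalues: np.ndarray     # (n_out,)

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, X: np.ndarray, part: str) -> np.ndarray:
        Xc = np.asarray(X, float) - self.part_means[part]
        scores = Xc @ self.components.T
        return scores / np.sqrt(self.eigenvalues)


def fit_pca_whiten(descriptors_by_part: dict[str, np.ndarray]) -> PcaWhitener:
    """Fit the centering/PCA/whitening transform for one descriptor type.

    ``descriptors_by_part`` maps part name -> (N_p, D) array.  Each part is
    centered at zero; PCA is fitted on the pooled centered data, keeping
    ceil(D/2) components.
    """
    parts = {p: np.asarray(X, float) for p, X in descriptors_by_part.items()
             if np.asarray(X).size}
    if not parts:
        raise ValueError("no descriptors to fit")
    dim = next(iter(parts.values())).shape[1]
    n_out = math.ceil(dim / 2)
    means = {p: X.mean(axis=0) for p, X in parts.items()}
    pooled = np.vstack([X - means[p] for p, X in parts.items()])
    if pooled.shape[0] < n_out + 1:
        raise ValueError(
            f"{pooled.shape[0]} descriptors cannot support {n_out} components")
    pca = PCA(n_components=n_out, svd_solver="full")
    pca.fit(pooled)
    eig = np.maximum(pca.explained_variance_, 1e-12)
    # parts never seen at fit time fall back to the pooled mean of means
    default = np.mean(list(means.values()), axis=0)
    all_means = {p: means.get(p, default) for p in PART_ORDER}
    return PcaWhitener(all_means, pca.components_, eig)


@dataclass
class GmmCodebook:
    """Whitening transform + diagonal GMM for one descriptor type."""

    whitener: PcaWhitener
    weights: np.ndarray        # (K,)
    means: np.ndarray          # (K, d)
    variances: np.ndarray      # (K, d)

    @property
    def k(self) -> int:
        return self.weights.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]


def fit_codebook(whitened: np.ndarray, k: int, n_subset: int = 256_000,
                 seed: int = 0, whitener: PcaWhitener | None = None
                 ) -> GmmCodebook:
    """Fit a K-component diagonal-covariance GMM on a seeded subset."""
    X = np.asarray(whitened, float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if X.shape[0] < k:
        raise ValueError(f"{X.shape[0]} samples cannot support K={k}")
    rng = np.random.default_rng(seed)
    if X.shape[0] > n_subset:
        X = X[rng.choice(X.shape[0], n_subset, replace=False)]
    gm = GaussianMixture(n_components=k, covariance_type="diag",
                         reg_covar=1e-6, max_iter=200, n_init=1,
                         random_state=int(rng.integers(2**31)))
    gm.fit(X)
    return GmmCodebook(whitener, gm.weights_, gm.means_,
                       np.maximum(gm.covariances_, 1e-8))


def _log_responsibilities(X: np.ndarray, cb: GmmCodebook) -> np.ndarray:
    """(T, K) log posterior responsibilities, computed in log space."""
    diff = X[:, None, :] - cb.means[None]                  # (T, K, d)
    log_det = np.sum(np.log(cb.variances), axis=1)         # (K,)
    maha = np.sum(diff**2 / cb.variances[None], axis=2)    # (T, K)
    log_prob = -0.5 * (maha + log_det + cb.dim * np.log(2 * np.pi))
    log_weighted = np.log(cb.weights)[None] + log_prob
    return log_weighted - logsumexp(log_weighted, axis=1, keepdims=True)


def fisher_vector(X: np.ndarray, codebook: GmmCodebook) -> np.ndarray:
    """Raw (un-normalized) Fisher vector of a whitened descriptor set.

    Layout: all mean gradients (K*d, component-major) followed by all
    variance gradients (K*d).  Components whose total responsibility is
    below 1e-10 contribute zero blocks.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != codebook.dim:
        raise ValueError(
            f"descriptor dim {X.shape[1]} != codebook dim {codebook.dim}")
    T = X.shape[0]
    gamma = np.exp(_log_responsibilities(X, codebook))     # (T, K)
    sigma = np.sqrt(codebook.variances)                    # (K, d)
    diff = (X[:, None, :] - codebook.means[None]) / sigma[None]  # (T, K, d)
    g_mu = np.einsum("tk,tkd->kd", gamma, diff)
    g_sigma = np.einsum("tk,tkd->kd", gamma, diff**2 - 1.0)
    g_mu /= T * np.sqrt(codebook.weights)[:, None]
    g_sigma /= T * np.sqrt(2.0 * codebook.weights)[:, None]
    dead = gamma.sum(axis=0) < RESPONSIBILITY_FLOOR
    g_mu[dead] = 0.0
    g_sigma[dead] = 0.0
    return np.concatenate([g_mu.ravel(), g_sigma.ravel()])


def normalize_fv(z: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Power normalization sign(z)|z|^alpha followed by l2 normalization."""
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    z = np.asarray(z, float)
    p = np.sign(z) * np.abs(z) ** alpha
    n = np.linalg.norm(p)
    return p / n if n > 0 else p


@dataclass
class FisherWindow:
    """Concatenated normalized Fisher vector of one window."""

    vector: np.ndarray
    window_id: str
    block_slices: dict[str, slice]
    label: int | None = None


def fit_codebooks(descriptors: dict[str, dict[str, np.ndarray]] | list,
                  config: PipelineConfig | None = None,
                  seed: int | None = None) -> dict[str, GmmCodebook]:
    """Fit the four per-type codebooks from pooled window descriptors.

    ``descriptors`` is either one window's {part: {type: array}} mapping or
    a list of them (pooled over windows).
    """
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    if isinstance(descriptors, dict):
        descriptors = [descriptors]
    codebooks = {}
    for j, dtype in enumerate(DESC_ORDER):
        by_part = {}
        for part in PART_ORDER:
            arrs = [w[part][dtype] for w in descriptors if w[part][dtype].size]
            by_part[part] = (np.vstack(arrs) if arrs
                             else np.empty((0, DESC_DIMS[dtype])))
        whitener = fit_pca_whiten(by_part)
        whitened = np.vstack([
            whitener.transform(X, p) for p, X in by_part.items() if X.size])
        codebooks[dtype] = fit_codebook(whitened, config.gmm_k,
                                        config.gmm_subset, seed + j,
                                        whitener=whitener)
    return codebooks


def block_layout(codebooks: dict[str, GmmCodebook]) -> dict[str, slice]:
    """Index map of the concatenated vector, '{part}/{type}' -> slice."""
    layout, offset = {}, 0
    for part in PART_ORDER:
        for dtype in DESC_ORDER:
            cb = codebooks[dtype]
            size = 2 * cb.k * cb.dim
            layout[f"{part}/{dtype}"] = slice(offset, offset + size)
            offset += size
    return layout


def encode_window(window_descriptors: dict[str, dict[str, np.ndarray]],
                  codebooks: dict[str, GmmCodebook],
                  alpha: float = 0.5, window_id: str = "",
                  label: int | None = None) -> FisherWindow:
    """Encode one window as the concatenated normalized Fisher vector."""
    layout = block_layout(codebooks)
    total = max(s.stop for s in layout.values())
    vec = np.zeros(total)
    for part in PART_ORDER:
        for dtype in DESC_ORDER:
            X = window_descriptors[part][dtype]
            if X.size == 0:
                continue
            cb = codebooks[dtype]
            Xw = cb.whitener.transform(X, part)
            raw = fisher_vector(Xw, cb)
            vec[layout[f"{part}/{dtype}"]] = normalize_fv(raw, alpha)
    n = np.linalg.norm(vec)
    if n > 0:
        vec = vec / n
    return FisherWindow(vec, window_id, layout, label)


# ---------------------------------------------------------------------------
# serialization


def save_codebooks(codebooks: dict[str, GmmCodebook], path: str | Path) -> None:
    """Serialize codebooks to a versioned .npz bundle."""
    arrays: dict[str, np.ndarray] = {}
    meta = {"version": 1, "types": list(codebooks)}
    for dtype, cb in codebooks.items():
        arrays[f"{dtype}_weights"] = cb.weights
        arrays[f"{dtype}_means"] = cb.means
        arrays[f"{dtype}_variances"] = cb.variances
        arrays[f"{dtype}_components"] = cb.whitener.components
        arrays[f"{dtype}_eigenvalues"] = cb.whitener.eigenvalues
        for part, m in cb.whitener.part_means.items():
            arrays[f"{dtype}_mean_{part}"] = m
    np.savez(path, _meta=json.dumps(meta), **arrays)


def load_codebooks(path: str | Path) -> dict[str, GmmCodebook]:
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["_meta"]))
    out = {}
    for dtype in meta["types"]:
        whitener = PcaWhitener(
            {p: data[f"{dtype}_mean_{p}"] for p in PART_ORDER},
            data[f"{dtype}_components"], data[f"{dtype}_eigenvalues"])
        out[dtype] = GmmCodebook(whitener, data[f"{dtype}_weights"],
                                 data[f"{dtype}_means"],
                                 data[f"{dtype}_variances"])
    return out
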