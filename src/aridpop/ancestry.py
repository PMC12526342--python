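"""Admixture inference by sparse nonnegative matrix factorization, with
cross-entropy model choice and DAPC cross-validation.

Genotypes are one-hot encoded per site (three genotype classes for a
diploid biallelic SNP) and factored as X ~ Q G, where Q (samples x K) holds
individual ancestry proportions on the probability simplex and G
(K x 3*sites) holds per-ancestry genotype-class frequencies, each site
block of each ancestry row summing to one. The factorization is fitted by
alternating nonnegative least squares with projection of Q rows onto the
simplex and renormalization of G blocks after each half-step.

The number of ancestral populations K is chosen by the cross-entropy
criterion: a fraction of observed genotype cells is hidden, the model is
fitted on the masked data, and the mean negative log-probability of the
true hidden classes under Q G is minimized over K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix, ValidationError

PROB_FLOOR = 1e-10


@dataclass
class AncestryResult:
    K: int
    Q: np.ndarray          # n_samples x K, rows on the simplex
    G: np.ndarray          # K x 3*n_sites, per-site blocks sum to 1
    loss: float            # squared Frobenius objective at convergence
    seed: int
    cross_entropy: float | None = None
    loss_history: np.ndarray | None = None


@dataclass
class DapcResult:
    retained_pcs: int
    n_discriminants: int
    sample_scores: np.ndarray   # n x n_discriminants
    posteriors: np.ndarray      # n x K, rows on the simplex
    loadings: np.ndarray        # retained_pcs x n_discriminants


def genotype_class_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Empirical (n_sites, 3) genotype-class frequencies over non-missing calls."""
    called = gm.called_mask()
    counts = np.stack(
        [((gm.dosage == k) & called).sum(axis=0) for k in (0, 1, 2)], axis=1
    ).astype(float)
    n = counts.sum(axis=1, keepdims=True)
    freqs = np.where(n > 0, counts / np.where(n == 0, 1, n), 1.0 / 3.0)
    return freqs


def encode_indicator(gm: GenotypeMatrix) -> np.ndarray:
    """One-hot encode dosages into an (n_samples, 3*n_sites) matrix.

    Dosage d becomes the unit vector e_d in the site's 3-column block;
    missing calls carry the site's empirical genotype-class frequencies so
    every row block still sums to one.
    """
    n, m = gm.dosage.shape
    X = np.zeros((n, 3 * m))
    freqs = genotype_class_frequencies(gm)
    for k in (0, 1, 2):
        X[:, k::3] = (gm.dosage == k).astype(float)
    miss = gm.dosage == MISSING
    for k in (0, 1, 2):
        block = X[:, k::3]
        block[miss] = np.broadcast_to(freqs[:, k], (n, m))[miss]
    return X


def _nnls_rows(AtX: np.ndarray, AtA: np.ndarray, B: np.ndarray,
               n_sweeps: int = 3) -> np.ndarray:
    """Cyclic coordinate descent for min ||X - A B||_F^2 over B >= 0.

    Works on the normal-equation blocks AtX = A'X (K x m) and AtA = A'A
    (K x K); exact row-wise minimization, vectorized over all columns.
    """
    K = AtA.shape[0]
    diag = np.maximum(np.diag(AtA), 1e-12)
    for _ in range(n_sweeps):
        for k in range(K):
            resid = AtX[k] - AtA[k] @ B + diag[k] * B[k]
            B[k] = np.maximum(0.0, resid / diag[k])
    return B


def _project_rows_to_simplex(Q: np.ndarray) -> np.ndarray:
    """Normalize nonnegative rows to sum 1 (uniform row where the sum is 0)."""
    s = Q.sum(axis=1, keepdims=True)
    K = Q.shape[1]
    return np.where(s > 0, Q / np.where(s == 0, 1, s), 1.0 / K)


def _renormalize_blocks(G: np.ndarray) -> np.ndarray:
    """Scale each ancestry row's per-site 3-block to sum 1 (uniform if 0)."""
    K, m3 = G.shape
    blocks = G.reshape(K, m3 // 3, 3)
    s = blocks.sum(axis=2, keepdims=True)
    blocks = np.where(s > 0, blocks / np.where(s == 0, 1, s), 1.0 / 3.0)
    return blocks.reshape(K, m3)


def snmf_fit(X: np.ndarray, K: int, seed: int = 0, max_iter: int = 200,
             tol: float = 1e-5) -> AncestryResult:
    """Alternating nonnegative least squares fit of X ~ Q G.

    Deterministic given ``seed`` (uniform random initialization of Q).
    Iterates until the relative loss change drops below ``tol`` or
    ``max_iter`` is reached. K = 1 has the closed-form solution Q = 1 and
    G = column means.
    """
    n, m3 = X.shape
    if K < 1:
        raise ValidationError("K must be >= 1")
    if K > n:
        raise ValidationError(f"K={K} exceeds the number of samples ({n})")
    if K == 1:
        G = _renormalize_blocks(X.mean(axis=0, keepdims=True))
        Q = np.ones((n, 1))
        loss = float(((X - Q @ G) ** 2).sum())
        return AncestryResult(K=1, Q=Q, G=G, loss=loss, seed=seed,
                              loss_history=np.array([loss]))
    rng = np.random.default_rng(seed)
    Q = _project_rows_to_simplex(rng.uniform(0.1, 1.0, size=(n, K)))
    G = _renormalize_blocks(np.maximum(rng.uniform(0.0, 1.0, size=(K, m3)), 1e-3))
    losses = []
    prev = np.inf
    for _ in range(max_iter):
        G = _nnls_rows(Q.T @ X, Q.T @ Q, G)
        G = _renormalize_blocks(G)
        Qt = _nnls_rows(G @ X.T, G @ G.T, Q.T.copy())
        Q = _project_rows_to_simplex(Qt.T)
        loss = float(((X - Q @ G) ** 2).sum())
        losses.append(loss)
        if np.isfinite(prev) and prev - loss <= tol * max(prev, 1e-12):
            break
        prev = loss
    return AncestryResult(K=K, Q=Q, G=G, loss=losses[-1], seed=seed,
                          loss_history=np.asarray(losses))


def predict_class_probabilities(res: AncestryResult) -> np.ndarray:
    """Per-cell genotype-class probabilities (n, n_sites, 3) from Q G."""
    P = res.Q @ res.G
    n, m3 = P.shape
    P = P.reshape(n, m3 // 3, 3)
    P = np.maximum(P, 0.0)
    s = P.sum(axis=2, keepdims=True)
    P = np.where(s > 0, P / np.where(s == 0, 1, s), 1.0 / 3.0)
    return np.maximum(P, PROB_FLOOR)


def cross_entropy(gm: GenotypeMatrix, K: int, mask_fraction: float = 0.05,
                  seed: int = 0, max_iter: int = 200, tol: float = 1e-5) -> float:
    """Masked-genotype prediction error of the K-ancestry model.

    A uniform random ``mask_fraction`` of the non-missing genotype cells is
    hidden, the factorization is fitted on the masked matrix, and the mean
    negative log-probability of the true genotype classes at the hidden
    cells (probabilities floored at 1e-10) is returned.
    """
    if not 0.0 < mask_fraction < 0.5:
        raise ValidationError("mask_fraction must be in (0, 0.5)")
    called = gm.called_mask()
    cells = np.flatnonzero(called.ravel())
    if cells.size == 0:
        raise ValidationError("no non-missing genotype cells to mask")
    rng = np.random.default_rng(seed)
    n_mask = max(1, int(round(mask_fraction * cells.size)))
    chosen = rng.choice(cells, size=n_mask, replace=False)
    masked = gm.dosage.copy().ravel()
    truth = masked[chosen].copy()
    masked[chosen] = MISSING
    masked_gm = GenotypeMatrix(gm.sample_ids, gm.sites,
                               masked.reshape(gm.dosage.shape), sort=False)
    res = snmf_fit(encode_indicator(masked_gm), K, seed=seed,
                   max_iter=max_iter, tol=tol)
    P = predict_class_probabilities(res)
    rows, cols = np.unravel_index(chosen, gm.dosage.shape)
    p_true = P[rows, cols, truth.astype(int)]
    return float(-np.log(p_true).mean())


def select_K(gm: GenotypeMatrix, k_range: range | list[int] = range(1, 11),
             replicates: int = 20, seed: int = 0, mask_fraction: float = 0.05,
             max_iter: int = 200, tol: float = 1e-5) -> tuple[pd.DataFrame, int]:
    """Cross-entropy table over K and replicates, plus the selected K.

    Each (K, replicate) run draws its own mask and initialization from a
    seed derived via ``SeedSequence(seed, K, replicate)``, so runs are
    reproducible in isolation and independent of iteration order. best_K
    minimizes the per-K mean replicate cross-entropy: the replicate minimum
    rides on mask/initialization noise and can be won by a neighboring K,
    while the mean tracks the curve's elbow. The full table is returned so
    both summaries (and the replicate cloud) can be inspected.
    """
    rows = []
    for K in k_range:
        for rep in range(replicates):
            rep_seed = int(np.random.SeedSequence((seed, K, rep)).generate_state(1)[0]
                           % (2**31))
            ce = cross_entropy(gm, K, mask_fraction=mask_fraction, seed=rep_seed,
                               max_iter=max_iter, tol=tol)
            rows.append((K, rep, rep_seed, ce))
    table = pd.DataFrame(rows, columns=["K", "replicate", "seed", "cross_entropy"])
    best_K = int(table.groupby("K")["cross_entropy"].mean().idxmin())
    return table, best_K


def assign_clusters(Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hard cluster labels (1-based) from ancestry proportions.

    Label = argmax of each Q row, ties to the lowest cluster index; the
    second array flags admixed individuals whose top proportion is < 0.5.
    """
    labels = np.argmax(Q, axis=1) + 1
    admixed = Q.max(axis=1) < 0.5
    return labels, admixed


def dapc_fit(gm: GenotypeMatrix, labels: np.ndarray, n_pca: int = 40,
             n_da: int = 3) -> DapcResult:
    """Discriminant analysis of principal components on given group labels.

    Missing dosages are mean-imputed per site, columns centered and scaled,
    PCA retains ``n_pca`` components (capped at the data rank), and linear
    discriminant analysis with pooled within-group covariance yields
    discriminant scores and posterior membership probabilities.
    """
    from sklearn.decomposition import PCA
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("DAPC needs at least 2 groups")
    if counts.min() < 2:
        raise ValidationError("every group needs at least 2 members")
    if n_pca < 1:
        raise ValidationError("n_pca must be >= 1")
    n_da = min(n_da, len(uniq) - 1)

    D = gm.dosage.astype(float)
    miss = gm.dosage == MISSING
    col_mean = np.where(miss, np.nan, D).T
    col_mean = np.nanmean(col_mean, axis=1)
    col_mean = np.nan_to_num(col_mean, nan=0.0)
    D = np.where(miss, col_mean[None, :], D)
    D -= D.mean(axis=0)
    sd = D.std(axis=0)
    D /= np.where(sd == 0, 1.0, sd)

    cap = min(n_pca, gm.n_samples - 1, gm.n_sites)
    pca = PCA(n_components=cap, random_state=0)
    scores = pca.fit_transform(D)
    lda = LinearDiscriminantAnalysis(n_components=n_da, solver="svd")
    da_scores = lda.fit_transform(scores, labels)
    posteriors = lda.predict_proba(scores)
    loadings = lda.scalings_[:, :n_da]
    return DapcResult(retained_pcs=cap, n_discriminants=n_da,
                      sample_scores=da_scores, posteriors=posteriors,
                      loadings=loadings)
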