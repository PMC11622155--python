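"""Ancestry structure: sparse-NMF ancestry coefficients and genotype PCA.

The sparse-NMF fit factorises the genotype dosage matrix G/2 into
admixture proportions Q (rows on the probability simplex) and ancestral
allele frequencies F (entries in [0, 1]) by alternating regularised least
squares.  A random fraction of observed entries is masked before fitting
and the binomial cross-entropy of those held-out calls scores the fit;
the number of ancestral populations K is chosen by the lowest held-out
cross-entropy over repeated seeded fits.  PCA scores on binomially scaled
genotypes feed the principal-component outlier scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MISSING

_EPS = 1e-6


@dataclass
class AncestryFit:
    """Result of one sparse-NMF fit."""

    Q: np.ndarray  # n_ind x K, rows sum to 1
    F: np.ndarray  # K x n_loci, entries in [0, 1]
    alpha: float
    cross_entropy: float
    seed: int
    n_iter: int
    loss: float


def _project_rows_to_simplex(Q: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = Q.shape
    u = np.sort(Q, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    theta = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(Q - theta[:, None], 0.0)


def _batched_weighted_ridge(
    A: np.ndarray, W: np.ndarray, B: np.ndarray, alpha: float
) -> np.ndarray:
    """Solve min_x ||w^(1/2) (b - A x)||^2 + alpha ||x||^2 per column of B.

    A is n x K, W and B are n x m (per-column weights/targets); returns a
    K x m matrix of solutions via batched K x K normal equations.
    """
    k = A.shape[1]
    # lhs[j] = A^T diag(W[:, j]) A ;  rhs[j] = A^T (W[:, j] * B[:, j])
    lhs = np.einsum("ik,ij,il->jkl", A, W, A) + alpha * np.eye(k)[None, :, :]
    rhs = np.einsum("ik,ij->jk", A, W * B)
    return np.linalg.solve(lhs, rhs[:, :, None])[:, :, 0].T


def fit_snmf(
    matrix: GenotypeMatrix,
    K: int,
    alpha: float = 10.0,
    mask_fraction: float = 0.05,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-6,
    callback=None,
) -> AncestryFit:
    """Alternating-least-squares sparse-NMF with held-out cross-entropy.

    Minimises ``||W ⊙ (G/2 - Q F)||^2 + alpha * mean_j ||f_j||^2`` where W
    masks missing entries and a random ``mask_fraction`` of observed
    entries held out for validation; Q rows are projected to the simplex
    after each update and F is clipped to [0, 1].  The ridge penalises the
    mean per-locus loading norm so its strength does not grow with panel
    size and the default stays mild, as in the original tool's regime.
    ``cross_entropy`` is the mean negative log-likelihood of the held-out
    calls under Binomial(2, (QF)).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > matrix.n_ind:
        raise ValueError("K cannot exceed the number of individuals")
    rng = np.random.default_rng(seed)
    G = matrix.calls.astype(float)
    observed = G != MISSING
    holdout = observed & (rng.random(G.shape) < mask_fraction)
    fit_mask = (observed & ~holdout).astype(float)
    P = np.where(observed, G / 2.0, 0.0)

    Q = rng.dirichlet(np.ones(K), size=matrix.n_ind)
    F = rng.uniform(0.2, 0.8, size=(K, matrix.n_loci))

    alpha_eff = alpha / matrix.n_loci
    prev_loss = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        F = _batched_weighted_ridge(Q, fit_mask, P, alpha_eff)
        F = np.clip(F, 0.0, 1.0)
        Qt = _batched_weighted_ridge(F.T, fit_mask.T, P.T, 0.0).T
        Q = _project_rows_to_simplex(Qt)
        resid = fit_mask * (P - Q @ F)
        loss = float((resid**2).sum() + alpha_eff * (F**2).sum())
        if callback is not None:
            callback(Q, F, loss)
        if np.isfinite(prev_loss) and prev_loss - loss <= tol * max(prev_loss, 1.0):
            break
        prev_loss = loss

    pred = np.clip(Q @ F, _EPS, 1.0 - _EPS)
    g = G[holdout]
    p = pred[holdout]
    if g.size:
        log_comb = np.where(g == 1, np.log(2.0), 0.0)
        ce = float(-np.mean(g * np.log(p) + (2.0 - g) * np.log1p(-p) + log_comb))
    else:
        ce = np.nan
    return AncestryFit(Q=Q, F=F, alpha=alpha, cross_entropy=ce, seed=seed,
                       n_iter=n_iter, loss=loss)


@dataclass
class KSelection:
    best_K: int
    cross_entropy: pd.DataFrame  # columns: K, repetition, cross_entropy
    criterion: str = "min"


def choose_K(
    matrix: GenotypeMatrix,
    K_range=range(1, 9),
    repetitions: int = 100,
    alpha: float = 10.0,
    mask_fraction: float = 0.05,
    seed: int = 0,
    criterion: str = "min",
    max_iter: int = 200,
) -> KSelection:
    """Pick the K with the lowest held-out cross-entropy over repetitions.

    ``criterion`` is the per-K summary of the repetition distribution:
    ``"min"`` (lowest score over repetitions, the default) or ``"median"``.
    """
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range must be non-empty")
    child_seeds = np.random.SeedSequence(seed).spawn(len(K_range) * repetitions)
    rows = []
    for i, K in enumerate(K_range):
        for rep in range(repetitions):
            s = int(child_seeds[i * repetitions + rep].generate_state(1)[0] % (2**31))
            fit = fit_snmf(matrix, K, alpha=alpha, mask_fraction=mask_fraction,
                           seed=s, max_iter=max_iter)
            rows.append({"K": K, "repetition": rep, "cross_entropy": fit.cross_entropy})
    ce = pd.DataFrame(rows)
    summary = ce.groupby("K")["cross_entropy"].min() if criterion == "min" \
        else ce.groupby("K")["cross_entropy"].median()
    return KSelection(best_K=int(summary.idxmin()), cross_entropy=ce, criterion=criterion)


@dataclass
class PCAResult:
    scores: np.ndarray        # n_ind x K
    loadings: np.ndarray      # n_loci_used x K
    explained_variance: np.ndarray
    total_variance: float
    used_loci: np.ndarray     # indices of polymorphic loci entering the PCA


def pca_scores(matrix: GenotypeMatrix, K: int) -> PCAResult:
    """Top-K PCA of binomially scaled genotypes.

    Loci are centred at 2p and scaled by sqrt(2 p (1-p)); monomorphic loci
    are excluded.  Scores are U*S from the SVD of the scaled matrix, and
    explained variances are S^2 / (n - 1).
    """
    if matrix.missing_mask().any():
        raise ValueError("matrix contains missing calls; impute first")
    p = matrix.allele_freq()
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise ValueError("all loci are monomorphic; PCA undefined")
    used = np.flatnonzero(poly)
    if K > min(matrix.n_ind, used.size):
        raise ValueError("K exceeds the usable rank of the matrix")
    X = (matrix.calls[:, used] - 2.0 * p[used]) / np.sqrt(2.0 * p[used] * (1.0 - p[used]))
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U[:, :K] * S[:K]
    return PCAResult(
        scores=scores,
        loadings=Vt[:K].T,
        explained_variance=S[:K] ** 2 / (matrix.n_ind - 1),
        total_variance=float((S**2).sum() / (matrix.n_ind - 1)),
        used_loci=used,
    )
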