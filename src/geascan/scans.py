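"""Three genome scans for environment-associated loci and their consensus.

* ``rda_scan`` — redundancy analysis: a constrained ordination of centred
  genotypes on standardized environmental predictors; loci loading beyond
  ``mean ± 2.5 SD`` on a constrained axis are outliers, with overall and
  per-axis significance by permutation of the site-level predictor rows.
* ``pcadapt_scan`` — per-locus z-scores from regression on the top-K
  principal components, robust Mahalanobis distances recalibrated by the
  genomic inflation factor, chi-squared p-values.
* ``lfmm_scan`` — latent-factor ridge regression per environmental
  variable: K latent factors absorb unobserved structure, per-locus
  environmental effects are tested with GIF-calibrated z-scores and a
  Benjamini-Hochberg FDR plus raw-p conjunction rule.

Loci flagged by at least two of the three methods form the candidate set
carried into the turnover and zygosity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ancestry import pca_scores
from .containers import GenotypeMatrix

CHI2_MEDIAN_1DF = sps.chi2.ppf(0.5, 1)


@dataclass
class ScanResult:
    """Per-locus statistics, outlier calls and calibration metadata."""

    method: str
    stats: pd.DataFrame
    outliers: set[str]
    per_variable: dict[str, int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


@dataclass
class CandidateSet:
    """Per-method outlier sets plus the >= min_methods consensus."""

    per_method: dict[str, set[str]]
    consensus: set[str]
    min_methods: int


def _env_design(matrix: GenotypeMatrix, env_table: pd.DataFrame) -> pd.DataFrame:
    """Expand site-level predictors to individuals and standardize them."""
    sites = matrix.ind_meta["site"]
    missing_sites = set(sites) - set(env_table.index)
    if missing_sites:
        raise KeyError(f"no environmental values for sites: {sorted(missing_sites)}")
    X = env_table.loc[sites].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    return pd.DataFrame(X, index=sites.index, columns=env_table.columns)


def _require_imputed(matrix: GenotypeMatrix) -> None:
    if matrix.missing_mask().any():
        raise ValueError("matrix contains missing calls; run imputation first")


# ---------------------------------------------------------------------------
# Redundancy analysis
# ---------------------------------------------------------------------------

def _rda_decompose(Y: np.ndarray, X: np.ndarray):
    """Fitted values of Y on X (with intercept via centring) and their SVD."""
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    Yhat = X @ B
    U, S, Vt = np.linalg.svd(Yhat, full_matrices=False)
    rank = min(np.linalg.matrix_rank(X), X.shape[1])
    return Yhat, U[:, :rank], S[:rank], Vt[:rank]


def rda_scan(
    matrix: GenotypeMatrix,
    env_table: pd.DataFrame,
    sd_cutoff: float = 2.5,
    n_permutations: int = 999,
    seed: int = 0,
    pool_axes: bool = False,
) -> ScanResult:
    """Constrained-ordination loading outliers with permutation tests.

    Outliers are loci whose loading on any constrained axis (or on the
    pooled loadings with ``pool_axes=True``) lies beyond ``mean ±
    sd_cutoff * SD`` of that axis's loadings.  Model and per-axis
    significance come from permuting the rows of the site-level
    environment table.
    """
    _require_imputed(matrix)
    env_std = _env_design(matrix, env_table)
    n, p = env_std.shape
    if p >= len(env_table):
        raise ValueError("more predictors than sites; prune predictors first")
    Y = matrix.calls.astype(float)
    Y = Y - Y.mean(axis=0)
    X = env_std.to_numpy()

    Yhat, U, S, Vt = _rda_decompose(Y, X)
    loadings = Vt.T  # n_loci x n_axes
    n_axes = loadings.shape[1]

    if pool_axes:
        pooled = loadings.ravel()
        z = (loadings - pooled.mean()) / pooled.std()
    else:
        z = (loadings - loadings.mean(axis=0)) / loadings.std(axis=0)
    outlier_mask = (np.abs(z) > sd_cutoff).any(axis=1)
    max_abs_z = np.abs(z).max(axis=1)
    pvals = 2.0 * sps.norm.sf(max_abs_z)

    # permutation tests: permute site rows of the env table, re-expand
    ss_total = (Y**2).sum()
    ss_constrained = (S**2).sum()
    dfr = n - p - 1
    f_obs = (ss_constrained / p) / ((ss_total - ss_constrained) / dfr)
    eig_obs = S**2
    rng = np.random.default_rng(seed)
    sites = matrix.ind_meta["site"]
    site_order = list(env_table.index)
    hits_f = 0
    hits_axis = np.zeros(n_axes)
    for _ in range(n_permutations):
        perm = rng.permutation(len(site_order))
        # permute which environment row each site receives, then re-expand
        Xp = env_table.iloc[perm].set_axis(site_order, axis=0).loc[sites].to_numpy(dtype=float)
        Xp = (Xp - Xp.mean(axis=0)) / Xp.std(axis=0)
        Bp, *_ = np.linalg.lstsq(Xp, Y, rcond=None)
        ssc = ((Xp @ Bp) ** 2).sum()
        fp = (ssc / p) / ((ss_total - ssc) / dfr)
        hits_f += fp >= f_obs
        Sp = np.linalg.svd(Xp @ Bp, compute_uv=False)[:n_axes]
        hits_axis += Sp**2 >= eig_obs
    p_model = (1 + hits_f) / (1 + n_permutations)
    p_axes = (1 + hits_axis) / (1 + n_permutations)

    locus_ids = matrix.locus_meta.index
    stats = pd.DataFrame(
        {"statistic": max_abs_z, "pvalue": pvals, "outlier": outlier_mask},
        index=locus_ids,
    )
    outliers = set(locus_ids[outlier_mask])
    per_variable = _attribute_to_variables(matrix, env_std, outliers)
    return ScanResult(
        method="rda",
        stats=stats,
        outliers=outliers,
        per_variable=per_variable,
        metadata={
            "sd_cutoff": sd_cutoff,
            "n_axes": int(n_axes),
            "model_p": float(p_model),
            "axis_p": p_axes.tolist(),
            "pseudo_F": float(f_obs),
            "loadings": loadings,
            "pool_axes": pool_axes,
        },
    )


def _attribute_to_variables(
    matrix: GenotypeMatrix, env_std: pd.DataFrame, outliers: set[str]
) -> dict[str, int]:
    """Assign each outlier locus to its most-correlated predictor."""
    counts = {v: 0 for v in env_std.columns}
    if not outliers:
        return counts
    idx = matrix.locus_meta.index.get_indexer(sorted(outliers))
    G = matrix.calls[:, idx].astype(float)
    G = G - G.mean(axis=0)
    X = env_std.to_numpy()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((G**2).sum(axis=0)[None, :] * (Xc**2).sum(axis=0)[:, None])
    with np.errstate(invalid="ignore", divide="ignore"):
        cors = np.abs(Xc.T @ G / denom)  # p x n_outliers
    best = np.nanargmax(cors, axis=0)
    for b in best:
        counts[env_std.columns[b]] += 1
    return counts


# ---------------------------------------------------------------------------
# PCA-based outlier scan
# ---------------------------------------------------------------------------

def pcadapt_scan(
    matrix: GenotypeMatrix,
    K: int = 5,
    alpha: float = 0.1,
    mode: str = "qvalue",
) -> ScanResult:
    """Structure-based outlier scan via robust Mahalanobis distances.

    Each scaled locus is regressed on the top-K PC score vectors; the
    K-vectors of regression z-scores get a robust Mahalanobis distance
    (minimum covariance determinant estimate), recalibrated by the genomic
    inflation factor, and chi-squared(K) p-values.  ``mode="qvalue"``
    declares outliers at BH q < alpha (default 0.1); ``mode="bonferroni"``
    at Bonferroni-adjusted p < alpha.
    """
    from sklearn.covariance import MinCovDet
    from statsmodels.stats.multitest import multipletests

    _require_imputed(matrix)
    if mode not in ("qvalue", "bonferroni"):
        raise ValueError("mode must be 'qvalue' or 'bonferroni'")
    pca = pca_scores(matrix, K)
    n = matrix.n_ind
    used = pca.used_loci
    p_freq = matrix.allele_freq()[used]
    Xs = (matrix.calls[:, used] - 2.0 * p_freq) / np.sqrt(2.0 * p_freq * (1.0 - p_freq))

    # scores = U S, so regression coefficients are V and residuals come
    # from the rank-K reconstruction
    T = pca.scores
    TtT = (T**2).sum(axis=0)  # diagonal because scores are orthogonal
    V = pca.loadings  # n_loci_used x K
    resid = Xs - T @ V.T
    dof = max(n - K - 1, 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    z = V * np.sqrt(TtT)[None, :] / np.sqrt(sigma2)[:, None]

    mcd = MinCovDet(random_state=0).fit(z)
    d2 = mcd.mahalanobis(z)
    gif = float(np.median(d2) / sps.chi2.ppf(0.5, K))
    pvals = sps.chi2.sf(d2 / gif, K)

    if mode == "qvalue":
        reject, padj, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    else:
        reject, padj, *_ = multipletests(pvals, alpha=alpha, method="bonferroni")

    locus_ids = matrix.locus_meta.index[used]
    stats = pd.DataFrame(
        {"statistic": d2, "pvalue": pvals, "padj": padj, "outlier": reject},
        index=locus_ids,
    )
    # monomorphic loci were untestable; record them as non-outliers
    stats = stats.reindex(matrix.locus_meta.index)
    stats["outlier"] = stats["outlier"].notna() & stats["outlier"].eq(True)
    outliers = set(locus_ids[reject])
    return ScanResult(
        method="pcadapt",
        stats=stats,
        outliers=outliers,
        metadata={"K": K, "gif": gif, "mode": mode, "alpha": alpha},
    )


# ---------------------------------------------------------------------------
# Latent-factor mixed model (ridge)
# ---------------------------------------------------------------------------

def lfmm_scan(
    matrix: GenotypeMatrix,
    env_table: pd.DataFrame,
    K: int = 8,
    fdr: float = 0.05,
    p_threshold: float = 0.001,
    ridge_scale: float = 1e-4,
    use_fdr: bool = True,
    use_p_threshold: bool = True,
) -> ScanResult:
    """Latent-factor ridge scan, one outlier set per environmental variable.

    For each predictor: latent factors are the top-K left singular vectors
    of the genotype matrix after regressing out the predictor; per-locus
    effects come from least squares of genotypes on [1, env, factors] with
    a ridge penalty (``ridge_scale`` x mean diagonal of the design Gram
    matrix) on the factor loadings; z-scores are calibrated by the genomic
    inflation factor; outliers satisfy BH-adjusted p < ``fdr`` AND raw
    p < ``p_threshold`` (each part switchable).  With ``K=0`` the effect
    reduces to the ordinary least-squares slope.
    """
    from statsmodels.stats.multitest import multipletests

    _require_imputed(matrix)
    env_std = _env_design(matrix, env_table)
    G = matrix.calls.astype(float)
    Gc = G - G.mean(axis=0)
    n = matrix.n_ind
    locus_ids = matrix.locus_meta.index

    rows = []
    per_variable: dict[str, int] = {}
    outliers: set[str] = set()
    gifs: dict[str, float] = {}
    for var in env_std.columns:
        x = env_std[var].to_numpy()
        if K > 0:
            coef = (x @ Gc) / (x @ x)
            resid = Gc - np.outer(x, coef)
            U, _, _ = np.linalg.svd(resid, full_matrices=False)
            factors = U[:, :K]
            D = np.column_stack([np.ones(n), x, factors])
        else:
            D = np.column_stack([np.ones(n), x])
        q = D.shape[1]
        DtD = D.T @ D
        penalty = np.zeros(q)
        if K > 0:
            lam = ridge_scale * np.trace(DtD) / q
            penalty[2:] = lam
        A = DtD + np.diag(penalty)
        Ainv = np.linalg.inv(A)
        B = Ainv @ (D.T @ G)  # q x n_loci
        resid = G - D @ B
        dof = max(n - q, 1)
        sigma2 = (resid**2).sum(axis=0) / dof
        M = Ainv @ DtD @ Ainv
        se = np.sqrt(sigma2 * M[1, 1])
        beta = B[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            z = beta / se
        gif = float(np.median(z**2) / CHI2_MEDIAN_1DF)
        pvals = sps.chi2.sf(z**2 / gif, 1)
        reject_fdr, padj, *_ = multipletests(pvals, alpha=fdr, method="fdr_bh")
        flag = np.ones(len(pvals), dtype=bool)
        if use_fdr:
            flag &= reject_fdr
        if use_p_threshold:
            flag &= pvals < p_threshold
        per_variable[var] = int(flag.sum())
        outliers |= set(locus_ids[flag])
        gifs[var] = gif
        rows.append(
            pd.DataFrame(
                {
                    "variable": var,
                    "locus": locus_ids,
                    "beta": beta,
                    "statistic": z,
                    "pvalue": pvals,
                    "padj": padj,
                    "outlier": flag,
                }
            )
        )
    stats = pd.concat(rows, ignore_index=True)
    return ScanResult(
        method="lfmm",
        stats=stats,
        outliers=outliers,
        per_variable=per_variable,
        metadata={
            "K": K,
            "fdr": fdr,
            "p_threshold": p_threshold,
            "ridge_scale": ridge_scale,
            "gif": gifs,
        },
    )


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

def consensus(results: list[ScanResult], min_methods: int = 2) -> CandidateSet:
    """Loci flagged by at least ``min_methods`` of the supplied scans.

    A locus counts once per method regardless of how many environmental
    variables flagged it within that method.
    """
    if len(results) < 2:
        raise ValueError("need at least two scan results")
    per_method = {r.method: set(r.outliers) for r in results}
    counts: dict[str, int] = {}
    for s in per_method.values():
        for locus in s:
            counts[locus] = counts.get(locus, 0) + 1
    cons = {locus for locus, c in counts.items() if c >= min_methods}
    return CandidateSet(per_method=per_method, consensus=cons, min_methods=min_methods)


def outlier_count_grid(results: list[ScanResult]) -> pd.DataFrame:
    """Methods x environmental-variables grid of outlier counts."""
    rows = {r.method: r.per_variable for r in results if r.per_variable}
    return pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
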