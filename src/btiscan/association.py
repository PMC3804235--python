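"""Structured association mapping between SNP genotypes and a resistance
phenotype.

Population structure is summarized by the leading principal components of the
SNP correlation matrix (missing genotypes mean-imputed for the PCA only).
Each marker is then tested in a least-squares fixed-effects model

    phenotype ~ intercept + PC1..PCk + genotype (additive dosage)

with the marker's contribution measured as the partial R^2
(RSS_reduced - RSS_full) / TSS and tested by the partial F test; individuals
missing a genotype are dropped for that marker only.  Family-wise multiple
testing is corrected by min-p permutation: the phenotype vector is permuted
across individuals (covariates stay attached to their individuals), every
marker is refitted, and the minimum raw p per permutation forms the reference
distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix

__all__ = [
    "AssociationResult",
    "pca_covariates",
    "marker_model",
    "permutation_adjust",
]


@dataclass
class AssociationResult:
    snp_names: list
    r2: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    effect_sign: np.ndarray
    alpha: float
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.snp_names,
                "r2": self.r2,
                "p_raw": self.p_raw,
                "p_adjusted": self.p_adjusted,
                "effect_sign": self.effect_sign,
                "significant": self.p_adjusted <= self.alpha,
            }
        )


def _imputed_standardized(gm: GenotypeMatrix):
    """Mean-impute missing dosages and z-score columns; drop monomorphic SNPs."""
    G = gm.genotypes.copy()
    col_mean = np.nanmean(G, axis=0)
    nan_rows, nan_cols = np.nonzero(np.isnan(G))
    G[nan_rows, nan_cols] = col_mean[nan_cols]
    sd = G.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all SNPs are monomorphic; cannot estimate structure")
    Z = (G[:, keep] - G[:, keep].mean(axis=0)) / sd[keep]
    return Z, keep


def pca_covariates(gm: GenotypeMatrix, k: int = 3) -> np.ndarray:
    """Scores of the top-k principal components of the SNP correlation matrix.

    Standardizing each SNP column makes the feature covariance the SNP
    correlation matrix, so the SVD of the standardized matrix yields its
    eigenvectors.  Sign convention: each component's largest-magnitude
    loading is made positive, so scores are reproducible.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = gm.n_individuals
    k = min(k, n - 1)  # cannot exceed n-1 informative axes
    if n < k + 1:
        raise ValueError(f"need at least k+1={k+1} individuals, have {n}")
    Z, _ = _imputed_standardized(gm)
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    V = vt[:k].T
    for j in range(k):
        lead = np.argmax(np.abs(V[:, j]))
        if V[lead, j] < 0:
            V[:, j] = -V[:, j]
    return Z @ V


def _partial_f(y: np.ndarray, covariates: np.ndarray, g: np.ndarray):
    """Partial F test of the marker given intercept + covariates.

    Returns (r2, p, sign of the marker coefficient).
    """
    n = y.size
    X_red = np.column_stack([np.ones(n), covariates])
    X_full = np.column_stack([X_red, g])
    p_full = X_full.shape[1]
    if n <= p_full:
        raise ValueError("not enough individuals for the full model")
    beta_red, _, rank_red, _ = np.linalg.lstsq(X_red, y, rcond=None)
    beta_full, _, rank_full, _ = np.linalg.lstsq(X_full, y, rcond=None)
    if rank_full <= rank_red:  # marker collinear with covariates
        warnings.warn("marker collinear with covariates; p set to 1", stacklevel=2)
        return 0.0, 1.0, 0.0
    rss_red = float(np.sum((y - X_red @ beta_red) ** 2))
    rss_full = float(np.sum((y - X_full @ beta_full) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0.0:
        return 0.0, 1.0, 0.0
    r2 = max(0.0, (rss_red - rss_full) / tss)
    df2 = n - p_full
    if rss_full <= 0.0:
        return r2, 0.0, float(np.sign(beta_full[-1]))
    f = (rss_red - rss_full) / (rss_full / df2)
    p = float(stats.f.sf(f, 1, df2))
    return r2, p, float(np.sign(beta_full[-1]))


def marker_model(gm: GenotypeMatrix, covariates: np.ndarray, snp_index: int):
    """Fit one marker; returns (r2, p, effect_sign).

    Individuals missing this genotype are dropped; the SNP must remain
    polymorphic among the rest.
    """
    g = gm.genotypes[:, snp_index]
    keep = ~np.isnan(g)
    g = g[keep]
    if np.unique(g).size < 2:
        raise ValueError(
            f"SNP {gm.snp_names[snp_index]!r} monomorphic among non-missing "
            "individuals"
        )
    y = gm.phenotypes[keep]
    C = np.asarray(covariates)[keep]
    return _partial_f(y, C, g)


def _null_min_p(gm: GenotypeMatrix, covariates: np.ndarray,
                poly: np.ndarray, B: int, rng: np.random.Generator) -> np.ndarray:
    """Minimum raw p across markers for each of B phenotype permutations.

    Uses the Frisch–Waugh reduction: per marker, the partial F depends only
    on the correlation between the covariate-residualized genotype and the
    covariate-residualized (permuted) phenotype, so all B permutations are
    handled with one matrix product per marker.
    """
    n = gm.n_individuals
    perms = np.stack([rng.permutation(gm.phenotypes) for _ in range(B)], axis=1)
    min_p = np.full(B, 1.0)
    C_all = np.asarray(covariates)
    for j in np.nonzero(poly)[0]:
        g = gm.genotypes[:, j]
        keep = ~np.isnan(g)
        gk = g[keep]
        if np.unique(gk).size < 2:
            continue
        Xr = np.column_stack([np.ones(keep.sum()), C_all[keep]])
        Q, _ = np.linalg.qr(Xr)
        g_res = gk - Q @ (Q.T @ gk)
        g_norm = np.linalg.norm(g_res)
        if g_norm == 0.0:
            continue
        Y = perms[keep]
        Y_res = Y - Q @ (Q.T @ Y)
        y_norm = np.linalg.norm(Y_res, axis=0)
        y_norm[y_norm == 0.0] = np.inf
        r = (g_res @ Y_res) / (g_norm * y_norm)
        df2 = keep.sum() - Xr.shape[1] - 1
        r2 = np.clip(r**2, 0.0, 1.0 - 1e-15)
        f = r2 * df2 / (1.0 - r2)
        p = stats.f.sf(f, 1, df2)
        min_p = np.minimum(min_p, p)
    return min_p


def permutation_adjust(
    gm: GenotypeMatrix,
    covariates: Optional[np.ndarray] = None,
    B: int = 1000,
    alpha: float = 0.05,
    k: int = 3,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> AssociationResult:
    """Per-marker association with min-p permutation adjustment.

    Adjusted p for marker j = (#{permutations with min-p <= raw p_j} + 1)/(B+1),
    a family-wise (max-T style) correction; markers with adjusted p <= alpha
    are flagged.  Monomorphic or collinear markers get raw p 1.
    """
    if B < 100:
        raise ValueError("need at least 100 permutations")
    if rng is None:
        rng = np.random.default_rng(seed)
    if covariates is None:
        covariates = pca_covariates(gm, k=k)

    m = gm.n_snps
    r2 = np.zeros(m)
    p_raw = np.ones(m)
    sign = np.zeros(m)
    poly = np.zeros(m, dtype=bool)
    for j in range(m):
        g = gm.genotypes[:, j]
        gk = g[~np.isnan(g)]
        if np.unique(gk).size < 2:
            continue
        poly[j] = True
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r2[j], p_raw[j], sign[j] = marker_model(gm, covariates, j)

    min_p = _null_min_p(gm, covariates, poly, B, rng)
    p_adj = np.array(
        [(np.sum(min_p <= p) + 1) / (B + 1) for p in p_raw]
    )
    return AssociationResult(
        snp_names=list(gm.snp_names),
        r2=r2,
        p_raw=p_raw,
        p_adjusted=p_adj,
        effect_sign=sign,
        alpha=alpha,
        n_permutations=B,
    )
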