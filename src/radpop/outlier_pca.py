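"""PCA-based outlier scan with genomic inflation correction.

Each SNP's (scaled) genotype column is regressed on the top K principal
component score vectors; the K standardized regression coefficients form a
z-vector whose Mahalanobis distance, rescaled by the genomic inflation
factor lambda = median(D^2) / median(chi^2_K), is referred to a chi-square
distribution with K degrees of freedom.  Loci strongly associated with
population structure stand out against this genome-wide background and are
declared outliers after Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .core import GenotypeMatrix

__all__ = [
    "PcaScanResult",
    "PCAOutlierScan",
    "scale_genotypes",
    "pca_scan",
    "bonferroni_decide",
]


def scale_genotypes(
    gm_or_array, unit_variance: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Center (and optionally scale) a dosage matrix for PCA.

    Entries become (g - 2 p_hat) / sqrt(2 p_hat (1 - p_hat)) with p_hat the
    pooled ALT frequency; missing entries are imputed at the column mean
    (0 after centering).  Monomorphic columns are dropped with a warning.

    Returns ``(X, kept_columns, p_hat_kept)``.
    """
    if isinstance(gm_or_array, GenotypeMatrix):
        G = gm_or_array.dosages()
    else:
        G = np.asarray(gm_or_array, dtype=float)
    present = np.isfinite(G)
    n = present.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, np.where(present, G, 0.0).sum(axis=0) / (2 * n), np.nan)
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    if (~keep).any():
        warnings.warn(f"dropping {int((~keep).sum())} monomorphic/all-missing loci")
    Gk = G[:, keep]
    pk = p[keep]
    X = Gk - 2 * pk
    if unit_variance:
        X = X / np.sqrt(2 * pk * (1 - pk))
    X[~np.isfinite(X)] = 0.0
    X[~present[:, keep]] = 0.0
    return X, np.flatnonzero(keep), pk


@dataclass
class PcaScanResult:
    """Per-locus scan output aligned with the *input* locus order.

    Loci dropped before the scan (monomorphic) or excluded from the test
    (zero residual variance) carry NaN p-values and False flags.
    """

    K: int
    zscores: np.ndarray  # (n_loci_in, K)
    dsq: np.ndarray
    gif: float
    pvalues: np.ndarray
    outlier_flags: np.ndarray
    bonferroni_alpha: float
    scree: np.ndarray
    tested: np.ndarray
    locus_ids: list[str] = field(default_factory=list)


class PCAOutlierScan(BaseEstimator):
    """Scan a dosage matrix for loci excessively associated with structure.

    Parameters
    ----------
    n_components : int
        Number of principal components K retained (chosen from the scree).
    alpha : float
        Family-wise error target; the per-locus cutoff is alpha / n_tested.
    robust_cov : bool
        Estimate the z-vector covariance robustly (coordinate medians and
        MAD-scaled, shrunk toward the sample covariance).  The default is
        the plain sample covariance; results can therefore diverge from
        tools using a fully robust estimator.

    Attributes (after ``fit(X)`` with X of shape (n_samples, n_loci))
    ----------
    zscores_, dsq_, pvalues_, outlier_flags_ : per-locus arrays
    gif_ : float — genomic inflation factor lambda
    singular_values_ : scree data
    tested_ : boolean mask of loci entering the chi-square test
    """

    def __init__(
        self,
        n_components: int = 2,
        alpha: float = 0.001,
        robust_cov: bool = False,
    ):
        self.n_components = n_components
        self.alpha = alpha
        self.robust_cov = robust_cov

    def fit(self, X, y=None):
        G = np.asarray(X, dtype=float)
        n, L = G.shape
        K = self.n_components
        if not 1 <= K < min(n, L):
            raise ValueError(f"need 1 <= K < min(n_samples, n_loci); K={K}")

        Xs, kept, _ = scale_genotypes(G)
        u, s, _ = np.linalg.svd(Xs, full_matrices=False)
        U = u[:, :K]  # orthonormal score directions

        B = U.T @ Xs  # (K, L_kept) least-squares coefficients
        resid = Xs - U @ B
        rss = (resid**2).sum(axis=0)
        dof = n - K
        sigma = np.sqrt(rss / dof)
        nonzero = sigma > 1e-12 * max(1.0, float(np.abs(Xs).max()))
        z = np.full_like(B, np.nan)
        z[:, nonzero] = B[:, nonzero] / sigma[nonzero]

        zt = z[:, nonzero].T  # (L_tested, K)
        cov = self._covariance(zt)
        center = np.median(zt, axis=0) if self.robust_cov else zt.mean(axis=0)
        delta = zt - center
        dsq_t = np.einsum("ij,jk,ik->i", delta, np.linalg.inv(cov), delta)

        gif = float(np.median(dsq_t) / stats.chi2.median(df=K))
        pv_t = stats.chi2.sf(dsq_t / gif, df=K)
        pv_t = np.maximum(pv_t, np.finfo(float).tiny)

        # re-expand to the input locus universe
        self.zscores_ = np.full((L, K), np.nan)
        self.dsq_ = np.full(L, np.nan)
        self.pvalues_ = np.full(L, np.nan)
        tested = np.zeros(L, dtype=bool)
        tested[kept[nonzero]] = True
        self.zscores_[kept] = z.T
        self.dsq_[tested] = dsq_t
        self.pvalues_[tested] = pv_t
        self.gif_ = gif
        self.singular_values_ = s
        self.tested_ = tested
        self.n_tested_ = int(tested.sum())
        self.outlier_flags_ = bonferroni_decide(
            self.pvalues_, self.alpha, n_tests=self.n_tested_
        )
        return self

    def _covariance(self, zt: np.ndarray) -> np.ndarray:
        cov = np.cov(zt, rowvar=False)
        cov = np.atleast_2d(cov)
        if self.robust_cov:
            mad = stats.median_abs_deviation(zt, axis=0, scale="normal")
            robust = np.diag(mad**2)
            cov = 0.5 * robust + 0.5 * cov  # shrinkage blend
        return cov

    def predict(self, X=None):
        """Outlier flags from the fitted scan (X ignored; scan is transductive)."""
        return self.outlier_flags_


def bonferroni_decide(
    pvalues: np.ndarray, alpha: float, n_tests: int | None = None
) -> np.ndarray:
    """Flag loci with p <= alpha / n (inclusive); NaN p-values never flag."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(pvalues, dtype=float)
    n = n_tests if n_tests is not None else int(np.isfinite(p).sum())
    if n == 0:
        return np.zeros_like(p, dtype=bool)
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(p), p <= alpha / n, False)


def pca_scan(
    gm: GenotypeMatrix, K: int = 2, alpha: float = 0.001, robust_cov: bool = False
) -> PcaScanResult:
    """Run the PCA outlier scan on a genotype matrix."""
    model = PCAOutlierScan(n_components=K, alpha=alpha, robust_cov=robust_cov)
    model.fit(gm.dosages())
    return PcaScanResult(
        K=K,
        zscores=model.zscores_,
        dsq=model.dsq_,
        gif=model.gif_,
        pvalues=model.pvalues_,
        outlier_flags=model.outlier_flags_,
        bonferroni_alpha=alpha,
        scree=model.singular_values_,
        tested=model.tested_,
        locus_ids=gm.locus_ids,
    )
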