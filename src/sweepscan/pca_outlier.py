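"""PCA-based outlier detection (pcadapt-style Mahalanobis scan).

Each SNP's standardized genotype vector is regressed on K principal-component
score vectors; the resulting length-K z-score vector is summarized by its
Mahalanobis distance D^2 from the bulk of SNPs, and an upper-tail chi-square
probability is attached.  K is chosen from the scree profile by an
operationalized Cattell rule ("last point before the curve flattens").

Note on degrees of freedom: df defaults to K, but is an explicit parameter
because published chi-square calibrations sometimes reflect fewer effective
dimensions than the number of retained components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_qc import MISSING, GenotypeDataset
from .structure import PcaResult


@dataclass
class OutlierScan:
    """Per-SNP Mahalanobis outlier scan result."""

    table: pd.DataFrame        # snp_id, chrom, pos, D2, p
    K: int
    df: int
    zbar: np.ndarray
    sigma: np.ndarray
    cov_method: str = "sample"
    inflation_lambda: float | None = None


def snp_zscores(d: GenotypeDataset, pca: PcaResult, K: int) -> np.ndarray:
    """Regress each standardized SNP on K PC score vectors; z = beta / se.

    The regression is ordinary least squares of the standardized genotype
    column (mean-imputed missing values) on the centered score matrix, with
    residual degrees of freedom n - K.  Returns an (m, K) array (NaN rows for
    monomorphic SNPs).
    """
    if K > pca.scores.shape[1]:
        raise ValueError(f"K={K} exceeds available components {pca.scores.shape[1]}")
    S = pca.scores.to_numpy()[:, :K]
    S = S - S.mean(axis=0, keepdims=True)
    n = S.shape[0]
    if n <= K:
        raise ValueError("need more samples than components for z-scores")
    StS = S.T @ S
    if np.linalg.matrix_rank(StS) < K:
        raise np.linalg.LinAlgError("collinear component scores")
    StS_inv = np.linalg.inv(StS)

    calls = d.calls
    obs = calls != MISSING
    n_obs = obs.sum(axis=0)
    p_hat = np.where(obs, calls, 0).sum(axis=0) / (2.0 * np.maximum(n_obs, 1))
    scale = np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    poly = (p_hat > 0) & (p_hat < 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        X = (calls.astype(float) - 2.0 * p_hat[None, :]) / scale[None, :]
    X[~obs] = 0.0
    X = X - X.mean(axis=0, keepdims=True)

    beta = StS_inv @ (S.T @ X)            # (K, m)
    resid = X - S @ beta
    dof = n - K
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(StS_inv), sigma2))  # (K, m)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, beta / se, 0.0).T        # (m, K)
    z[~poly] = np.nan
    return z


def mahalanobis_d2(z: np.ndarray, cov_method: str = "sample"
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mahalanobis distance of each z-score vector from the SNP bulk.

    D2_j = (z_j - zbar)^T Sigma^-1 (z_j - zbar).  ``cov_method='sample'``
    uses the sample mean/covariance over all (finite) SNPs;
    ``'robust'`` uses the coordinate-wise median and a MAD-scaled covariance
    (correlations from the sample estimate, scales from 1.4826*MAD).
    Returns (D2 with NaN rows propagated, zbar, Sigma).
    """
    z = np.asarray(z, dtype=float)
    finite = np.isfinite(z).all(axis=1)
    zf = z[finite]
    K = z.shape[1]
    if zf.shape[0] <= K:
        raise ValueError("need more than K SNPs to estimate the z covariance")
    if cov_method == "sample":
        zbar = zf.mean(axis=0)
        sigma = np.cov(zf, rowvar=False)
    elif cov_method == "robust":
        zbar = np.median(zf, axis=0)
        mad = 1.4826 * np.median(np.abs(zf - zbar), axis=0)
        corr = np.corrcoef(zf, rowvar=False)
        sigma = corr * np.outer(mad, mad)
    else:
        raise ValueError(f"unknown cov_method {cov_method!r}")
    sigma = np.atleast_2d(sigma)
    try:
        sigma_inv = np.linalg.inv(sigma)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular z-score covariance; reduce K") from exc
    diff = z - zbar
    d2 = np.einsum("jk,kl,jl->j", diff, sigma_inv, diff)
    d2 = np.where(finite, d2, np.nan)
    return d2, zbar, sigma


def outlier_pvalues(d2: np.ndarray, df: int) -> np.ndarray:
    """Upper-tail chi-square probability; for df=2 this is exp(-D2/2)."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return stats.chi2.sf(d2, df)


def cattell_rule(variance_proportions, flatness_ratio: float = 0.1) -> int:
    """Operationalized scree-plot elbow: K is the component after the last
    drop whose size, relative to the full scree range v_1 - v_last, exceeds
    ``flatness_ratio``; K=1 when no drop qualifies (flat profile)."""
    v = np.asarray(variance_proportions, dtype=float)
    if len(v) < 2:
        raise ValueError("need >= 2 variance proportions")
    if np.any(np.diff(v) > 1e-12):
        raise ValueError("variance proportions must be non-increasing")
    rng = v[0] - v[-1]
    if rng <= 0:
        warnings.warn("constant variance proportions; returning K=1")
        return 1
    drops = -np.diff(v) / rng
    qualifying = np.flatnonzero(drops > flatness_ratio)
    if len(qualifying) == 0:
        return 1
    return int(qualifying[-1] + 2)  # drop j is between components j+1, j+2 (1-based)


def pcadapt_scan(d: GenotypeDataset, pca: PcaResult, K: int | None = None,
                 df: int | None = None, cov_method: str = "sample",
                 genomic_inflation: bool = False) -> OutlierScan:
    """Full outlier scan: z-scores -> Mahalanobis D2 -> chi-square p.

    K defaults to the Cattell-rule choice on ``pca.variance_ratio``; df
    defaults to K.  ``genomic_inflation`` optionally rescales D2 by the
    genomic inflation factor lambda = median(D2)/chi2_median(df).
    """
    if K is None:
        K = cattell_rule(pca.variance_ratio)
    if df is None:
        df = K
    z = snp_zscores(d, pca, K)
    d2, zbar, sigma = mahalanobis_d2(z, cov_method=cov_method)
    lam = None
    if genomic_inflation:
        lam = float(np.nanmedian(d2) / stats.chi2.ppf(0.5, df))
        d2 = d2 / lam
    p = outlier_pvalues(d2, df)
    table = pd.DataFrame({
        "snp_id": d.markers["snp_id"],
        "chrom": d.markers["chrom"],
        "pos": d.markers["pos"],
        "D2": d2, "df": df, "p": p,
    })
    return OutlierScan(table=table, K=K, df=df, zbar=zbar, sigma=sigma,
                       cov_method=cov_method, inflation_lambda=lam)
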