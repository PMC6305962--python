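"""Kinship, unrelated-subset selection, genotype PCA and supervised admixture.

Kinship uses the KING-robust within-family estimator, which stays unbiased
under population structure; "unrelated" defaults to the 3rd-degree cutoff
0.0884.  PCA standardizes genotypes by sqrt(2p(1-p)), fits the SVD on an
unrelated subset and projects relatives onto its loadings — a desk-scale
stand-in for PC-AiR's partition-and-project scheme.  Global ancestry
proportions are estimated per individual by supervised maximum likelihood
against fixed source-panel allele frequencies (EM on the simplex), the
supervised analogue of an ADMIXTURE Q matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_qc import MISSING, GenotypeDataset

KING_UNRELATED_THRESHOLD = 0.0884  # 3rd-degree relationship cutoff


def king_kinship(d: GenotypeDataset) -> pd.DataFrame:
    """KING-robust kinship for all sample pairs.

    phi_hat(i,j) = (N_het,het - 2 N_opp_hom) / (N_het,i + N_het,j) over
    jointly non-missing SNPs, where N_het,i counts SNPs heterozygous in i
    within the joint set.  Returns a sample x sample DataFrame; the diagonal
    is 0.5 by convention; pairs with zero denominator are NaN.
    """
    if d.n_samples < 2:
        raise ValueError("kinship needs >= 2 samples")
    calls = d.calls
    n, m = calls.shape
    het = (calls == 1).astype(np.float64)
    hom0 = (calls == 0).astype(np.float64)
    hom2 = (calls == 2).astype(np.float64)
    obs = (calls != MISSING).astype(np.float64)
    # pairwise counts via matrix products
    n_hethet = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    n_het_i = het @ obs.T          # het in i among jointly observed
    denom = n_het_i + n_het_i.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_hethet - 2.0 * n_opp) / denom, np.nan)
    np.fill_diagonal(phi, 0.5)
    ids = d.samples["sample_id"].tolist()
    return pd.DataFrame(phi, index=ids, columns=ids)


def select_unrelated(kinship: pd.DataFrame,
                     threshold: float = KING_UNRELATED_THRESHOLD) -> list[str]:
    """Greedy unrelated-subset selection.

    Repeatedly removes the sample with the most kinship ties >= ``threshold``
    (ties broken by removing the later sample id in the matrix order) until no
    related pair remains.  Deterministic.
    """
    ids = list(kinship.index)
    k = kinship.to_numpy(copy=True)
    np.fill_diagonal(k, 0.0)
    related = np.nan_to_num(k, nan=-np.inf) >= threshold
    active = np.ones(len(ids), dtype=bool)
    while True:
        degree = (related & active[None, :] & active[:, None]).sum(axis=1)
        degree[~active] = 0
        if degree.max() == 0:
            break
        worst = np.flatnonzero(degree == degree.max())[-1]  # later id on ties
        active[worst] = False
    return [ids[i] for i in np.flatnonzero(active)]


@dataclass
class PcaResult:
    """Genotype PCA scores with per-component variance proportions."""

    scores: pd.DataFrame            # samples x PCs, indexed by sample_id
    variance_ratio: np.ndarray      # proportion of total variance, non-increasing
    loadings: np.ndarray            # SNPs x PCs (standardized-genotype space)
    snp_means: np.ndarray           # 2*p_hat used for centering
    snp_scales: np.ndarray          # sqrt(2 p (1-p)) used for scaling
    fitted_on: list[str] | None = None  # sample ids used to fit (None = all)


def _standardize_calls(calls: np.ndarray, means: np.ndarray,
                       scales: np.ndarray) -> np.ndarray:
    x = (calls.astype(float) - means[None, :]) / scales[None, :]
    x[calls == MISSING] = 0.0  # mean imputation post-centering
    return x


def pca_genotypes(d: GenotypeDataset, n_components: int = 10,
                  unrelated_only: bool = True,
                  kinship: pd.DataFrame | None = None,
                  kinship_threshold: float = KING_UNRELATED_THRESHOLD) -> PcaResult:
    """PCA of standardized genotypes, optionally fit on an unrelated subset.

    Genotypes are centered by 2*p_hat and scaled by sqrt(2 p_hat (1-p_hat))
    (p_hat from the fitting subset); missing calls are mean-imputed after
    centering.  When ``unrelated_only`` and a kinship matrix is available,
    the SVD is fit on the unrelated subset and relatives are projected onto
    its loadings.  Variance proportions are relative to the total variance of
    the standardized fitting matrix.
    """
    ids = d.samples["sample_id"].tolist()
    if unrelated_only:
        if kinship is None:
            kinship = king_kinship(d)
        fit_ids = select_unrelated(kinship, kinship_threshold)
    else:
        fit_ids = ids
    fit_idx = [ids.index(s) for s in fit_ids]
    fit_calls = d.calls[fit_idx]

    obs = fit_calls != MISSING
    n_obs = obs.sum(axis=0)
    p_hat = np.where(obs, fit_calls, 0).sum(axis=0) / (2.0 * np.maximum(n_obs, 1))
    poly = (p_hat > 0) & (p_hat < 1) & (n_obs > 0)
    if not poly.any():
        raise ValueError("no polymorphic SNPs in the PCA fitting subset")
    means = 2.0 * p_hat[poly]
    scales = np.sqrt(2.0 * p_hat[poly] * (1.0 - p_hat[poly]))

    X = _standardize_calls(fit_calls[:, poly], means, scales)
    Xc = X - X.mean(axis=0, keepdims=True)
    max_rank = min(Xc.shape)
    k = min(n_components, max_rank)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = (S ** 2).sum()
    var_ratio = (S[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    loadings = Vt[:k].T  # (m_poly, k)

    # project everyone (fit samples reproduce their scores exactly)
    X_all = _standardize_calls(d.calls[:, np.flatnonzero(poly)], means, scales)
    X_all = X_all - X.mean(axis=0, keepdims=True)
    scores = X_all @ loadings

    # expand loadings back to full SNP panel (zeros on monomorphic SNPs)
    full_load = np.zeros((d.n_snps, k))
    full_load[np.flatnonzero(poly)] = loadings
    full_means = np.full(d.n_snps, np.nan)
    full_means[np.flatnonzero(poly)] = means
    full_scales = np.full(d.n_snps, np.nan)
    full_scales[np.flatnonzero(poly)] = scales

    score_df = pd.DataFrame(scores, index=ids,
                            columns=[f"PC{i + 1}" for i in range(k)])
    return PcaResult(scores=score_df, variance_ratio=var_ratio, loadings=full_load,
                     snp_means=full_means, snp_scales=full_scales,
                     fitted_on=fit_ids if unrelated_only else None)


@dataclass
class AdmixtureQ:
    """Per-sample global ancestry proportions on the simplex."""

    q: pd.DataFrame                 # samples x K, indexed by sample_id
    sources: list[str]
    log_likelihood: np.ndarray      # per sample at convergence
    converged: np.ndarray           # per sample
    identifiable: bool = True


def supervised_admixture(d: GenotypeDataset, ref_freqs: pd.DataFrame,
                         max_iter: int = 1000, tol: float = 1e-6,
                         pseudocount: float = 0.5) -> AdmixtureQ:
    """Supervised ancestry-proportion estimation with fixed source frequencies.

    ``ref_freqs``: SNPs x K DataFrame of source alt-allele frequencies aligned
    to ``d.markers`` (rows in the same order; columns are source labels).
    Each individual's Q maximizes the binomial mixture likelihood
    sum_j [g_j log(sum_k q_k f_kj) + (2-g_j) log(sum_k q_k (1-f_kj))] via EM
    from a uniform start; the log-likelihood is non-decreasing by construction.
    Source frequencies are clipped away from {0,1} by a pseudocount.
    """
    sources = list(ref_freqs.columns)
    K = len(sources)
    if K < 2:
        raise ValueError("need >= 2 source populations")
    F = ref_freqs.to_numpy(dtype=float)  # (m, K)
    if F.shape[0] != d.n_snps:
        raise ValueError("ref_freqs rows must align with dataset markers")
    eps = pseudocount / (2.0 * d.n_samples + 1.0)
    F = np.clip(F, eps, 1.0 - eps)
    identifiable = bool(np.ptp(F, axis=1).max() > 1e-9)

    calls = d.calls
    n = d.n_samples
    Q = np.full((n, K), 1.0 / K)
    ll = np.full(n, -np.inf)
    converged = np.zeros(n, dtype=bool)
    G = calls.astype(float)
    obs = calls != MISSING
    Gm = np.where(obs, G, 0.0)
    Cm = np.where(obs, 2.0 - G, 0.0)

    for _ in range(max_iter):
        # mixture means per individual per SNP
        A = Q @ F.T            # (n, m): sum_k q_k f_kj
        B = Q @ (1.0 - F).T
        new_ll = (Gm * np.log(A) + Cm * np.log(B)).sum(axis=1)
        # EM responsibilities accumulated over alleles
        W_alt = Gm / A         # (n, m)
        W_ref = Cm / B
        num = Q * (W_alt @ F + W_ref @ (1.0 - F))   # (n, K)
        denom = (Gm + Cm).sum(axis=1, keepdims=True)
        Q_new = num / np.maximum(denom, 1e-300)
        Q_new /= Q_new.sum(axis=1, keepdims=True)
        delta = np.abs(Q_new - Q).max(axis=1)
        Q, ll = Q_new, new_ll
        converged |= delta < tol
        if converged.all():
            break

    qdf = pd.DataFrame(Q, index=d.samples["sample_id"], columns=sources)
    return AdmixtureQ(q=qdf, sources=sources, log_likelihood=ll,
                      converged=converged, identifiable=identifiable)
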