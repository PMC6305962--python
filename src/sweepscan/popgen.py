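"""Allele-frequency spectra, heterozygosity, LD pruning and inbreeding.

Implements the classical single-marker diversity statistics for SNP-array
cohorts: the five-bin MAF spectrum, per-sample observed heterozygosity
(N - O)/N, pairwise genotype-correlation LD (r^2), PLINK-style sliding-window
LD pruning (``--indep-pairwise``-like), the method-of-moments inbreeding
coefficient based on observed vs expected homozygosity, and the Hudson Fst
estimator between two populations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_qc import MISSING, GenotypeDataset

MAF_BIN_EDGES = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)
MAF_BIN_LABELS = ("[0.0,0.1]", "(0.1,0.2]", "(0.2,0.3]", "(0.3,0.4]", "(0.4,0.5]")


def allele_freq_table(d: GenotypeDataset) -> pd.DataFrame:
    """Per-SNP frequency table: p (ref), q (alt), maf, n_obs."""
    obs = d.calls != MISSING
    n_obs = obs.sum(axis=0)
    q = d.alt_frequencies()
    p = 1.0 - q
    return pd.DataFrame({
        "snp_id": d.markers["snp_id"],
        "p": p, "q": q,
        "maf": np.fmin(p, q),
        "n_obs": n_obs,
    })


def maf_spectrum(freqs: pd.DataFrame, groups: pd.Series | None = None) -> pd.DataFrame:
    """Proportion of SNPs per MAF bin, optionally per group.

    Bins are [0,0.1], (0.1,0.2], (0.2,0.3], (0.3,0.4], (0.4,0.5] — right
    closed, with the first bin closed at zero.  Proportions per group sum to 1.
    """
    maf = np.asarray(freqs["maf"], dtype=float)
    if np.any(maf < 0) or np.any(maf > 0.5 + 1e-12):
        raise ValueError("maf values must lie in [0, 0.5]")
    # np.digitize with right=True: values == 0.1 go to the first bin
    bin_idx = np.clip(np.digitize(maf, MAF_BIN_EDGES[1:], right=True), 0, 4)

    def _props(idx: np.ndarray) -> np.ndarray:
        counts = np.bincount(idx, minlength=5)
        return counts / counts.sum()

    if groups is None:
        return pd.DataFrame({"bin": MAF_BIN_LABELS, "proportion": _props(bin_idx)})
    groups = np.asarray(groups)
    rows = []
    for g in pd.unique(groups):
        sel = groups == g
        if not sel.any():
            raise ValueError(f"empty group {g!r}")
        for lab, prop in zip(MAF_BIN_LABELS, _props(bin_idx[sel])):
            rows.append({"group": g, "bin": lab, "proportion": prop})
    return pd.DataFrame(rows)


def observed_heterozygosity(d: GenotypeDataset) -> pd.DataFrame:
    """Per-sample observed heterozygosity (N - O)/N.

    N = non-missing genotypes, O = observed homozygotes.  Samples with no
    non-missing genotype are excluded (NaN row dropped with a note column).
    """
    calls = d.calls
    obs = calls != MISSING
    N = obs.sum(axis=1)
    het = (calls == 1).sum(axis=1)
    O = N - het
    with np.errstate(invalid="ignore", divide="ignore"):
        het_obs = np.where(N > 0, het / np.where(N > 0, N, 1), np.nan)
    out = pd.DataFrame({
        "sample_id": d.samples["sample_id"],
        "population": d.samples["population"],
        "n_obs": N, "n_hom": O, "het_obs": het_obs,
    })
    return out[out["n_obs"] > 0].reset_index(drop=True)


def het_population_summary(het: pd.DataFrame) -> pd.DataFrame:
    return (het.groupby("population")["het_obs"]
            .agg(["mean", "std", "count"]).reset_index())


def ld_r2(d: GenotypeDataset, snp_i: int, snp_j: int) -> float:
    """Squared Pearson correlation of alt-allele counts over jointly
    non-missing samples; NaN if either SNP is monomorphic in that set."""
    x = d.calls[:, snp_i].astype(float)
    y = d.calls[:, snp_j].astype(float)
    ok = (d.calls[:, snp_i] != MISSING) & (d.calls[:, snp_j] != MISSING)
    x, y = x[ok], y[ok]
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _pairwise_r2(calls: np.ndarray) -> np.ndarray:
    """All-pairs genotype r^2 for a small window, missing-aware."""
    m = calls.shape[1]
    obs = calls != MISSING
    if obs.all():  # complete window: one matrix correlation
        x = calls.astype(float)
        sd = x.std(axis=0)
        out = np.full((m, m), np.nan)
        ok = sd > 0
        if ok.sum() >= 2:
            with np.errstate(invalid="ignore"):
                r = np.corrcoef(x[:, ok].T)
            sub = r * r
            np.fill_diagonal(sub, np.nan)
            grid = np.ix_(np.flatnonzero(ok), np.flatnonzero(ok))
            out[grid] = sub
        return out
    out = np.full((m, m), np.nan)
    x = calls.astype(float)
    for i in range(m):
        for j in range(i + 1, m):
            ok = obs[:, i] & obs[:, j]
            xi, xj = x[ok, i], x[ok, j]
            if len(xi) < 2 or xi.std() == 0 or xj.std() == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            out[i, j] = out[j, i] = r * r
    return out


def ld_prune(d: GenotypeDataset, window: int = 50, step: int = 5,
             r2_max: float = 0.3) -> list[str]:
    """Sliding-window LD pruning: in each ``window``-SNP window (advancing by
    ``step``), while any retained pair has r^2 > ``r2_max``, drop the
    lower-MAF SNP of the pair (ties -> the later map position).  A SNP removed
    in any window stays removed.  Returns retained snp_ids in map order.
    """
    if not window > step >= 1:
        raise ValueError("require window > step >= 1")
    d = d.sort_by_position()
    freq = d.alt_frequencies()
    maf = np.fmin(freq, 1 - freq)
    snp_ids = d.markers["snp_id"].to_numpy()
    removed = np.zeros(d.n_snps, dtype=bool)
    for chrom, grp in d.markers.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        start = 0
        while True:
            win = idx[start:start + window]
            if len(win) >= 2:
                active = [int(k) for k in win if not removed[k]]
                r2 = _pairwise_r2(d.calls[:, active]) if len(active) >= 2 else None
                while len(active) >= 2:
                    ii, jj = np.unravel_index(np.nanargmax(np.nan_to_num(r2, nan=-1.0)),
                                              r2.shape)
                    if not (r2[ii, jj] > r2_max):
                        break
                    gi, gj = active[ii], active[jj]
                    # drop the lower-MAF member; tie -> later position
                    if maf[gi] < maf[gj]:
                        drop_local = ii
                    elif maf[gj] < maf[gi]:
                        drop_local = jj
                    else:
                        drop_local = ii if gi > gj else jj
                    removed[active[drop_local]] = True
                    del active[drop_local]
                    r2 = np.delete(np.delete(r2, drop_local, 0), drop_local, 1)
            if start + window >= len(idx):
                break
            start += step
    return [str(s) for s in snp_ids[~removed]]


def inbreeding_f(d: GenotypeDataset, pruned: list[str] | None = None) -> pd.DataFrame:
    """Method-of-moments inbreeding coefficient per sample.

    F_hat = (O - E)/(N - E) over the (optionally LD-pruned) SNP set, where O
    is the observed homozygote count, N the non-missing count, and
    E = sum_j [1 - 2 p_j q_j * 2n_j/(2n_j - 1)] the expected homozygote count
    under random mating with the small-sample correction, restricted to the
    sample's non-missing SNPs.  Inverts the relation
    P(hom) = f + (1 - f)(p^2 + q^2) at the moment level.
    """
    if pruned is not None:
        if len(pruned) == 0:
            raise ValueError("pruned SNP set is empty")
        keep = d.markers.set_index("snp_id").index.get_indexer(pruned)
        if (keep < 0).any():
            missing = [s for s, k in zip(pruned, keep) if k < 0]
            raise KeyError(f"pruned snp_ids not in dataset: {missing[:5]}")
        d = d.take_snps(keep)
    calls = d.calls
    obs = calls != MISSING
    n_j = obs.sum(axis=0)
    q = d.alt_frequencies()
    p = 1.0 - q
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(n_j > 0, 2.0 * n_j / np.maximum(2.0 * n_j - 1.0, 1.0), np.nan)
    e_hom_j = 1.0 - 2.0 * p * q * corr  # expected hom prob at SNP j
    usable = n_j > 0
    E = (obs[:, usable] * e_hom_j[usable]).sum(axis=1)
    N = obs[:, usable].sum(axis=1).astype(float)
    O = N - (calls[:, usable] == 1).sum(axis=1)
    denom = N - E
    with np.errstate(invalid="ignore", divide="ignore"):
        f_hat = np.where(np.abs(denom) > 1e-12, (O - E) / denom, np.nan)
    return pd.DataFrame({
        "sample_id": d.samples["sample_id"],
        "population": d.samples["population"],
        "n_obs": N.astype(int), "o_hom": O.astype(int), "e_hom": E,
        "f_hat": f_hat,
    })


def hudson_fst(d: GenotypeDataset, pop1: str, pop2: str) -> float:
    """Hudson's Fst (ratio-of-averages form) between two labelled populations.

    Per SNP: num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
             den = p1(1-p2) + p2(1-p1); Fst = sum(num)/sum(den) over SNPs
    with at least two observed allele copies in each population.
    """
    sub1 = d.subset_population(pop1)
    sub2 = d.subset_population(pop2)
    p1 = sub1.alt_frequencies()
    p2 = sub2.alt_frequencies()
    n1 = 2.0 * (sub1.calls != MISSING).sum(axis=0)
    n2 = 2.0 * (sub2.calls != MISSING).sum(axis=0)
    ok = (n1 > 1) & (n2 > 1) & ~np.isnan(p1) & ~np.isnan(p2)
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())
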